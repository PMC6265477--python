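"""Free-energy-surface reconstruction and minimum-free-energy-path analysis.

The free energy estimate is the standard metadynamics one: the negative of
the accumulated Gaussian bias, shifted so its minimum is zero.  Paths
between basins are bottleneck-optimal ("minimax") paths over the grid
graph: among all grid-adjacent routes they minimize the maximum free energy
en route, which is exactly the quantity that defines the barrier of a
minimum free energy path.  Grid adjacency includes diagonal neighbors.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .metad import HillsLog

__all__ = ["FESGrid", "PathResult", "MechanismReport", "default_axes",
           "reconstruct_fes", "slice_fes_2d", "find_basins", "minimax_path",
           "mechanism_order", "convergence_check"]


@dataclass
class FESGrid:
    """Free energies (kcal/mol) on a regular 1-3D grid over named CVs.

    ``axes`` holds ``(name, lo, hi, n_points)`` per CV; ``values`` has shape
    ``(n_1, ..., n_d)`` with the last axis fastest when flattened.  Values
    are normalized so the minimum is zero.
    """

    axes: list[tuple[str, float, float, int]]
    values: np.ndarray
    origin_log_hash: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        shape = tuple(n for _, _, _, n in self.axes)
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != axes {shape}")
        for name, lo, hi, n in self.axes:
            if hi <= lo or n < 2:
                raise ValueError(f"axis {name!r} must be strictly increasing")

    @property
    def dimension(self) -> int:
        return len(self.axes)

    @property
    def cv_names(self) -> list[str]:
        return [a[0] for a in self.axes]

    def axis_points(self, k: int) -> np.ndarray:
        _, lo, hi, n = self.axes[k]
        return np.linspace(lo, hi, n)

    def node_coords(self, node: tuple[int, ...]) -> np.ndarray:
        return np.array([self.axis_points(k)[i] for k, i in enumerate(node)])

    def nearest_node(self, s) -> tuple[int, ...]:
        s = np.atleast_1d(np.asarray(s, float))
        return tuple(int(np.argmin(np.abs(self.axis_points(k) - s[k])))
                     for k in range(self.dimension))


def default_axes(hills_log: HillsLog, resolution: float = 0.02,
                 pad_sigmas: float = 3.0) -> list[tuple[str, float, float, int]]:
    """Axes covering the hills' bounding box padded by ``pad_sigmas`` widths."""
    if len(hills_log) == 0:
        raise ValueError("empty log has no bounding box")
    c, w = hills_log.centers, hills_log.widths
    lo = c.min(axis=0) - pad_sigmas * w.max(axis=0)
    hi = c.max(axis=0) + pad_sigmas * w.max(axis=0)
    return [(name, float(l), float(h), int(np.ceil((h - l) / resolution)) + 1)
            for name, l, h in zip(hills_log.cv_names, lo, hi)]


def reconstruct_fes(hills_log: HillsLog,
                    axes: list[tuple[str, float, float, int]],
                    cutoff_sigmas: float = 6.0,
                    average_from: float | None = None) -> FESGrid:
    """F(s) = -V_bias(s) on the grid, minimum shifted to zero.

    Each hill is accumulated only within ``cutoff_sigmas`` of its center
    (relative error < 2e-8 of the hill height), which keeps reconstruction
    linear in the number of hills rather than hills x grid points.

    With ``average_from`` set to a fraction f in [0, 1), the estimate is
    instead the time average of -V_bias over the depositions after the
    first f of the log.  For fixed-height hills the instantaneous -V_bias
    oscillates around the true surface with an amplitude that does not
    decay; averaging over the post-fill depositions cancels those
    oscillations.  The average reduces to a per-hill height reweighting
    w_j = (n - max(j, n0)) / (n - n0) with n0 = floor(f n), so the default
    f = None (plain -V_bias) is the w_j = 1 special case.
    """
    if len(axes) != hills_log.dimension:
        raise ValueError("axes count must match log dimensionality")
    if len(axes) > 3:
        raise ValueError("only 1-3 dimensional grids are supported")
    n_hills = len(hills_log)
    if average_from is None:
        weights = np.ones(n_hills)
    else:
        if not 0.0 <= average_from < 1.0:
            raise ValueError("average_from must lie in [0, 1)")
        n0 = int(average_from * n_hills)
        weights = (n_hills - np.maximum(np.arange(n_hills), n0)) / (n_hills - n0)
    pts = [np.linspace(lo, hi, n) for _, lo, hi, n in axes]
    shape = tuple(n for _, _, _, n in axes)
    bias = np.zeros(shape)
    n_out = 0
    for weight, hill in zip(weights, hills_log.hills()):
        oneds, sls = [], []
        outside = False
        for k, ax in enumerate(pts):
            if not (axes[k][1] <= hill.center[k] <= axes[k][2]):
                outside = True
            i0 = max(0, int(np.searchsorted(ax, hill.center[k] - cutoff_sigmas * hill.widths[k])) - 1)
            i1 = min(len(ax), int(np.searchsorted(ax, hill.center[k] + cutoff_sigmas * hill.widths[k])) + 1)
            z = (ax[i0:i1] - hill.center[k]) / hill.widths[k]
            oneds.append(np.exp(-0.5 * z * z))
            sls.append(slice(i0, i1))
        n_out += outside
        h = weight * hill.height
        if len(axes) == 1:
            bias[sls[0]] += h * oneds[0]
        elif len(axes) == 2:
            bias[sls[0], sls[1]] += h * np.outer(oneds[0], oneds[1])
        else:
            bias[sls[0], sls[1], sls[2]] += h * np.einsum("i,j,k->ijk", *oneds)
    if len(hills_log) and n_out / len(hills_log) > 0.01:
        warnings.warn(f"{n_out} of {len(hills_log)} hill centers fall outside "
                      "the requested axes", stacklevel=2)
    values = -bias
    values -= values.min()
    return FESGrid(list(axes), values)


def slice_fes_2d(fes3d: FESGrid, axis_name: str, value: float):
    """Nearest-plane 2D slice; returns (slice_grid, global_offset)."""
    if fes3d.dimension != 3:
        raise ValueError("slice_fes_2d requires a 3D grid")
    names = fes3d.cv_names
    if axis_name not in names:
        raise ValueError(f"unknown axis {axis_name!r}; known axes: {names}")
    k = names.index(axis_name)
    _, lo, hi, _ = fes3d.axes[k]
    if not lo <= value <= hi:
        raise ValueError(f"value {value} outside axis range [{lo}, {hi}]")
    idx = int(np.argmin(np.abs(fes3d.axis_points(k) - value)))
    plane = np.take(fes3d.values, idx, axis=k)
    offset = float(plane.min())
    axes2d = [a for j, a in enumerate(fes3d.axes) if j != k]
    return FESGrid(axes2d, plane - offset), offset


def find_basins(fes: FESGrid) -> list[tuple[tuple[int, ...], float]]:
    """Strict local minima (plateaus merged) sorted by free energy."""
    v = fes.values
    if np.ptp(v) == 0:
        warnings.warn("flat surface: no basins", stacklevel=2)
        return []
    foot = np.ones((3,) * fes.dimension, dtype=bool)
    cand = v == ndimage.minimum_filter(v, footprint=foot, mode="nearest")
    labels, n_lab = ndimage.label(cand, structure=foot)
    basins = []
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        comp_val = float(v[comp].min())
        ring = ndimage.binary_dilation(comp, structure=foot) & ~comp
        if ring.any() and v[ring].min() <= comp_val:
            continue  # shelf attached to lower ground, not a basin
        node = tuple(int(i[0]) for i in np.nonzero(comp))
        basins.append((node, comp_val))
    basins.sort(key=lambda b: (b[1], b[0]))
    return basins


@dataclass
class PathResult:
    """Grid-adjacent path from reactant to product with its barrier."""

    nodes: list[tuple[int, ...]]
    free_energies: np.ndarray
    ts_index: int
    barrier: float
    reactant_node: tuple[int, ...]
    product_node: tuple[int, ...]


def _neighbors(shape):
    d = len(shape)
    offs = [o for o in itertools.product((-1, 0, 1), repeat=d) if any(o)]
    offs.sort()
    return offs


def _descend(v: np.ndarray, node: tuple[int, ...]) -> tuple[int, ...]:
    """Steepest-descent walk to the local minimum of the containing basin."""
    offs = _neighbors(v.shape)
    cur = node
    while True:
        best, best_val = cur, v[cur]
        for o in offs:
            nb = tuple(i + di for i, di in zip(cur, o))
            if all(0 <= i < n for i, n in zip(nb, v.shape)) and v[nb] < best_val:
                best, best_val = nb, v[nb]
        if best == cur:
            return cur
        cur = best


def minimax_path(fes: FESGrid, reactant_node, product_node) -> PathResult:
    """Bottleneck-optimal grid path (Dijkstra on the max-en-route metric).

    Ties are broken by shorter path, then by lexicographic node order.  The
    barrier is the path maximum measured from the reactant-basin minimum
    (steepest descent from ``reactant_node``).  NaN cells are impassable.
    """
    v = fes.values
    start, goal = tuple(reactant_node), tuple(product_node)
    for node in (start, goal):
        if not all(0 <= i < n for i, n in zip(node, v.shape)) or len(node) != v.ndim:
            raise ValueError(f"node {node} not on the grid")
        if np.isnan(v[node]):
            raise ValueError(f"node {node} lies in a NaN-masked region")
    offs = _neighbors(v.shape)
    best: dict[tuple, tuple[float, int]] = {start: (float(v[start]), 0)}
    parent: dict[tuple, tuple] = {}
    pq = [(float(v[start]), 0, start)]
    while pq:
        b, length, node = heapq.heappop(pq)
        if (b, length) > best.get(node, (np.inf, 0)):
            continue
        if node == goal:
            break
        for o in offs:
            nb = tuple(i + di for i, di in zip(node, o))
            if not all(0 <= i < n for i, n in zip(nb, v.shape)):
                continue
            val = v[nb]
            if np.isnan(val):
                continue
            cand = (max(b, float(val)), length + 1)
            if cand < best.get(nb, (np.inf, np.inf)):
                best[nb] = cand
                parent[nb] = node
                heapq.heappush(pq, (cand[0], cand[1], nb))
    if goal not in best or (goal != start and goal not in parent):
        raise ValueError(
            "no grid path between the requested nodes: the region between "
            "them is blocked by NaN-masked cells")
    nodes = [goal]
    while nodes[-1] != start:
        nodes.append(parent[nodes[-1]])
    nodes.reverse()
    fe = np.array([v[n] for n in nodes])
    ts = int(np.argmax(fe))
    ref = float(v[_descend(v, start)])
    return PathResult(nodes, fe, ts, float(fe.max() - ref), start, goal)


@dataclass
class MechanismReport:
    """Per-CV completion at the rate-limiting TS, plus a tightness call."""

    progress: dict[str, float]   # NaN marks a CV with no net displacement
    ordering: str
    tightness: str               # "tight" | "loose" | "indeterminate"


def mechanism_order(fes: FESGrid, path: PathResult,
                    transfer_cv: str | None = None,
                    partner_distance_sum: float | None = None,
                    partner_distance_threshold: float = 4.6) -> MechanismReport:
    """Fractional progress of every CV at the path's transition state.

    Progress of CV i is ``(s_TS - s_R) / (s_P - s_R)`` clipped to [0, 1],
    using the path's endpoint coordinates as reactant/product.  The
    tightness call is "tight" when the phosphoryl-transfer CV sits within
    the central 25% of its reactant-to-product range at the TS (and, when
    the sum of nucleophile/leaving-group distances from atomistic snapshots
    is supplied, that sum falls below the threshold); "loose" when the
    supplied distance sum exceeds the threshold; otherwise "indeterminate".
    """
    s_r = fes.node_coords(path.nodes[0])
    s_p = fes.node_coords(path.nodes[-1])
    s_ts = fes.node_coords(path.nodes[path.ts_index])
    steps = np.array([(hi - lo) / (n - 1) for _, lo, hi, n in fes.axes])
    progress: dict[str, float] = {}
    for k, name in enumerate(fes.cv_names):
        disp = s_p[k] - s_r[k]
        if abs(disp) < 0.5 * steps[k]:
            progress[name] = float("nan")
        else:
            progress[name] = float(np.clip((s_ts[k] - s_r[k]) / disp, 0.0, 1.0))
    ranked = sorted((n for n in progress if not np.isnan(progress[n])),
                    key=lambda n: -progress[n])
    ordering = " > ".join(f"{n} ({progress[n]:.2f})" for n in ranked) or "n/a"
    if transfer_cv is None:
        hits = [n for n in fes.cv_names if "transfer" in n.lower()]
        transfer_cv = hits[0] if hits else None
    tightness = "indeterminate"
    if transfer_cv is not None and transfer_cv in progress:
        p = progress[transfer_cv]
        central = not np.isnan(p) and abs(p - 0.5) <= 0.125
        if partner_distance_sum is not None:
            if partner_distance_sum >= partner_distance_threshold:
                tightness = "loose"
            elif central:
                tightness = "tight"
        elif central:
            tightness = "tight"
    return MechanismReport(progress, ordering, tightness)


def convergence_check(hills_log: HillsLog,
                      axes: list[tuple[str, float, float, int]],
                      split: float = 0.5) -> float:
    """Max |dF| between surfaces built from the two portions of the log."""
    if not 0.0 < split < 1.0:
        raise ValueError("split must lie in (0, 1)")
    n = len(hills_log)
    if n < 10:
        raise ValueError("need at least 10 hills for a convergence check")
    k = min(max(int(round(split * n)), 1), n - 1)
    first, second = HillsLog(hills_log.cv_names), HillsLog(hills_log.cv_names)
    for i, (hill, wid) in enumerate(zip(hills_log.hills(), hills_log.walker_ids)):
        (first if i < k else second).append(hill, wid)
    f1 = reconstruct_fes(first, axes)
    f2 = reconstruct_fes(second, axes)
    return float(np.abs(f1.values - f2.values).max())
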