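"""Solvation statistics around reference atoms.

Radial distribution functions g(r) with their running integrals (shell
occupancies), first-solvation-shell location/occupancy, and distance time
courses with mean and RMSF bands across independent trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .surfaces import HydrationSnapshotSet

__all__ = ["RDFResult", "FirstShell", "TimeCourse", "rdf",
           "first_shell_count", "distance_timecourse"]


@dataclass
class RDFResult:
    bin_centers: np.ndarray   # A
    g: np.ndarray             # dimensionless
    n_integrated: np.ndarray  # mean cumulative count within r
    n_frames: int
    density_bulk: float       # A^-3 used for normalization


def rdf(snapshots: HydrationSnapshotSet | Sequence[np.ndarray],
        centers: np.ndarray | None = None,
        r_max: float = 8.0, bin_width: float = 0.1,
        density_bulk: float | None = None) -> RDFResult:
    """Center-to-target g(r) and running coordination number.

    ``snapshots`` is either a :class:`HydrationSnapshotSet` or a list of
    point arrays with ``centers`` given per frame.  g(r) is the distance
    histogram normalized by the spherical shell volume ``4 pi r^2 dr`` and
    the bulk number density; when no density is supplied it is estimated
    from the outer 20% of ``r_max``.  ``n_integrated`` is the raw mean
    count within r (no density normalization).
    """
    if isinstance(snapshots, HydrationSnapshotSet):
        frames = snapshots.frames
        ctrs = snapshots.centers
        if density_bulk is None and snapshots.density_bulk > 0:
            density_bulk = snapshots.density_bulk
    else:
        frames = [np.asarray(f, float) for f in snapshots]
        if centers is None:
            raise ValueError("centers are required for raw frame lists")
        ctrs = np.atleast_2d(np.asarray(centers, float))
        if ctrs.shape[0] == 1:
            ctrs = np.tile(ctrs, (len(frames), 1))
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    for pts, c in zip(frames, ctrs):
        if len(pts):
            d = np.linalg.norm(pts - c, axis=1)
            hist += np.histogram(d, bins=edges)[0]
    hist /= len(frames)
    centers_r = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if density_bulk is None:
        outer = centers_r >= 0.8 * r_max
        density_bulk = float(hist[outer].sum() / shell_vol[outer].sum())
    if density_bulk > 0:
        g = hist / (shell_vol * density_bulk)
    else:
        g = np.zeros_like(hist)
    return RDFResult(centers_r, g, np.cumsum(hist), len(frames),
                     float(density_bulk))


@dataclass
class FirstShell:
    found: bool
    r_min: float | None = None   # first post-peak minimum of smoothed g, A
    count: float | None = None   # n_integrated at r_min


def first_shell_count(result: RDFResult, smooth_bins: int = 5,
                      min_prominence: float = 0.5) -> FirstShell:
    """Occupancy of the first solvation shell, or a no-shell outcome.

    g(r) is smoothed with a moving average and the first peak with relative
    prominence ``min_prominence * max(g)`` is located.  The shell boundary
    is the minimum of smoothed g between that peak and the next one (or the
    profile end); on a flat minimal plateau the plateau middle is used.
    Featureless (e.g. pure ideal-gas) profiles return ``found=False``.
    """
    g = result.g
    if len(g) < 2 * smooth_bins or np.all(g == 0):
        return FirstShell(False)
    kern = np.ones(smooth_bins) / smooth_bins
    gs = np.convolve(g, kern, mode="same")
    peaks, _ = find_peaks(gs, prominence=min_prominence * gs.max())
    if len(peaks) == 0:
        return FirstShell(False)
    p = peaks[0]
    end = peaks[1] if len(peaks) > 1 else len(gs)
    window = gs[p + 1:end]
    if window.size == 0 or window.min() >= gs[p]:
        return FirstShell(False)
    low = np.flatnonzero(window <= window.min() + 1e-12)
    run = low[:np.argmax(np.diff(low, prepend=low[0] - 1) > 1) or len(low)]
    m = p + 1 + int(run[len(run) // 2])
    return FirstShell(True, float(result.bin_centers[m]),
                      float(result.n_integrated[m]))


@dataclass
class TimeCourse:
    traces: np.ndarray       # (n_trajectories, n_frames) A
    mean_trace: np.ndarray   # pointwise mean across trajectories
    rmsf_trace: np.ndarray   # pointwise RMS deviation from the global mean
    n_trajectories: int


def distance_timecourse(trajectories: Sequence[np.ndarray],
                        atom_pair: tuple[int, int]) -> TimeCourse:
    """Distance traces for one atom pair across independent trajectories.

    ``trajectories`` are coordinate arrays of shape (n_frames, n_atoms, 3);
    unequal lengths are truncated to the shortest with a warning.  The RMSF
    band is the RMS deviation from the time-and-trajectory mean, computed
    pointwise across trajectories.
    """
    if len(trajectories) == 0:
        raise ValueError("need at least one trajectory")
    i, j = atom_pair
    lengths = [len(t) for t in trajectories]
    n = min(lengths)
    if len(set(lengths)) > 1:
        warnings.warn(f"unequal trajectory lengths {lengths}; truncating to {n}",
                      stacklevel=2)
    traces = np.stack([
        np.linalg.norm(np.asarray(t)[:n, i] - np.asarray(t)[:n, j], axis=1)
        for t in trajectories])
    grand_mean = traces.mean()
    rmsf = np.sqrt(np.mean((traces - grand_mean) ** 2, axis=0))
    return TimeCourse(traces, traces.mean(axis=0), rmsf, len(trajectories))
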