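"""Multi-walker metadynamics on model surfaces.

Dynamics run directly in collective-variable space: each walker is a
Langevin particle with a per-CV effective mass moving on
``surface.energy + V_bias``, where ``V_bias`` is the history-dependent sum
of repulsive Gaussians deposited by all walkers.  This preserves the
bias/free-energy mathematics of metadynamics exactly while replacing the
atomistic engine with a desk-scale surrogate.

Defaults follow common biased-sampling practice for reaction coordinates:
Gaussian hills of height 0.1 kcal/mol and width 0.1 A deposited every 200
steps of 0.5 fs dynamics, with all walkers pooling their hills at
deposition time.

Integrator: BAOAB splitting (kick - drift - Ornstein-Uhlenbeck - drift -
kick), reflecting walls at the surface's domain box.  During dynamics the
bias force is looked up on an accumulation grid (spacing ``hill_width/2.5``)
for speed; the public :func:`bias_energy` / :func:`bias_force` and all
free-energy reconstruction remain exact Gaussian sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surfaces import ModelSurface

__all__ = ["Hill", "HillsLog", "SamplerConfig", "bias_energy", "bias_force",
           "run_walker", "run_multiwalker", "MultiWalkerResult"]

KCAL_TO_MD = 418.4        # kcal/mol -> amu A^2 / ps^2
R_KCAL = 1.987204259e-3   # gas constant, kcal / (mol K)


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian bias hill."""

    time: float                 # ps
    center: np.ndarray          # (d,) A
    widths: np.ndarray          # (d,) sigma, A
    height: float               # kcal/mol
    bias_factor: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "center", np.atleast_1d(np.asarray(self.center, float)))
        object.__setattr__(self, "widths", np.atleast_1d(np.asarray(self.widths, float)))
        if np.any(self.widths <= 0):
            raise ValueError("hill widths must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")


class HillsLog:
    """Time-ordered record of deposited hills over named CVs."""

    def __init__(self, cv_names):
        self.cv_names = list(cv_names)
        self.times: list[float] = []
        self._centers: list[np.ndarray] = []
        self._widths: list[np.ndarray] = []
        self.heights: list[float] = []
        self.bias_factors: list[float | None] = []
        self.walker_ids: list[int] = []

    @property
    def dimension(self) -> int:
        return len(self.cv_names)

    def __len__(self) -> int:
        return len(self.times)

    def append(self, hill: Hill, walker_id: int = 0) -> None:
        if hill.center.shape != (self.dimension,):
            raise ValueError("hill dimensionality does not match cv_names")
        if self.times:
            mine = [t for t, w in zip(self.times, self.walker_ids) if w == walker_id]
            if mine and hill.time < mine[-1]:
                raise ValueError("times must be non-decreasing within a walker")
        self.times.append(float(hill.time))
        self._centers.append(hill.center)
        self._widths.append(hill.widths)
        self.heights.append(float(hill.height))
        self.bias_factors.append(hill.bias_factor)
        self.walker_ids.append(int(walker_id))

    @property
    def centers(self) -> np.ndarray:
        return (np.array(self._centers) if self._centers
                else np.empty((0, self.dimension)))

    @property
    def widths(self) -> np.ndarray:
        return (np.array(self._widths) if self._widths
                else np.empty((0, self.dimension)))

    def hills(self):
        for t, c, w, h, bf in zip(self.times, self._centers, self._widths,
                                  self.heights, self.bias_factors):
            yield Hill(t, c, w, h, bf)

    def extend(self, other: "HillsLog") -> "HillsLog":
        if other.cv_names != self.cv_names:
            raise ValueError("cv name mismatch")
        for hill, wid in zip(other.hills(), other.walker_ids):
            self.append(hill, wid)
        return self


def bias_energy(hills_log: HillsLog, s) -> np.ndarray | float:
    """Exact metadynamics bias V(s) = sum_i h_i exp(-sum_d (s-c)^2/(2 sigma^2))."""
    s = np.asarray(s, dtype=float)
    scalar_in = s.ndim <= 1
    pts = np.atleast_2d(s)
    if pts.shape[-1] != hills_log.dimension:
        raise ValueError(f"point dimension {pts.shape[-1]} does not match "
                         f"log dimension {hills_log.dimension}")
    if len(hills_log) == 0:
        out = np.zeros(pts.shape[0])
        return float(out[0]) if scalar_in else out.reshape(s.shape[:-1])
    c, w = hills_log.centers, hills_log.widths
    h = np.asarray(hills_log.heights)
    out = np.zeros(pts.shape[0])
    for lo in range(0, len(h), 4096):
        hi = lo + 4096
        z = (pts[:, None, :] - c[None, lo:hi, :]) / w[None, lo:hi, :]
        out += np.einsum("j,pj->p", h[lo:hi], np.exp(-0.5 * np.sum(z * z, axis=-1)))
    return float(out[0]) if scalar_in else out.reshape(s.shape[:-1])


def bias_force(hills_log: HillsLog, s) -> np.ndarray:
    """Negative gradient of :func:`bias_energy` (kcal/mol/A), exact."""
    s = np.asarray(s, dtype=float)
    scalar_in = s.ndim <= 1
    pts = np.atleast_2d(s)
    if pts.shape[-1] != hills_log.dimension:
        raise ValueError("dimension mismatch")
    out = np.zeros_like(pts)
    if len(hills_log):
        c, w = hills_log.centers, hills_log.widths
        h = np.asarray(hills_log.heights)
        for lo in range(0, len(h), 4096):
            hi = lo + 4096
            dz = pts[:, None, :] - c[None, lo:hi, :]
            z = dz / w[None, lo:hi, :]
            e = h[lo:hi] * np.exp(-0.5 * np.sum(z * z, axis=-1))   # (p, j)
            out += np.einsum("pj,pjd->pd", e, dz / w[None, lo:hi, :] ** 2)
    return out[0] if scalar_in else out.reshape(s.shape)


@dataclass
class SamplerConfig:
    """Langevin/metadynamics parameters (units: fs, K, ps^-1, amu, kcal/mol, A)."""

    timestep: float = 0.5          # fs
    temperature: float = 298.15    # K
    friction: float = 10.0         # ps^-1
    masses: float | np.ndarray = 50.0   # amu per CV
    hill_height: float = 0.1       # kcal/mol
    hill_width: float = 0.1        # A
    pace: int = 200                # steps between depositions
    n_walkers: int = 1
    steps_per_walker: int = 10_000
    seed: int = 0
    save_stride: int | None = None  # defaults to pace
    bias_factor: float | None = None  # well-tempered when set (> 1)

    def __post_init__(self):
        if min(self.timestep, self.friction, self.hill_width) <= 0:
            raise ValueError("timestep, friction and hill_width must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.pace < 1 or self.n_walkers < 1 or self.steps_per_walker < 1:
            raise ValueError("pace, n_walkers, steps_per_walker must be >= 1")
        if self.hill_height < 0:
            raise ValueError("hill_height must be non-negative")


class _BiasGrid:
    """Grid accumulation of the bias and its gradient for fast force lookup."""

    def __init__(self, box: np.ndarray, spacing: float):
        self.lo = box[:, 0].astype(float)
        self.hi = box[:, 1].astype(float)
        self.n = np.maximum(((self.hi - self.lo) / spacing).astype(int) + 2, 4)
        self.axes = [np.linspace(lo, hi, n)
                     for lo, hi, n in zip(self.lo, self.hi, self.n)]
        self.dx = np.array([ax[1] - ax[0] for ax in self.axes])
        self.energy = np.zeros(tuple(self.n))
        self.grad = [np.zeros(tuple(self.n)) for _ in self.n]

    def deposit(self, center, widths, height):
        d = len(self.n)
        oneds, donds, sls = [], [], []
        for k in range(d):
            ax = self.axes[k]
            i0 = max(0, int(np.searchsorted(ax, center[k] - 6 * widths[k])) - 1)
            i1 = min(len(ax), int(np.searchsorted(ax, center[k] + 6 * widths[k])) + 1)
            z = (ax[i0:i1] - center[k]) / widths[k]
            g = np.exp(-0.5 * z * z)
            oneds.append(g)
            donds.append(-g * z / widths[k])
            sls.append(slice(i0, i1))
        if d == 1:
            self.energy[sls[0]] += height * oneds[0]
            self.grad[0][sls[0]] += height * donds[0]
        elif d == 2:
            self.energy[sls[0], sls[1]] += height * np.outer(oneds[0], oneds[1])
            self.grad[0][sls[0], sls[1]] += height * np.outer(donds[0], oneds[1])
            self.grad[1][sls[0], sls[1]] += height * np.outer(oneds[0], donds[1])
        else:
            e = height * np.einsum("i,j,k->ijk", oneds[0], oneds[1], oneds[2])
            self.energy[sls[0], sls[1], sls[2]] += e
            self.grad[0][sls[0], sls[1], sls[2]] += height * np.einsum(
                "i,j,k->ijk", donds[0], oneds[1], oneds[2])
            self.grad[1][sls[0], sls[1], sls[2]] += height * np.einsum(
                "i,j,k->ijk", oneds[0], donds[1], oneds[2])
            self.grad[2][sls[0], sls[1], sls[2]] += height * np.einsum(
                "i,j,k->ijk", oneds[0], oneds[1], donds[2])

    def force(self, pts: np.ndarray) -> np.ndarray:
        """Nearest-node bias force, -grad V_bias, for points (w, d)."""
        idx = tuple(
            np.clip(np.rint((pts[:, k] - self.lo[k]) / self.dx[k]).astype(int),
                    0, self.n[k] - 1)
            for k in range(len(self.n)))
        return -np.stack([g[idx] for g in self.grad], axis=-1)

    def energy_at(self, pts: np.ndarray) -> np.ndarray:
        idx = tuple(
            np.clip(np.rint((pts[:, k] - self.lo[k]) / self.dx[k]).astype(int),
                    0, self.n[k] - 1)
            for k in range(len(self.n)))
        return self.energy[idx]


@dataclass
class MultiWalkerResult:
    log: HillsLog
    trajectories: np.ndarray  # (n_walkers, n_saved, d)
    config: SamplerConfig


def _engine(surface: ModelSurface, config: SamplerConfig, n_walkers: int,
            initial_s: np.ndarray, shared_log: HillsLog | None,
            walker_id_offset: int = 0) -> MultiWalkerResult:
    d = surface.dimension
    box = np.asarray(surface.domain_box, dtype=float)
    x = np.array(initial_s, dtype=float).reshape(n_walkers, d).copy()
    if np.any(x < box[:, 0]) or np.any(x > box[:, 1]):
        raise ValueError("initial_s outside the surface domain box")

    dt = config.timestep * 1e-3  # ps
    m = np.broadcast_to(np.asarray(config.masses, float), (d,))
    gamma = config.friction
    kbt_md = R_KCAL * config.temperature * KCAL_TO_MD
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kbt_md / m * (1.0 - c1 * c1))

    log = shared_log if shared_log is not None else HillsLog(surface.cv_names)
    grid = _BiasGrid(box, config.hill_width / 2.5)
    for hill in log.hills():
        grid.deposit(hill.center, hill.widths, hill.height)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    stride = config.save_stride or config.pace
    n_saved = config.steps_per_walker // stride + 1
    traj = np.empty((n_walkers, n_saved, d))
    traj[:, 0] = x
    widths = np.full(d, config.hill_width)
    v = rng.normal(size=(n_walkers, d)) * np.sqrt(kbt_md / m)
    force = -surface.gradient(x) * KCAL_TO_MD + grid.force(x) * KCAL_TO_MD
    if config.temperature == 0:
        v[:] = 0.0

    isave = 1
    for step in range(1, config.steps_per_walker + 1):
        v += 0.5 * dt * force / m
        x += 0.5 * dt * v
        if config.temperature > 0:
            v = c1 * v + c2 * rng.normal(size=(n_walkers, d))
        else:
            v *= c1
        x += 0.5 * dt * v
        # reflecting walls
        for k in range(d):
            low, high = box[k]
            under = x[:, k] < low
            over = x[:, k] > high
            x[under, k] = 2 * low - x[under, k]
            x[over, k] = 2 * high - x[over, k]
            flip = under | over
            v[flip, k] *= -1.0
            np.clip(x[:, k], low, high, out=x[:, k])
        if config.hill_height > 0 and step % config.pace == 0:
            t_ps = step * dt
            heights = np.full(n_walkers, config.hill_height)
            if config.bias_factor is not None:
                dT = (config.bias_factor - 1.0) * R_KCAL * config.temperature
                heights *= np.exp(-grid.energy_at(x) / dT)
            for w in range(n_walkers):
                log.append(Hill(t_ps, x[w].copy(), widths, float(heights[w]),
                                config.bias_factor), walker_id_offset + w)
                grid.deposit(x[w], widths, heights[w])
        e = surface.energy(x)
        if np.any(~np.isfinite(e)):
            raise FloatingPointError(f"non-finite energy at step {step}")
        force = -surface.gradient(x) * KCAL_TO_MD + grid.force(x) * KCAL_TO_MD
        v += 0.5 * dt * force / m
        if step % stride == 0:
            traj[:, isave] = x
            isave += 1
    return MultiWalkerResult(log, traj[:, :isave], config)


def run_walker(surface: ModelSurface, config: SamplerConfig, initial_s,
               shared_log: HillsLog | None = None):
    """Single-walker metadynamics; returns (trajectory (n_saved, d), log)."""
    initial = np.atleast_1d(np.asarray(initial_s, float)).reshape(1, -1)
    res = _engine(surface, config, 1, initial, shared_log)
    return res.trajectories[0], res.log


def run_multiwalker(surface: ModelSurface, config: SamplerConfig,
                    initial_s=None) -> MultiWalkerResult:
    """Walkers sharing one hills log, pooled at every deposition.

    All walkers are advanced synchronously from a common seeded generator,
    so runs are reproducible for a fixed config.  By default every walker
    starts at the surface's first listed feature (the reactant minimum).
    """
    n = config.n_walkers
    if initial_s is None:
        start = surface.known_features[0][1]
        initial = np.tile(np.asarray(start, float), (n, 1))
    else:
        initial = np.asarray(initial_s, float)
        if initial.ndim == 1:
            initial = np.tile(initial, (n, 1))
    return _engine(surface, config, n, initial, None)
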