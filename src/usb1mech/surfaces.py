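"""Synthetic model systems with analytically known ground truth.

Every downstream stage of the toolkit (biased sampling, free-energy
reconstruction, path analysis, solvation statistics, rate fitting) is
validated against generators defined here.  The generators replace the
atomistic/electronic-structure layer of a real enzyme simulation with
closed-form model potentials, toy atom clusters and seeded random data whose
true basins, saddles, shell occupancies and kinetic parameters are known
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModelSurface",
    "ToyCluster",
    "HydrationSnapshotSet",
    "KineticsSample",
    "make_double_well",
    "make_harmonic",
    "make_mechanism_surface",
    "make_toy_reaction_cluster",
    "sample_hydration_shell",
    "generate_mm_kinetics",
    "MM_SUBSTRATE_UM",
]

#: Default substrate dilution series (uM) used for single-cleavage kinetics.
MM_SUBSTRATE_UM = (0.85, 1.7, 3.4, 6.8, 13.7, 27.5, 55.0)


@dataclass
class ModelSurface:
    """Analytic energy surface over 1-3 collective variables.

    ``energy`` and ``gradient`` accept arrays of shape ``(..., dimension)``
    and return shapes ``(...)`` and ``(..., dimension)`` respectively.
    ``known_features`` lists exact critical points as
    ``(label, cv_vector, energy)``; the analytic gradient vanishes at each.
    Energies are in kcal/mol, CVs in the same length units as the sampler
    (Angstrom for stretch-type CVs).
    """

    dimension: int
    cv_names: list[str]
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    known_features: list[tuple[str, np.ndarray, float]]
    domain_box: np.ndarray  # (dimension, 2)

    def feature(self, label: str) -> tuple[np.ndarray, float]:
        for name, s, e in self.known_features:
            if name == label:
                return np.asarray(s, dtype=float), float(e)
        raise KeyError(f"no feature labelled {label!r}")


def _as_points(s: np.ndarray, dim: int) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape == () and dim == 1:
        s = s.reshape(1)
    if s.shape[-1] != dim:
        raise ValueError(f"expected trailing axis of size {dim}, got shape {s.shape}")
    return s


def make_double_well(barrier: float, separation: float) -> ModelSurface:
    """Symmetric 1D double well V(x) = barrier * ((2x/separation)^2 - 1)^2.

    Minima at x = +-separation/2 with V = 0; saddle at x = 0 with
    V = barrier.  The standard oracle for barrier-recovery tests.
    """
    if barrier <= 0 or separation <= 0:
        raise ValueError("barrier and separation must be positive")
    a = separation / 2.0

    def energy(s):
        s = _as_points(s, 1)
        x = s[..., 0]
        return barrier * ((x / a) ** 2 - 1.0) ** 2

    def gradient(s):
        s = _as_points(s, 1)
        x = s[..., 0]
        g = barrier * 2.0 * ((x / a) ** 2 - 1.0) * (2.0 * x / a**2)
        return g[..., None]

    feats = [
        ("reactant", np.array([-a]), 0.0),
        ("ts", np.array([0.0]), float(barrier)),
        ("product", np.array([a]), 0.0),
    ]
    box = np.array([[-separation, separation]], dtype=float)
    return ModelSurface(1, ["x"], energy, gradient, feats, box)


def make_harmonic(k: float | Sequence[float], dimension: int = 1) -> ModelSurface:
    """Isotropic (or per-axis) harmonic well V = sum_i k_i s_i^2 / 2."""
    kvec = np.broadcast_to(np.asarray(k, dtype=float), (dimension,)).copy()
    if np.any(kvec <= 0):
        raise ValueError("force constants must be positive")

    def energy(s):
        s = _as_points(s, dimension)
        return 0.5 * np.sum(kvec * s**2, axis=-1)

    def gradient(s):
        s = _as_points(s, dimension)
        return kvec * s

    feats = [("minimum", np.zeros(dimension), 0.0)]
    box = np.tile([[-10.0, 10.0]], (dimension, 1))
    return ModelSurface(dimension, [f"s{i}" for i in range(dimension)],
                        energy, gradient, feats, box)


# -- three-coordinate mechanism surface --------------------------------------
#
# CVs mirror the antisymmetric-stretch reaction coordinates of a
# two-histidine transphosphorylation: nucleophile deprotonation (x),
# phosphoryl transfer (y) and leaving-group protonation (z), each running
# from -R0 (reactant) to +R0 (product).  The surface is built so the minimum
# free energy path first completes the deprotonation (uphill by
# ``deprotonation_cost`` to a shoulder with no appreciable reverse barrier)
# and then moves transfer and protonation concertedly through a single
# rate-limiting saddle ``main_barrier`` above the reactant minimum.

_R0 = 0.8  # Angstrom; basin CV value, matches the toy-cluster construction


def _smoothstep5(u: np.ndarray) -> np.ndarray:
    """C2 quintic smoothstep clamped to [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _smoothstep5_d(u: np.ndarray) -> np.ndarray:
    inside = (u > 0.0) & (u < 1.0)
    uc = np.clip(u, 0.0, 1.0)
    d = 30.0 * uc**2 * (1.0 - uc) ** 2
    return np.where(inside, d, 0.0)


def make_mechanism_surface(
    deprotonation_cost: float = 6.0,
    main_barrier: float = 21.6,
    asynchronicity: float = 0.0,
) -> ModelSurface:
    """3D model surface with a sequential-then-concerted mechanism.

    Parameters
    ----------
    deprotonation_cost:
        Free energy (kcal/mol) of the deprotonated shoulder above the
        reactant minimum.  Must satisfy 0 < cost < barrier.
    main_barrier:
        Height (kcal/mol) of the single rate-limiting saddle above the
        reactant minimum.
    asynchronicity:
        Shifts the saddle off the transfer/protonation diagonal: at the
        saddle the protonation CV leads the transfer CV by
        ``2*asynchronicity`` Angstrom.  Zero gives a perfectly synchronous
        saddle.  |asynchronicity| must stay below 0.48 for the progress
        fractions to remain inside (0.2, 0.8).

    The listed ``known_features`` (reactant, shoulder, ts, product) are
    exact critical points of the analytic form.
    """
    d, B, a = float(deprotonation_cost), float(main_barrier), float(asynchronicity)
    if not 0.0 < d < B:
        raise ValueError("require 0 < deprotonation_cost < main_barrier")
    if abs(a) >= _R0:
        raise ValueError("asynchronicity magnitude must be < 0.8")
    R = _R0
    bx = min(0.5, d / 4.0)       # small x-confinement double well
    c_ord = B                    # ordering coupling strength
    kap = 4.0 * (B - d) / R**2   # transverse confinement

    def _terms(s):
        s = _as_points(s, 3)
        x, y, z = s[..., 0], s[..., 1], s[..., 2]
        q = 0.5 * (y + z)
        r = 0.5 * (z - y)
        u = (x + R) / (2.0 * R)
        h = _smoothstep5(u)
        return x, y, z, q, r, u, h

    def _m(q):
        inside = np.abs(q) <= R
        return np.where(inside, np.cos(np.pi * q / (2.0 * R)) ** 2, 0.0)

    def _m_d(q):
        inside = np.abs(q) <= R
        return np.where(inside, -np.sin(np.pi * q / R) * np.pi / (2.0 * R), 0.0)

    def energy(s):
        x, y, z, q, r, u, h = _terms(s)
        vx = d * h + bx * ((x / R) ** 2 - 1.0) ** 2
        w = (B - d) * ((q / R) ** 2 - 1.0) ** 2
        t = 0.5 * kap * (r - a * _m(q)) ** 2
        ucpl = c_ord * (1.0 - h) * (q + R) ** 2
        return vx + w + t + ucpl

    def gradient(s):
        x, y, z, q, r, u, h = _terms(s)
        hd = _smoothstep5_d(u) / (2.0 * R)
        dvx = d * hd + bx * 2.0 * ((x / R) ** 2 - 1.0) * (2.0 * x / R**2)
        dw = (B - d) * 2.0 * ((q / R) ** 2 - 1.0) * (2.0 * q / R**2)
        dev = r - a * _m(q)
        dt_dq = kap * dev * (-a * _m_d(q))
        dt_dr = kap * dev
        du_dx = -c_ord * hd * (q + R) ** 2
        du_dq = 2.0 * c_ord * (1.0 - h) * (q + R)
        gx = dvx + du_dx
        gq = dw + dt_dq + du_dq
        gr = dt_dr
        gy = 0.5 * gq - 0.5 * gr
        gz = 0.5 * gq + 0.5 * gr
        return np.stack([gx, gy, gz], axis=-1)

    feats = [
        ("reactant", np.array([-R, -R, -R]), 0.0),
        ("shoulder", np.array([R, -R, -R]), d),
        ("ts", np.array([R, -a, a]), B),
        ("product", np.array([R, R, R]), d),
    ]
    box = np.tile([[-1.15, 1.15]], (3, 1))
    names = ["Nucleophile Deprotonation", "Phosphoryl Transfer",
             "Leaving Group Protonation"]
    return ModelSurface(3, names, energy, gradient, feats, box)


# -- toy reaction cluster ----------------------------------------------------

TOY_ATOM_LABELS = ["O2p", "H2p", "NE2_120", "P", "O5p", "NE2_208", "HE2_208",
                   "O1P", "O2P"]


@dataclass
class ToyCluster:
    """Nine named atoms interpolating a transphosphorylation geometry.

    At ``progress = 0`` each transferring atom sits 1.0 A from its donor and
    1.8 A from its acceptor; at ``progress = 1`` those distances are
    swapped, so each antisymmetric-stretch CV sweeps -0.8 -> +0.8 A.
    """

    atom_labels: list[str]
    coords: np.ndarray  # (9, 3) Angstrom
    progress: float

    def index(self, label: str) -> int:
        return self.atom_labels.index(label)


def make_toy_reaction_cluster(progress: float) -> ToyCluster:
    p = float(progress)
    if not 0.0 <= p <= 1.0:
        raise ValueError("progress must lie in [0, 1]")
    near, far = 1.0 + 0.8 * p, 1.8 - 0.8 * p
    # deprotonation triple along +x
    o2p = np.array([0.0, 0.0, 0.0])
    h2p = np.array([near, 0.0, 0.0])
    ne2_120 = np.array([2.8, 0.0, 0.0])
    # phosphoryl triple along +y (shares O2p); d(O2p,P) shrinks 1.8 -> 1.0
    pa = np.array([0.0, far, 0.0])
    o5p = np.array([0.0, 2.8, 0.0])
    # leaving-group triple along +z from O5p; d(HE2,O5p) shrinks 1.8 -> 1.0
    he2 = np.array([0.0, 2.8, far])
    ne2_208 = np.array([0.0, 2.8, 2.8])
    # non-bridging oxygens flanking P
    o1p = pa + np.array([1.5, 0.0, 0.0])
    o2p_nb = pa + np.array([-1.5, 0.0, 0.0])
    coords = np.stack([o2p, h2p, ne2_120, pa, o5p, ne2_208, he2, o1p, o2p_nb])
    return ToyCluster(list(TOY_ATOM_LABELS), coords, p)


# -- hydration snapshots -----------------------------------------------------


@dataclass
class HydrationSnapshotSet:
    """Frames of solvent-oxygen positions around a fixed reference center."""

    frames: list[np.ndarray]      # each (Ni, 3) Angstrom
    centers: np.ndarray           # (n_frames, 3)
    box: float | None             # cubic edge length, Angstrom
    density_bulk: float           # number density, A^-3
    seed: int


def sample_hydration_shell(
    n_shell: int,
    r_shell: float,
    density_bulk: float,
    n_frames: int,
    seed: int,
    box: float = 16.0,
) -> HydrationSnapshotSet:
    """Planted first solvation shell plus an ideal-gas background.

    Each frame carries exactly ``n_shell`` points at ``r_shell +- 0.05`` A
    from the center plus uniform background at ``density_bulk`` excluded
    from a sphere of radius ``r_shell + 1`` A.  The center sits at the box
    middle so shells out to ``box/2`` are volume-complete.
    """
    if n_shell < 0 or r_shell <= 0 or n_frames < 1:
        raise ValueError("require n_shell >= 0, r_shell > 0, n_frames >= 1")
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2.0) if density_bulk > 0 else np.zeros(3)
    use_box = box if density_bulk > 0 else None
    frames = []
    excl = r_shell + 1.0
    for _ in range(n_frames):
        pts = []
        if n_shell:
            v = rng.normal(size=(n_shell, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            radii = r_shell + rng.uniform(-0.05, 0.05, size=n_shell)
            pts.append(center + v * radii[:, None])
        if density_bulk > 0:
            n_bg = rng.poisson(density_bulk * box**3)
            bg = rng.uniform(0.0, box, size=(n_bg, 3))
            keep = np.linalg.norm(bg - center, axis=1) > excl
            pts.append(bg[keep])
        frames.append(np.concatenate(pts) if pts else np.empty((0, 3)))
    centers = np.tile(center, (n_frames, 1))
    return HydrationSnapshotSet(frames, centers, use_box, density_bulk, seed)


# -- Michaelis-Menten data ---------------------------------------------------


@dataclass
class KineticsSample:
    """Replicated initial-rate measurements with recorded ground truth."""

    substrate_concentrations: np.ndarray  # (nS,) uM
    velocities: np.ndarray                # (nS, replicates) uM/s
    enzyme_concentration: float           # uM
    truth: tuple[float, float]            # (kcat s^-1, Km uM)
    noise_sd: float                       # uM/s
    seed: int | None = None


def generate_mm_kinetics(
    kcat: float,
    Km: float,
    E0: float,
    S: Sequence[float] = MM_SUBSTRATE_UM,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int | None = None,
) -> KineticsSample:
    """Noisy saturation-kinetics data v = kcat*E0*S/(Km+S) + N(0, sd), v >= 0."""
    S = np.asarray(S, dtype=float)
    if kcat <= 0 or Km <= 0 or E0 <= 0 or np.any(S <= 0):
        raise ValueError("rates and concentrations must be positive")
    v_true = kcat * E0 * S / (Km + S)
    v = np.tile(v_true[:, None], (1, replicates))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = np.clip(v + rng.normal(0.0, noise_sd, size=v.shape), 0.0, None)
    return KineticsSample(S, v, float(E0), (float(kcat), float(Km)),
                          float(noise_sd), seed)
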