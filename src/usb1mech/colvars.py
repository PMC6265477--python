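"""Reaction coordinates on atomic coordinates.

Three CV kinds are supported, all carrying length units (Angstrom):

* ``antisym_stretch`` -- d(A,H) - d(H,B) for a proton (or phosphoryl group)
  H transferring from donor A to acceptor B.  Negative in the reactant
  (H bonded to A), positive in the product.
* ``relay_zeta`` -- average of two consecutive antisymmetric stretches for a
  donor -> shuttle -> acceptor proton relay.  This is a deliberate
  simplification of the center-of-excess-charge coordinate used for
  triester-like mechanisms: it preserves the relay topology and
  monotonicity but not the literal charge-weighted form.
* ``distance`` -- plain Euclidean distance, for monitoring contacts.

All gradients are analytic and returned per atom; entries for atoms outside
the CV's index set are zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["CVSpec", "CVValue", "antisym_stretch", "relay_zeta",
           "distance_cv", "evaluate_cvs"]

_KIND_NATOMS = {"antisym_stretch": 3, "relay_zeta": 5, "distance": 2}


@dataclass(frozen=True)
class CVSpec:
    """Declaration of one collective variable over a coordinate set."""

    kind: str
    atom_indices: tuple[int, ...]
    label: str

    def __post_init__(self):
        if self.kind not in _KIND_NATOMS:
            raise ValueError(f"unknown CV kind {self.kind!r}; "
                             f"choose from {sorted(_KIND_NATOMS)}")
        n = _KIND_NATOMS[self.kind]
        if len(self.atom_indices) != n:
            raise ValueError(f"{self.kind} needs exactly {n} atom indices")
        if len(set(self.atom_indices)) != n:
            raise ValueError("atom indices must be distinct")


@dataclass
class CVValue:
    label: str
    value: float                      # Angstrom
    gradient: np.ndarray | None = None  # (n_atoms, 3), A/A


def _dist_and_unit(coords, i, j):
    rij = coords[i] - coords[j]
    d = float(np.linalg.norm(rij))
    if d == 0.0:
        raise ValueError(f"coincident atoms {i} and {j}")
    return d, rij / d


def antisym_stretch(coords: np.ndarray, A: int, H: int, B: int,
                    label: str = "antisym") -> CVValue:
    """d(A,H) - d(H,B) with analytic per-atom gradient."""
    coords = np.asarray(coords, dtype=float)
    if len({A, H, B}) != 3:
        raise ValueError("atoms must be distinct")
    dAH, uAH = _dist_and_unit(coords, A, H)   # unit from H toward A
    dHB, uHB = _dist_and_unit(coords, B, H)   # unit from H toward B
    grad = np.zeros_like(coords)
    grad[A] = uAH
    grad[B] = -uHB
    grad[H] = -uAH + uHB
    return CVValue(label, dAH - dHB, grad)


def relay_zeta(coords: np.ndarray, D: int, H1: int, S: int, H2: int, A: int,
               label: str = "zeta") -> CVValue:
    """Relay-average coordinate: mean of the two component stretches."""
    if len({D, H1, S, H2, A}) != 5:
        raise ValueError("atoms must be distinct")
    c1 = antisym_stretch(coords, D, H1, S)
    c2 = antisym_stretch(coords, S, H2, A)
    return CVValue(label, 0.5 * (c1.value + c2.value),
                   0.5 * (c1.gradient + c2.gradient))


def distance_cv(coords: np.ndarray, i: int, j: int,
                label: str = "distance") -> CVValue:
    coords = np.asarray(coords, dtype=float)
    if i == j:
        raise ValueError("atoms must be distinct")
    d, u = _dist_and_unit(coords, i, j)
    grad = np.zeros_like(coords)
    grad[i] = u
    grad[j] = -u
    return CVValue(label, d, grad)


def _evaluate_one(coords: np.ndarray, spec: CVSpec) -> CVValue:
    fn = {"antisym_stretch": antisym_stretch, "relay_zeta": relay_zeta,
          "distance": distance_cv}[spec.kind]
    return fn(coords, *spec.atom_indices, label=spec.label)


def evaluate_cvs(trajectory: Sequence[np.ndarray] | np.ndarray,
                 specs: Sequence[CVSpec]) -> dict[str, np.ndarray]:
    """Evaluate each spec on every frame; returns label -> value series."""
    frames = [np.asarray(f, dtype=float) for f in trajectory]
    out: dict[str, np.ndarray] = {}
    for spec in specs:
        vals = np.empty(len(frames))
        for k, coords in enumerate(frames):
            if max(spec.atom_indices) >= len(coords):
                raise IndexError(
                    f"CV {spec.label!r}: atom index "
                    f"{max(spec.atom_indices)} out of range in frame {k}")
            vals[k] = _evaluate_one(coords, spec).value
        out[spec.label] = vals
    return out
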