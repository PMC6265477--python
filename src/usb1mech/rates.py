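"""Transition-state-theory rates and solvent isotope observables.

* Eyring conversion between activation free energies and rate constants,
  k = kappa * (k_B T / h) * exp(-dG / RT).
* Gross-Butler proton-inventory curves, k_n = k0 * prod_i (1 - n + n phi_i):
  exactly one exchangeable site in flight gives an exactly linear k_n vs n,
  the classic one-proton diagnostic.
* A semiclassical H/D kinetic isotope effect from zero-point energies of a
  harmonic stretch lost (or softened) at the TS, with deuterium frequencies
  idealized as nu_H / sqrt(2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants

__all__ = ["RateResult", "ProtonInventoryCurve", "KIEModel", "eyring_rate",
           "barrier_from_rate", "gross_butler", "semiclassical_kie"]

R_KCAL = constants.R / constants.calorie / 1000.0   # kcal / (mol K)
KB_OVER_H = constants.k / constants.h               # s^-1 K^-1
HC_OVER_KB_CM = constants.h * constants.c * 100.0 / constants.k  # K per cm^-1


@dataclass
class RateResult:
    barrier: float       # kcal/mol
    temperature: float   # K
    rate: float          # s^-1
    transmission: float = 1.0


def eyring_rate(barrier: float, temperature: float = 298.15,
                transmission: float = 1.0) -> RateResult:
    """k = transmission * (k_B T / h) * exp(-barrier / RT)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rate = transmission * KB_OVER_H * temperature * np.exp(
        -barrier / (R_KCAL * temperature))
    return RateResult(float(barrier), float(temperature), float(rate),
                      float(transmission))


def barrier_from_rate(rate: float, temperature: float = 298.15,
                      transmission: float = 1.0) -> float:
    """Exact inverse of :func:`eyring_rate` (kcal/mol)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(-R_KCAL * temperature
                 * np.log(rate / (transmission * KB_OVER_H * temperature)))


@dataclass
class ProtonInventoryCurve:
    phis: tuple[float, ...]
    k0: float
    n_grid: np.ndarray
    curve: np.ndarray
    linearity: float   # max |deviation from the chord| / k0


def gross_butler(k0: float, phis, n_points: int = 21) -> ProtonInventoryCurve:
    """Gross-Butler rate vs D2O mole fraction for TS fractionation factors."""
    phis = tuple(float(p) for p in np.atleast_1d(phis))
    if k0 <= 0 or any(p <= 0 for p in phis):
        raise ValueError("k0 and every phi must be positive")
    n = np.linspace(0.0, 1.0, n_points)
    kn = k0 * np.prod([1.0 - n + n * p for p in phis], axis=0)
    chord = kn[0] + (kn[-1] - kn[0]) * n
    linearity = float(np.abs(kn - chord).max() / k0)
    return ProtonInventoryCurve(phis, float(k0), n, kn, linearity)


@dataclass
class KIEModel:
    gs_frequency: float   # cm^-1
    ts_frequency: float   # cm^-1
    temperature: float    # K
    kie: float
    inverse: bool = False


def semiclassical_kie(gs_frequency: float, ts_frequency: float,
                      temperature: float = 298.15) -> KIEModel:
    """Zero-point-energy H/D KIE for a harmonic stretch softened at the TS.

    Deuterium frequencies are idealized as nu_H / sqrt(2) (reduced-mass
    ratio of 2); real X-H/X-D frequency ratios are ~1.35-1.41, so this
    slightly overestimates the isotopic zero-point difference.

        KIE = exp[(dnu_H - dnu_D) * hc / (2 k_B T)],  dnu = nu_GS - nu_TS.
    """
    if gs_frequency < 0 or ts_frequency < 0:
        raise ValueError("frequencies must be non-negative")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dnu = gs_frequency - ts_frequency
    inverse = dnu < 0
    if inverse:
        warnings.warn("TS frequency exceeds GS frequency: inverse KIE",
                      stacklevel=2)
    kie = float(np.exp(dnu * (1.0 - 1.0 / np.sqrt(2.0))
                       * HC_OVER_KB_CM / (2.0 * temperature)))
    return KIEModel(float(gs_frequency), float(ts_frequency),
                    float(temperature), kie, inverse)
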