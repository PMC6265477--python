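"""Single-cleavage Michaelis-Menten kinetics and substrate efficiency tables.

Single-cleavage substrates carry a 2'-deoxy substitution at the n-1
position, which removes the attacking 2'-OH after one cut and makes initial
rates interpretable as a single transphosphorylation event.  Fitted
kcat/Km efficiencies ranked against a reference substrate quantify the
enzyme's preference for the identity of the terminal (n) nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .surfaces import KineticsSample

__all__ = ["MMFit", "SubstrateRow", "EfficiencyTable", "TABLE_SUBSTRATES",
           "fit_michaelis_menten", "efficiency_table"]


@dataclass
class MMFit:
    Vmax: float        # uM/s
    Km: float          # uM
    kcat: float        # s^-1 (Vmax / E0, assuming fully active enzyme)
    Vmax_se: float
    Km_se: float
    kcat_se: float
    ill_determined: bool


def _mm(S, Vmax, Km):
    return Vmax * S / (Km + S)


def fit_michaelis_menten(dataset: KineticsSample) -> MMFit:
    """Nonlinear least squares fit of v = Vmax S / (Km + S).

    Initialized from a Hanes-Woolf linearization (S/v regressed on S);
    standard errors come from the asymptotic covariance of the fit.  A Km
    outside [min(S)/50, 50 max(S)] is flagged ill-determined.
    """
    S_levels = dataset.substrate_concentrations
    if len(np.unique(S_levels)) < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    if dataset.enzyme_concentration <= 0:
        raise ValueError("enzyme concentration must be positive")
    reps = dataset.velocities.shape[1]
    S = np.repeat(S_levels, reps)
    v = dataset.velocities.ravel()
    # Hanes-Woolf: S/v = S/Vmax + Km/Vmax
    good = v > 0
    slope, intercept = np.polyfit(S[good], S[good] / v[good], 1)
    Vmax0 = 1.0 / slope if slope > 0 else v.max()
    Km0 = intercept * Vmax0 if intercept * Vmax0 > 0 else np.median(S_levels)
    try:
        popt, pcov = curve_fit(_mm, S, v, p0=[Vmax0, Km0], maxfev=10_000)
    except RuntimeError as e:
        resid = v - _mm(S, Vmax0, Km0)
        raise RuntimeError(
            f"Michaelis-Menten fit did not converge; residuals from the "
            f"linearized start: {resid}") from e
    Vmax, Km = popt
    se = np.sqrt(np.diag(pcov))
    E0 = dataset.enzyme_concentration
    ill = not (S_levels.min() / 50.0 <= Km <= 50.0 * S_levels.max())
    return MMFit(float(Vmax), float(Km), float(Vmax / E0),
                 float(se[0]), float(se[1]), float(se[0] / E0), ill)


@dataclass(frozen=True)
class SubstrateRow:
    """One substrate with fitted kcat (s^-1) and Km (uM).

    Substrate names mark the 2'-deoxy position with a 'd' prefix on one
    residue (e.g. UAUUUdUUA).  ``from_milli`` accepts kcat on the
    10^-3 s^-1 scale commonly used for slow single-cleavage turnover.
    """

    name: str
    kcat: float      # s^-1
    kcat_se: float
    Km: float        # uM
    Km_se: float

    def __post_init__(self):
        if self.kcat <= 0 or self.Km <= 0:
            raise ValueError("kcat and Km must be positive")

    @classmethod
    def from_milli(cls, name, kcat_e3, kcat_e3_se, Km, Km_se):
        return cls(name, kcat_e3 * 1e-3, kcat_e3_se * 1e-3, Km, Km_se)

    @property
    def efficiency(self) -> float:
        """kcat/Km on the 10^3 M^-1 s^-1 scale."""
        return self.kcat / (self.Km * 1e-6) / 1e3


#: Measured single-cleavage parameters for the four dinucleotide-end series
#: (kcat in 10^-3 s^-1, Km in uM).  The terminal two residues after the
#: deoxy block are the dinucleotide actually cleaved.
TABLE_SUBSTRATES = [
    SubstrateRow.from_milli("UAUUUdUUU", 1.31, 0.02, 7.58, 0.38),
    SubstrateRow.from_milli("UAUUUdUAU", 1.07, 0.05, 9.75, 1.22),
    SubstrateRow.from_milli("UAUUUdUUA", 11.85, 0.61, 3.12, 0.56),
    SubstrateRow.from_milli("UAUUUdUAA", 8.78, 0.48, 7.17, 1.21),
]


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))


@dataclass
class EfficiencyTable:
    rows: list[SubstrateRow]
    reference: str
    efficiency: dict[str, float]   # 10^3 M^-1 s^-1, unrounded
    relative: dict[str, float]     # unrounded ratio to the reference row

    def to_frame(self) -> pd.DataFrame:
        """Display table: efficiency to 2 decimals, relative to 2 sig figs."""
        return pd.DataFrame({
            "substrate": [r.name for r in self.rows],
            "kcat_e-3_per_s": [r.kcat * 1e3 for r in self.rows],
            "Km_uM": [r.Km for r in self.rows],
            "kcat/Km_1e3_M-1s-1": [round(self.efficiency[r.name], 2)
                                   for r in self.rows],
            "relative": [_round_sig(self.relative[r.name], 2)
                         for r in self.rows],
        })


def efficiency_table(rows: list[SubstrateRow],
                     reference_name: str) -> EfficiencyTable:
    """Specificity constants and their ratios to a reference substrate.

    Relative values are computed from unrounded efficiencies; rounding is
    applied only at display time (efficiency 2 decimals, relative 2
    significant figures).
    """
    names = [r.name for r in rows]
    if len(set(names)) != len(names):
        raise ValueError("duplicate substrate names")
    if reference_name not in names:
        raise ValueError(f"reference {reference_name!r} not among {names}")
    eff = {r.name: r.efficiency for r in rows}
    ref = eff[reference_name]
    rel = {n: e / ref for n, e in eff.items()}
    return EfficiencyTable(list(rows), reference_name, eff, rel)
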