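"""Reaction free-energy composition and linear calibration onto experiment.

The quantum-chemically composed complexation free energy in solution is

    dG_sol,QC = dE_high-level-DFT + dG_RRHO + d(dG_solv),

each difference taken as complex - molecule - reference partner.  Raw
dG_sol,QC values carry a large systematic error; an affine calibration maps
them onto the experimental scales (4-fluorophenol complexation for
acceptors, acetone complexation for donors):

    HBA: dG = 0.56 * dG_sol,QC - 20.12 kJ/mol
    HBD: dG = 0.63 * dG_sol,QC - 20.94 kJ/mol

The two printed equations are the canonical defaults; ``fit_calibration``
refits by ordinary least squares and reports cross-validation stability, but
never silently overrides the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .molio import StrengthEntry


@dataclass
class EnergyBreakdown:
    """(complex, molecule, reference) energy triples in kJ/mol."""

    e_highdft: tuple[float, float, float]
    g_rrho: tuple[float, float, float]
    dg_solv: tuple[float, float, float]

    def deltas(self) -> tuple[float, float, float]:
        return tuple(t[0] - t[1] - t[2] for t in (self.e_highdft, self.g_rrho, self.dg_solv))


def compose_dg(breakdown: EnergyBreakdown) -> float:
    """dG_sol,QC in kJ/mol from the three component triples."""
    for triple in (breakdown.e_highdft, breakdown.g_rrho, breakdown.dg_solv):
        if triple is None or len(triple) != 3 or not all(np.isfinite(triple)):
            raise ValueError("incomplete or non-finite energy breakdown")
    return float(sum(breakdown.deltas()))


def compose_entry(entry: StrengthEntry) -> float:
    """Compose dG_sol,QC from an entry's stored triples."""
    if entry.e_highdft is None or entry.g_rrho is None or entry.dg_solv is None:
        raise ValueError("entry is missing energy component triples")
    return compose_dg(EnergyBreakdown(entry.e_highdft, entry.g_rrho, entry.dg_solv))


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map from dG_sol,QC to the experimental scale (kJ/mol)."""

    slope: float
    intercept: float
    role: str

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if self.role not in ("HBA", "HBD"):
            raise ValueError(f"role must be HBA or HBD, got {self.role!r}")


DEFAULT_CALIBRATIONS = {
    "HBA": CalibrationModel(slope=0.56, intercept=-20.12, role="HBA"),
    "HBD": CalibrationModel(slope=0.63, intercept=-20.94, role="HBD"),
}


def default_calibration(role: str) -> CalibrationModel:
    try:
        return DEFAULT_CALIBRATIONS[role]
    except KeyError:
        raise ValueError(f"role must be HBA or HBD, got {role!r}") from None


def calibrate(dg_qc: float, model: CalibrationModel) -> float:
    """Apply the affine calibration: slope * dG_sol,QC + intercept."""
    return model.slope * dg_qc + model.intercept


def invert_calibration(dg: float, model: CalibrationModel) -> float:
    """Recover dG_sol,QC from a calibrated value."""
    return (dg - model.intercept) / model.slope


@dataclass
class CalibrationStability:
    """Cross-validation stability of a fitted calibration."""

    fold_slopes: np.ndarray
    fold_intercepts: np.ndarray
    slope_rsd: float  # relative standard deviation across folds
    intercept_rsd: float
    rmse_before: float  # raw dG_sol,QC against experiment
    rmse_after: float  # calibrated values against experiment


def fit_calibration(
    pairs: list[tuple[float, float]],
    role: str,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[CalibrationModel, CalibrationStability]:
    """OLS fit of experimental dG on dG_sol,QC with k-fold stability report.

    Each fold's slope/intercept comes from refitting on the other k-1 folds;
    the report carries their relative standard deviations and the RMSE of
    the raw and calibrated predictions on the full set.
    """
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 pairs to calibrate, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: dG_sol,QC values have zero variance")
    fit = stats.linregress(x, y)
    model = CalibrationModel(slope=float(fit.slope), intercept=float(fit.intercept), role=role)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    k = min(cv_folds, len(x))
    folds = np.array_split(order, k)
    slopes, intercepts = [], []
    for fold in folds:
        mask = np.ones(len(x), dtype=bool)
        mask[fold] = False
        if mask.sum() >= 2 and np.ptp(x[mask]) > 0:
            f = stats.linregress(x[mask], y[mask])
            slopes.append(f.slope)
            intercepts.append(f.intercept)
    slopes = np.array(slopes)
    intercepts = np.array(intercepts)
    fitted = model.slope * x + model.intercept
    stability = CalibrationStability(
        fold_slopes=slopes,
        fold_intercepts=intercepts,
        slope_rsd=float(slopes.std(ddof=1) / abs(slopes.mean())),
        intercept_rsd=float(intercepts.std(ddof=1) / abs(intercepts.mean())),
        rmse_before=float(np.sqrt(np.mean((x - y) ** 2))),
        rmse_after=float(np.sqrt(np.mean((fitted - y) ** 2))),
    )
    return model, stability
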