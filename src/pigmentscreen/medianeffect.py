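"""Median-effect dose-response model and combination-index synergy scoring.

The median-effect equation relates dose D to the fraction affected fa:

    fa / (1 - fa) = (D / Dm)^m

with Dm the median-effect dose (the IC50) and m the sigmoidicity.  It is
fitted by unweighted least squares on the linearized form

    log10(fa / (1 - fa)) = m * log10(D) - m * log10(Dm).

For a combination applying doses (d1, d2) and producing effect fa, the
combination index is

    CI(fa) = d1 / Dx1(fa) + d2 / Dx2(fa),

where Dxi(fa) = Dm_i * (fa/(1-fa))^(1/m_i) is the dose of drug i alone
needed for the same effect.  CI < 1 indicates Loewe synergy, CI = 1
additivity, CI > 1 antagonism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "MedianEffectModel",
    "ExcessED50",
    "CI_BANDS",
    "fit_median_effect",
    "dose_for_effect",
    "compute_ci",
    "classify_ci",
    "excess_ed50",
    "design_fixed_ratio",
]

#: Effect-fraction clipping bounds applied before the logit transform.
FA_CLIP = (0.005, 0.995)

#: Default CI classification bands (upper edges; inclusive on "additive").
CI_BANDS = {
    "strong_synergy": 0.3,  # ci < 0.3
    "synergy": 0.9,         # 0.3 <= ci < 0.9
    "additive": 1.1,        # 0.9 <= ci <= 1.1
    # ci > 1.1 -> antagonism
}


class MedianEffectModel:
    """Median-effect dose-response model with an estimator-style interface.

    Parameters can be given directly (``MedianEffectModel(dm=2, m=1.5)``)
    or estimated from data with :meth:`fit`.

    Fitted attributes
    -----------------
    dm_ : float
        Median-effect dose (IC50), same units as the input doses.
    m_ : float
        Sigmoidicity (slope of the linearized fit).
    r_squared_ : float
        Coefficient of determination of the linearized regression.
    n_points_ : int
        Number of points used.
    dose_range_ : tuple[float, float]
        (min, max) dose of the fitted data.
    n_clipped_ : int
        Points whose fa fell outside the clipping bounds.
    non_inhibitor_ : bool
        True when the fitted slope is not positive (signal does not fall
        with dose); the fit is still returned for inspection.
    """

    def __init__(self, dm: float | None = None, m: float | None = None):
        if dm is not None:
            if dm <= 0:
                raise ValueError("dm must be positive")
            self.dm_ = float(dm)
        if m is not None:
            self.m_ = float(m)
            self.non_inhibitor_ = m <= 0

    def fit(self, dose, fraction_affected) -> "MedianEffectModel":
        dose = np.asarray(dose, float)
        fa = np.asarray(fraction_affected, float)
        if dose.shape != fa.shape:
            raise ValueError("dose and fraction_affected must align")
        if np.any(dose <= 0):
            raise DataError("fit_median_effect: doses must be positive")
        keep = np.isfinite(dose) & np.isfinite(fa)
        dose, fa = dose[keep], fa[keep]
        clipped = (fa < FA_CLIP[0]) | (fa > FA_CLIP[1])
        fa = np.clip(fa, *FA_CLIP)
        if dose.size < 3:
            raise DataError(
                f"fit_median_effect: need >=3 usable points, got {dose.size}"
            )
        x = np.log10(dose)
        y = np.log10(fa / (1.0 - fa))
        res = stats.linregress(x, y)
        m = float(res.slope)
        self.m_ = m
        self.non_inhibitor_ = m <= 0
        if self.non_inhibitor_:
            warnings.warn(
                "median-effect slope <= 0: series is not an inhibitor response",
                RuntimeWarning,
                stacklevel=2,
            )
            self.dm_ = float("nan") if m == 0 else float(10 ** (-res.intercept / m))
        else:
            self.dm_ = float(10 ** (-res.intercept / m))
        self.r_squared_ = float(res.rvalue**2)
        self.n_points_ = int(dose.size)
        self.dose_range_ = (float(dose.min()), float(dose.max()))
        self.n_clipped_ = int(clipped.sum())
        return self

    def predict_fa(self, dose):
        """Fraction affected at the given dose(s)."""
        d = np.asarray(dose, float)
        r = (d / self.dm_) ** self.m_
        return r / (1.0 + r)

    def dose_for_effect(self, fa):
        """Dose Dx producing effect fa; strictly increasing in fa."""
        fa_arr = np.asarray(fa, float)
        if np.any((fa_arr <= 0) | (fa_arr >= 1)):
            raise ValueError("fa must lie strictly inside (0, 1)")
        out = self.dm_ * (fa_arr / (1.0 - fa_arr)) ** (1.0 / self.m_)
        return float(out) if np.isscalar(fa) else out

    def get_params(self) -> dict:
        return {"dm": getattr(self, "dm_", None), "m": getattr(self, "m_", None)}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if hasattr(self, "dm_"):
            return f"MedianEffectModel(dm={self.dm_:.4g}, m={self.m_:.4g})"
        return "MedianEffectModel(<unfitted>)"


def fit_median_effect(table: pd.DataFrame) -> MedianEffectModel:
    """Fit the median-effect model to a (dose, fraction_affected) table."""
    return MedianEffectModel().fit(
        table["dose_um"].to_numpy(float),
        table["fraction_affected"].to_numpy(float),
    )


def dose_for_effect(fit: MedianEffectModel, fa: float) -> float:
    """Dx for a fitted model; thin functional wrapper."""
    return float(fit.dose_for_effect(fa))


def classify_ci(ci: float, bands: dict | None = None) -> str:
    """Map a combination index to its synergy class."""
    b = bands or CI_BANDS
    if ci < b["strong_synergy"]:
        return "strong_synergy"
    if ci < b["synergy"]:
        return "synergy"
    if ci <= b["additive"]:
        return "additive"
    return "antagonism"


def compute_ci(
    fit1: MedianEffectModel,
    fit2: MedianEffectModel,
    combo_rows: pd.DataFrame,
    bands: dict | None = None,
) -> pd.DataFrame:
    """Combination indices for observed combination rows (d1, d2, fa).

    ``combo_rows`` needs columns ``d1``, ``d2`` and ``fraction_affected``.
    A zero dose contributes nothing (the CI degenerates to the remaining
    single-agent potency ratio).  Returns a table with the equivalent
    single-agent doses, the CI, and its classification.
    """
    for f in (fit1, fit2):
        if not hasattr(f, "dm_") or not np.isfinite(f.dm_) or f.dm_ <= 0:
            raise DataError("compute_ci: invalid median-effect fit")
    out = []
    for row in combo_rows.itertuples(index=False):
        fa = float(row.fraction_affected)
        if not 0.0 < fa < 1.0:
            raise ValueError(f"fa must lie in (0,1), got {fa}")
        dx1 = fit1.dose_for_effect(fa)
        dx2 = fit2.dose_for_effect(fa)
        d1, d2 = float(row.d1), float(row.d2)
        ci = (d1 / dx1 if d1 > 0 else 0.0) + (d2 / dx2 if d2 > 0 else 0.0)
        out.append(
            {
                "d1": d1,
                "d2": d2,
                "fraction_affected": fa,
                "dx1": dx1,
                "dx2": dx2,
                "ci": ci,
                "classification": classify_ci(ci, bands),
            }
        )
    return pd.DataFrame(
        out,
        columns=["d1", "d2", "fraction_affected", "dx1", "dx2", "ci",
                 "classification"],
    )


@dataclass(frozen=True)
class ExcessED50:
    """Dose suppressing half of the transgenic signal excess over wild type."""

    dose_um: float
    target_signal: float
    method: str = "log_linear"


def excess_ed50(dose_series: pd.DataFrame, wt_level: float) -> ExcessED50:
    """Dose at which normalized signal reaches wt_level + 0.5*(1 - wt_level).

    The series (columns ``dose_um``, ``normalized_signal``, on the
    1.0 = untreated-V12RAS scale) must bracket the target; the dose is found
    by interpolating the signal linearly in log10(dose) between the two
    bracketing tested doses.  No extrapolation is performed.
    """
    target = wt_level + 0.5 * (1.0 - wt_level)
    ser = dose_series.sort_values("dose_um")
    doses = ser["dose_um"].to_numpy(float)
    sig = ser["normalized_signal"].to_numpy(float)
    if np.any(doses <= 0):
        raise DataError("excess_ed50: doses must be positive")
    resid = sig - target
    exact = np.flatnonzero(resid == 0)
    if exact.size:
        return ExcessED50(dose_um=float(doses[exact[0]]), target_signal=target)
    cross = np.flatnonzero(resid[:-1] * resid[1:] < 0)
    if cross.size == 0:
        raise DataError(
            f"excess_ed50: target signal {target:.4g} not bracketed by the "
            "tested dose range"
        )
    i = int(cross[0])
    x0, x1 = np.log10(doses[i]), np.log10(doses[i + 1])
    frac = (target - sig[i]) / (sig[i + 1] - sig[i])
    return ExcessED50(dose_um=float(10 ** (x0 + frac * (x1 - x0))),
                      target_signal=target)


def design_fixed_ratio(
    ed50_a: ExcessED50 | float,
    ed50_b: ExcessED50 | float,
    n_dilutions: int,
    dilution_factor: float = 2.0,
) -> list[tuple[float, float]]:
    """Constant-ratio dilution series anchored at the two single-agent ED50s.

    The top mixture pairs the two ED50 doses; each further step divides both
    by ``dilution_factor``, so the a:b dose ratio is constant down the series.
    """
    a = ed50_a.dose_um if isinstance(ed50_a, ExcessED50) else float(ed50_a)
    b = ed50_b.dose_um if isinstance(ed50_b, ExcessED50) else float(ed50_b)
    if a <= 0 or b <= 0 or dilution_factor <= 0 or n_dilutions < 1:
        raise ValueError("design_fixed_ratio: inputs must be positive")
    return [
        (a / dilution_factor**i, b / dilution_factor**i)
        for i in range(n_dilutions)
    ]
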