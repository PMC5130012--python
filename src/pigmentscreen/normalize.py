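"""Plate normalization and assay-quality statistics.

Raw 340 nm absorbances are converted to a dimensionless scale in which 0.0
is the casper background (eye melanin only) and 1.0 is the plate's mean
vehicle-treated (DMSO) V12RAS signal after background subtraction:

    normalized = (raw - mean_casper) / (mean_v12ras_dmso - mean_casper)

Normalization is strictly per plate: each plate carries its own casper and
DMSO-V12RAS control wells for internal calibration, and no screen-global
scaling is ever applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "AssayQC",
    "normalize_plate",
    "normalize_plates",
    "z_factor",
    "assay_qc",
    "fold_change",
]


@dataclass(frozen=True)
class AssayQC:
    """Z-factor quality summary of a positive/negative control pair."""

    z_factor: float
    mu_pos: float
    mu_neg: float
    sigma_pos: float
    sigma_neg: float
    n_pos: int
    n_neg: int


def _control_stat(values: np.ndarray, stat: str) -> float:
    if stat == "mean":
        return float(np.mean(values))
    if stat == "median":
        return float(np.median(values))
    raise ValueError(f"unknown control aggregator {stat!r}")


def normalize_plate(wells: pd.DataFrame, control_stat: str = "mean") -> pd.DataFrame:
    """Normalize one plate of well records against its own control wells.

    Parameters
    ----------
    wells
        Well-record table for a single plate (all rows share ``plate_id``).
    control_stat
        Aggregator for control wells, ``"mean"`` (default) or ``"median"``.

    Returns
    -------
    The input table with an appended ``normalized_signal`` column.
    """
    plates = wells["plate_id"].unique()
    if len(plates) != 1:
        raise DataError(
            f"normalize_plate expects one plate, got {sorted(map(str, plates))}"
        )
    plate_id = plates[0]
    casper = wells.loc[wells["role"] == "casper", "raw_absorbance"].to_numpy(float)
    dmso = wells.loc[wells["role"] == "v12ras_dmso", "raw_absorbance"].to_numpy(float)
    if casper.size == 0:
        raise DataError(f"plate {plate_id}: no casper background wells")
    if dmso.size == 0:
        raise DataError(f"plate {plate_id}: no v12ras_dmso control wells")
    background = _control_stat(casper, control_stat)
    top = _control_stat(dmso, control_stat)
    denom = top - background
    if denom <= 0:
        raise DataError(
            f"plate {plate_id}: degenerate controls, v12ras_dmso "
            f"({top:.4g}) does not exceed casper background ({background:.4g})"
        )
    out = wells.copy()
    out["normalized_signal"] = (out["raw_absorbance"] - background) / denom
    return out


def normalize_plates(wells: pd.DataFrame, control_stat: str = "mean") -> pd.DataFrame:
    """Normalize a multi-plate well table plate by plate."""
    parts = [
        normalize_plate(grp, control_stat=control_stat)
        for _, grp in wells.groupby("plate_id", sort=True)
    ]
    if not parts:
        out = wells.copy()
        out["normalized_signal"] = pd.Series(dtype=float)
        return out
    return pd.concat(parts, ignore_index=True)


def z_factor(mu_pos: float, sigma_pos: float, mu_neg: float, sigma_neg: float) -> float:
    """Screening-window Z-factor, Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|.

    Z' > 0.5 indicates an assay window wide enough for single-replicate
    screening.  Symmetric in the two controls and invariant to rescaling all
    four inputs by a positive constant.
    """
    if sigma_pos < 0 or sigma_neg < 0:
        raise ValueError("sigmas must be non-negative")
    sep = abs(mu_pos - mu_neg)
    if sep == 0:
        raise DataError("z_factor undefined: control means are equal")
    return 1.0 - 3.0 * (sigma_pos + sigma_neg) / sep


def assay_qc(pos: np.ndarray, neg: np.ndarray) -> AssayQC:
    """Z-factor summary from raw positive/negative control readings."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    sd_p = float(pos.std(ddof=1)) if pos.size > 1 else 0.0
    sd_n = float(neg.std(ddof=1)) if neg.size > 1 else 0.0
    return AssayQC(
        z_factor=z_factor(mu_p, sd_p, mu_n, sd_n),
        mu_pos=mu_p,
        mu_neg=mu_n,
        sigma_pos=sd_p,
        sigma_neg=sd_n,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def fold_change(
    wt_values: np.ndarray,
    v12ras_values: np.ndarray,
    experiment: np.ndarray | None = None,
) -> tuple[float, float]:
    """Transgenic-over-wild-type fold elevation of background-subtracted signal.

    ``wt_values`` and ``v12ras_values`` are background-subtracted absorbances.
    ``experiment`` optionally labels independent experiments (same length as
    the corresponding value array); the fold change is computed per
    experiment as mean(V12RAS)/mean(WT) and summarized as (mean, SEM) over
    experiments.  Without labels, all values form a single experiment and the
    SEM is 0.
    """
    wt_values = np.asarray(wt_values, float)
    v12ras_values = np.asarray(v12ras_values, float)
    if experiment is None:
        wt_groups = [wt_values]
        tg_groups = [v12ras_values]
    else:
        experiment = np.asarray(experiment)
        labels = pd.unique(experiment)
        wt_groups = [wt_values[experiment == lab] for lab in labels]
        tg_groups = [v12ras_values[experiment == lab] for lab in labels]
    folds = []
    for wt, tg in zip(wt_groups, tg_groups):
        if wt.size == 0 or tg.size == 0:
            raise DataError("fold_change: empty group in an experiment")
        wt_mean = wt.mean()
        if wt_mean <= 0:
            raise DataError(
                f"fold_change: non-positive WT subtracted mean ({wt_mean:.4g})"
            )
        folds.append(tg.mean() / wt_mean)
    folds = np.asarray(folds)
    mean = float(folds.mean())
    sem = float(folds.std(ddof=1) / np.sqrt(folds.size)) if folds.size > 1 else 0.0
    return mean, sem
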