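"""Hit-calling cascade for the pigmentation-suppression screen.

Decision order mirrors the screening workflow:

1. toxicity filter — wells with < 80% embryo survival are not analysed;
   the offending compound is queued for a rescreen at half dose, and a
   compound failing again is excluded outright;
2. primary hit call — one-sided median/MAD rule over the whole screen arm,
   hit if normalized signal < median - k * c * MAD (default k = 2.5);
3. retest — 5 replicate wells per primary hit; the compound passes if its
   replicate mean still clears the primary cutoff;
4. triage — operational versions of the qualitative follow-up criteria:
   clear dose dependency, cooperation with the backbone inhibitor, and a
   negligible effect on wild-type pigmentation.

Only suppressors are ever hits; pigmentation enhancers are reported in the
statistics but never flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "MadStats",
    "TriageConfig",
    "toxicity_filter",
    "mad_hit_call",
    "retest",
    "triage",
]


@dataclass(frozen=True)
class MadStats:
    """Median/MAD location-scale summary with the one-sided hit cutoff."""

    median: float
    mad: float
    scale_constant: float
    cutoff_k: float
    cutoff_value: float
    n: int
    fallback_sd: bool = False  # True when MAD was 0 and the SD was used


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds giving operational meaning to the triage criteria.

    rho_max
        Spearman rank correlation of (dose, signal) at or below which a
        series counts as dose dependent (default -0.8, i.e. near-monotone
        suppression).
    span_min
        Minimum top-to-bottom spread of per-dose mean signals (normalized
        units) for dose dependency; rules out flat-but-ranked noise.
    coop_margin
        Combination mean must undercut the single-agent mean by at least
        this much to count as cooperation.
    wt_tolerance
        Maximum allowed |change| of wild-type normalized signal from the
        wild-type DMSO baseline.
    min_doses
        Minimum number of distinct doses required to assess dose dependency.
    """

    rho_max: float = -0.8
    span_min: float = 0.15
    coop_margin: float = 0.05
    wt_tolerance: float = 0.10
    min_doses: int = 3


def toxicity_filter(
    wells: pd.DataFrame, min_survival: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate wells with survival and flag toxic compounds for rescreen.

    Returns ``(annotated, rescreen)``: the input with ``survival_fraction``
    and ``survival_ok`` columns, and a per-compound rescreen request table
    (``compound_id``, ``dose_um`` halved) for compounds whose every analysed
    well failed the survival threshold.  Survival of exactly
    ``min_survival`` passes (80% or more of embryos must survive).
    """
    if (wells["embryos_in"] <= 0).any():
        raise DataError("toxicity_filter: embryos_in must be positive")
    out = wells.copy()
    out["survival_fraction"] = out["embryos_alive"] / out["embryos_in"]
    out["survival_ok"] = out["survival_fraction"] >= min_survival
    comp = out[out["compound_id"] != ""]
    failing = []
    for compound_id, grp in comp.groupby("compound_id", sort=True):
        if not grp["survival_ok"].any():
            failing.append(
                {
                    "compound_id": compound_id,
                    "dose_um": float(grp["dose_um"].iloc[0]) / 2.0,
                }
            )
    rescreen = pd.DataFrame(failing, columns=["compound_id", "dose_um"])
    return out, rescreen


def mad_hit_call(
    signals: pd.Series,
    k: float = 2.5,
    scale_constant: float = 1.4826,
) -> tuple[MadStats, pd.Series]:
    """One-sided median/MAD hit call over per-compound normalized signals.

    ``signals`` is indexed by compound id.  The location and scale are
    computed over the whole screen arm (never per plate).  A compound is a
    hit iff its signal lies strictly below

        cutoff = median - k * scale_constant * MAD.

    ``scale_constant`` defaults to 1.4826 (MAD consistent with a normal SD);
    pass 1.0 for the raw MAD.  If the MAD is zero the arm SD is substituted
    with a warning; if that is also zero no hits are declared.
    """
    if len(signals) < 5:
        raise DataError("mad_hit_call needs at least 5 compounds")
    x = signals.to_numpy(float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    fallback = False
    dispersion = mad
    if mad == 0.0:
        sd = float(np.std(x, ddof=1))
        fallback = True
        warnings.warn(
            "MAD is zero; falling back to the arm SD"
            if sd > 0
            else "MAD and SD are both zero; declaring no hits",
            RuntimeWarning,
            stacklevel=2,
        )
        dispersion = sd
    cutoff = med - k * scale_constant * dispersion
    if fallback and dispersion == 0.0:
        hits = pd.Series(False, index=signals.index)
    else:
        hits = pd.Series(x < cutoff, index=signals.index)
    stats_ = MadStats(
        median=med,
        mad=mad,
        scale_constant=scale_constant,
        cutoff_k=k,
        cutoff_value=cutoff,
        n=len(signals),
        fallback_sd=fallback,
    )
    return stats_, hits


def retest(
    retest_wells: pd.DataFrame,
    mad_stats: MadStats,
    min_survival: float = 0.8,
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Re-evaluate primary hits on replicate wells against the primary cutoff.

    ``retest_wells`` must carry ``compound_id``, ``normalized_signal``,
    ``embryos_in`` and ``embryos_alive``.  A compound passes when the mean
    of its surviving replicates is below the primary ``cutoff_value``;
    compounds with fewer than ``min_replicates`` surviving wells are flagged
    indeterminate and are not hits.
    """
    rows = []
    for compound_id, grp in retest_wells.groupby("compound_id", sort=True):
        surviving = grp[grp["embryos_alive"] / grp["embryos_in"] >= min_survival]
        vals = surviving["normalized_signal"].to_numpy(float)
        if vals.size < min_replicates:
            rows.append(
                {
                    "compound_id": compound_id,
                    "retest_mean": np.nan,
                    "retest_sem": np.nan,
                    "n_replicates": int(vals.size),
                    "indeterminate": True,
                    "retest_hit": False,
                }
            )
            continue
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows.append(
            {
                "compound_id": compound_id,
                "retest_mean": mean,
                "retest_sem": sem,
                "n_replicates": int(vals.size),
                "indeterminate": False,
                "retest_hit": mean < mad_stats.cutoff_value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "retest_mean",
            "retest_sem",
            "n_replicates",
            "indeterminate",
            "retest_hit",
        ],
    )


def _dose_dependent(grp: pd.DataFrame, cfg: TriageConfig) -> bool | None:
    by_dose = grp.groupby("dose_um")["normalized_signal"].mean().sort_index()
    if len(by_dose) < cfg.min_doses:
        return None
    span = float(by_dose.max() - by_dose.min())
    if span == 0.0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> nan rho
        rho = stats.spearmanr(by_dose.index.to_numpy(), by_dose.to_numpy()).statistic
    if not np.isfinite(rho):
        return False
    return bool(rho <= cfg.rho_max and span >= cfg.span_min)


def triage(
    dose_table: pd.DataFrame,
    wt_table: pd.DataFrame,
    combo_table: pd.DataFrame,
    config: TriageConfig | None = None,
) -> pd.DataFrame:
    """Apply the three follow-up predicates to retest survivors.

    Parameters
    ----------
    dose_table
        Normalized wells of the per-compound dose series (compound + backbone
        at several doses): columns ``compound_id``, ``dose_um``,
        ``normalized_signal``.
    wt_table
        Normalized wild-type wells; rows with an empty ``compound_id`` are
        the wild-type DMSO baseline.
    combo_table
        Normalized single-agent (role ``compound``) and combination (role
        ``compound_plus_*``) wells at the screening dose.

    Returns one row per compound present in any table, with the three flags,
    ``final_hit`` (their conjunction), and a ``reason`` for indeterminate
    compounds.
    """
    cfg = config or TriageConfig()
    if "role" in wt_table.columns:
        wt_table = wt_table[wt_table["role"] == "wt"]
    baseline_rows = wt_table[wt_table["compound_id"] == ""]
    wt_baseline = (
        float(baseline_rows["normalized_signal"].mean())
        if len(baseline_rows)
        else np.nan
    )
    compounds = sorted(
        set(dose_table["compound_id"])
        | set(wt_table.loc[wt_table["compound_id"] != "", "compound_id"])
        | set(combo_table["compound_id"])
    )
    rows = []
    for compound_id in compounds:
        reason = []
        dose_grp = dose_table[dose_table["compound_id"] == compound_id]
        dd = _dose_dependent(dose_grp, cfg) if len(dose_grp) else None
        if dd is None:
            reason.append("missing or short dose series")

        wt_grp = wt_table[wt_table["compound_id"] == compound_id]
        if len(wt_grp) == 0 or not np.isfinite(wt_baseline):
            sparing = None
            reason.append("missing wild-type series")
        else:
            change = float(wt_grp["normalized_signal"].mean()) - wt_baseline
            sparing = abs(change) <= cfg.wt_tolerance

        cgrp = combo_table[combo_table["compound_id"] == compound_id]
        single = cgrp.loc[cgrp["role"] == "compound", "normalized_signal"]
        combo = cgrp.loc[
            cgrp["role"].isin(["compound_plus_mek", "compound_plus_pi3k"]),
            "normalized_signal",
        ]
        if len(single) == 0 or len(combo) == 0:
            coop = None
            reason.append("missing single-agent vs combination wells")
        else:
            coop = float(combo.mean()) < float(single.mean()) - cfg.coop_margin

        indeterminate = dd is None or sparing is None or coop is None
        rows.append(
            {
                "compound_id": compound_id,
                "dose_dependent": bool(dd) if dd is not None else False,
                "cooperative": bool(coop) if coop is not None else False,
                "wt_sparing": bool(sparing) if sparing is not None else False,
                "indeterminate": indeterminate,
                "final_hit": (not indeterminate)
                and bool(dd)
                and bool(coop)
                and bool(sparing),
                "reason": "; ".join(reason),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "dose_dependent",
            "cooperative",
            "wt_sparing",
            "indeterminate",
            "final_hit",
            "reason",
        ],
    )
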