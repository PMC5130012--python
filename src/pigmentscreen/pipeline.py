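"""End-to-end screen orchestration: simulate -> normalize -> QC -> hit cascade.

`run_screen_cascade` chains the analysis stages on an in-memory screen
(simulated or loaded); `run_pipeline` adds configuration handling and writes
the result tables, QC summary and a stage-count report to disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hits as hitmod
from . import normalize as normmod
from .errors import ConfigurationError
from .screen_io import write_results
from .synthetic import ScreenSimulation, SyntheticScreenSpec, generate_screen

__all__ = ["RunConfig", "ScreenResult", "run_screen_cascade", "run_pipeline"]

#: Backbone inhibitors applied at sub-optimal doses in the two screen arms.
DEFAULT_ARMS = {
    "MEKi_combo": {"backbone": "PD184352", "dose_um": 0.1},
    "PI3Ki_combo": {"backbone": "NVPBEZ235", "dose_um": 0.3},
}


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "results"
    k: float = 2.5
    scale_constant: float = 1.4826
    min_survival: float = 0.8
    control_stat: str = "mean"
    rho_max: float = -0.8
    span_min: float = 0.15
    coop_margin: float = 0.05
    wt_tolerance: float = 0.10
    screen: dict = field(default_factory=dict)  # SyntheticScreenSpec overrides
    arms: dict = field(default_factory=lambda: dict(DEFAULT_ARMS))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        spec_fields = {f.name for f in dataclasses.fields(SyntheticScreenSpec)}
        bad = set(cfg.screen) - spec_fields
        if bad:
            raise ConfigurationError(f"unknown screen keys: {sorted(bad)}")
        return cfg

    def triage_config(self) -> hitmod.TriageConfig:
        return hitmod.TriageConfig(
            rho_max=self.rho_max,
            span_min=self.span_min,
            coop_margin=self.coop_margin,
            wt_tolerance=self.wt_tolerance,
        )

    def screen_spec(self) -> SyntheticScreenSpec:
        return SyntheticScreenSpec(seed=self.seed, **self.screen)


@dataclass
class ScreenResult:
    """Hit table, MAD statistics, QC and per-stage counts of one arm."""

    hit_table: pd.DataFrame
    mad_stats: hitmod.MadStats
    qc: normmod.AssayQC
    stage_counts: dict


def _per_compound_signal(norm_wells: pd.DataFrame, min_survival: float) -> pd.Series:
    ok = norm_wells[
        norm_wells["embryos_alive"] / norm_wells["embryos_in"] >= min_survival
    ]
    return ok.groupby("compound_id")["normalized_signal"].mean()


def run_screen_cascade(
    sim: ScreenSimulation,
    k: float = 2.5,
    scale_constant: float = 1.4826,
    min_survival: float = 0.8,
    control_stat: str = "mean",
    triage_config: hitmod.TriageConfig | None = None,
) -> ScreenResult:
    """Run toxicity filter, MAD hit call, retest and triage on one screen arm."""
    spec = sim.spec
    norm_primary = normmod.normalize_plates(sim.primary_wells, control_stat)
    comp = norm_primary[norm_primary["compound_id"] != ""]
    annotated, rescreen_req = hitmod.toxicity_filter(comp, min_survival)

    # rescreen signals for compounds whose primary wells all failed survival
    rescreen_signal = pd.Series(dtype=float)
    if len(sim.rescreen_wells):
        norm_rescreen = normmod.normalize_plates(sim.rescreen_wells, control_stat)
        rescue = norm_rescreen[norm_rescreen["compound_id"] != ""]
        rescreen_signal = _per_compound_signal(rescue, min_survival)

    primary_signal = _per_compound_signal(annotated[annotated["survival_ok"]],
                                          min_survival)
    survival = annotated.groupby("compound_id")["survival_fraction"].mean()

    status, signal = {}, {}
    for cid in sorted(annotated["compound_id"].unique()):
        if cid in primary_signal.index:
            status[cid] = "ok"
            signal[cid] = primary_signal[cid]
        elif cid in rescreen_signal.index:
            status[cid] = "toxic_rescreen"
            signal[cid] = rescreen_signal[cid]
        else:
            status[cid] = "toxic_excluded"
            signal[cid] = np.nan

    analysed = pd.Series(
        {c: v for c, v in signal.items() if status[c] != "toxic_excluded"}
    ).sort_index()
    mad_stats, primary_hits = hitmod.mad_hit_call(
        analysed, k=k, scale_constant=scale_constant
    )

    hit_ids = sorted(primary_hits.index[primary_hits])
    norm_retest = normmod.normalize_plates(sim.retest_wells, control_stat)
    retest_wells = norm_retest[norm_retest["compound_id"].isin(hit_ids)]
    retest_table = hitmod.retest(retest_wells, mad_stats, min_survival)
    retest_hits = set(
        retest_table.loc[retest_table["retest_hit"], "compound_id"]
    )

    dose = normmod.normalize_plates(sim.dose_wells, control_stat)
    wt = normmod.normalize_plates(sim.wt_wells, control_stat)
    combo = normmod.normalize_plates(sim.combo_wells, control_stat)
    wt_rows = wt[wt["role"] == "wt"]
    triage_table = hitmod.triage(
        dose[dose["compound_id"].isin(retest_hits)],
        wt_rows[wt_rows["compound_id"].isin(retest_hits) | (wt_rows["compound_id"] == "")],
        combo[combo["compound_id"].isin(retest_hits)],
        config=triage_config,
    )

    # assay QC from the plate controls on the normalized scale
    controls = norm_primary[norm_primary["role"].isin(["casper", "v12ras_dmso"])]
    qc = normmod.assay_qc(
        controls.loc[controls["role"] == "v12ras_dmso", "normalized_signal"],
        controls.loc[controls["role"] == "casper", "normalized_signal"],
    )

    retest_idx = retest_table.set_index("compound_id")
    triage_idx = triage_table.set_index("compound_id")
    rows = []
    for cid in sorted(status):
        is_primary = bool(primary_hits.get(cid, False))
        in_retest = cid in retest_idx.index
        is_retest = cid in retest_hits
        in_triage = cid in triage_idx.index
        rows.append(
            {
                "compound_id": cid,
                "arm": spec.arm,
                "primary_signal": signal[cid],
                "survival_fraction": float(survival.get(cid, np.nan)),
                "toxicity_status": status[cid],
                "primary_hit": is_primary,
                "retest_mean": float(retest_idx.at[cid, "retest_mean"])
                if in_retest
                else np.nan,
                "retest_sem": float(retest_idx.at[cid, "retest_sem"])
                if in_retest
                else np.nan,
                "retest_hit": is_retest,
                "dose_dependent": bool(triage_idx.at[cid, "dose_dependent"])
                if in_triage
                else False,
                "cooperative": bool(triage_idx.at[cid, "cooperative"])
                if in_triage
                else False,
                "wt_sparing": bool(triage_idx.at[cid, "wt_sparing"])
                if in_triage
                else False,
                "final_hit": bool(triage_idx.at[cid, "final_hit"])
                if in_triage
                else False,
            }
        )
    hit_table = pd.DataFrame(rows)
    stage_counts = {
        "screened": int(len(hit_table)),
        "toxic_rescreened": int((hit_table["toxicity_status"] == "toxic_rescreen").sum()),
        "toxic_excluded": int((hit_table["toxicity_status"] == "toxic_excluded").sum()),
        "primary_hits": int(hit_table["primary_hit"].sum()),
        "retest_hits": int(hit_table["retest_hit"].sum()),
        "final_hits": int(hit_table["final_hit"].sum()),
    }
    return ScreenResult(
        hit_table=hit_table, mad_stats=mad_stats, qc=qc, stage_counts=stage_counts
    )


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a screen under ``config`` and write all outputs.

    Writes hits.csv, qc.json, report.json, and the resolved run
    configuration next to the outputs.  Returns the report dictionary.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = generate_screen(config.screen_spec())
    result = run_screen_cascade(
        sim,
        k=config.k,
        scale_constant=config.scale_constant,
        min_survival=config.min_survival,
        control_stat=config.control_stat,
        triage_config=config.triage_config(),
    )
    write_results({"hits": result.hit_table}, out_dir)
    qc = {
        "z_factor": result.qc.z_factor,
        "mu_pos": result.qc.mu_pos,
        "mu_neg": result.qc.mu_neg,
        "sigma_pos": result.qc.sigma_pos,
        "sigma_neg": result.qc.sigma_neg,
        "n_pos": result.qc.n_pos,
        "n_neg": result.qc.n_neg,
        "mad_median": result.mad_stats.median,
        "mad": result.mad_stats.mad,
        "cutoff_value": result.mad_stats.cutoff_value,
    }
    report = {
        "seed": config.seed,
        "stage_counts": result.stage_counts,
        "cutoff_value": result.mad_stats.cutoff_value,
        "z_factor": result.qc.z_factor,
    }
    for name, payload in (
        ("qc.json", qc),
        ("report.json", report),
        ("run_config.json", dataclasses.asdict(config)),
    ):
        with open(out_dir / name, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
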