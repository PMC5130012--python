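"""Hit-calling cascade: toxicity filter, median/MAD call, retest, triage."""

import numpy as np
import pandas as pd
import pytest

from pigmentscreen import (
    MadStats,
    TriageConfig,
    mad_hit_call,
    retest,
    toxicity_filter,
    triage,
)


def brute_force_mad(values, k=2.5, scale_constant=1.0):
    """Independent median/MAD by explicit sorting, for cross-checking."""
    xs = sorted(values)
    n = len(xs)

    def med(sorted_vals):
        m = len(sorted_vals)
        mid = m // 2
        return sorted_vals[mid] if m % 2 else 0.5 * (sorted_vals[mid - 1] + sorted_vals[mid])

    location = med(xs)
    mad = med(sorted(abs(x - location) for x in xs))
    cutoff = location - k * scale_constant * mad
    hits = [x < cutoff for x in values]
    return location, mad, cutoff, hits


def _wells(records):
    return pd.DataFrame(
        records,
        columns=["compound_id", "dose_um", "embryos_in", "embryos_alive"],
    )


class TestToxicityFilter:
    def test_eighty_percent_survival_is_inclusive_pass(self):
        wells = _wells([("C1", 1.0, 10, 8), ("C2", 1.0, 10, 10)])
        annotated, rescreen = toxicity_filter(wells)
        assert annotated["survival_ok"].all()
        assert rescreen.empty

    def test_failing_compound_queued_at_half_dose(self):
        wells = _wells([("C1", 2.0, 10, 7)])
        annotated, rescreen = toxicity_filter(wells)
        assert not annotated["survival_ok"].any()
        assert rescreen.iloc[0]["compound_id"] == "C1"
        assert rescreen.iloc[0]["dose_um"] == pytest.approx(1.0)


class TestMadHitCall:
    def test_hand_computed_example(self):
        signals = pd.Series(
            [1.02, 0.98, 1.00, 1.01, 0.99, 0.50],
            index=[f"C{i}" for i in range(6)],
        )
        stats, hits = mad_hit_call(signals, k=2.5, scale_constant=1.0)
        assert stats.median == pytest.approx(0.995)
        assert stats.mad == pytest.approx(0.015)
        assert stats.cutoff_value == pytest.approx(0.9575)
        assert set(hits.index[hits]) == {"C5"}

    def test_degenerate_equal_values_warn_and_yield_no_hits(self):
        signals = pd.Series([1.0] * 6, index=[f"C{i}" for i in range(6)])
        with pytest.warns(RuntimeWarning):
            stats, hits = mad_hit_call(signals)
        assert stats.mad == 0.0
        assert not hits.any()

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("scale_constant", [1.0, 1.4826])
    def test_matches_brute_force_on_random_tables(self, seed, scale_constant):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        vals = rng.normal(1.0, 0.1, size=n)
        signals = pd.Series(vals, index=[f"C{i}" for i in range(n)])
        stats, hits = mad_hit_call(signals, scale_constant=scale_constant)
        med, mad, cutoff, ref_hits = brute_force_mad(
            vals.tolist(), scale_constant=scale_constant
        )
        assert stats.median == pytest.approx(med, abs=1e-12)
        assert stats.mad == pytest.approx(mad, abs=1e-12)
        assert stats.cutoff_value == pytest.approx(cutoff, abs=1e-12)
        assert hits.tolist() == ref_hits

    def test_one_sided_cutoff_never_flags_enhancers(self):
        signals = pd.Series(
            [1.0, 1.0, 1.01, 0.99, 1.0, 2.5],  # strong enhancer
            index=[f"C{i}" for i in range(6)],
        )
        _, hits = mad_hit_call(signals)
        assert not hits["C5"]

    def test_monotone_cascade_lowering_a_signal_keeps_it_a_hit(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(1.0, 0.05, 30)
        vals[7] = 0.5
        signals = pd.Series(vals, index=[f"C{i}" for i in range(30)])
        _, hits = mad_hit_call(signals)
        assert hits["C7"]
        lower = signals.copy()
        lower["C7"] = 0.3
        _, hits2 = mad_hit_call(lower)
        assert hits2["C7"]

    def test_pure_null_bounded_noise_yields_zero_hits(self):
        rng = np.random.default_rng(9)
        vals = 1.0 + rng.uniform(-0.04, 0.04, 200)
        _, hits = mad_hit_call(pd.Series(vals, index=[f"C{i}" for i in range(200)]))
        assert hits.sum() == 0


def _retest_wells(compound_id, signals, alive=10):
    return pd.DataFrame(
        {
            "compound_id": compound_id,
            "normalized_signal": signals,
            "embryos_in": 10,
            "embryos_alive": alive,
        }
    )


class TestRetest:
    STATS = MadStats(median=1.0, mad=0.02, scale_constant=1.0, cutoff_k=2.5,
                     cutoff_value=0.95, n=640)

    def test_fluke_reverts_and_fails_while_suppressor_passes(self):
        wells = pd.concat(
            [
                _retest_wells("FLUKE", [1.01, 0.99, 1.0, 1.02, 0.98]),
                _retest_wells("TRUE", [0.56, 0.54, 0.55, 0.53, 0.57]),
            ]
        )
        out = retest(wells, self.STATS).set_index("compound_id")
        assert not out.at["FLUKE", "retest_hit"]
        assert out.at["TRUE", "retest_hit"]
        assert out.at["TRUE", "retest_mean"] == pytest.approx(0.55)

    def test_too_few_surviving_replicates_is_indeterminate(self):
        wells = _retest_wells("C1", [0.5, 0.5, 0.5, 0.5, 0.5],
                              alive=[10, 10, 5, 5, 5])
        out = retest(wells, self.STATS).set_index("compound_id")
        assert out.at["C1", "indeterminate"]
        assert not out.at["C1", "retest_hit"]


def _triage_tables(dose_sig, wt_sig, single_sig, combo_sig, cid="C1"):
    doses = [0.5, 1.0, 2.0, 4.0]
    dose = pd.DataFrame(
        {"compound_id": cid, "dose_um": doses, "normalized_signal": dose_sig}
    )
    wt = pd.DataFrame(
        {
            "compound_id": [""] * 3 + [cid] * 3,
            "normalized_signal": [0.70, 0.69, 0.71] + wt_sig,
        }
    )
    combo = pd.DataFrame(
        {
            "compound_id": cid,
            "role": ["compound"] * 3 + ["compound_plus_mek"] * 3,
            "normalized_signal": single_sig + combo_sig,
        }
    )
    return dose, wt, combo


class TestTriage:
    GOOD = dict(
        dose_sig=[0.95, 0.80, 0.65, 0.50],
        wt_sig=[0.70, 0.71, 0.69],
        single_sig=[0.80, 0.81, 0.79],
        combo_sig=[0.55, 0.56, 0.54],
    )

    def test_engineered_profile_passes_all_three(self):
        out = triage(*_triage_tables(**self.GOOD)).set_index("compound_id")
        row = out.loc["C1"]
        assert row["dose_dependent"] and row["cooperative"] and row["wt_sparing"]
        assert row["final_hit"]

    def test_flat_dose_series_is_not_dose_dependent(self):
        args = dict(self.GOOD, dose_sig=[0.55, 0.56, 0.55, 0.54])
        out = triage(*_triage_tables(**args)).set_index("compound_id")
        assert not out.at["C1", "dose_dependent"]
        assert not out.at["C1", "final_hit"]

    def test_wt_pigment_suppression_fails_sparing(self):
        # profile suppressing wild-type pigment outright, like the screen's
        # most potent but non-selective primary hit
        args = dict(self.GOOD, wt_sig=[0.10, 0.12, 0.08])
        out = triage(*_triage_tables(**args)).set_index("compound_id")
        assert not out.at["C1", "wt_sparing"]
        assert not out.at["C1", "final_hit"]

    def test_insufficient_combination_margin_fails_cooperation(self):
        args = dict(self.GOOD, single_sig=[0.57, 0.56, 0.58])
        out = triage(*_triage_tables(**args)).set_index("compound_id")
        assert not out.at["C1", "cooperative"]

    def test_missing_series_marks_indeterminate_with_reason(self):
        dose, wt, combo = _triage_tables(**self.GOOD)
        out = triage(dose.iloc[0:0], wt, combo).set_index("compound_id")
        assert out.at["C1", "indeterminate"]
        assert "dose series" in out.at["C1", "reason"]
        assert not out.at["C1", "final_hit"]

    def test_thresholds_are_configurable(self):
        cfg = TriageConfig(wt_tolerance=0.9)
        args = dict(self.GOOD, wt_sig=[0.10, 0.12, 0.08])
        out = triage(*_triage_tables(**args), config=cfg).set_index("compound_id")
        assert out.at["C1", "wt_sparing"]
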