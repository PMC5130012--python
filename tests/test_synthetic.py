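"""Generator contracts: determinism, calibration, bounded noise, spiking plan."""

import numpy as np
import pandas as pd
import pytest

from pigmentscreen import (
    ConfigurationError,
    ImageSpec,
    MedianEffectParams,
    NumericalError,
    PlateLayout,
    SyntheticScreenSpec,
    generate_combination,
    generate_dose_response,
    generate_larva_image,
    generate_plate,
    generate_screen,
    normalize_plates,
)


def _layout(plate_id="P1"):
    return PlateLayout(
        plate_id,
        [
            ("A1", "casper", "", np.nan),
            ("A2", "v12ras_dmso", "", np.nan),
            ("A3", "wt", "", np.nan),
            ("B1", "compound_plus_mek", "C0001", 1.0),
        ],
    )


class TestGeneratePlate:
    def test_noiseless_inactive_compound_reads_exactly_the_transgenic_mean(self):
        spec = SyntheticScreenSpec(seed=0, noise_scale=0.0)
        wells = generate_plate(spec, _layout())
        raw = wells.set_index("role")["raw_absorbance"]
        assert raw["compound_plus_mek"] == pytest.approx(spec.v12ras_mean)

    def test_calibrated_wildtype_normalized_level(self):
        spec = SyntheticScreenSpec(seed=0, noise_scale=0.0)
        wells = generate_plate(spec, _layout())
        norm = normalize_plates(wells).set_index("role")["normalized_signal"]
        # (0.35 - 0.05) / (0.479 - 0.05); the subtracted transgenic/wild-type
        # ratio is then 1/0.699... = 1.43
        assert norm["wt"] == pytest.approx(0.30 / 0.429, abs=1e-9)

    def test_same_seed_reproduces_identical_tables(self):
        spec = SyntheticScreenSpec(seed=12, noise_scale=0.04)
        a = generate_plate(spec, _layout())
        b = generate_plate(spec, _layout())
        pd.testing.assert_frame_equal(a, b)

    def test_layout_without_controls_names_the_missing_role(self):
        layout = PlateLayout("P1", [("A1", "casper", "", np.nan),
                                    ("B1", "compound", "C1", 1.0)])
        with pytest.raises(ConfigurationError, match="v12ras_dmso"):
            generate_plate(SyntheticScreenSpec(), layout)


class TestGenerateScreen:
    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_screen(SyntheticScreenSpec(n_compounds=10,
                                                n_true_suppressors=8,
                                                n_primary_flukes=5))
        with pytest.raises(ConfigurationError):
            generate_screen(SyntheticScreenSpec(n_true_suppressors=5,
                                                n_triage_pass=6))

    def test_determinism_bit_identical_tables(self, preset_screen):
        again = generate_screen(SyntheticScreenSpec(seed=11))
        for attr in ("primary_wells", "rescreen_wells", "retest_wells",
                     "dose_wells", "wt_wells", "combo_wells", "truth"):
            pd.testing.assert_frame_equal(getattr(preset_screen, attr),
                                          getattr(again, attr))

    def test_bounded_noise_guarantee_on_null_wells(self, preset_screen):
        spec = preset_screen.spec
        norm = normalize_plates(preset_screen.primary_wells)
        nulls = set(
            preset_screen.truth.loc[
                (preset_screen.truth["category"] == "null")
                & ~preset_screen.truth["toxic"],
                "compound_id",
            ]
        )
        sig = norm.loc[norm["compound_id"].isin(nulls), "normalized_signal"]
        assert sig.min() >= 1.0 - spec.noise_scale - 1e-9
        assert sig.max() <= 1.0 + spec.noise_scale + 1e-9

    def test_primary_hits_by_independent_scan(self, preset_screen):
        """Brute-force re-evaluation of the spiked table: the -2.5 MAD cutoff
        separates exactly suppressors + flukes from the bounded nulls."""
        norm = normalize_plates(preset_screen.primary_wells)
        comp = norm[norm["compound_id"] != ""]
        ok = comp[comp["embryos_alive"] / comp["embryos_in"] >= 0.8]
        signals = ok.groupby("compound_id")["normalized_signal"].mean()
        rescreen_norm = normalize_plates(preset_screen.rescreen_wells)
        rescue = rescreen_norm[rescreen_norm["compound_id"] != ""]
        signals = pd.concat(
            [signals, rescue.groupby("compound_id")["normalized_signal"].mean()]
        ).sort_index()
        xs = np.sort(signals.to_numpy())
        med = float(np.median(xs))
        mad = float(np.median(np.abs(xs - med)))
        cutoff = med - 2.5 * 1.4826 * mad
        hits = signals.index[signals < cutoff]
        spiked = preset_screen.truth.loc[
            preset_screen.truth["category"].isin(["suppressor", "fluke"]),
            "compound_id",
        ]
        assert set(hits) == set(spiked)
        assert len(hits) == 37

    def test_retest_wells_keep_suppressors_and_revert_flukes(self, preset_screen):
        norm = normalize_plates(preset_screen.retest_wells)
        means = (
            norm[norm["compound_id"] != ""]
            .groupby("compound_id")["normalized_signal"]
            .mean()
        )
        truth = preset_screen.truth.set_index("compound_id")
        for cid, mean in means.items():
            if truth.at[cid, "category"] == "suppressor":
                assert mean < 0.65
            else:
                assert mean > 0.9
        n_suppressors = (truth.loc[means.index, "category"] == "suppressor").sum()
        assert n_suppressors == 25

    def test_pure_null_screen_has_no_spiked_compounds(self):
        sim = generate_screen(
            SyntheticScreenSpec(seed=3, n_compounds=60, n_true_suppressors=0,
                                n_primary_flukes=0, n_triage_pass=0,
                                toxic_fraction=0.0)
        )
        assert (sim.truth["category"] == "null").all()
        assert sim.retest_wells.empty

    def test_toxic_wells_fail_the_survival_threshold(self, preset_screen):
        toxic = set(preset_screen.truth.loc[preset_screen.truth["toxic"],
                                            "compound_id"])
        wells = preset_screen.primary_wells
        tox_wells = wells[wells["compound_id"].isin(toxic)]
        assert (tox_wells["embryos_alive"] / tox_wells["embryos_in"] < 0.8).all()


class TestDoseResponseGenerators:
    def test_median_effect_dose_gives_half_effect(self):
        table = generate_dose_response(MedianEffectParams(1.0, 1.0), [1.0])
        assert table["fraction_affected"].iloc[0] == pytest.approx(0.5)

    def test_hill_arithmetic(self):
        table = generate_dose_response(MedianEffectParams(2.0, 1.5), [8.0])
        assert table["fraction_affected"].iloc[0] == pytest.approx(8 / 9)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            generate_dose_response(MedianEffectParams(1.0, 1.0), [1.0, 0.0])

    def test_combination_algebraic_solution(self):
        # identical drugs, CI 0.5, total dose 0.5 -> Dx(fa) = 1 -> fa = 0.5
        p = MedianEffectParams(1.0, 1.0)
        table = generate_combination(p, p, (1, 1), target_ci=0.5,
                                     total_doses=[0.5])
        assert table["fraction_affected"].iloc[0] == pytest.approx(0.5, abs=1e-10)

    def test_combination_rejects_bad_inputs(self):
        p = MedianEffectParams(1.0, 1.0)
        with pytest.raises(ValueError):
            generate_combination(p, p, (1, 1), target_ci=0.0, total_doses=[1.0])
        with pytest.raises(ValueError):
            generate_combination(p, p, (0, 1), target_ci=1.0, total_doses=[1.0])


class TestImageGenerator:
    def test_zero_spots_is_blank_inside_roi(self):
        img, truth = generate_larva_image(ImageSpec(n_spots=0, noise_sd=0, seed=1))
        assert truth["area_px"] == 0
        assert (img == 200).all()

    def test_ground_truth_mask_matches_rendered_foreground(self):
        spec = ImageSpec(n_spots=25, noise_sd=0.0, seed=4)
        img, truth = generate_larva_image(spec)
        assert (img[truth["mask"]] == spec.spot_intensity).all()
        assert truth["area_px"] == int(truth["mask"].sum())
        # all foreground inside the roi
        left, top, w, h = spec.roi
        ys, xs = np.nonzero(truth["mask"])
        assert xs.min() >= left and xs.max() < left + w
        assert ys.min() >= top and ys.max() < top + h

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ConfigurationError, match="roi"):
            generate_larva_image(ImageSpec(width=500, height=300,
                                           roi=(0, 0, 1000, 500)))

    def test_seeded_determinism(self):
        spec = ImageSpec(n_spots=15, seed=8)
        a, _ = generate_larva_image(spec)
        b, _ = generate_larva_image(spec)
        assert np.array_equal(a, b)
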