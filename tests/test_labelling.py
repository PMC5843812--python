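"""Chemistry calculators: specific activity, osmolarity, dilution, fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vialdosim as vd
from vialdosim.labelling import FitError, logistic


class TestSpecificActivity:
    def test_bi213_carrier_free(self):
        assert vd.max_specific_activity(45.6 * 60.0) == pytest.approx(152.6, rel=1e-3)

    def test_lu177(self):
        assert vd.max_specific_activity(6.71 * 86400.0) == pytest.approx(0.72, rel=0.01)

    def test_inverse_proportionality(self):
        assert vd.max_specific_activity(2 * 2736.0) == pytest.approx(
            vd.max_specific_activity(2736.0) / 2
        )

    def test_achievable_fraction(self):
        assert vd.achievable_sa(155.0, 0.6) == pytest.approx(93.0)
        assert vd.achievable_sa(155.0, 0.0) == 0.0
        assert vd.achievable_sa(155.0, 1.0) == 155.0
        with pytest.raises(ValueError):
            vd.achievable_sa(155.0, 1.2)

    @given(st.floats(60.0, 1e7), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_achievable_never_exceeds_max(self, half_life, ratio):
        mx = vd.max_specific_activity(half_life)
        assert vd.achievable_sa(mx, ratio) <= mx * (1 + 1e-12)


class TestOsmolarity:
    def test_standard_recipe(self):
        assert vd.osmolarity(vd.standard_recipe()) == pytest.approx(0.7, abs=0.02)

    def test_optimized_recipe(self):
        assert vd.osmolarity(vd.optimized_recipe()) == pytest.approx(0.45, abs=0.01)

    def test_pure_water_is_zero(self):
        rec = vd.LabellingRecipe(components=[], total_volume_uL=800.0)
        assert vd.osmolarity(rec) == 0.0

    def test_additivity_in_components(self):
        base = vd.LabellingRecipe(
            components=[vd.RecipeComponent("TRIS", 0.15, 800.0, 1)],
            total_volume_uL=800.0,
        )
        extra = vd.LabellingRecipe(
            components=[
                vd.RecipeComponent("TRIS", 0.15, 800.0, 1),
                vd.RecipeComponent("NaI", 0.1, 600.0, 2),
            ],
            total_volume_uL=800.0,
        )
        assert vd.osmolarity(extra) == pytest.approx(
            vd.osmolarity(base) + 0.1 * 600 / 800 * 2
        )

    def test_component_volume_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            vd.LabellingRecipe(
                components=[vd.RecipeComponent("TRIS", 0.1, 900.0, 1)],
                total_volume_uL=800.0,
            )


class TestDilution:
    def test_clonogenic_dilution_matches_reported_concentrations(self):
        conc = vd.dilute(vd.standard_recipe(), 400.0, 8400.0)
        assert conc["TRIS"] * 1e3 == pytest.approx(16.0, rel=0.02)
        assert conc["ascorbic acid"] * 1e3 == pytest.approx(3.4, rel=0.02)
        assert conc["NaI"] * 1e3 == pytest.approx(3.6, rel=0.02)

    def test_identity_dilution(self):
        rec = vd.standard_recipe()
        assert vd.dilute(rec, 800.0, 800.0) == rec.final_concentrations_M()

    def test_aliquot_larger_than_final_rejected(self):
        with pytest.raises(ValueError):
            vd.dilute(vd.standard_recipe(), 900.0, 800.0)


class TestIncorporationFit:
    amounts = np.array([1.7, 2.0, 2.2, 2.4, 2.6, 2.8, 3.2, 3.5, 7.0])

    def test_noiseless_exact_recovery(self):
        y = logistic(self.amounts, 2.4, 0.25, 99.0)
        fit = vd.fit_incorporation(self.amounts, y)
        assert fit.m50_nmol == pytest.approx(2.4, abs=1e-6)
        assert fit.slope_nmol == pytest.approx(0.25, abs=1e-6)
        assert fit.asymptote_pct == pytest.approx(99.0, abs=1e-5)

    def test_noisy_recovery_within_three_se(self):
        df = vd.gen_incorporation(vd.GeneratorConfig(seed=42))
        fit = vd.fit_incorporation(df["peptide_nmol"], df["incorporation_pct"])
        assert abs(fit.m50_nmol - 2.4) < 3 * fit.se_m50
        assert fit.slope_nmol > 0

    def test_bias_shrinks_with_noise(self):
        """Mean |m₅₀ bias| over seeds decreases as σ → 0."""
        biases = []
        for sd in (3.0, 1.0, 0.1):
            errs = []
            for seed in range(10):
                df = vd.gen_incorporation(
                    vd.GeneratorConfig(seed=seed, noise_sd_pct=sd)
                )
                fit = vd.fit_incorporation(df["peptide_nmol"], df["incorporation_pct"])
                errs.append(abs(fit.m50_nmol - 2.4))
            biases.append(np.mean(errs))
        assert biases[0] > biases[2]
        assert biases[2] < 0.01

    def test_decreasing_data_fails_loudly(self):
        y = logistic(self.amounts, 2.4, 0.25, 99.0)[::-1]
        with pytest.raises(FitError) as exc:
            vd.fit_incorporation(self.amounts, y)
        assert "increase" in str(exc.value)

    def test_sparse_design_fixes_asymptote(self):
        m = np.repeat([1.7, 2.4, 3.5, 7.0], 3)
        y = logistic(m, 2.4, 0.25, 99.0)
        fit = vd.fit_incorporation(m, y)
        assert fit.asymptote_fixed

    def test_minimum_peptide_for_target(self):
        fit = vd.fit_incorporation(
            self.amounts, logistic(self.amounts, 2.4, 0.25, 99.0)
        )
        m_min = vd.minimum_peptide_for_incorporation(fit, 95.0)
        assert logistic(m_min, 2.4, 0.25, 99.0) == pytest.approx(95.0, abs=0.1)
        assert vd.minimum_peptide_for_incorporation(fit, 99.5) == np.inf


class TestAscorbicRequirement:
    def test_anchor_dose(self):
        res = vd.required_ascorbic(200.0, 800.0)
        assert res["mmol_per_L"] == pytest.approx(0.9)
        assert not res["extrapolated"]

    def test_zero_dose(self):
        assert vd.required_ascorbic(0.0, 800.0)["mmol_per_L"] == 0.0

    def test_linear_extrapolation_above_anchor(self):
        res = vd.required_ascorbic(400.0, 800.0)
        assert res["mmol_per_L"] == pytest.approx(1.8)
        assert res["extrapolated"]

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            vd.required_ascorbic(-1.0)


class TestRcpPass:
    def test_stable_series_passes(self):
        s = vd.StabilitySeries([0, 60, 120], [88.0, 88.0, 88.0], 71.0)
        ok, summary = vd.rcp_pass(s, 85.0, 120.0)
        assert ok and summary["violations"] == []

    def test_low_quencher_series_fails(self):
        # 0.1 mmol/L condition: RCP ~75 % directly after labelling
        s = vd.StabilitySeries([0, 60, 120], [75.0, 70.0, 60.0], 0.1)
        ok, summary = vd.rcp_pass(s, 85.0, 120.0)
        assert not ok
        assert len(summary["violations"]) == 3

    def test_empty_horizon_window_rejected(self):
        s = vd.StabilitySeries([60, 120], [88.0, 88.0], 71.0)
        with pytest.raises(ValueError):
            vd.rcp_pass(s, 85.0, 30.0)


def test_recipe_csv_round_trip(tmp_path):
    rec = vd.standard_recipe()
    path = tmp_path / "recipe.csv"
    vd.recipe_to_csv(rec, path)
    back = vd.recipe_from_csv(path)
    assert back.total_volume_uL == rec.total_volume_uL
    assert back.final_concentrations_M() == pytest.approx(rec.final_concentrations_M())
    assert vd.osmolarity(back) == pytest.approx(vd.osmolarity(rec))
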