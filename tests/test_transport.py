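"""Transport engine: range models, β sampling, absorbed fractions, S-values."""

import numpy as np
import pytest

import vialdosim as vd
from vialdosim.nuclides import EmissionLine
from vialdosim.transport import (
    ALPHA_CALIBRATION,
    ELECTRON_CALIBRATION,
    REFERENCE_VOLUMES_UL,
    fit_range_energy,
)


class TestRangeEnergyModel:
    def test_alpha_exponent_matches_two_point_closed_form(self, range_models):
        expected = np.log(81.75 / 46.47) / np.log(8.38 / 5.87)
        assert range_models["alpha"].p == pytest.approx(expected, rel=1e-9)

    def test_calibration_points_reproduced(self, range_models):
        for model, points in (
            (range_models["alpha"], ALPHA_CALIBRATION),
            (range_models["electron"], ELECTRON_CALIBRATION),
        ):
            for E, R in points:
                assert model.range_um(E) == pytest.approx(R, rel=0.05)

    def test_low_energy_electron_range(self, range_models):
        assert range_models["electron"].range_um(0.197) == pytest.approx(440.0, rel=0.10)

    def test_strictly_increasing_and_invertible(self, range_models):
        for model in range_models.values():
            E = np.geomspace(0.01, 10.0, 200)
            R = model.range_um(E)
            assert np.all(np.diff(R) > 0)
            assert np.allclose(model.energy_MeV(R), E, rtol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_range_energy([(5.87, 46.47)], "alpha")
        with pytest.raises(ValueError):
            fit_range_energy(ALPHA_CALIBRATION, "electron")


class TestBetaSampling:
    @pytest.mark.parametrize(
        "E_max, Z, mean",
        [(1.422, 84, 0.434), (1.944, 82, 0.655), (0.644, 83, 0.197)],
    )
    def test_sample_mean_near_tabulated(self, E_max, Z, mean):
        samples = vd.sample_beta_energy(E_max, Z, 200_000, rng=1)
        assert samples.mean() == pytest.approx(mean, rel=0.15)
        assert np.all(samples > 0) and np.all(samples < E_max)

    def test_invalid_endpoint(self):
        with pytest.raises(ValueError):
            vd.sample_beta_energy(-1.0, 84)


class TestAbsorbedFraction:
    def test_zero_range_particle_fully_absorbed(self, geometry, range_models):
        # energy far below every calibration point → extrapolated range
        # ~1e-4 μm, smaller than any boundary distance resolution
        line = EmissionLine(kind="recoil", yield_per_decay=1.0, energy_MeV=0.1)
        res = vd.absorbed_fraction(geometry, 10.0, line, range_models, n=10_000, rng=0)
        assert res.absorbed_fraction == 1.0

    def test_alpha_absorbed_fractions_near_reference(self, geometry, range_models, chain):
        (bi_a,) = chain["Bi-213"].lines(("alpha",))
        (po_a,) = chain["Po-213"].lines(("alpha",))
        cases = [
            (bi_a, 10.0, 0.989),
            (bi_a, 800.0, 0.997),
            (po_a, 10.0, 0.972),
            (po_a, 800.0, 0.992),
        ]
        for line, vol, ref in cases:
            res = vd.absorbed_fraction(geometry, vol, line, range_models, n=200_000, rng=8)
            assert res.absorbed_fraction == pytest.approx(ref, rel=0.02)
            assert 0.0 <= res.absorbed_fraction <= 1.0
            assert res.standard_error < 0.01

    def test_phi_monotone_in_volume(self, geometry, range_models, chain):
        (po_a,) = chain["Po-213"].lines(("alpha",))
        (bi_b,) = chain["Bi-213"].lines(("beta_spectrum",))
        for line in (po_a, bi_b):
            phis = [
                vd.absorbed_fraction(
                    geometry, v, line, range_models, n=100_000, rng=4, nuclide="Bi-213"
                ).absorbed_fraction
                for v in REFERENCE_VOLUMES_UL
            ]
            assert all(b > a for a, b in zip(phis, phis[1:]))

    def test_deterministic_under_seed(self, geometry, range_models, chain):
        (po_a,) = chain["Po-213"].lines(("alpha",))
        r1 = vd.absorbed_fraction(geometry, 50.0, po_a, range_models, n=50_000, rng=9)
        r2 = vd.absorbed_fraction(geometry, 50.0, po_a, range_models, n=50_000, rng=9)
        assert r1.absorbed_fraction == r2.absorbed_fraction

    def test_energy_conservation_per_history(self, geometry, range_models, chain):
        (bi_b,) = chain["Bi-213"].lines(("beta_spectrum",))
        res = vd.absorbed_fraction(
            geometry, 50.0, bi_b, range_models, n=20_000, rng=2,
            nuclide="Bi-213", keep_histories=True,
        )
        deposited, emitted = res.deposited_MeV, res.emitted_MeV
        escaped = emitted - deposited
        assert np.all(deposited >= 0) and np.all(escaped >= -1e-15)
        np.testing.assert_allclose(deposited + escaped, emitted, rtol=1e-12)

    def test_sphere_oracle_agreement(self, geometry, range_models, chain):
        """The cone engine and the analytic equal-volume-sphere chord
        integral agree within 1 % absolute for α emissions."""
        (bi_a,) = chain["Bi-213"].lines(("alpha",))
        (po_a,) = chain["Po-213"].lines(("alpha",))
        for line in (bi_a, po_a):
            for vol in (10.0, 100.0, 800.0):
                mc = vd.absorbed_fraction(
                    geometry, vol, line, range_models, n=200_000, rng=6
                ).absorbed_fraction
                analytic = vd.sphere_absorbed_fraction(vol, line.energy_MeV, range_models["alpha"])
                assert abs(mc - analytic) < 0.01


class TestSValues:
    def test_total_equals_component_sum(self, computed_svalues):
        df = computed_svalues.table
        for (nuc, vol), grp in df.groupby(["nuclide", "volume_uL"]):
            total = grp.loc[grp.component == "total", "svalue"].iloc[0]
            parts = grp.loc[grp.component != "total", "svalue"].sum()
            assert total == pytest.approx(parts, abs=1e-9)

    def test_full_absorption_bound(self, computed_svalues, chain, geometry):
        """Every S-value respects the φ = 1 bound Σ y·E·C/m."""
        from vialdosim.transport import MEV_TO_MGY_PER_MBQ_S, _KIND_TO_COMPONENT

        for nuc in chain.nuclides:
            for vol in computed_svalues.volumes():
                mass_kg = geometry.fluid_mass_g(vol) * 1e-3
                for comp in ("alpha", "beta", "electron", "gamma"):
                    bound = sum(
                        ln.yield_per_decay * ln.effective_energy_MeV
                        * MEV_TO_MGY_PER_MBQ_S / mass_kg
                        for ln in nuc.lines()
                        if _KIND_TO_COMPONENT[ln.kind] == comp and ln.kind != "recoil"
                    )
                    assert computed_svalues.value(nuc.name, comp, vol) <= bound * (1 + 1e-9)

    def test_svalues_non_increasing_in_volume(self, computed_svalues):
        df = computed_svalues.table
        for (nuc, comp), grp in df.groupby(["nuclide", "component"]):
            vals = grp.sort_values("volume_uL")["svalue"].to_numpy()
            assert np.all(np.diff(vals) < 0)

    def test_po213_alpha_svalue_at_10uL(self, computed_svalues):
        assert computed_svalues.value("Po-213", "alpha", 10.0) == pytest.approx(130.0, rel=0.10)

    def test_bi213_alpha_svalue_at_10uL(self, computed_svalues):
        assert computed_svalues.value("Bi-213", "alpha", 10.0) == pytest.approx(1.94, rel=0.10)

    def test_bad_volume_rejected(self, chain, geometry):
        with pytest.raises(ValueError):
            vd.svalues(chain, geometry, volumes_uL=(0.0,), n=1000)


class TestReferenceSValues:
    def test_spot_values(self, reference_svalues):
        assert reference_svalues.value("Pb-209", "beta", 800.0) == 0.04
        assert reference_svalues.value("Bi-213", "total", 10.0) == 5.12
        assert reference_svalues.value("Po-213", "alpha", 10.0) == 130.0
        assert reference_svalues.provenance == "reference"

    def test_totals_consistent_with_component_sums(self, reference_svalues):
        df = reference_svalues.table
        for (nuc, vol), grp in df.groupby(["nuclide", "volume_uL"]):
            total = grp.loc[grp.component == "total", "svalue"].iloc[0]
            parts = grp.loc[grp.component != "total", "svalue"].sum()
            # printed two-significant-figure rounding
            assert total == pytest.approx(parts, abs=0.015)


def test_half_angle_sweep_reports_mild_sensitivity(chain):
    """φ varies only weakly with the assumed cone shape at fixed
    capacity (surface-to-volume driven)."""
    (po_a,) = chain["Po-213"].lines(("alpha",))
    df = vd.sweep_half_angle(po_a, 800.0, cone_heights_mm=(16.0, 20.0, 24.0), n=50_000)
    assert list(df.columns) == ["cone_height_mm", "half_angle_deg", "absorbed_fraction", "se"]
    assert df["absorbed_fraction"].between(0.97, 1.0).all()
    assert df["absorbed_fraction"].max() - df["absorbed_fraction"].min() < 0.01
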