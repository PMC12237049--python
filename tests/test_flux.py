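"""Flux arithmetic: number and carbon fluxes, uncertainties, partitioning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gelflux as gf
from gelflux import (
    CellCarbonModel,
    FluxProfile,
    FluxRecord,
    TrapSample,
    bulk_poc_flux,
    cell_carbon,
    depth_average_flux,
    fold_change,
    number_flux,
    percent_of_bulk_poc,
    solitary_fraction,
    sphere_volume,
)
from gelflux.errors import UnitError, UserInputError


class TestNumberFlux:
    @pytest.mark.parametrize(
        "count,area,duration,value,sigma",
        [
            (0, 0.001, 2.0, 0.0, 0.0),
            (100, 0.0005, 2.0, 1.0e5, 1.0e4),
            (400, 0.002, 5.0, 40000.0, 2000.0),
        ],
    )
    def test_count_to_flux_arithmetic(self, count, area, duration, value, sigma):
        rec = number_flux(count, area, duration)
        assert rec.value == pytest.approx(value)
        assert rec.sigma == pytest.approx(sigma)
        assert rec.n_counted == count

    def test_relative_uncertainty_depends_only_on_count(self):
        # a typical per-gel count of 657 cells gives ~3.9% relative error
        # regardless of surveyed area and duration
        for area, duration in [(0.0005, 2.0), (0.01, 5.5)]:
            rec = number_flux(657, area, duration)
            assert rec.relative_sigma == pytest.approx(1 / math.sqrt(657))
            assert rec.relative_sigma == pytest.approx(0.039, abs=0.001)

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, 0, 1), (1, 1, 0), (1, -2, 3)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(UserInputError):
            number_flux(*bad)

    @settings(derandomize=True, max_examples=50)
    @given(
        count=st.integers(1, 10_000),
        area=st.floats(1e-5, 1e-2),
        duration=st.floats(0.5, 10.0),
        k=st.integers(2, 9),
    )
    def test_flux_linearity_and_sigma_scaling(self, count, area, duration, k):
        # scaling count and area together keeps the value; sigma falls 1/sqrt(k)
        base = number_flux(count, area, duration)
        scaled = number_flux(k * count, k * area, duration)
        assert scaled.value == pytest.approx(base.value, rel=1e-12)
        assert scaled.sigma == pytest.approx(base.sigma / math.sqrt(k), rel=1e-12)


class TestBulkPocFlux:
    def test_single_split_identity(self):
        rec = bulk_poc_flux([2.5], split_fraction=1.0, duration_d=1.0, area_m2=1.0)
        assert rec.value == pytest.approx(2.5)
        assert rec.sigma == 0.0
        assert "single_replicate" in rec.flags

    def test_split_into_eight_fractions(self):
        # three equal 1.0-unit masses, 1/8 split, 2 d, combined 0.0226 m^2 area
        rec = bulk_poc_flux([1.0, 1.0, 1.0], 0.125, 2.0, 0.0226)
        assert rec.value == pytest.approx(1.0 / 0.125 / 2.0 / 0.0226, rel=1e-12)
        assert rec.value == pytest.approx(177.0, abs=0.05)
        assert rec.sigma == 0.0

    def test_combined_area_is_two_tubes(self):
        s = TrapSample(site="NA", deployment=1, platform="STT", depth_m=100, duration_d=2)
        assert s.combined_area_m2 == pytest.approx(2 * s.tube_area_m2)
        assert s.combined_area_m2 == pytest.approx(0.0226)

    def test_replicate_spread_propagates(self):
        rec = bulk_poc_flux([0.9, 1.0, 1.1], 1.0, 1.0, 1.0)
        assert rec.sigma == pytest.approx(np.std([0.9, 1.0, 1.1], ddof=1) / math.sqrt(3))

    def test_empty_replicates_rejected(self):
        with pytest.raises(UserInputError):
            bulk_poc_flux([], 0.5, 1.0, 1.0)


class TestDepthAverageAndFoldChange:
    def test_single_depth_passthrough(self):
        p = FluxProfile(depths_m=[100.0], values=[5.0e5], sigmas=[1e4])
        rec = depth_average_flux(p)
        assert rec.value == pytest.approx(5.0e5)
        assert rec.sigma == pytest.approx(1e4)

    def test_symmetric_mean(self):
        p = FluxProfile(depths_m=[50, 150, 500], values=[1e6, 2e6, 3e6])
        assert depth_average_flux(p).value == pytest.approx(2e6)

    def test_trapezoid_scheme_weights_spacing(self):
        # constant flux: both schemes agree exactly
        p = FluxProfile(depths_m=[50, 100, 400], values=[7.0, 7.0, 7.0])
        assert depth_average_flux(p, "trapezoid").value == pytest.approx(7.0)
        assert depth_average_flux(p, "mean").value == pytest.approx(7.0)

    def test_noise_free_truth_recovery(self, default_dataset):
        # depth averaging the generator's truth fluxes returns their exact mean
        cfg = default_dataset.config
        taxon = "Thalassiosira"
        z = np.array(cfg.depths_m)
        truth = np.array([cfg.true_flux(taxon, zz, 1) for zz in z])
        p = FluxProfile(depths_m=z, values=truth)
        assert depth_average_flux(p).value == pytest.approx(truth.mean(), rel=1e-9)

    @pytest.mark.parametrize(
        "later,earlier,expected,decimals",
        [
            (1.26e6, 0.42e6, 3.0, 1),
            (2.23e6, 1.26e6, 1.8, 1),
            (0.23e6, 0.055e6, 4.2, 1),
        ],
    )
    def test_reference_fold_changes(self, later, earlier, expected, decimals):
        fc = fold_change(FluxRecord(later, 0.0), FluxRecord(earlier, 0.0))
        assert round(fc.value, decimals) == pytest.approx(expected)

    def test_identity_ratio(self):
        r = FluxRecord(3.3e5, 1e4)
        assert fold_change(r, r).value == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(UserInputError):
            fold_change(FluxRecord(1.0, 0.0), FluxRecord(0.0, 0.0))

    def test_unit_mixing_rejected(self):
        with pytest.raises(UnitError):
            fold_change(FluxRecord(1.0, 0.0, units=gf.CELLS), FluxRecord(1.0, 0.0, units=gf.CARBON))


class TestCellCarbon:
    def test_unit_sphere(self):
        assert sphere_volume(1.0) == pytest.approx(math.pi / 6)

    def test_midpoint_diameter_volume(self):
        assert sphere_volume(45.0) == pytest.approx(47712.9, abs=0.1)

    def test_cubic_scaling(self):
        assert sphere_volume(30.0) == pytest.approx(8 * sphere_volume(15.0))

    def test_allometric_identities(self):
        m = CellCarbonModel(diameter_um=45, allometric_a=0.288, allometric_b=0.811)
        assert cell_carbon(1.0, m) == pytest.approx(m.allometric_a)
        lin = CellCarbonModel(diameter_um=45, allometric_a=0.1, allometric_b=1.0)
        assert cell_carbon(2000.0, lin) == pytest.approx(0.1 * 2000.0)
        v1, v2 = 5000.0, 40000.0
        assert cell_carbon(v1, m) / cell_carbon(v2, m) == pytest.approx(
            (v1 / v2) ** m.allometric_b
        )

    def test_invalid_model_rejected(self):
        with pytest.raises(UserInputError):
            CellCarbonModel(diameter_um=5.0)
        with pytest.raises(UserInputError):
            CellCarbonModel(allometric_b=1.5)


class TestPercentOfBulkPoc:
    def test_equal_fluxes_give_100_percent(self):
        carbon_pg = 10.0
        cell = FluxRecord(1.2011e9, 0.0, units=gf.CELLS)  # x10 pg = 12.011e9 pg = 1 mmol
        bulk = FluxRecord(1.0, 0.0, units=gf.CARBON)
        pct = percent_of_bulk_poc(cell, carbon_pg, bulk)
        assert pct.value == pytest.approx(100.0)

    def test_zero_cell_flux(self):
        pct = percent_of_bulk_poc(
            FluxRecord(0.0, 0.0, units=gf.CELLS), 10.0, FluxRecord(1.0, 0.1, units=gf.CARBON)
        )
        assert pct.value == 0.0

    def test_configured_truth_fraction_recovered(self):
        # scenario built so solitary-cell carbon is 3% of bulk POC; the
        # estimated percent, averaged over seeds, recovers that within 0.5 pp
        estimates = []
        for seed in range(12):
            ds = gf.generate_scenario(gf.ScenarioConfig(seed=seed))
            samples = ds.samples_by_id
            ft = gf.fluxes_from_counts(ds.counts, samples)
            carbon_pg = ds.config.carbon_model.carbon_per_cell_pg()
            for sid, grp in ds.bulk_masses.groupby("sample_id"):
                s = samples[sid]
                bulk = bulk_poc_flux(
                    grp["mass_mmol"].to_numpy(),
                    ds.config.split_fraction,
                    s.duration_d,
                    s.combined_area_m2,
                )
                sub = ft[ft["sample_id"] == sid]
                cell = FluxRecord(
                    float(sub["flux"].sum()),
                    float(np.sqrt((sub["sigma"] ** 2).sum())),
                    units=gf.CELLS,
                )
                estimates.append(percent_of_bulk_poc(cell, carbon_pg, bulk).value)
        assert np.mean(estimates) == pytest.approx(3.0, abs=0.5)


class TestSolitaryFraction:
    def test_identity_and_zero(self):
        gel = number_flux(120, 0.001, 2.0)
        assert solitary_fraction(gel, gel).value == pytest.approx(1.0)
        zero = number_flux(0, 0.001, 2.0)
        frac = solitary_fraction(zero, gel)
        assert frac.value == 0.0
        # zero-count numerator carries the 1.84-count upper-bound sigma
        assert frac.sigma == pytest.approx(1.84 * zero.per_count / gel.value)

    def test_exceeds_unity_flagged(self):
        gel = number_flux(150, 0.001, 2.0)
        bulk = number_flux(100, 0.001, 2.0)
        frac = solitary_fraction(gel, bulk)
        assert frac.value > 1
        assert "exceeds_unity" in frac.flags

    def test_non_co_deployed_pairing_rejected(self):
        a = TrapSample(site="NA", deployment=3, platform="STT", depth_m=500, duration_d=1.8)
        b = TrapSample(site="NA", deployment=2, platform="STT", depth_m=500, duration_d=1.8)
        gel = number_flux(10, 0.001, 1.8)
        with pytest.raises(UserInputError):
            solitary_fraction(gel, gel, gel_sample=a, bulk_sample=b)

    def test_configured_embedded_split_recovered(self):
        # gel counts drawn at 22% of the bulk cell flux: the aggregate ratio
        # across taxa lands within counting error of 0.22
        rng = np.random.default_rng(5)
        area, dur = 0.001, 1.8
        bulk_flux = np.array([2e5, 1e5, 5e4, 3e4])  # per taxon
        gel_counts = rng.poisson(0.22 * bulk_flux * area * dur)
        bulk_counts = rng.poisson(bulk_flux * area * dur)
        gel = number_flux(int(gel_counts.sum()), area, dur)
        bulk = number_flux(int(bulk_counts.sum()), area, dur)
        frac = solitary_fraction(gel, bulk)
        assert frac.value == pytest.approx(0.22, abs=3 * frac.sigma + 0.01)


class TestUncertaintyCalibration:
    def test_68_percent_interval_coverage(self):
        # over many Poisson replicates at realistic count levels, value±sigma
        # covers the true flux 62-74% of the time
        rng = np.random.default_rng(2024)
        area, dur = 0.0005, 5.0
        true_fluxes = rng.uniform(2e4, 4e5, size=1500)  # lambda ~ 50..1000
        covered = 0
        for f in true_fluxes:
            lam = f * area * dur
            n = rng.poisson(lam)
            rec = number_flux(int(n), area, dur)
            if abs(rec.value - f) <= rec.sigma:
                covered += 1
        assert 0.62 <= covered / len(true_fluxes) <= 0.74
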