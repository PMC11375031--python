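"""Oligomer deconvolution: centers, mixture fit, gating, CIs, threshold sweep."""

import math

import numpy as np
import pytest
from scipy.special import erf

from smds import synthetic
from smds.exceptions import InvalidInputError, InvalidParameterError
from smds.oligomers import (
    SpeciesRegion,
    abundance_ci,
    fit_brightness_mixture,
    gate_bursts,
    oligomer_centers,
    select_species_count,
    skewnorm_moments,
    skewnorm_params_from_moments,
    species_regions,
    threshold_sweep,
)

TRUTH = np.array([0.679, 0.207, 0.072, 0.042])


class TestCenters:
    def test_multiples_of_monomer_mean(self):
        np.testing.assert_allclose(oligomer_centers(75.33, 4),
                                   [150.66, 225.99, 301.32])

    def test_unit_monomer(self):
        np.testing.assert_allclose(oligomer_centers(1.0, 3), [2.0, 3.0])

    def test_linearity(self):
        np.testing.assert_allclose(oligomer_centers(2 * 75.33, 4),
                                   2 * oligomer_centers(75.33, 4))

    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            oligomer_centers(0.0, 4)
        with pytest.raises(InvalidParameterError):
            oligomer_centers(75.33, 1)


def test_skewnorm_moment_roundtrip():
    xi, om, al = skewnorm_params_from_moments(75.33, 37.44, 4.0)
    mean, sd = skewnorm_moments(xi, om, al)
    assert mean == pytest.approx(75.33, rel=1e-12)
    assert sd == pytest.approx(37.44, rel=1e-12)


class TestMixtureFit:
    def test_pure_monomer(self):
        x, _ = synthetic.generate_oligomer_bursts(75.33, 37.44,
                                                  np.array([1.0]), 5000, seed=0)
        mix = fit_brightness_mixture(x, 1)
        assert mix.abundances == pytest.approx([1.0])
        assert mix.i_monomer == pytest.approx(75.33, rel=0.05)
        assert mix.sigma_monomer == pytest.approx(37.44, rel=0.10)

    def test_four_species_recovery(self):
        x, _ = synthetic.generate_oligomer_bursts(75.33, 37.44, TRUTH,
                                                  10_000, seed=1)
        mix = fit_brightness_mixture(x, 4)
        assert np.max(np.abs(mix.abundances - TRUTH)) < 0.03
        assert mix.i_monomer == pytest.approx(75.33, rel=0.05)

    def test_tied_center_constraint(self):
        x, _ = synthetic.generate_oligomer_bursts(75.33, 37.44, TRUTH,
                                                  10_000, seed=2)
        mix = fit_brightness_mixture(x, 4)
        np.testing.assert_allclose(mix.oligomer_centers,
                                   [2, 3, 4] * np.array(mix.i_monomer), rtol=1e-12)

    def test_too_few_bursts_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_brightness_mixture(np.random.default_rng(0).normal(75, 37, 100), 4)
        with pytest.raises(InvalidParameterError):
            fit_brightness_mixture(np.random.default_rng(0).normal(75, 37, 500), 0)


class TestModelSelection:
    def test_single_candidate_degenerate(self):
        x, _ = synthetic.generate_oligomer_bursts(75.33, 37.44, TRUTH, 2000, seed=3)
        k, table = select_species_count(x, [3])
        assert k == 3 and len(table) == 1

    def test_one_species_data_selects_one(self):
        wins = 0
        for seed in range(8):
            x, _ = synthetic.generate_oligomer_bursts(
                75.33, 37.44, np.array([1.0]), 5000, seed=10 + seed)
            k, _ = select_species_count(x, [1, 2, 3])
            wins += k == 1
        assert wins >= 7

    def test_four_species_data_selects_four(self):
        wins = 0
        for seed in range(5):
            x, _ = synthetic.generate_oligomer_bursts(75.33, 37.44, TRUTH,
                                                      10_000, seed=30 + seed)
            k, _ = select_species_count(x, [3, 4, 5])
            wins += k == 4
        assert wins >= 4


class TestGating:
    def test_region_below_everything(self):
        x, _ = synthetic.generate_oligomer_bursts(75.33, 37.44, TRUTH, 1000, seed=4)
        bursts = x  # gate_bursts works on Burst lists; use array-based path
        from smds.bursts import Burst
        bl = [Burst(0.0, 1.0, max(int(v), 1), v) for v in x]
        assert gate_bursts(bl, SpeciesRegion("sub", -100.0, 1.0)) == []

    def test_disjoint_exhaustive_regions_partition(self):
        from smds.bursts import Burst
        rng = np.random.default_rng(5)
        bl = [Burst(0.0, 1.0, 10, v) for v in rng.uniform(0, 300, 500)]
        regions = [SpeciesRegion(f"r{i}", 50.0 + 100.0 * i, 50.0) for i in range(3)]
        gated = [gate_bursts(bl, r) for r in regions]
        assert sum(len(g) for g in gated) == len(bl)
        ids = [id(b) for g in gated for b in g]
        assert len(set(ids)) == len(ids)

    def test_dimer_capture_fraction_matches_gaussian_integral(self):
        """+/- 1 sd gate on pure Gaussian dimer bursts captures erf(1/sqrt(2))."""
        from smds.bursts import Burst
        i_mono, sd = 75.33, 37.44
        rng = np.random.default_rng(6)
        x = rng.normal(2 * i_mono, sd, 20_000)
        bl = [Burst(0.0, 1.0, 10, v) for v in x]
        captured = len(gate_bursts(bl, SpeciesRegion("dimer", 2 * i_mono, sd)))
        expected = erf(1.0 / math.sqrt(2.0))  # 0.6827
        assert captured / len(bl) == pytest.approx(expected, abs=0.01)

    def test_regions_from_mixture(self):
        x, _ = synthetic.generate_oligomer_bursts(75.33, 37.44, TRUTH, 5000, seed=7)
        mix = fit_brightness_mixture(x, 4)
        regs = species_regions(mix)
        assert [r.label for r in regs] == ["monomer", "dimer", "trimer", "tetramer"]
        assert regs[1].center == pytest.approx(2 * mix.i_monomer)
        assert regs[1].half_width == pytest.approx(mix.sigma_monomer)


class TestAbundanceCI:
    def test_deterministic_under_fixed_seed(self):
        x, _ = synthetic.generate_oligomer_bursts(75.33, 37.44, TRUTH, 3000, seed=8)
        mix = fit_brightness_mixture(x, 4)
        ci1 = abundance_ci(mix, x, n_boot=100, seed=42)
        ci2 = abundance_ci(mix, x, n_boot=100, seed=42)
        np.testing.assert_array_equal(ci1, ci2)

    def test_pure_monomer_ci_contains_one(self):
        x, _ = synthetic.generate_oligomer_bursts(75.33, 37.44,
                                                  np.array([1.0]), 3000, seed=9)
        mix = fit_brightness_mixture(x, 1)
        ci = abundance_ci(mix, x, n_boot=100, seed=0)
        assert ci[0, 0] <= 1.0 <= ci[0, 1] + 1e-12

    def test_n_boot_floor(self):
        x, _ = synthetic.generate_oligomer_bursts(75.33, 37.44, TRUTH, 1000, seed=10)
        mix = fit_brightness_mixture(x, 4)
        with pytest.raises(InvalidParameterError):
            abundance_ci(mix, x, n_boot=50)


class TestThresholdSweep:
    def _traces(self, geom, flow100, cond, basis, species, seed, total=4000):
        acq = synthetic.AcquisitionSpec(seed=seed, dwell_s=1.0,
                                        background_rate_khz=1.0,
                                        n_steps_per_crossing=40)
        pos, bounds = synthetic.step_positions(geom, 40)
        scale = total / sum(
            synthetic.expected_total_counts([s], geom, flow100, acq, basis,
                                            pos, bounds) for s in species)
        species = [synthetic.SpeciesSpec(s.r_h_nm, s.concentration_M * scale,
                                         s.brightness_photons_ms,
                                         dict(s.labeled_units_dist), s.label)
                   for s in species]
        traces, man = synthetic.generate_step_scan(species, geom, flow100, cond,
                                                   acq, basis)
        return traces, [tuple(b) for b in man["crossing_boundaries"]]

    def test_single_value_equals_plain_fit(self, geom, flow100, cond, basis_small):
        traces, bounds = self._traces(geom, flow100, cond, basis_small,
                                      [synthetic.SpeciesSpec(10.0, 1e-12)], seed=11)
        table, ensemble = threshold_sweep(traces, [5], 0.01, basis_small,
                                          crossing_boundaries=bounds)
        assert len(table) == 1
        assert table.loc[0, "r_h_nm"] == pytest.approx(ensemble.r_h_nm, rel=1e-9)

    def test_monodisperse_sample_is_flat(self, geom, flow100, cond, basis_small):
        traces, bounds = self._traces(geom, flow100, cond, basis_small,
                                      [synthetic.SpeciesSpec(10.0, 1e-12)],
                                      seed=12, total=6000)
        table, _ = threshold_sweep(traces, [5, 10, 20, 40], 0.01, basis_small,
                                   crossing_boundaries=bounds)
        good = table[~table["undersampled"]]
        r = good["r_h_nm"].to_numpy()
        assert r.size >= 3
        assert (r.max() - r.min()) / r.mean() < 0.25

    def test_brightness_size_correlation_raises_rh(self, geom, flow100, cond,
                                                   basis_small):
        """With brightness ~ monomer count, higher N_min selects bigger species."""
        species = [
            synthetic.SpeciesSpec(3.0, 1e-12, label="small"),
            synthetic.SpeciesSpec(30.0, 1e-12,
                                  labeled_units_dist={6: 1.0}, label="big"),
        ]
        traces, bounds = self._traces(geom, flow100, cond, basis_small, species,
                                      seed=13, total=8000)
        # low threshold sees everything; a photon floor above the small
        # species' per-transit yield isolates the bright hexameric species
        table, _ = threshold_sweep(traces, [10, 400], 0.01, basis_small,
                                   crossing_boundaries=bounds)
        r = table["r_h_nm"].to_numpy()
        assert not table["undersampled"].any()
        assert r[1] > r[0]
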