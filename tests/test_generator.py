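"""Simulation operations: determinism, exact degenerate cases, moments."""

import numpy as np
import pytest

from irsim import (
    ComponentLibrary,
    DiscriminantModel,
    SimulationConfig,
    ValidationError,
    apply_noise,
    calibrate_descriptive,
    simulate_bottom_up,
    simulate_case_control,
    simulate_descriptive,
    subsample_basis,
    subsample_basis_pair,
)


class TestSimulateDescriptive:
    def test_zero_scales_reproduce_mean_exactly(self, small_models):
        model = small_models["control"]
        sim = simulate_descriptive(model, small_models["noise"], n=5, beta_scale=0, eps_scale=0)
        assert np.array_equal(sim.absorbance, np.tile(model.mean_spectrum, (5, 1)))

    def test_seed_determinism(self, small_models):
        a = simulate_descriptive(small_models["control"], small_models["noise"], 8, seed=42)
        b = simulate_descriptive(small_models["control"], small_models["noise"], 8, seed=42)
        c = simulate_descriptive(small_models["control"], small_models["noise"], 8, seed=43)
        assert np.array_equal(a.absorbance, b.absorbance)
        assert not np.array_equal(a.absorbance, c.absorbance)

    def test_moment_recovery(self, small_reference, small_models):
        """20,000 draws match the calibrating mean and variance + noise
        within 4 standard errors at every feature."""
        controls = small_reference[0]
        model, noise = small_models["control"], small_models["noise"]
        n = 20_000
        sim = simulate_descriptive(model, noise, n, seed=11)
        target_var = controls.absorbance.var(axis=0, ddof=1) + noise.sigma**2
        se_mean = np.sqrt(target_var / n)
        assert np.all(np.abs(sim.absorbance.mean(axis=0) - model.mean_spectrum) < 4 * se_mean)
        sample_var = sim.absorbance.var(axis=0, ddof=1)
        se_var = target_var * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(sample_var - target_var) < 4 * se_var)

    def test_negative_inputs_rejected(self, small_models):
        with pytest.raises(ValidationError):
            simulate_descriptive(small_models["control"], small_models["noise"], 3, beta_scale=-1)
        with pytest.raises(ValidationError):
            simulate_descriptive(small_models["control"], small_models["noise"], 0)


class TestSelfConsistency:
    def test_recalibration_round_trip(self, small_models):
        """Calibrating on a large noise-free simulated cohort reproduces the
        original model's first two moments within Monte-Carlo error."""
        model = small_models["control"]
        sim = simulate_descriptive(model, None, 5000, eps_scale=0.0, seed=3)
        recal = calibrate_descriptive(sim)
        target_var = model.implied_variance()
        np.testing.assert_allclose(
            recal.mean_spectrum, model.mean_spectrum, atol=4 * np.sqrt(target_var / 5000).max()
        )
        np.testing.assert_allclose(recal.implied_variance(), target_var, rtol=0.15)


class TestSimulateCaseControl:
    def test_discriminant_zero_sigma_exact(self, small_models):
        model = small_models["control"]
        d = np.linspace(-1, 1, model.p)
        disc = DiscriminantModel(model.wavenumbers, d, delta_mu=2.0, delta_sigma=0.0)
        sim = simulate_case_control(
            model, disc, None,
            SimulationConfig(n_controls=3, n_cases=4, beta_scale=0, eps_scale=0,
                             case_mode="discriminant"),
        )
        cases = sim.with_label("case").absorbance
        np.testing.assert_allclose(
            cases, np.tile(model.mean_spectrum + 2.0 * d, (4, 1)), rtol=0, atol=0
        )
        controls = sim.with_label("control").absorbance
        assert np.array_equal(controls, np.tile(model.mean_spectrum, (3, 1)))

    def test_zero_discriminant_classes_indistinguishable(self, small_models):
        from scipy.stats import ks_2samp

        model, noise = small_models["control"], small_models["noise"]
        disc = DiscriminantModel(model.wavenumbers, np.zeros(model.p), delta_mu=1.0)
        sim = simulate_case_control(
            model, disc, noise,
            SimulationConfig(n_controls=400, n_cases=400, case_mode="discriminant", seed=9),
        )
        stat = ks_2samp(
            sim.with_label("case").absorbance[:, 10], sim.with_label("control").absorbance[:, 10]
        )
        assert stat.pvalue > 0.01

    def test_two_pool_mean_difference(self, small_reference, small_models):
        """The simulated differential fingerprint matches the calibrating
        pools' mean difference within Monte-Carlo error (n = 20,000)."""
        controls, cases = small_reference[0], small_reference[1]
        sim = simulate_case_control(
            small_models["control"], small_models["case"], small_models["noise"],
            SimulationConfig(n_controls=20_000, n_cases=20_000, seed=21),
        )
        ref_diff = cases.absorbance.mean(axis=0) - controls.absorbance.mean(axis=0)
        sim_diff = (
            sim.with_label("case").absorbance.mean(axis=0)
            - sim.with_label("control").absorbance.mean(axis=0)
        )
        per_feature_sd = np.sqrt(
            cases.absorbance.var(axis=0, ddof=1) + controls.absorbance.var(axis=0, ddof=1)
        )
        assert np.all(np.abs(sim_diff - ref_diff) < 4 * per_feature_sd / np.sqrt(20_000))

    def test_missing_case_spec_rejected(self, small_models):
        with pytest.raises(ValidationError):
            simulate_case_control(
                small_models["control"], None, None, SimulationConfig(5, 5)
            )


class TestSubsampleBasis:
    def test_full_subset_keeps_row_set(self, small_models):
        model = small_models["control"]
        sub = subsample_basis(model, model.m, seed=1)
        assert sorted(sub.source_indices.tolist()) == list(range(model.m))
        np.testing.assert_array_equal(np.sort(sub.basis, axis=0), np.sort(model.basis, axis=0))

    def test_paired_draws_are_disjoint(self, small_models):
        a, b = subsample_basis_pair(
            small_models["control"], small_models["case"], 20, seed=3
        )
        assert a.m == b.m == 20
        assert not (set(a.source_indices.tolist()) & set(b.source_indices.tolist()))

    def test_beta_sigma_recalibration_and_pinning(self, small_models):
        model = small_models["control"]
        sub = subsample_basis(model, 10, seed=0)
        assert sub.beta_sigma == pytest.approx(1 / np.sqrt(9))
        pinned = subsample_basis(model, 10, seed=0, pin_beta_sigma=True)
        assert pinned.beta_sigma == model.beta_sigma

    def test_inclusion_uniformity(self, small_models):
        """Per-row inclusion frequency over repeated draws is uniform within
        binomial 4 SE (m_subset = 5 from a 100-row pool, 2000 draws)."""
        model = small_models["control"]
        draws = 2000
        counts = np.zeros(model.m)
        for i in range(draws):
            counts[subsample_basis(model, 5, seed=i).source_indices] += 1
        p = 5 / model.m
        se = np.sqrt(p * (1 - p) * draws)
        assert np.all(np.abs(counts - draws * p) < 4 * se)

    def test_out_of_range_rejected(self, small_models):
        with pytest.raises(ValidationError):
            subsample_basis(small_models["control"], 1)
        with pytest.raises(ValidationError):
            subsample_basis(small_models["control"], small_models["control"].m + 1)


class TestBottomUp:
    def grid(self, p):
        return np.arange(p, dtype=float) + 900.0

    def test_deterministic_single_component(self):
        lib = ComponentLibrary(self.grid(2), [[1.0, 1.0]], [2.0], [0.0])
        sim = simulate_bottom_up(lib, n=4, seed=0)
        assert np.array_equal(sim.absorbance, np.full((4, 2), 2.0))

    def test_two_components_exact_weighted_sum(self):
        lib = ComponentLibrary(
            self.grid(3), [[1.0, 0.0, 2.0], [0.0, 1.0, 1.0]], [3.0, 0.5], [0.0, 0.0]
        )
        sim = simulate_bottom_up(lib, n=2, seed=1)
        expected = 3.0 * np.array([1.0, 0.0, 2.0]) + 0.5 * np.array([0.0, 1.0, 1.0])
        np.testing.assert_array_equal(sim.absorbance, np.tile(expected, (2, 1)))

    def test_variance_of_mixture(self, rng):
        """Per-feature variance matches sum_i sigma_i^2 x_ij^2 within 4 SE."""
        X = rng.standard_normal((3, 12))
        sigma = np.array([0.5, 1.0, 2.0])
        lib = ComponentLibrary(self.grid(12), X, np.array([5.0, 6.0, 7.0]), sigma)
        n = 20_000
        sim = simulate_bottom_up(lib, n=n, seed=8)
        target = (sigma[:, None] ** 2 * X**2).sum(axis=0)
        se = target * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(sim.absorbance.var(axis=0, ddof=1) - target) < 4 * se)

    def test_negative_concentration_warning(self, caplog):
        lib = ComponentLibrary(self.grid(2), [[1.0, 1.0]], [1.0], [1.0])
        with caplog.at_level("WARNING", logger="irsim.generator"):
            simulate_bottom_up(lib, n=2, seed=0)
        assert any("negative concentration" in r.message for r in caplog.records)


class TestApplyNoise:
    def test_zero_scale_identity(self, small_simulated, small_models):
        out = apply_noise(small_simulated, small_models["noise"], eps_scale=0.0)
        assert np.array_equal(out.absorbance, small_simulated.absorbance)

    def test_noise_std_scaling(self, small_models):
        from irsim import NoiseModel, SpectralCohort

        p = 100
        wn = np.arange(p, dtype=float)
        noise = NoiseModel(wn, np.ones(p))
        base = SpectralCohort.from_arrays(wn, np.zeros((10_000, p)), "control", "s")
        noisy = apply_noise(base, noise, eps_scale=2.0, seed=4)
        assert 1.99 < noisy.absorbance.std(ddof=1) < 2.01

    def test_seed_contract(self, small_simulated, small_models):
        a = apply_noise(small_simulated, small_models["noise"], seed=1)
        b = apply_noise(small_simulated, small_models["noise"], seed=1)
        c = apply_noise(small_simulated, small_models["noise"], seed=2)
        assert np.array_equal(a.absorbance, b.absorbance)
        assert not np.array_equal(a.absorbance, c.absorbance)
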