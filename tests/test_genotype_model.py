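"""The joint genotype / fetal-fraction model: maps, likelihood, posteriors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddnipt.droplet_stats import ChannelCounts
from ddnipt.fetal_fraction import FFAssayObservation
from ddnipt.genotype_model import (
    AssayMode,
    FetalGenotype,
    MCMCConfig,
    ModelConfig,
    SampleObservation,
    calibrate_bias,
    convergence_diagnostics,
    expected_cnv_ratio,
    expected_ref_fraction,
    log_likelihood,
    quadrature_posterior,
    run_mcmc,
)
from ddnipt.simulator import SimulationSpec, simulate_sample

V = 8.5e-4
HOM, HET = FetalGenotype.HOM_REF, FetalGenotype.HET


def make_obs(k_ref, k_var, k_mat, k_pat, n=120000, mode=AssayMode.ALLELIC):
    return SampleObservation(
        sample_id="s",
        variant_a=ChannelCounts(k_ref, n),
        variant_b=ChannelCounts(k_var, n),
        ff_assay=FFAssayObservation(
            maternal_channel=ChannelCounts(k_mat, n),
            paternal_channel=ChannelCounts(k_pat, n),
        ),
        droplet_volume=V,
        assay_mode=mode,
    )


class TestExpectedRefFraction:
    def test_hom_ref_at_ten_percent_is_55(self):
        assert expected_ref_fraction(HOM, 0.10) == pytest.approx(0.55)

    @pytest.mark.parametrize("f", [0.0, 0.05, 0.1, 0.3, 1.0])
    def test_het_always_balanced(self, f):
        assert expected_ref_fraction(HET, f) == pytest.approx(0.50)

    def test_zero_fetal_dna_collapses_genotypes(self):
        assert expected_ref_fraction(HOM, 0.0) == pytest.approx(0.50)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            expected_ref_fraction(HOM, 1.2)
        with pytest.raises(ValueError):
            expected_ref_fraction(HOM, 0.1, bias=0.0)

    @given(st.floats(0.0, 0.499), st.floats(0.001, 0.5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_increasing_with_range(self, f, df):
        lo = expected_ref_fraction(HOM, f)
        hi = expected_ref_fraction(HOM, min(f + df, 0.5))
        if f + df <= 0.5:
            assert hi > lo
        assert 0.5 <= lo <= 0.75

    @given(st.floats(0.0, 0.5), st.floats(0.5, 2.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bias_inversion_mirrors_fraction(self, f, bias):
        # relabelling the channels inverts the bias and complements the
        # fraction: theta(theta0, b) = 1 - theta(1 - theta0, 1/b)
        theta0 = 0.5 + f / 2
        theta = bias * theta0 / (bias * theta0 + 1 - theta0)
        theta0c = 1 - theta0
        mirrored = (1 / bias) * theta0c / ((1 / bias) * theta0c + 1 - theta0c)
        assert theta == pytest.approx(1 - mirrored, abs=1e-12)


class TestExpectedCnvRatio:
    # oracle: copy counting over genome equivalents, ((1-f)*m + f*c)/2
    @pytest.mark.parametrize(
        "genotype, f, expected",
        [(HET, 0.2, 0.5), (HOM, 0.2, 0.6), (HOM, 0.0, 0.5)],
    )
    def test_copy_counting(self, genotype, f, expected):
        assert expected_cnv_ratio(genotype, f) == pytest.approx(expected)


class TestLogLikelihood:
    def test_all_negative_wells_closed_form(self):
        obs = make_obs(0, 0, 0, 0, n=10000)
        f, cv, cf = 0.1, 30.0, 20.0
        theta = expected_ref_fraction(HOM, f)
        lam = [cv * theta, cv * (1 - theta), cf * (1 - f / 2), cf * f / 2]
        expected = sum(-10000 * l * V for l in lam)
        assert log_likelihood(obs, HOM, f, cv, cf) == pytest.approx(expected)

    def test_het_invariant_under_channel_swap(self):
        a = log_likelihood(make_obs(900, 1100, 2000, 100), HET, 0.1, 30, 20)
        b = log_likelihood(make_obs(1100, 900, 2000, 100), HET, 0.1, 30, 20)
        assert a == pytest.approx(b)

    def test_generating_parameters_beat_distant_ones(self, make_sim):
        sim = make_sim(f=0.10, genotype=HOM, seed=5)
        truth = sim.true_lambdas
        cv = truth["REF_ALLELE"] + truth["VAR_ALLELE"]
        cf = truth["MATERNAL_ALLELE"] + truth["PATERNAL_ALLELE"]
        at_truth = log_likelihood(sim.obs, HOM, 0.10, cv, cf)
        shifted = log_likelihood(sim.obs, HOM, 0.40, cv, cf)
        assert at_truth > shifted

    def test_out_of_support_is_minus_inf(self):
        obs = make_obs(100, 100, 200, 10)
        assert log_likelihood(obs, HOM, 0.9, 30, 20) == -np.inf  # beyond f_high
        assert log_likelihood(obs, HOM, 0.1, -1.0, 20) == -np.inf


class TestQuadraturePosterior:
    def test_balanced_high_count_sample_calls_het(self):
        post = quadrature_posterior(make_obs(6000, 6000, 11000, 600))
        assert post.p_hom <= 0.05

    def test_shifted_sample_calls_hom_ref(self):
        # variant-assay fraction ~ 0.5 + f/2 at high counts
        post = quadrature_posterior(make_obs(6600, 5400, 11000, 600))
        assert post.p_hom >= 0.95

    def test_point_prior_at_zero_f_returns_genotype_prior(self):
        cfg = ModelConfig(f_low=0.0, f_high=0.0, genotype_prior=0.3)
        post = quadrature_posterior(make_obs(3000, 3000, 6000, 0), cfg)
        assert post.p_hom == pytest.approx(0.3, abs=1e-9)

    def test_grid_resolution_floor(self):
        with pytest.raises(ValueError):
            quadrature_posterior(make_obs(100, 100, 200, 20), n_f=32)

    def test_monotone_in_reference_count(self):
        p = [
            quadrature_posterior(make_obs(6000 + dk, 6000, 11000, 600)).p_hom
            for dk in (0, 150, 300, 450, 600)
        ]
        assert all(b >= a for a, b in zip(p, p[1:]))

    def test_quantiles_ordered_and_cover_truth(self, make_sim):
        sim = make_sim(f=0.12, seed=11)
        post = quadrature_posterior(sim.obs)
        assert post.f_post["q2.5"] <= post.f_post["median"] <= post.f_post["q97.5"]
        assert post.f_post["q2.5"] <= 0.12 <= post.f_post["q97.5"] or (
            abs(post.f_post["median"] - 0.12) < 0.02
        )

    def test_cnv_deletion_mode_recovers_genotype(self):
        for genotype, check in ((HOM, lambda p: p > 0.95), (HET, lambda p: p < 0.05)):
            sim = simulate_sample(
                SimulationSpec(
                    true_genotype=genotype,
                    true_f=0.15,
                    assay_mode=AssayMode.CNV_DELETION,
                    seed=7,
                )
            )
            post = quadrature_posterior(sim.obs)
            assert check(post.p_hom), (genotype, post.p_hom)

    def test_prior_sensitivity_small_on_informative_samples(self, make_sim):
        # a high-information sample should swamp reasonable prior changes
        sim = make_sim(f=0.15, seed=9)
        base = quadrature_posterior(sim.obs, ModelConfig()).p_hom
        for cfg in (
            ModelConfig(genotype_prior=0.3),
            ModelConfig(genotype_prior=0.7),
            ModelConfig(conc_max_mult=10.0),
        ):
            assert abs(quadrature_posterior(sim.obs, cfg).p_hom - base) < 0.01


class TestRunMCMC:
    SMALL = MCMCConfig(chains=4, adapt_iters=500, burn_in=1000, sampling_iters=4000, seed=2)

    def test_seed_reproducibility(self, make_sim):
        sim = make_sim(f=0.08, seed=13)
        a = run_mcmc(sim.obs, mcmc=self.SMALL)
        b = run_mcmc(sim.obs, mcmc=self.SMALL)
        assert a.p_hom == b.p_hom
        assert a.f_post == b.f_post

    def test_total_samples_bookkeeping(self, make_sim):
        sim = make_sim(seed=13)
        post = run_mcmc(sim.obs, mcmc=self.SMALL)
        assert post.total_samples == 4 * 4000

    def test_agrees_with_quadrature(self, make_sim):
        for f, genotype, seed in ((0.05, HOM, 21), (0.04, HET, 22)):
            sim = make_sim(f=f, genotype=genotype, seed=seed)
            m = run_mcmc(sim.obs, mcmc=self.SMALL)
            q = quadrature_posterior(sim.obs)
            assert m.p_hom == pytest.approx(q.p_hom, abs=0.05)
            assert m.f_post["median"] == pytest.approx(q.f_post["median"], abs=0.01)

    def test_diagnostics_populated_and_converged(self, make_sim):
        sim = make_sim(seed=13)
        post = run_mcmc(sim.obs, mcmc=self.SMALL, return_draws=True)
        assert set(post.diagnostics) == {"f", "conc_var", "conc_ff"}
        assert post.converged
        assert post.draws["f"].shape == (4, 4000)


class TestCalibrateBias:
    def test_balanced_control_is_unbiased(self):
        assert calibrate_bias(
            ChannelCounts(1000, 20000), ChannelCounts(1000, 20000), V
        ) == pytest.approx(1.0)

    def test_known_value(self):
        # oracle: (-ln(0.945)) / (-ln(0.955)) evaluated independently
        assert calibrate_bias(
            ChannelCounts(1100, 20000), ChannelCounts(900, 20000), V
        ) == pytest.approx(1.228617, abs=1e-4)

    def test_zero_counts_uncalibratable(self):
        with pytest.raises(ValueError):
            calibrate_bias(ChannelCounts(0, 20000), ChannelCounts(900, 20000), V)

    def test_self_consistency_on_control_data(self):
        # with the calibrated bias, the model's expected apparent fraction on
        # the same heterozygous control equals the control's observed fraction
        from ddnipt.droplet_stats import fractional_abundance

        ref, var = ChannelCounts(1100, 20000), ChannelCounts(900, 20000)
        b = calibrate_bias(ref, var, V)
        observed = fractional_abundance(ref, var, V).frac
        assert expected_ref_fraction(HET, 0.1, bias=b) == pytest.approx(observed)


class TestConvergenceDiagnostics:
    def test_constant_chains_flagged(self):
        diag = convergence_diagnostics({"x": np.ones((4, 500))})
        assert diag["x"]["flag"] and diag["x"]["rhat"] is None

    def test_well_mixed_chains(self):
        rng = np.random.default_rng(0)
        diag = convergence_diagnostics({"x": rng.normal(size=(4, 20000))})
        assert 0.99 <= diag["x"]["rhat"] <= 1.01
        assert not diag["x"]["flag"]

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(4, 500)) + np.arange(4)[:, None] * 10
        diag = convergence_diagnostics({"x": chains})
        assert diag["x"]["rhat"] > 1.05 and diag["x"]["flag"]

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            convergence_diagnostics({"x": np.random.default_rng(0).normal(size=(1, 500))})
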