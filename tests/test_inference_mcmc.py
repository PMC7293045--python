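"""Sampler components: Gibbs labels, MH updates, variance draw, chains."""

import numpy as np
import pytest

from bremsc.core_model import complete_log_posterior
from bremsc.datatypes import ModelParams, PairedCounts
from bremsc.inference_em import EMConfig, run_jointdimm
from bremsc.inference_mcmc import (
    MCMCConfig,
    alpha_proposal_logratio,
    b_proposal_logratio,
    flag_vague_cells,
    gibbs_update_z,
    mh_update_alpha,
    mh_update_b,
    run_bremsc,
    run_chain,
    update_sigma_b2,
)
from bremsc.initialization import initial_params
from bremsc.metrics import adjusted_rand_index
from bremsc.simulator import scenario_config, simulate_bremsc


class TestGibbsUpdateZ:
    def test_single_cluster_is_deterministic(self, toy_instance):
        data, params = toy_instance
        single = ModelParams(
            alpha_rna=params.alpha_rna[:1], alpha_adt=params.alpha_adt[:1],
            b=params.b, sigma_b2=params.sigma_b2, z=np.ones(3, dtype=int),
        )
        z = gibbs_update_z(data, single, np.random.default_rng(0))
        assert np.all(z == 1)

    def test_identical_rows_assign_half_half(self, toy_instance):
        data, params = toy_instance
        same = ModelParams(
            alpha_rna=np.vstack([params.alpha_rna[0]] * 2),
            alpha_adt=np.vstack([params.alpha_adt[0]] * 2),
            b=params.b, sigma_b2=params.sigma_b2, z=params.z,
        )
        rng = np.random.default_rng(1)
        draws = np.array([gibbs_update_z(data, same, rng) for _ in range(4000)])
        assert np.abs((draws == 1).mean() - 0.5) < 0.02

    def test_separated_clusters_recover_truth(self):
        data, truth = simulate_bremsc(
            scenario_config(K=2, cells_per_cluster=40, G=20, D=6, sigma_b=0.0, seed=2)
        )
        params = ModelParams(
            alpha_rna=truth.params_true.alpha_rna,
            alpha_adt=truth.params_true.alpha_adt,
            b=np.ones(data.n_cells), sigma_b2=1.0,
            z=np.ones(data.n_cells, dtype=int),
        )
        rng = np.random.default_rng(3)
        hits = np.mean(
            [np.mean(gibbs_update_z(data, params, rng) == truth.z_true) for _ in range(50)]
        )
        assert hits >= 0.99


class TestMetropolisUpdates:
    def test_zero_step_always_accepts_unchanged(self, toy_instance):
        data, params = toy_instance
        rng = np.random.default_rng(4)
        before_rna = params.alpha_rna.copy()
        block, accepted, proposed = mh_update_alpha(data, params, "rna", rng, step=0.0)
        assert np.array_equal(block, before_rna)
        assert accepted[proposed].all()
        before_b = params.b.copy()
        b_new, acc = mh_update_b(data, params, rng, step=0.0)
        assert np.array_equal(b_new, before_b)
        assert acc.all()

    def test_alpha_logratio_matches_posterior_difference(self, toy_instance):
        data, params = toy_instance
        rng = np.random.default_rng(5)
        for source in ("rna", "adt"):
            for k in (1, 2):
                block = params.alpha_rna if source == "rna" else params.alpha_adt
                prop = block[k - 1] * np.exp(rng.normal(0, 0.3, size=block.shape[1]))
                got = alpha_proposal_logratio(data, params, source, k, prop)
                changed = params.copy()
                if source == "rna":
                    changed.alpha_rna[k - 1] = prop
                else:
                    changed.alpha_adt[k - 1] = prop
                expected = (
                    complete_log_posterior(data, changed)
                    - complete_log_posterior(data, params)
                    + np.log(prop / block[k - 1]).sum()
                )
                assert got == pytest.approx(expected, abs=1e-9)

    def test_b_logratio_matches_posterior_difference(self, toy_instance):
        data, params = toy_instance
        rng = np.random.default_rng(6)
        b_prop = params.b * np.exp(rng.normal(0, 0.3, size=3))
        ratios = b_proposal_logratio(data, params, b_prop)
        for j in range(3):
            changed = params.copy()
            changed.b = params.b.copy()
            changed.b[j] = b_prop[j]
            expected = (
                complete_log_posterior(data, changed)
                - complete_log_posterior(data, params)
                + np.log(b_prop[j] / params.b[j])
            )
            assert ratios[j] == pytest.approx(expected, abs=1e-9)

    def test_b_sampler_has_lognormal_stationary_law_without_data(self):
        # with all counts zero the DM terms vanish and the exact posterior
        # of each b_j is its LogNormal(0, sigma_b2) prior; the MH kernel
        # must reproduce its moments (checks the asymmetry correction)
        c, sigma2 = 40, 0.36
        data = PairedCounts(
            rna_counts=np.zeros((2, c), dtype=int),
            adt_counts=np.zeros((2, c), dtype=int),
        )
        params = ModelParams(
            alpha_rna=np.ones((1, 2)), alpha_adt=np.ones((1, 2)),
            b=np.ones(c), sigma_b2=sigma2, z=np.ones(c, dtype=int),
        )
        rng = np.random.default_rng(7)
        samples = []
        for t in range(4000):
            params.b, _ = mh_update_b(data, params, rng, step=0.6)
            if t >= 500:
                samples.append(np.log(params.b))
        logs = np.concatenate(samples)
        assert abs(logs.mean()) < 0.02
        assert abs(logs.var() - sigma2) < 0.03

    def test_tiny_prior_variance_pins_b_near_one(self):
        data, truth = simulate_bremsc(
            scenario_config(K=2, cells_per_cluster=15, G=10, D=4, sigma_b=0.0, seed=8)
        )
        config = MCMCConfig(
            n_iter=120, n_chains=1, seed=0,
            sigma_b2_mode="fixed", sigma_b2_fixed=1e-8,
        )
        init = initial_params(data, 2, seed=0)
        trace = run_chain(data, 2, init, config, chain_seed=9)
        assert np.max(np.abs(trace.final_params.b - 1.0)) < 1e-3


class TestSigmaB2Update:
    def test_fixed_mode_returns_fixed_value(self, toy_instance):
        _, params = toy_instance
        config = MCMCConfig(sigma_b2_mode="fixed", sigma_b2_fixed=0.123)
        assert update_sigma_b2(params, np.random.default_rng(0), config) == 0.123

    def test_unit_b_draws_concentrate_near_zero(self):
        params = ModelParams(
            alpha_rna=np.ones((1, 2)), alpha_adt=np.ones((1, 2)),
            b=np.ones(500), sigma_b2=1.0, z=np.ones(500, dtype=int),
        )
        rng = np.random.default_rng(1)
        config = MCMCConfig()
        draws = [update_sigma_b2(params, rng, config) for _ in range(200)]
        # posterior InvGamma(0.01 + 250, 0.01): mean = 0.01/249.01
        assert np.mean(draws) < 1e-3

    def test_recovers_variance_of_lognormal_b(self):
        rng = np.random.default_rng(2)
        b = np.exp(rng.normal(0, 0.5, size=2000))
        params = ModelParams(
            alpha_rna=np.ones((1, 2)), alpha_adt=np.ones((1, 2)),
            b=b, sigma_b2=1.0, z=np.ones(2000, dtype=int),
        )
        config = MCMCConfig()
        draws = [update_sigma_b2(params, rng, config) for _ in range(300)]
        assert 0.2 <= np.mean(draws) <= 0.3


class TestChains:
    def test_same_seed_identical_traces(self, small_strong_data):
        data, _ = small_strong_data
        config = MCMCConfig(n_iter=40, n_chains=1, seed=0)
        init = initial_params(data, 3, seed=1)
        t1 = run_chain(data, 3, init, config, chain_seed=5)
        t2 = run_chain(data, 3, init, config, chain_seed=5)
        assert np.array_equal(t1.z_samples, t2.z_samples)
        assert np.array_equal(t1.log_post, t2.log_post)

    def test_single_cluster_z_trace_constant(self, toy_instance):
        data, _ = toy_instance
        config = MCMCConfig(n_iter=20, n_chains=1, seed=0)
        init = initial_params(data, 1, seed=0)
        trace = run_chain(data, 1, init, config, chain_seed=0)
        assert np.all(trace.z_samples == 1)

    def test_log_posterior_reaches_plateau(self, small_strong_data):
        data, _ = small_strong_data
        config = MCMCConfig(n_iter=300, n_chains=1, seed=0)
        init = initial_params(data, 3, seed=2)
        trace = run_chain(data, 3, init, config, chain_seed=3)
        lp = trace.log_post
        last_decile = lp[-len(lp) // 10 :]
        assert abs(last_decile.mean() - lp.max()) < 0.01 * abs(lp.max())

    def test_adapted_acceptance_in_healthy_range(self, small_strong_data):
        data, _ = small_strong_data
        config = MCMCConfig(n_iter=300, n_chains=1, seed=0)
        init = initial_params(data, 3, seed=4)
        trace = run_chain(data, 3, init, config, chain_seed=6)
        for frac in (trace.accept_alpha_rna, trace.accept_alpha_adt, trace.accept_b):
            assert 0.15 <= frac <= 0.50


class TestRunBremsc:
    def test_posterior_rows_sum_to_one_and_labels_argmax(self, small_strong_data):
        data, truth = small_strong_data
        result = run_bremsc(data, 3, MCMCConfig(n_iter=150, n_chains=2, seed=1))
        assert result.posterior.sum(axis=1) == pytest.approx(
            np.ones(data.n_cells), abs=1e-9
        )
        assert np.array_equal(result.labels, result.posterior.argmax(axis=1) + 1)
        assert adjusted_rand_index(result.labels, truth.z_true) >= 0.9

    def test_k_larger_than_cells_rejected(self, toy_instance):
        data, _ = toy_instance
        with pytest.raises(ValueError):
            run_bremsc(data, 4, MCMCConfig(n_iter=10))

    def test_agrees_with_em_when_independence_holds(self):
        data, truth = simulate_bremsc(
            scenario_config(cells_per_cluster=50, G=30, D=9, sigma_b=0.0, seed=31)
        )
        mcmc = run_bremsc(data, 3, MCMCConfig(n_iter=200, n_chains=1, seed=2))
        em = run_jointdimm(data, 3, EMConfig(seed=2))
        assert adjusted_rand_index(mcmc.labels, em.labels) >= 0.95


class TestFlagVagueCells:
    def test_count_contract_and_tie_break(self):
        from bremsc.inference_mcmc import ClusterResult

        posterior = np.zeros((100, 2))
        posterior[:, 0] = 1.0  # all rows maximally confident: pure tie-break
        result = ClusterResult(
            labels=np.ones(100, dtype=int), posterior=posterior,
            selected_chain=0, log_post_trace=np.zeros(1),
            params_hat=None,
        )
        flags = flag_vague_cells(result, 0.05)
        assert flags.sum() == 5
        assert np.flatnonzero(flags).tolist() == [0, 1, 2, 3, 4]
        with pytest.raises(ValueError):
            flag_vague_cells(result, 1.5)

    def test_boundary_cells_enriched_among_flags(self):
        # overlapping clusters: cells whose true responsibility is diffuse
        # should be flagged far more often than confident cells
        from bremsc.core_model import cluster_logweights_all, softmax_rows

        data, truth = simulate_bremsc(
            scenario_config(
                K=2, cells_per_cluster=150, G=30, D=6,
                rna_signal="weak", adt_signal="weak", sigma_b=1.0, seed=17,
            )
        )
        result = run_bremsc(data, 2, MCMCConfig(n_iter=200, n_chains=1, seed=3))
        true_resp = softmax_rows(
            cluster_logweights_all(data, truth.params_true), axis=0
        ).T
        uncertain = true_resp.max(axis=1) < 0.7
        assert uncertain.any() and (~uncertain).any()
        flags = flag_vague_cells(result, 0.2)
        rate_uncertain = flags[uncertain].mean()
        rate_background = max(flags[~uncertain].mean(), 1e-3)
        assert rate_uncertain >= 2.0 * rate_background
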