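"""Tests for sampling, diagnostics, edge probabilities, and posterior averaging."""

import itertools

import numpy as np
import pytest

from conftest import random_params
from pollinet.inference import (
    EdgeProbabilityMatrix,
    ParameterDraws,
    SamplerConfig,
    check_convergence,
    edge_probability,
    posterior_average,
    posterior_edge_matrix,
    sample_incidence,
    sample_parameters,
)
from pollinet.model import (
    IncidenceMatrix,
    ModelParameters,
    VisitationMatrix,
    log_posterior_joint,
)
from pollinet.synthetic import GeneratorConfig, SyntheticScenario

CHEAP = SamplerConfig(chains=2, warmup=300, draws=100)


def _fake_draws(rng, n, n_p, n_a, chains=2):
    """IID pseudo-posterior draws, cheap stand-in for MCMC output."""
    return ParameterDraws(
        C=rng.uniform(5, 50, n),
        r=rng.uniform(1, 50, n),
        rho=rng.uniform(0.1, 0.9, n),
        sigma=rng.dirichlet(np.ones(n_p), n),
        tau=rng.dirichlet(np.ones(n_a), n),
        chain_id=np.repeat(np.arange(chains), n // chains),
        log_posterior=rng.normal(-100, 3, n),
        config=SamplerConfig(chains=chains, warmup=0, draws=n // chains),
    )


@pytest.fixture(scope="module")
def fitted():
    scen = SyntheticScenario.create(4, 6, GeneratorConfig(C=120, r=25, rho=0.3), seed=5)
    data = scen.simulate()
    draws = sample_parameters(data, config=CHEAP, seed=9)
    return data, draws


class TestSampleParameters:
    def test_draw_count_and_chains(self, fitted):
        data, draws = fitted
        assert len(draws) == CHEAP.chains * CHEAP.draws
        assert draws.n_chains == CHEAP.chains

    def test_simplex_constraint_every_draw(self, fitted):
        _, draws = fitted
        assert np.all(np.abs(draws.sigma.sum(axis=1) - 1) < 1e-12)
        assert np.all(np.abs(draws.tau.sum(axis=1) - 1) < 1e-12)

    def test_deterministic_under_seed(self, fitted):
        data, draws = fitted
        again = sample_parameters(data, config=CHEAP, seed=9)
        assert np.array_equal(draws.C, again.C)
        assert np.array_equal(draws.sigma, again.sigma)
        assert np.array_equal(draws.log_posterior, again.log_posterior)

    def test_different_seed_differs(self, fitted):
        data, draws = fitted
        other = sample_parameters(data, config=CHEAP, seed=10)
        assert not np.array_equal(draws.C, other.C)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(draws=0)
        with pytest.raises(ValueError):
            SamplerConfig(chains=0)
        with pytest.raises(ValueError):
            SamplerConfig(warmup=-1)

    def test_dataframe_roundtrip(self, fitted):
        _, draws = fitted
        df = draws.to_dataframe()
        back = ParameterDraws.from_dataframe(df, config=CHEAP)
        assert np.allclose(back.C, draws.C)
        assert np.allclose(back.sigma, draws.sigma)
        assert np.array_equal(back.chain_id, draws.chain_id)


class TestCheckConvergence:
    def test_identical_chains_not_flagged(self, rng):
        draws = _fake_draws(rng, 200, 3, 3, chains=2)
        lp = rng.normal(-50, 2, 100)
        draws = ParameterDraws(
            C=np.tile(draws.C[:100], 2),
            r=np.tile(draws.r[:100], 2),
            rho=np.tile(draws.rho[:100], 2),
            sigma=np.tile(draws.sigma[:100], (2, 1)),
            tau=np.tile(draws.tau[:100], (2, 1)),
            chain_id=np.repeat([0, 1], 100),
            log_posterior=np.tile(lp, 2),
            config=draws.config,
        )
        report = check_convergence(draws)
        assert not report.trapped

    def test_shifted_chain_flagged(self, rng):
        draws = _fake_draws(rng, 200, 3, 3, chains=2)
        lp = draws.log_posterior.copy()
        lp[draws.chain_id == 1] -= 1000.0
        draws = ParameterDraws(
            C=draws.C, r=draws.r, rho=draws.rho, sigma=draws.sigma, tau=draws.tau,
            chain_id=draws.chain_id, log_posterior=lp, config=draws.config,
        )
        report = check_convergence(draws)
        assert report.trapped
        assert report.trapped_chains == [1]

    def test_calibration_false_positive_rate(self, rng):
        """Same-distribution chains are flagged in at most ~5% of repetitions."""
        flags = 0
        for _ in range(100):
            draws = _fake_draws(rng, 200, 2, 2, chains=2)
            flags += check_convergence(draws).trapped
        assert flags <= 5

    def test_single_chain_warns(self, rng):
        draws = _fake_draws(rng, 100, 2, 2, chains=1)
        with pytest.warns(UserWarning, match="single chain"):
            report = check_convergence(draws)
        assert not report.trapped

    def test_rhat_reported(self, fitted):
        _, draws = fitted
        report = check_convergence(draws)
        assert set(report.rhat) == {"C", "r", "rho"}
        assert all(np.isfinite(v) for v in report.rhat.values())


class TestEdgeProbability:
    def test_r_zero_gives_rho(self, rng):
        data = VisitationMatrix(rng.integers(0, 9, (3, 4)))
        p = random_params(rng, 3, 4)
        params = ModelParameters(C=p.C, r=0.0, rho=0.42, sigma=p.sigma, tau=p.tau)
        q = edge_probability(params, data).probabilities
        assert np.allclose(q, 0.42, atol=1e-12)

    def test_degenerate_rho(self, rng):
        data = VisitationMatrix(rng.integers(0, 9, (2, 3)))
        p = random_params(rng, 2, 3)
        zero = ModelParameters(C=p.C, r=p.r, rho=0.0, sigma=p.sigma, tau=p.tau)
        one = ModelParameters(C=p.C, r=p.r, rho=1.0, sigma=p.sigma, tau=p.tau)
        assert np.all(edge_probability(zero, data).probabilities == 0.0)
        assert np.all(edge_probability(one, data).probabilities == 1.0)

    def test_enumeration_oracle_2x3(self, rng):
        """Q matches brute-force conditional marginals over all 2^6 networks."""
        data = VisitationMatrix(rng.integers(0, 7, (2, 3)))
        params = random_params(rng, 2, 3)
        logw = {}
        for bits in itertools.product([0, 1], repeat=6):
            b = np.array(bits).reshape(2, 3)
            logw[bits] = log_posterior_joint(data, IncidenceMatrix(b), params)
        mx = max(logw.values())
        weights = {k: np.exp(v - mx) for k, v in logw.items()}
        total = sum(weights.values())
        brute = np.zeros((2, 3))
        for bits, w in weights.items():
            brute += np.array(bits).reshape(2, 3) * w
        brute /= total
        q = edge_probability(params, data).probabilities
        assert np.allclose(q, brute, atol=1e-10)

    def test_probability_bounds_validated(self):
        with pytest.raises(ValueError):
            EdgeProbabilityMatrix(np.array([[1.2]]), ["p"], ["a"])


class TestPosteriorEdgeMatrix:
    def test_single_draw_equals_edge_probability(self, rng):
        data = VisitationMatrix(rng.integers(0, 9, (3, 3)))
        draws = _fake_draws(rng, 1, 3, 3, chains=1)
        q1 = posterior_edge_matrix(draws, data).probabilities
        q2 = edge_probability(draws[0], data).probabilities
        assert np.allclose(q1, q2)

    def test_identical_draws_equal_single(self, rng):
        data = VisitationMatrix(rng.integers(0, 9, (3, 3)))
        single = _fake_draws(rng, 1, 3, 3, chains=1)
        rep = ParameterDraws(
            C=np.repeat(single.C, 10), r=np.repeat(single.r, 10),
            rho=np.repeat(single.rho, 10),
            sigma=np.repeat(single.sigma, 10, axis=0),
            tau=np.repeat(single.tau, 10, axis=0),
            chain_id=np.zeros(10, dtype=int),
            log_posterior=np.repeat(single.log_posterior, 10),
            config=single.config,
        )
        assert np.allclose(
            posterior_edge_matrix(rep, data).probabilities,
            edge_probability(single[0], data).probabilities,
        )

    def test_matches_incidence_sampling_frequency(self, rng):
        data = VisitationMatrix(rng.integers(0, 9, (3, 3)))
        draws = _fake_draws(rng, 20, 3, 3)
        q = posterior_edge_matrix(draws, data).probabilities
        freq = np.zeros_like(q)
        n_rep = 400
        for k, params in enumerate(draws):
            qk = edge_probability(params, data).probabilities
            rng_k = np.random.default_rng(1234 + k)
            freq += (rng_k.random((n_rep,) + qk.shape) < qk).mean(axis=0)
        freq /= len(draws)
        se = np.sqrt(q * (1 - q) / (n_rep * len(draws))).mean() + 1e-3
        assert np.abs(freq - q).mean() < 3 * se


class TestSampleIncidence:
    def test_degenerate_probabilities(self):
        ones = EdgeProbabilityMatrix(np.ones((2, 3)), ["a", "b"], ["x", "y", "z"])
        zeros = EdgeProbabilityMatrix(np.zeros((2, 3)), ["a", "b"], ["x", "y", "z"])
        assert np.all(sample_incidence(ones, seed=1).entries == 1)
        assert np.all(sample_incidence(zeros, seed=1).entries == 0)

    def test_reproducible(self, rng):
        q = EdgeProbabilityMatrix(rng.uniform(0, 1, (3, 3)), list("abc"), list("xyz"))
        b1 = sample_incidence(q, seed=5)
        b2 = sample_incidence(q, seed=5)
        assert np.array_equal(b1.entries, b2.entries)

    def test_binomial_concentration(self, rng):
        q_val = rng.uniform(0.1, 0.9, (2, 2))
        q = EdgeProbabilityMatrix(q_val, ["a", "b"], ["x", "y"])
        n = 10_000
        acc = np.zeros((2, 2))
        for s in range(n):
            acc += sample_incidence(q, seed=s).entries
        freq = acc / n
        assert np.all(np.abs(freq - q_val) < 3 * np.sqrt(q_val * (1 - q_val) / n) + 1e-9)


class TestPosteriorAverage:
    def test_constant_function(self, rng):
        data = VisitationMatrix(rng.integers(0, 9, (3, 3)))
        draws = _fake_draws(rng, 20, 3, 3)
        est = posterior_average(lambda b, t: 1.0, draws, data)
        assert est.estimate == 1.0
        assert est.standard_error == 0.0

    def test_parameter_function_exact_mean(self, rng):
        data = VisitationMatrix(rng.integers(0, 9, (3, 3)))
        draws = _fake_draws(rng, 20, 3, 3)
        est = posterior_average(lambda b, t: t.rho, draws, data)
        assert est.estimate == pytest.approx(draws.rho.mean())

    def test_rao_blackwell_consistency(self, rng):
        data = VisitationMatrix(rng.integers(0, 9, (3, 3)))
        draws = _fake_draws(rng, 50, 3, 3)
        q = posterior_edge_matrix(draws, data).probabilities
        est = posterior_average(
            lambda b, t: float(b.entries[1, 2]), draws, data, n_networks_per_draw=4, seed=3
        )
        assert abs(est.estimate - q[1, 2]) <= 3 * max(est.standard_error, 1e-3)

    def test_error_context(self, rng):
        data = VisitationMatrix(rng.integers(0, 9, (2, 2)))
        draws = _fake_draws(rng, 4, 2, 2)

        def bad(b, t):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="draw 0"):
            posterior_average(bad, draws, data)

    def test_chain_order_invariance(self, rng):
        data = VisitationMatrix(rng.integers(0, 9, (3, 3)))
        draws = _fake_draws(rng, 40, 3, 3, chains=2)
        swapped = ParameterDraws(
            C=np.concatenate([draws.C[20:], draws.C[:20]]),
            r=np.concatenate([draws.r[20:], draws.r[:20]]),
            rho=np.concatenate([draws.rho[20:], draws.rho[:20]]),
            sigma=np.concatenate([draws.sigma[20:], draws.sigma[:20]]),
            tau=np.concatenate([draws.tau[20:], draws.tau[:20]]),
            chain_id=np.concatenate([draws.chain_id[20:], draws.chain_id[:20]]),
            log_posterior=np.concatenate(
                [draws.log_posterior[20:], draws.log_posterior[:20]]
            ),
            config=draws.config,
        )
        q1 = posterior_edge_matrix(draws, data).probabilities
        q2 = posterior_edge_matrix(swapped, data).probabilities
        assert np.allclose(q1, q2, atol=1e-10)
        f = lambda b, t: float(b.entries.sum()) + t.rho
        e1 = posterior_average(f, draws, data, seed=11)
        e2 = posterior_average(f, swapped, data, seed=11)
        assert e1.estimate == pytest.approx(e2.estimate, abs=1e-10)


class TestInformationMonotonicity:
    def test_more_effort_no_less_certainty(self):
        """Mean edge-probability entropy does not increase when C is scaled x10."""
        entropies = []
        for c_scale in (1.0, 10.0):
            scen = SyntheticScenario.create(
                5, 6, GeneratorConfig(C=60 * c_scale, r=30, rho=0.3), seed=31
            )
            data = scen.simulate(seed=77)
            draws = sample_parameters(data, config=CHEAP, seed=13)
            q = posterior_edge_matrix(draws, data).probabilities
            q = np.clip(q, 1e-12, 1 - 1e-12)
            h = -(q * np.log(q) + (1 - q) * np.log(1 - q)).mean()
            entropies.append(h)
        assert entropies[1] <= entropies[0]

    def test_aggregation_sharpens_edges(self):
        """Summing replicate matrices leaves fewer mid-range edge probabilities."""
        scen = SyntheticScenario.create(
            8, 12, GeneratorConfig(C=15, r=40, rho=0.25, concentration=2.0), seed=41
        )
        reps = [scen.simulate(seed=100 + k) for k in range(4)]
        fracs = []
        for data in reps:
            draws = sample_parameters(data, config=CHEAP, seed=3)
            q = posterior_edge_matrix(draws, data).probabilities
            fracs.append(((q > 0.05) & (q < 0.95)).mean())
        summed = VisitationMatrix(
            sum(d.counts for d in reps),
            plant_labels=reps[0].plant_labels,
            pollinator_labels=reps[0].pollinator_labels,
        )
        draws = sample_parameters(summed, config=CHEAP, seed=3)
        q = posterior_edge_matrix(draws, summed).probabilities
        agg_frac = ((q > 0.05) & (q < 0.95)).mean()
        assert agg_frac <= np.mean(fracs)
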