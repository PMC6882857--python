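import math

import numpy as np
import pytest
from scipy import stats

from phasekit import genotype_graph as gg
from phasekit import lsm

import oracles


def make_case(rng, n_sites, K, ps=None, missing=False):
    g = rng.integers(0, 3, n_sites).astype(np.int8)
    if missing:
        g[rng.random(n_sites) < 0.15] = -1
    graph = gg.build_graph(g)
    if ps is not None:
        gg.attach_phase_sets(graph, ps)
    cond = rng.integers(0, 2, size=(K, n_sites)).astype(np.uint8)
    cm = np.cumsum(rng.random(n_sites)) * 0.01
    params = lsm.LsmParams(ne=12_000, n_hap=40)
    return graph, cond, cm, params


class TestClosedForms:
    def test_zero_distance_no_recombination(self):
        stay, sw = lsm.transition_probs(0.0, 5, 15_000, 100)
        assert stay == pytest.approx(1.0)
        assert sw == pytest.approx(0.0)

    def test_infinite_distance_stationary(self):
        stay, sw = lsm.transition_probs(1e9, 4, 15_000, 100)
        assert stay == pytest.approx(0.25)
        assert sw == pytest.approx(0.25)

    def test_rows_normalize(self):
        for k in (1, 2, 7):
            stay, sw = lsm.transition_probs(0.3, k, 15_000, 64)
            assert stay + (k - 1) * sw == pytest.approx(1.0)

    def test_k4_closed_form_value(self):
        # choose g so that rho/K == 1: rho = 4*Ne*(g/100)/n_hap
        ne, n_hap, K = 15_000.0, 120, 4
        g = 100.0 * K * n_hap / (4 * ne)
        stay, sw = lsm.transition_probs(g, K, ne, n_hap)
        e = math.exp(-1.0)
        assert stay == pytest.approx(e + (1 - e) / 4, abs=1e-12)
        assert sw == pytest.approx((1 - e) / 4, abs=1e-12)

    def test_theta_harmonic(self):
        assert lsm.theta_from_k(2) == pytest.approx(1.0)
        assert lsm.theta_from_k(4) == pytest.approx(1 / (1 + 0.5 + 1 / 3))

    def test_emission_sums_to_one(self):
        for k in (2, 5, 30):
            assert (lsm.emission_prob(0, 0, k)
                    + lsm.emission_prob(0, 1, k)) == pytest.approx(1.0)

    def test_emission_limits(self):
        # large K: mismatch probability vanishes
        assert lsm.emission_prob(1, 0, 10**7) < 1e-6
        k = 10
        theta = lsm.theta_from_k(k)
        want_mis = 0.5 * theta / (k + theta)
        assert lsm.emission_prob(1, 0, k) == pytest.approx(want_mis)
        assert lsm.emission_prob(1, 1, k) == pytest.approx(
            k / (k + theta) + want_mis)


class TestForwardBackward:
    def test_single_state_posterior_mass_one(self, rng):
        g = np.array([0, 2, 0], np.int8)
        graph = gg.build_graph(g)
        cond = np.array([[0, 1, 0]], np.uint8)
        res = lsm.forward_backward(graph, cond, lsm.LsmParams(n_hap=4),
                                   np.array([0.0, 0.01, 0.02]))
        assert res.marg0 == pytest.approx([1.0])

    def test_symmetric_het_configs_equal_posterior(self):
        g = np.ones(2, np.int8)
        graph = gg.build_graph(g)
        cond = np.array([[0, 1], [1, 0]], np.uint8)
        res = lsm.forward_backward(graph, cond, lsm.LsmParams(n_hap=4),
                                   np.array([0.0, 0.01]))
        m = res.marg0
        # (01 / 10) and (10 / 01) configurations are exchangeable
        assert m[1] == pytest.approx(m[2], rel=1e-12)
        assert m[0] == pytest.approx(m[3], rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        graph, cond, cm, params = make_case(rng, n_sites=8,
                                            K=int(rng.integers(1, 4)))
        if graph.n_segments > 3:
            pytest.skip("case too large for the oracle")
        res = lsm.forward_backward(graph, cond, params, cm)
        marg0, tables, loglik = oracles.enumerate_hmm(graph, cond, params, cm)
        np.testing.assert_allclose(res.marg0, marg0, atol=1e-9)
        for got, want in zip(res.boundary_posteriors, tables):
            np.testing.assert_allclose(got, want, atol=1e-9)
        assert res.loglik == pytest.approx(loglik, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_with_missing(self, seed):
        rng = np.random.default_rng(100 + seed)
        graph, cond, cm, params = make_case(rng, n_sites=7, K=2, missing=True)
        if graph.n_segments > 3 or graph.n_paths > 256:
            pytest.skip("case too large for the oracle")
        res = lsm.forward_backward(graph, cond, params, cm)
        marg0, tables, _ = oracles.enumerate_hmm(graph, cond, params, cm)
        np.testing.assert_allclose(res.marg0, marg0, atol=1e-9)
        for got, want in zip(res.boundary_posteriors, tables):
            np.testing.assert_allclose(got, want, atol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_with_phase_sets(self, seed):
        rng = np.random.default_rng(200 + seed)
        g = np.array([1, 1, 1, 0, 1, 1, 1], np.int8)
        graph = gg.build_graph(g)
        hets = graph.het_sites()
        entries = {int(h): (1, int(rng.integers(0, 2))) for h in hets[:4]}
        gg.attach_phase_sets(graph, gg.PhaseSetConstraints(entries, eps=0.01))
        cond = rng.integers(0, 2, size=(2, 7)).astype(np.uint8)
        cm = np.cumsum(rng.random(7)) * 0.01
        params = lsm.LsmParams(n_hap=10)
        res = lsm.forward_backward(graph, cond, params, cm)
        marg0, tables, _ = oracles.enumerate_hmm(graph, cond, params, cm)
        np.testing.assert_allclose(res.marg0, marg0, atol=1e-9)
        for got, want in zip(res.boundary_posteriors, tables):
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_eps_half_equals_no_reads(self, rng):
        graph, cond, cm, params = make_case(rng, n_sites=9, K=3)
        res_plain = lsm.forward_backward(graph, cond, params, cm)
        plain = [t.copy() for t in res_plain.boundary_posteriors]
        marg_plain = res_plain.marg0.copy()
        hets = graph.het_sites()
        entries = {int(h): (1, 1) for h in hets}
        gg.attach_phase_sets(graph, gg.PhaseSetConstraints(entries, eps=0.5))
        res_ps = lsm.forward_backward(graph, cond, params, cm)
        np.testing.assert_allclose(res_ps.marg0, marg_plain, atol=1e-12)
        for a, b in zip(res_ps.boundary_posteriors, plain):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_duplicated_conditioning_equals_plain(self, rng):
        # multiplicity-merged chain must equal the chain on duplicated rows
        graph, cond, cm, params = make_case(rng, n_sites=6, K=2)
        dup = np.vstack([cond, cond[0:1], cond[0:1]])
        res = lsm.forward_backward(graph, dup, params, cm)
        marg0, tables, loglik = oracles.enumerate_hmm(graph, dup, params, cm)
        np.testing.assert_allclose(res.marg0, marg0, atol=1e-9)
        for got, want in zip(res.boundary_posteriors, tables):
            np.testing.assert_allclose(got, want, atol=1e-9)
        assert res.loglik == pytest.approx(loglik, abs=1e-9)

    def test_truth_duplicate_no_recomb_recovers_truth(self, rng):
        # one conditioning haplotype duplicated as the truth, no
        # recombination: samples equal the truth at all non-het-ambiguous
        # sites, and missing sites impute the conditioning allele
        g = rng.integers(0, 3, 20).astype(np.int8)
        g[[4, 11]] = -1
        graph = gg.build_graph(g)
        truth1 = (g == 2).astype(np.uint8)
        truth1[4] = truth1[11] = 1
        cond = np.tile(truth1, (5, 1))
        cm = np.zeros(20)  # no recombination
        res = lsm.forward(graph, cond, lsm.LsmParams(n_hap=12), cm)
        fixed = (g == 0) | (g == 2)
        miss_votes = 0
        for s in range(30):
            h1, h2, _ = lsm.sample_pair(res, np.random.default_rng(s))
            np.testing.assert_array_equal(h1[fixed], truth1[fixed])
            np.testing.assert_array_equal(h2[fixed], truth1[fixed])
            miss_votes += int(h1[4] == 1) + int(h1[11] == 1)
        assert miss_votes > 45   # imputation pulled toward the copied allele


class TestSampling:
    def test_degenerate_posterior_unique_path(self, rng):
        g = np.array([1, 0, 1], np.int8)
        graph = gg.build_graph(g)
        gg.apply_scaffold(graph, {0: 1, 2: 0})
        cond = rng.integers(0, 2, (3, 3)).astype(np.uint8)
        res = lsm.forward(graph, cond, lsm.LsmParams(n_hap=8),
                          np.array([0.0, 0.01, 0.02]))
        draws = {lsm.sample_pair(res, np.random.default_rng(s))[0].tobytes()
                 for s in range(20)}
        assert len(draws) == 1

    def test_sampled_pair_genotype_consistent(self, rng):
        for seed in range(5):
            graph, cond, cm, params = make_case(
                np.random.default_rng(300 + seed), 15, 3, missing=True)
            res = lsm.forward(graph, cond, params, cm)
            h1, h2, _ = lsm.sample_pair(res, rng)
            ok = graph.g >= 0
            np.testing.assert_array_equal(
                (h1.astype(np.int16) + h2)[ok], graph.g[ok])

    def test_empirical_frequencies_match_enumeration(self):
        rng = np.random.default_rng(17)
        g = np.array([1, 0, 1, 2, 1, 1], np.int8)   # 2 segments
        graph = gg.build_graph(g)
        cond = rng.integers(0, 2, (2, 6)).astype(np.uint8)
        cm = np.cumsum(rng.random(6)) * 0.05
        params = lsm.LsmParams(n_hap=6)
        marg0, tables, _ = oracles.enumerate_hmm(graph, cond, params, cm)
        # enumerate exact path probabilities
        counts_cfg = graph.config_counts()
        res = lsm.forward(graph, cond, params, cm)
        n_draws = 10_000
        draw_rng = np.random.default_rng(99)
        counts = {}
        for _ in range(n_draws):
            _, _, path = lsm.sample_pair(res, draw_rng)
            counts[tuple(path)] = counts.get(tuple(path), 0) + 1
        # exact joint over (c0, c1) is the boundary table itself
        expected = np.asarray(tables[0]) * n_draws
        observed = np.zeros_like(expected)
        for (c0, c1), n in counts.items():
            observed[c0, c1] = n
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        dof = int(keep.sum()) - 1
        p = 1.0 - stats.chi2.cdf(chi2, dof)
        assert p > 0.001


class TestSolve:
    def _stored_graph(self, rng, g, n_iter=3, K=3):
        graph = gg.build_graph(g)
        cond = rng.integers(0, 2, (K, len(g))).astype(np.uint8)
        cm = np.cumsum(rng.random(len(g))) * 0.02
        params = lsm.LsmParams(n_hap=8)
        for _ in range(n_iter):
            res = lsm.forward_backward(graph, cond, params, cm)
            graph.store_posteriors(res.marg0, res.boundary_posteriors)
        return graph

    def test_no_stored_iterations_errors(self):
        graph = gg.build_graph(np.ones(4, np.int8))
        with pytest.raises(ValueError):
            lsm.accumulate_and_solve(graph)

    def test_single_degenerate_iteration(self):
        graph = gg.build_graph(np.ones(4, np.int8))   # segments 3 + 1
        marg0 = np.zeros(8)
        marg0[5] = 1.0
        table = np.zeros((8, 2))
        table[5, 1] = 1.0
        graph.store_posteriors(marg0, [table])
        h1, h2, path = lsm.accumulate_and_solve(graph)
        assert list(path) == [5, 1]

    def test_averaging_identical_tables_idempotent(self, rng):
        g = np.array([1, 1, 1, 0, 1], np.int8)
        a = self._stored_graph(np.random.default_rng(3), g, n_iter=1)
        b = self._stored_graph(np.random.default_rng(3), g, n_iter=4)
        np.testing.assert_allclose(a.averaged_posteriors()[0],
                                   b.averaged_posteriors()[0])
        assert lsm.accumulate_and_solve(a)[2].tolist() \
            == lsm.accumulate_and_solve(b)[2].tolist()

    def test_dp_matches_exhaustive_argmax(self):
        for seed in range(5):
            rng = np.random.default_rng(400 + seed)
            g = rng.integers(0, 3, 10).astype(np.int8)
            graph = gg.build_graph(g)
            if graph.n_segments < 2:
                continue
            marg0 = rng.random(graph.config_counts()[0])
            marg0 /= marg0.sum()
            tables = []
            for c1, c2 in zip(graph.config_counts(),
                              graph.config_counts()[1:]):
                t = rng.random((c1, c2))
                tables.append(t / t.sum())
            graph.store_posteriors(marg0, tables)
            _, _, path = lsm.accumulate_and_solve(graph)

            def score(p):
                s = marg0[p[0]]
                for b, t in enumerate(tables):
                    row = t[p[b]]
                    s *= row[p[b + 1]] / row.sum()
                return s
            from itertools import product
            best = max(product(*(range(c) for c in graph.config_counts())),
                       key=score)
            assert tuple(path) == best
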