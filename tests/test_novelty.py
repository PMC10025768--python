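"""E-score surface, bimodality coefficient, detection rule, mixup threshold."""

import numpy as np
import pytest
from scipy.special import softmax

import sfanno as sf


class TestEScoreComponents:
    def test_onehot_everywhere(self):
        p = np.eye(3)[[0]]
        EN, CF, CS = sf.e_score_components(p, p, p, 3)
        assert EN[0] == pytest.approx(0.0) and CF[0] == 1.0 and CS[0] == 1.0
        assert sf.e_score(EN, CF, CS, 3)[0] == pytest.approx(1.0)

    def test_uniform_everywhere(self):
        p = np.full((1, 4), 0.25)
        EN, CF, CS = sf.e_score_components(p, p, p, 4)
        assert EN[0] == pytest.approx(np.log(4))
        assert CF[0] == 0.25 and CS[0] == pytest.approx(0.25)
        assert sf.e_score(EN, CF, CS, 4)[0] == pytest.approx(1.0 / 6.0)

    def test_worked_example(self):
        p = np.array([[0.7, 0.2, 0.1]])
        p1 = np.array([[0.6, 0.3, 0.1]])
        p2 = np.array([[0.5, 0.4, 0.1]])
        EN, CF, CS = sf.e_score_components(p, p1, p2, 3)
        assert EN[0] == pytest.approx(0.801819, abs=1e-6)
        assert CF[0] == pytest.approx(0.7)
        assert CS[0] == pytest.approx(0.43)
        assert sf.e_score(EN, CF, CS, 3)[0] == pytest.approx(0.466717, abs=1e-6)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            sf.e_score_components(np.array([[0.5, 0.1]]), np.eye(2)[[0]], np.eye(2)[[0]], 2)

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            sf.e_score(np.zeros(1), np.ones(1), np.ones(1), 1)

    def test_monotonicity_over_random_triples(self):
        rng = np.random.default_rng(0)
        n = 10_000
        K = 5
        EN = rng.uniform(0, np.log(K), n)
        CF = rng.uniform(1 / K, 1, n)
        CS = rng.uniform(0.01, 1, n)
        d = 1e-3
        base = sf.e_score(EN, CF, CS, K)
        assert (sf.e_score(EN + d, CF, CS, K) < base).all()
        assert (sf.e_score(EN, np.minimum(CF + d, 1.0 + d), CS, K) > base).all()
        assert (sf.e_score(EN, CF, CS + d, K) > base).all()

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(4), size=20)
        p1 = rng.dirichlet(np.ones(4), size=20)
        p2 = rng.dirichlet(np.ones(4), size=20)
        rep = sf.escore_report(p, p1, p2, 4)
        perm = rng.permutation(20)
        rep_p = sf.escore_report(p[perm], p1[perm], p2[perm], 4)
        assert np.allclose(rep.e_score[perm], rep_p.e_score)


class TestBimodalityCoefficient:
    def test_normal_uniform_two_point_benchmarks(self):
        rng = np.random.default_rng(0)
        n = 100_000
        assert sf.bimodality_coefficient(rng.normal(size=n)) == pytest.approx(1 / 3, abs=0.02)
        assert sf.bimodality_coefficient(rng.random(n)) == pytest.approx(5 / 9, abs=0.02)
        two_point = np.repeat([0.0, 1.0], n // 2)
        assert sf.bimodality_coefficient(two_point) == pytest.approx(1.0, abs=0.02)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            sf.bimodality_coefficient([1.0, 2.0, 3.0])

    def test_zero_variance_defined_as_zero(self):
        with pytest.warns(UserWarning):
            assert sf.bimodality_coefficient(np.ones(10)) == 0.0


class TestDetectNovelty:
    def test_unimodal_high_scores_silent(self):
        rng = np.random.default_rng(0)
        false_fires = sum(
            sf.detect_novelty(rng.beta(8, 2, 400), seed=0).novel_detected for _ in range(20)
        )
        assert false_fires <= 1

    def test_bimodal_mixture_fires(self):
        rng = np.random.default_rng(1)
        fires = 0
        for _ in range(20):
            x = np.concatenate([rng.beta(2, 10, 160), rng.beta(10, 2, 240)])
            fires += sf.detect_novelty(x, seed=0).novel_detected
        assert fires >= 19

    def test_or_rule(self):
        # bimodality coefficient fires while the dip test does not: still detected
        rng = np.random.default_rng(2)
        x = rng.beta(0.9, 2.5, size=400)  # heavily skewed unimodal -> high BC
        res = sf.detect_novelty(x, seed=0)
        if res.bc_value > res.bc_threshold and res.dip_pvalue >= res.alpha_dip:
            assert res.novel_detected
        assert res.novel_detected == (
            res.bc_value > res.bc_threshold or res.dip_pvalue < res.alpha_dip
        )


def linear_heads(K=3, d=4, seed=0):
    """Deterministic stand-in classifier ensemble for threshold tests."""
    rng = np.random.default_rng(seed)
    Ws = [rng.normal(size=(d, K)) for _ in range(3)]
    return lambda z: tuple(softmax(z @ W, axis=1) for W in Ws)


class TestMixupThreshold:
    def test_degenerate_bank_returns_point_escore(self):
        heads = linear_heads()
        z = np.array([0.3, -1.0, 0.5, 2.0])
        R = np.tile(z, (6, 1))
        p, p1, p2 = heads(z[None, :])
        expected = sf.escore_report(p, p1, p2, 3).e_score[0]
        assert sf.mixup_threshold(R, heads, n_pairs="all", seed=0) == pytest.approx(expected)

    def test_all_pairs_matches_enumeration_oracle(self):
        heads = linear_heads(seed=3)
        rng = np.random.default_rng(4)
        R = rng.normal(size=(3, 4))
        lam = np.array([0.1, 0.9, 0.5, 0.25, 0.75, 0.4])
        delta = sf.mixup_threshold(R, heads, n_pairs="all", seed=0, lambdas=lam)
        # independent loop over the 6 ordered pairs
        pairs = [(i, j) for i in range(3) for j in range(3) if i != j]
        scores = []
        for (i, j), l in zip(pairs, lam):
            zmix = l * R[i] + (1 - l) * R[j]
            p, p1, p2 = heads(zmix[None, :])
            scores.append(sf.escore_report(p, p1, p2, 3).e_score[0])
        assert delta == pytest.approx(np.mean(scores), abs=1e-12)

    def test_monte_carlo_converges_to_all_pairs(self):
        heads = linear_heads(seed=5)
        rng = np.random.default_rng(6)
        R = rng.normal(size=(200, 4))
        exact = sf.mixup_threshold(R, heads, n_pairs="all", seed=0)
        err = {
            m: abs(sf.mixup_threshold(R, heads, n_pairs=m, seed=1) - exact)
            for m in (100, 1000, 10_000)
        }
        assert err[10_000] < 0.01
        assert err[10_000] < err[100] + 0.005

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            sf.mixup_threshold(np.ones((1, 3)), linear_heads(), seed=0)


class TestPartition:
    def test_no_novelty_keeps_everything_known(self):
        part = sf.partition(np.array([0.1, 0.9]), None, False)
        assert list(part.known_idx) == [0, 1] and len(part.unknown_idx) == 0
        assert part.delta is None

    def test_strict_inequality_at_threshold(self):
        part = sf.partition(np.array([0.9, 0.2, 0.55]), 0.55, True)
        assert list(part.known_idx) == [0]
        assert list(part.unknown_idx) == [1, 2]

    def test_separated_scores_partition_accurately(self):
        rng = np.random.default_rng(0)
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            known = rng.beta(10, 2, 150)
            unknown = rng.beta(2, 10, 50)
            es = np.concatenate([known, unknown])
            truth = np.array([True] * 150 + [False] * 50)
            delta = 0.5  # midpoint of the two humps
            part = sf.partition(es, delta, True)
            pred_known = np.zeros(200, dtype=bool)
            pred_known[part.known_idx] = True
            hits.append((pred_known == truth).mean())
        assert min(hits) >= 0.95
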