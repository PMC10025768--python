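"""Cosine k-NN, neighbor taxonomy, memory banks, and the affinity loss
against brute-force oracles."""

import numpy as np
import pytest

import sfanno as sf
from sfanno.autodiff import Parameter, log_softmax


def brute_force_knn(R, M):
    """Exhaustive cosine search with (similarity desc, index asc) ordering."""
    norms = np.linalg.norm(R, axis=1)
    out = []
    for i in range(R.shape[0]):
        sims = []
        for j in range(R.shape[0]):
            if norms[i] == 0 or norms[j] == 0:
                s = 1.0 if i == j else 0.0
            else:
                s = float(R[i] @ R[j] / (norms[i] * norms[j]))
            sims.append((-s, j))
        sims.sort()
        out.append(np.array([j for _, j in sims[:M]]))
    return out


def brute_force_split(VM):
    vm = [set(v.tolist()) for v in VM]
    V1 = [set(j for j in vm[i] if i in vm[j]) for i in range(len(vm))]
    V2 = [vm[i] - V1[i] for i in range(len(vm))]
    V3 = [set().union(*(vm[j] for j in vm[i])) - vm[i] for i in range(len(vm))]
    return V1, V2, V3


class TestCosineKnn:
    def test_three_point_instance(self):
        R = np.array([[1.0, 0.0], [1.0, 0.1], [0.0, 1.0]])
        vm = sf.cosine_knn(R, range(3), M=2)
        assert set(vm[0]) == {0, 1}
        assert set(vm[2]) == {2, 1}

    def test_m1_returns_self(self):
        rng = np.random.default_rng(0)
        R = rng.normal(size=(20, 5))
        vm = sf.cosine_knn(R, range(20), M=1)
        assert all(v[0] == i for i, v in enumerate(vm))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            R = rng.normal(size=(50, 8))
            M = int(rng.integers(1, 11))
            vm = sf.cosine_knn(R, range(50), M)
            ref = brute_force_knn(R, M)
            for a, b in zip(vm, ref):
                assert list(a) == list(b)

    def test_zero_norm_row_warns(self):
        R = np.array([[0.0, 0.0], [1.0, 0.0], [0.9, 0.1]])
        with pytest.warns(UserWarning, match="zero-norm"):
            vm = sf.cosine_knn(R, range(3), M=2)
        assert vm[0][0] == 0  # self still first

    def test_m_exceeding_bank_rejected(self):
        with pytest.raises(ValueError):
            sf.cosine_knn(np.ones((3, 2)), range(3), M=4)


class TestSplitNeighbors:
    def test_three_point_worked_example(self):
        R = np.array([[1.0, 0.0], [1.0, 0.1], [0.0, 1.0]])
        nbrs = sf.split_neighbors(sf.cosine_knn(R, range(3), M=2))
        assert set(nbrs.V1[0]) == {0, 1} and len(nbrs.V2[0]) == 0
        assert set(nbrs.V1[2]) == {2} and set(nbrs.V2[2]) == {1} and set(nbrs.V3[2]) == {0}

    def test_identical_cells_fully_mutual(self):
        # with n == M every identical cell keeps every other: full mutuality
        R = np.ones((3, 3))
        nbrs = sf.split_neighbors(sf.cosine_knn(R, range(3), M=3))
        for i in range(3):
            assert set(nbrs.V1[i]) == set(nbrs.VM[i])
            assert len(nbrs.V2[i]) == 0

    def test_self_always_included(self):
        # even under similarity ties, a cell never evicts itself
        R = np.ones((6, 3))
        nbrs = sf.split_neighbors(sf.cosine_knn(R, range(6), M=3))
        for i in range(6):
            assert i in set(nbrs.VM[i])
            assert i in set(nbrs.V1[i])

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            R = rng.normal(size=(50, 6))
            M = int(rng.integers(2, 9))
            vm = sf.cosine_knn(R, range(50), M)
            nbrs = sf.split_neighbors(vm)
            V1, V2, V3 = brute_force_split(vm)
            for i in range(50):
                assert set(nbrs.V1[i]) == V1[i]
                assert set(nbrs.V2[i]) == V2[i]
                assert set(nbrs.V3[i]) == V3[i]
                # structural invariants
                assert i in set(nbrs.V1[i])
                assert set(nbrs.V1[i]) | set(nbrs.V2[i]) == set(nbrs.VM[i])
                assert set(nbrs.V3[i]) & set(nbrs.VM[i]) == set()


class TestAffinityLoss:
    def test_self_regularization_term(self):
        # single known cell whose only neighbor is itself, uniform prediction
        R = np.ones((1, 2))
        nbrs = sf.split_neighbors(sf.cosine_knn(R, range(1), M=1))
        S = np.array([[0.5, 0.5]])
        part = sf.partition(np.array([0.9]), None, False)
        from sfanno.autodiff import Tensor

        loss = sf.affinity_loss([0], Tensor(np.array([[0.5, 0.5]])), nbrs, S, part)
        assert float(loss.data) == pytest.approx(-0.5)

    def test_perfect_agreement_neighbor(self):
        # mutual neighbor with matching one-hot soft label contributes -1
        R = np.array([[1.0, 0.0], [1.0, 0.0]])
        nbrs = sf.split_neighbors(sf.cosine_knn(R, range(2), M=2))
        S = np.eye(2)[[0, 0]]
        part = sf.partition(np.array([0.9, 0.9]), None, False)
        from sfanno.autodiff import Tensor

        loss = sf.affinity_loss([0], Tensor(np.eye(2)[[0]]), nbrs, S, part)
        # V1(0) = {0, 1}: two matching one-hot neighbors, |D| = 2
        assert float(loss.data) == pytest.approx(-2.0 / 2.0)

    def test_matches_loop_reference(self):
        rng = np.random.default_rng(3)
        n, K, M = 10, 3, 3
        R = rng.normal(size=(n, 4))
        S = rng.dirichlet(np.ones(K), size=n)
        vm = sf.cosine_knn(R, range(n), M)
        nbrs = sf.split_neighbors(vm)
        es = rng.random(n)
        part = sf.partition(es, 0.4, True)
        batch = list(range(n))
        p_np = rng.dirichlet(np.ones(K), size=n)
        from sfanno.autodiff import Tensor

        a2, a3 = 0.1, 0.07
        ours = float(sf.affinity_loss(batch, Tensor(p_np), nbrs, S, part, a2, a3).data)
        # independent loop-based evaluation
        known = set(part.known_idx.tolist())
        tot = 0.0
        for r, i in enumerate(batch):
            if i not in known:
                continue
            w = np.zeros(K)
            for j in nbrs.V1[i]:
                if j in known:
                    w += S[j]
            for j in nbrs.V2[i]:
                if j in known:
                    w += a2 * S[j]
            for j in nbrs.V3[i]:
                if j in known:
                    w += a3 * S[j]
            tot += w @ p_np[r]
        ref = -tot / len(known)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_unknown_cells_get_zero_gradient(self):
        rng = np.random.default_rng(4)
        n, K = 8, 3
        R = rng.normal(size=(n, 4))
        S = rng.dirichlet(np.ones(K), size=n)
        nbrs = sf.split_neighbors(sf.cosine_knn(R, range(n), M=3))
        es = np.array([0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1])
        part = sf.partition(es, 0.5, True)
        logits = Parameter(rng.normal(size=(n, K)))
        p = log_softmax(logits).exp()
        loss = sf.affinity_loss(list(range(n)), p, nbrs, S, part)
        loss.backward()
        assert np.abs(logits.grad[4:]).max() == 0.0
        assert np.abs(logits.grad[:4]).max() > 0.0

    def test_empty_known_set_warns_and_zeroes(self):
        from sfanno.autodiff import Tensor

        part = sf.Partition(delta=0.9, known_idx=np.array([], dtype=int), unknown_idx=np.arange(2))
        nbrs = sf.split_neighbors(sf.cosine_knn(np.ones((2, 2)), range(2), M=1))
        with pytest.warns(UserWarning, match="empty"):
            loss = sf.affinity_loss([0, 1], Tensor(np.full((2, 2), 0.5)), nbrs, np.full((2, 2), 0.5), part)
        assert float(loss.data) == 0.0


class TestMemoryBanks:
    def test_identical_cells_identical_rows(self, trained_small_model):
        model = trained_small_model["model"]
        pre_t = trained_small_model["pre_t"]
        import copy

        pre = copy.deepcopy(pre_t)
        pre.x_input[1] = pre.x_input[0]
        banks = sf.init_banks(model, pre)
        assert np.array_equal(banks.R[0], banks.R[1])
        assert np.array_equal(banks.S[0], banks.S[1])

    def test_banks_equal_batchwise_forward(self, trained_small_model):
        model = trained_small_model["model"]
        pre_t = trained_small_model["pre_t"]
        banks = sf.init_banks(model, pre_t)
        z, p, p1, p2 = model.predict(pre_t.x_input)
        assert np.allclose(banks.R, z) and np.allclose(banks.S, p)

    def test_escores_consistent_with_soft_labels(self, trained_small_model):
        model = trained_small_model["model"]
        banks = sf.init_banks(model, trained_small_model["pre_t"])
        rep = sf.escore_report(banks.S, banks.S1, banks.S2, model.n_classes)
        assert np.allclose(banks.e_scores, rep.e_score, atol=1e-12)
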