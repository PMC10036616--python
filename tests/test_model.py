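"""Multilevel assignment network: pooling, stochasticity, locality,
training behaviour, and hyperparameter search."""

import numpy as np
import pandas as pd
import pytest

import tmenet as tm
from tmenet import autograd as ag
from tmenet.graphs import build_patch_graph
from tmenet.model import (MultilevelNet, ModelConfig, PatientDataset,
                          classify, grid_cardinality, hyperparameter_search,
                          max_sum_pool, train_model, EnrichmentVector,
                          PUBLISHED_GRID)

from conftest import grid_patchset


def brute_force_max_sum(S):
    """Row-by-row oracle: keep each row's first maximal entry, sum columns."""
    out = np.zeros(S.shape[1])
    for row in S:
        best = 0
        for j in range(1, len(row)):
            if row[j] > row[best]:
                best = j
        out[best] += row[best]
    return out


class TestMaxSumPool:
    def test_hand_computed_example(self):
        S = np.array([[0.6, 0.4], [0.3, 0.7]])
        assert np.allclose(max_sum_pool(S), [0.6, 0.7])

    def test_one_hot_gives_row_counts(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=50)
        S = np.eye(4)[labels]
        pooled = max_sum_pool(S)
        assert np.array_equal(pooled, np.bincount(labels, minlength=4))
        assert pooled.sum() == 50

    def test_single_element_all_ones(self):
        assert np.allclose(max_sum_pool(np.ones((7, 1))), [7.0])

    def test_soft_mode_is_column_sum(self):
        S = np.array([[0.6, 0.4], [0.3, 0.7]])
        assert np.allclose(max_sum_pool(S, mode="soft"), [0.9, 1.1])

    def test_ties_break_to_lowest_index(self):
        S = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert np.allclose(max_sum_pool(S), [1.0, 0.0])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            S = rng.dirichlet(np.ones(4), size=10)
            assert np.allclose(max_sum_pool(S), brute_force_max_sum(S),
                               atol=1e-12)

    def test_hard_max_conservation_bounds(self):
        rng = np.random.default_rng(2)
        S = rng.dirichlet(np.ones(5), size=30)
        total = max_sum_pool(S).sum()
        assert 30 / 5 < total <= 30

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_sum_pool(np.zeros((0, 3)))


class TestPoolingProperties:
    """Invariants of max-sum pooling over arbitrary row-stochastic inputs."""

    from hypothesis import given, settings, strategies as st

    @given(st.integers(2, 40), st.integers(1, 6), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conservation_and_bounds(self, L, E, seed):
        rng = np.random.default_rng(seed)
        S = rng.dirichlet(np.ones(E), size=L)
        pooled = max_sum_pool(S)
        assert np.all(pooled >= 0)
        total = pooled.sum()
        assert total <= L + 1e-9
        assert total > L / E - 1e-9
        # hard-max never exceeds the soft column sums... per column it keeps
        # a subset of entries, so each abundance <= soft abundance
        assert np.all(pooled <= max_sum_pool(S, mode="soft") + 1e-12)

    @given(st.integers(2, 30), st.integers(2, 5), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equals_brute_force(self, L, E, seed):
        rng = np.random.default_rng(seed)
        S = rng.dirichlet(np.ones(E), size=L)
        assert np.allclose(max_sum_pool(S), brute_force_max_sum(S),
                           atol=1e-12)


class TestAssignments:
    def _net(self, **kw):
        cfg = ModelConfig(**{"P": 3, "N": 2, "A": 2, "hidden": 8,
                             "n_mlp_layers": 3, "seed": 0, **kw})
        return MultilevelNet(6, cfg), cfg

    def test_rows_stochastic_everywhere(self):
        net, _ = self._net()
        ps = grid_patchset(4, 4, d=6, seed=3)
        g = build_patch_graph(ps)
        _, _, bundle = net.predict(ps, g)
        bundle.validate(atol=1e-5)

    def test_single_phenotype_assigns_everything_to_it(self):
        net, _ = self._net(P=1)
        S = net.phenotype_assign(np.random.default_rng(0).normal(size=(5, 6)))
        assert np.allclose(S, 1.0)

    def test_single_area_assigns_everything_to_it(self):
        net, _ = self._net(A=1)
        ps = grid_patchset(3, 3, d=6, seed=4)
        g = build_patch_graph(ps)
        S_N = net.neighborhood_assign(ps.embeddings, g)
        sa_n, sa_p = net.area_assign(S_N, g, ps.embeddings)
        assert np.allclose(sa_n, 1.0) and np.allclose(sa_p, 1.0)

    def test_identical_embeddings_get_identical_phenotype_rows(self):
        net, _ = self._net()
        E = np.random.default_rng(1).normal(size=(4, 6))
        E[2] = E[0]
        S = net.phenotype_assign(E)
        assert np.allclose(S[2], S[0])

    def test_nan_embeddings_rejected(self):
        net, _ = self._net()
        E = np.full((3, 6), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            net.phenotype_assign(E)

    def test_sigmoid_activation_rows_still_sum_to_one(self):
        net, _ = self._net(activation="sigmoid")
        S = net.phenotype_assign(np.random.default_rng(2).normal(size=(5, 6)))
        assert np.allclose(S.sum(axis=1), 1.0, atol=1e-9)


class TestNeighborhoodLocality:
    def _setup(self, K):
        cfg = ModelConfig(P=3, N=2, A=2, K=K, hidden=8, n_mlp_layers=2,
                          seed=0)
        net = MultilevelNet(6, cfg)
        ps = grid_patchset(7, 7, d=6, seed=5)
        g = build_patch_graph(ps)
        return net, ps, g

    def test_k0_ignores_all_other_patches(self):
        net, ps, g = self._setup(K=0)
        base = net.neighborhood_assign(ps.embeddings, g)
        perturbed = ps.embeddings.copy()
        perturbed[0] += 10.0  # far corner
        out = net.neighborhood_assign(perturbed, g)
        center = 3 * 7 + 3
        assert np.allclose(out[center], base[center])
        assert not np.allclose(out[0], base[0])

    def test_k2_receptive_field_is_exactly_the_12_patch_neighborhood(self):
        from tmenet.graphs import k_hop_nodes
        net, ps, g = self._setup(K=2)
        center = 3 * 7 + 3
        hood = k_hop_nodes(g, center, 2)
        assert len(hood) == 12
        base = net.neighborhood_assign(ps.embeddings, g)[center]
        inside = next(iter(hood))
        pert = ps.embeddings.copy()
        pert[inside] += 5.0
        assert not np.allclose(
            net.neighborhood_assign(pert, g)[center], base)
        outside = next(i for i in range(g.L)
                       if i != center and i not in hood)
        pert = ps.embeddings.copy()
        pert[outside] += 5.0
        assert np.allclose(net.neighborhood_assign(pert, g)[center], base,
                           atol=1e-12)

    def test_constant_embeddings_give_identical_rows(self):
        net, ps, g = self._setup(K=2)
        E = np.ones_like(ps.embeddings)
        out = net.neighborhood_assign(E, g)
        assert np.allclose(out, out[0])


class TestClassifier:
    def test_zero_parameters_give_half_half(self):
        enr = EnrichmentVector(phenotypes=np.array([3.0, 2.0]),
                               neighborhoods=np.array([4.0]),
                               areas=np.array([1.0]), L=5)
        pred = classify(enr, (np.zeros((4, 2)), np.zeros(2)))
        assert pred.p_recurrence == pytest.approx(0.5)
        assert pred.confidence == pytest.approx(0.5)

    def test_probabilities_sum_to_one_for_random_weights(self):
        rng = np.random.default_rng(0)
        enr = EnrichmentVector(phenotypes=rng.random(3),
                               neighborhoods=rng.random(2),
                               areas=rng.random(2), L=4)
        pred = classify(enr, (rng.normal(size=(7, 2)), rng.normal(size=2)))
        assert pred.p_recurrence + pred.p_no_recurrence == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        enr = EnrichmentVector(phenotypes=np.ones(2),
                               neighborhoods=np.ones(2),
                               areas=np.ones(2), L=2)
        with pytest.raises(ValueError, match="enrichment length"):
            classify(enr, (np.zeros((9, 2)), np.zeros(2)))

    def test_separable_enrichments_reach_perfect_training_accuracy(self):
        """The affine+softmax head converges on linearly separable data."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-1.0, 0.2, size=(20, 4)),
                       rng.normal(1.0, 0.2, size=(20, 4))])
        y = np.array([0] * 20 + [1] * 20)
        w = ag.Tensor(np.zeros((4, 2)), requires_grad=True)
        b = ag.Tensor(np.zeros(2), requires_grad=True)
        opt = ag.Adam([w, b], lr=0.1)
        onehot = np.eye(2)[y]
        for _ in range(200):
            logp = ag.log_row_softmax(ag.Tensor(X) @ w + b)
            loss = -(logp * ag.Tensor(onehot)).sum() * (1 / len(y))
            opt.zero_grad()
            loss.backward()
            opt.step()
        pred = np.argmax(X @ w.data + b.data, axis=1)
        assert np.all(pred == y)


def _toy_dataset(n_patients=6, rows=3, d=6, seed=0, signal=2.0):
    """Tiny learnable dataset: class-1 patients have shifted embeddings."""
    rng = np.random.default_rng(seed)
    patchsets, labels = {}, {}
    for i in range(n_patients):
        label = i % 2
        ps = grid_patchset(rows, rows, d=d, seed=seed + i,
                           patient=f"pt{i}")
        ps.embeddings = ps.embeddings + label * signal
        patchsets[f"pt{i}"] = ps
        labels[f"pt{i}"] = label
    graphs = {p: build_patch_graph(ps) for p, ps in patchsets.items()}
    return PatientDataset(patchsets=patchsets, graphs=graphs, labels=labels)


class TestTraining:
    CFG = dict(P=2, N=2, A=2, hidden=8, n_mlp_layers=2, epochs=8,
               patients_per_batch=3, lr=1e-2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_decreases_on_learnable_data(self, seed):
        ds = _toy_dataset(seed=seed)
        _, hist = train_model(ds, ModelConfig(seed=seed, **self.CFG))
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_same_seed_reproduces_final_parameters(self):
        ds = _toy_dataset()
        cfg = ModelConfig(seed=7, **self.CFG)
        net1, h1 = train_model(ds, cfg)
        net2, h2 = train_model(ds, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        for p1, p2 in zip(net1.params, net2.params):
            assert np.array_equal(p1.data, p2.data)

    def test_single_class_rejected(self):
        ds = _toy_dataset()
        for pid in ds.labels:
            ds.labels[pid] = 0
        with pytest.raises(ValueError, match="both classes"):
            train_model(ds, ModelConfig(**self.CFG))

    def test_assignments_stay_stochastic_during_training(self):
        ds = _toy_dataset()
        cfg = ModelConfig(seed=0, **{**self.CFG, "epochs": 2,
                                     "confidence_weight": 0.05,
                                     "balance_weight": 0.1})
        net, _ = train_model(ds, cfg)
        for pid in ds.patient_ids:
            _, _, bundle = net.predict(ds.patchsets[pid], ds.graphs[pid])
            bundle.validate(atol=1e-5)

    def test_save_load_round_trip(self, tmp_path):
        ds = _toy_dataset()
        net, _ = train_model(ds, ModelConfig(seed=1, **self.CFG))
        net.save(tmp_path / "m.npz")
        back = MultilevelNet.load(tmp_path / "m.npz")
        pid = ds.patient_ids[0]
        a, _, _ = net.predict(ds.patchsets[pid], ds.graphs[pid])
        b, _, _ = back.predict(ds.patchsets[pid], ds.graphs[pid])
        assert a.p_recurrence == pytest.approx(b.p_recurrence, abs=1e-12)

    def test_warmstart_runs_and_trains(self):
        ds = _toy_dataset()
        cfg = ModelConfig(seed=0, **{**self.CFG, "warmstart_epochs": 1})
        _, hist = train_model(ds, cfg)
        assert hist["train_loss"][-1] < hist["train_loss"][0]


class TestHyperparameterSearch:
    def test_published_grid_cardinality(self):
        assert grid_cardinality(PUBLISHED_GRID) == 138_240

    def test_budget_one_returns_single_config(self):
        ds = _toy_dataset()
        base = ModelConfig(P=2, N=2, A=2, hidden=8, n_mlp_layers=2,
                           patients_per_batch=3)
        best, trials = hyperparameter_search(
            ds, {"lr": [1e-2, 1e-3]}, budget=1, seed=0, base_config=base,
            min_epochs=2)
        assert len(trials) == 1
        assert best.lr in (1e-2, 1e-3)

    def test_rigged_search_picks_trainable_learning_rate(self):
        """A divergent lr loses the race against a sane one."""
        ds = _toy_dataset(n_patients=8)
        base = ModelConfig(P=2, N=2, A=2, hidden=8, n_mlp_layers=2,
                           patients_per_batch=4)
        best, trials = hyperparameter_search(
            ds, {"lr": [50.0, 1e-2]}, budget=2, seed=0, base_config=base,
            min_epochs=2)
        assert best.lr == 1e-2
        assert {50.0, 1e-2} == set(trials["lr"].unique())

    def test_budget_exceeding_grid_is_capped_with_warning(self):
        ds = _toy_dataset()
        base = ModelConfig(P=2, N=2, A=2, hidden=8, n_mlp_layers=2,
                           patients_per_batch=3)
        with pytest.warns(UserWarning, match="capped"):
            hyperparameter_search(ds, {"lr": [1e-2]}, budget=5, seed=0,
                                  base_config=base, min_epochs=1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            hyperparameter_search(_toy_dataset(), {}, budget=1)
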