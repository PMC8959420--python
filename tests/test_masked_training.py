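"""Confidence mask, masked loss, training loop and inference tests."""

import numpy as np
import pytest
import scipy.sparse as sp

from msgcn import (
    ConfidenceMask,
    GroupAtlas,
    GraphSignals,
    MsgcnModel,
    ChebLayerParams,
    ParcellationMap,
    ProbabilityMap,
    SubjectData,
    TrainingConfig,
    build_confidence_mask,
    init_model,
    masked_kl_loss,
    predict_parcellation,
    train,
)


class TestConfidenceMask:
    def test_session_identical_to_atlas_keeps_whole_cortex(self):
        atlas = GroupAtlas(labels=np.array([0, 1, 1, 2, 2, 3]))
        pm = ParcellationMap(labels=atlas.labels.copy())
        mask = build_confidence_mask([pm], atlas)
        np.testing.assert_array_equal(mask.weights, atlas.labels > 0)

    def test_session_disagreement_zeroes_vertex(self):
        atlas = GroupAtlas(labels=np.array([1, 1, 2, 2]))
        s1 = ParcellationMap(labels=np.array([1, 1, 2, 2]))
        s2 = ParcellationMap(labels=np.array([1, 2, 2, 2]))
        mask = build_confidence_mask([s1, s2], atlas)
        np.testing.assert_array_equal(mask.weights, [1, 0, 1, 1])

    def test_six_vertex_fixture_matches_bruteforce(self):
        """Hand-built 6-vertex, 2-session case against a literal rule check."""
        atlas_labels = np.array([1, 1, 2, 2, 3, 0])
        ses1 = np.array([1, 2, 2, 2, 3, 1])   # v1 differs from atlas
        ses2 = np.array([1, 1, 2, 0, 3, 1])   # v3 unassigned in session 2
        atlas = GroupAtlas(labels=atlas_labels)
        mask = build_confidence_mask(
            [ParcellationMap(labels=ses1), ParcellationMap(labels=ses2)], atlas
        )
        expected = np.zeros(6)
        for v in range(6):
            rule1 = ses1[v] != 0 and ses2[v] != 0                 # assigned
            rule2 = ses1[v] == atlas_labels[v] and ses2[v] == atlas_labels[v]
            rule3 = ses1[v] == ses2[v]                            # overlap
            expected[v] = float(rule1 and rule2 and rule3 and atlas_labels[v] != 0)
        np.testing.assert_array_equal(mask.weights, expected)
        assert mask.coverage == expected.mean()

    def test_mask_subset_chain_on_random_inputs(self):
        """mask <= atlas-match-every-session <= cortex, for random labelings."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 40
            atlas = GroupAtlas(
                labels=np.concatenate([np.arange(1, 5), rng.integers(0, 5, n - 4)])
            )
            sessions = [
                ParcellationMap(labels=rng.integers(0, 5, n)) for _ in range(3)
            ]
            mask = build_confidence_mask(sessions, atlas)
            cortex = atlas.labels > 0
            match_all = cortex.copy()
            for s in sessions:
                match_all &= s.labels == atlas.labels
            on = mask.weights > 0
            assert (on <= match_all).all()
            assert (match_all <= cortex).all()

    def test_empty_session_list_rejected(self):
        atlas = GroupAtlas(labels=np.array([1, 2]))
        with pytest.raises(ValueError, match="at least one"):
            build_confidence_mask([], atlas)


class TestMaskedLoss:
    def test_perfect_prediction_zero_loss(self):
        p = np.eye(4)[[1, 2, 3, 1]]
        p = np.clip(p, 1e-9, 1)  # rows renormalized below
        p /= p.sum(axis=1, keepdims=True)
        probs = ProbabilityMap(P=p)
        targets = ParcellationMap(labels=np.array([1, 2, 3, 1]))
        mask = ConfidenceMask(weights=np.ones(4))
        assert masked_kl_loss(probs, targets, mask) == pytest.approx(0.0, abs=1e-6)

    def test_all_weights_zero_gives_zero(self):
        probs = ProbabilityMap(P=np.full((3, 2), 0.5))
        targets = ParcellationMap(labels=np.array([1, 1, 1]))
        assert masked_kl_loss(probs, targets,
                              ConfidenceMask(weights=np.zeros(3))) == 0.0

    def test_uniform_probabilities_analytic_value(self):
        """M masked vertices, 201 uniform classes -> loss = M ln 201."""
        m, k = 7, 201
        probs = ProbabilityMap(P=np.full((10, k), 1.0 / k))
        targets = ParcellationMap(labels=np.full(10, 5))
        w = np.zeros(10)
        w[:m] = 1
        loss = masked_kl_loss(probs, targets, ConfidenceMask(weights=w))
        assert loss == pytest.approx(m * np.log(k), rel=1e-12)

    def test_equals_crossentropy_restricted_to_mask(self):
        """Oracle: plain per-vertex NLL summed over mask-1 vertices."""
        rng = np.random.default_rng(4)
        p = rng.dirichlet(np.ones(5), size=12)
        y = rng.integers(1, 5, size=12)
        w = (rng.random(12) < 0.5).astype(float)
        loss = masked_kl_loss(
            ProbabilityMap(P=p), ParcellationMap(labels=y),
            ConfidenceMask(weights=w),
        )
        oracle = -sum(np.log(p[v, y[v]]) for v in range(12) if w[v] == 1)
        assert loss == pytest.approx(oracle, rel=1e-12)

    def test_masked_unassigned_vertex_rejected(self):
        probs = ProbabilityMap(P=np.full((2, 3), 1 / 3))
        targets = ParcellationMap(labels=np.array([0, 1]))
        with pytest.raises(ValueError, match="label 0"):
            masked_kl_loss(probs, targets, ConfidenceMask(weights=np.ones(2)))


def _toy_problem(seed=0):
    """10-node path graph, 2 well-separated classes, fully confident mask."""
    rng = np.random.default_rng(seed)
    n = 10
    a = sp.diags([np.ones(n - 1), np.ones(n - 1)], [-1, 1], format="csr")
    d = np.asarray(a.sum(axis=1)).ravel()
    lap = sp.eye(n) - sp.diags(1 / np.sqrt(d)) @ a @ sp.diags(1 / np.sqrt(d))
    lam = np.linalg.eigvalsh(lap.toarray())[-1]
    ls = ((2 / lam) * lap - sp.eye(n)).tocsr()
    y = np.array([1] * 5 + [2] * 5)
    x = np.where(y[:, None] == 1, 1.0, -1.0) + 0.05 * rng.normal(size=(n, 2))
    sig = GraphSignals(X=x, feature_meaning=np.array([1, 2]))
    sub = SubjectData(
        subject_id="toy",
        signals=[sig],
        mask=ConfidenceMask(weights=np.ones(n)),
        targets=ParcellationMap(labels=y),
    )
    return ls, sub


class TestTraining:
    def test_toy_convergence_and_accuracy(self):
        ls, sub = _toy_problem()
        model = init_model(n_features=2, n_classes=3, hidden=4, order=1,
                           dropout_rate=0.0, seed=0)
        config = TrainingConfig(epochs=60, patience=60, dropout=0.0,
                                learning_rate=0.05, seed=0)
        trained, hist = train(model, [sub], [sub], ls, config)
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        pm = predict_parcellation(trained, sub.signals[0], ls)
        assert (pm.labels == sub.targets.labels).mean() == 1.0

    def test_early_stopping_contract(self):
        """Validation loss that only worsens stops after `patience` epochs."""
        ls, sub = _toy_problem()
        model = init_model(n_features=2, n_classes=3, hidden=4, order=1,
                           dropout_rate=0.0, seed=1)
        # adversarial validation: targets anticorrelated with the training
        # labels, so fitting train strictly worsens validation
        bad = SubjectData(
            subject_id="bad", signals=sub.signals, mask=sub.mask,
            targets=ParcellationMap(labels=np.where(sub.targets.labels == 1, 2, 1)),
        )
        config = TrainingConfig(epochs=50, patience=5, dropout=0.0,
                                learning_rate=0.05, seed=0)
        _, hist = train(model, [sub], [bad], ls, config)
        best = hist["best_epoch"]
        assert len(hist["val_loss"]) == best + 5
        assert hist["val_loss"][best - 1] == min(hist["val_loss"])

    def test_same_seed_reproducible(self):
        ls, sub = _toy_problem()
        results = []
        for _ in range(2):
            model = init_model(n_features=2, n_classes=3, hidden=4, order=1,
                               seed=3)
            config = TrainingConfig(epochs=10, patience=10, dropout=0.5,
                                    learning_rate=0.05, seed=7)
            trained, hist = train(model, [sub], [sub], ls, config)
            results.append((trained, hist))
        (m1, h1), (m2, h2) = results
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]
        for l1, l2 in zip(m1.layers, m2.layers):
            assert (l1.theta == l2.theta).all()

    def test_full_mask_reduces_to_supervised_atlas_fit(self, tiny_cohort):
        """All weights 1, no warp: plain node classification hits the atlas."""
        from msgcn import connectivity_fingerprint

        cohort = tiny_cohort
        atlas = cohort.atlas
        sig = connectivity_fingerprint(cohort.sessions[0][0], atlas)
        sub = SubjectData(
            subject_id="s0", signals=[sig],
            mask=ConfidenceMask(weights=(atlas.labels > 0).astype(float)),
            targets=ParcellationMap(labels=atlas.labels),
        )
        model = init_model(n_features=atlas.n_parcels,
                           n_classes=atlas.n_parcels + 1,
                           dropout_rate=0.0, seed=0)
        config = TrainingConfig(epochs=120, patience=120, dropout=0.0,
                                learning_rate=0.01, weight_decay=0.0, seed=0)
        trained, _ = train(model, [sub], [sub], cohort.laplacian.L_scaled, config)
        pm = predict_parcellation(trained, sig, cohort.laplacian.L_scaled)
        assert (pm.labels == atlas.labels).mean() >= 0.99

    def test_empty_training_set_rejected(self):
        ls, sub = _toy_problem()
        model = init_model(n_features=2, n_classes=3, seed=0)
        with pytest.raises(ValueError, match="empty training"):
            train(model, [], [sub], ls, TrainingConfig())


class TestPredict:
    def test_argmax_and_background(self):
        # identity-filter model: logits equal the input features
        n = 4
        ls = sp.csr_matrix((n, n))
        x = np.array([[10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0], [10.0, 0, 0]])
        theta = np.zeros((1, 3, 3))
        theta[0] = np.eye(3)
        model = MsgcnModel(
            layers=[
                ChebLayerParams(order=0, theta=theta),
                ChebLayerParams(order=0, theta=np.eye(3)[None]),
            ],
            dropout_rate=0.0,
        )
        sig = GraphSignals(X=x, feature_meaning=np.arange(3))
        pm = predict_parcellation(model, sig, ls)
        # class 0 is background -> label 0; classes 1,2 are parcels
        np.testing.assert_array_equal(pm.labels, [0, 1, 2, 0])

    def test_exact_tie_prefers_lower_class(self):
        n = 2
        ls = sp.csr_matrix((n, n))
        x = np.zeros((n, 2))  # all logits equal -> argmax picks class 0
        model = MsgcnModel(
            layers=[
                ChebLayerParams(order=0, theta=np.zeros((1, 2, 2))),
                ChebLayerParams(order=0, theta=np.eye(2)[None]),
            ],
            dropout_rate=0.0,
        )
        sig = GraphSignals(X=x, feature_meaning=np.arange(2))
        pm = predict_parcellation(model, sig, ls)
        np.testing.assert_array_equal(pm.labels, [0, 0])

    def test_feature_mismatch_rejected(self):
        model = init_model(n_features=5, n_classes=3, seed=0)
        sig = GraphSignals(X=np.zeros((4, 3)), feature_meaning=np.arange(3))
        with pytest.raises(ValueError, match="features"):
            predict_parcellation(model, sig, sp.csr_matrix((4, 4)))
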