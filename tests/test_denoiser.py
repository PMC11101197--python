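"""Hybrid loss identities, gradients, training behaviour."""

import numpy as np
import pytest

from demist.channels import shift_channels
from demist.denoiser import (
    DemistDenoiser,
    fidelity_loss,
    hybrid_loss,
    select_lambda,
    slice_range_for_defect,
    task_loss,
)


@pytest.fixture(scope="module")
def toy_batch():
    rng = np.random.default_rng(42)
    shape = (3, 16, 16, 8)
    target = rng.random(shape)
    pred = target + 0.1 * rng.standard_normal(shape)
    centroids = [(8, 8, 4), (7, 9, 3), (9, 6, 5)]
    return pred, target, centroids


@pytest.fixture(scope="module")
def toy_channels():
    from demist.channels import build_rotational_channels
    return build_rotational_channels(2, 16, 0.442)


class TestFidelityLoss:
    def test_zero_for_identical_batches(self, toy_batch):
        _, target, _ = toy_batch
        assert fidelity_loss(target, target) == 0.0

    def test_single_voxel_difference_formula(self):
        target = np.zeros((2, 8, 8, 4))
        pred = target.copy()
        pred[1, 3, 2, 1] = 0.7
        expected = 0.7**2 / (2 * 8 * 8 * 4)
        assert np.isclose(fidelity_loss(pred, target), expected, atol=1e-15)

    def test_matches_explicit_summation_oracle(self, toy_batch):
        pred, target, _ = toy_batch
        ref = 0.0
        for j in range(pred.shape[0]):
            ref += np.sum((target[j] - pred[j]) ** 2)
        ref /= pred.shape[0] * pred[0].size
        assert np.isclose(fidelity_loss(pred, target), ref, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fidelity_loss(np.zeros((1, 4, 4, 2)), np.zeros((1, 4, 4, 3)))


class TestTaskLoss:
    def test_zero_for_identical_batches(self, toy_batch, toy_channels):
        _, target, centroids = toy_batch
        assert task_loss(target, target, toy_channels, centroids, 2, 5) == 0.0

    def test_dc_perturbation_invisible_to_channels(self, toy_batch, toy_channels):
        # centred centroids (identity shift): channels exclude DC exactly;
        # acyclic truncation of off-centre shifts leaks a little DC
        _, target, _ = toy_batch
        centroids = [(8, 8, 4)] * target.shape[0]
        loss = task_loss(target + 0.5, target, toy_channels, centroids, 2, 5)
        assert loss < 1e-8

    def test_matches_brute_force_oracle(self, toy_batch, toy_channels):
        pred, target, centroids = toy_batch
        s1, s2 = 2, 5
        got = task_loss(pred, target, toy_channels, centroids, s1, s2)
        C = toy_channels.n_channels
        ref = 0.0
        for j in range(pred.shape[0]):
            U = shift_channels(toy_channels, centroids[j][:2])
            acc = 0.0
            for s in range(s1, s2 + 1):
                diff = (target[j, :, :, s] - pred[j, :, :, s]).ravel()
                v = np.array([U[:, c] @ diff for c in range(C)])
                acc += np.sum(v**2)
            ref += acc / (C * (s2 - s1 + 1))
        ref /= pred.shape[0]
        assert np.isclose(got, ref, atol=1e-10)

    def test_missing_centroids_rejected(self, toy_batch, toy_channels):
        pred, target, _ = toy_batch
        with pytest.raises(ValueError):
            task_loss(pred, target, toy_channels, None, 0, 3)


class TestHybridLoss:
    def test_lambda_zero_equals_fidelity(self, toy_batch, toy_channels):
        pred, target, centroids = toy_batch
        h = hybrid_loss(pred, target, toy_channels, centroids, lam=0.0, s1=2, s2=5)
        assert h == fidelity_loss(pred, target)

    def test_additive_composition(self, toy_batch, toy_channels):
        pred, target, centroids = toy_batch
        a = fidelity_loss(pred, target)
        b = task_loss(pred, target, toy_channels, centroids, 2, 5)
        h = hybrid_loss(pred, target, toy_channels, centroids, lam=1.0, s1=2, s2=5)
        assert np.isclose(h, a + b, atol=1e-12)

    def test_decomposition_identity_random_lambda(self, toy_batch, toy_channels):
        pred, target, centroids = toy_batch
        for lam in (0.3, 2.0, 7.5):
            h = hybrid_loss(pred, target, toy_channels, centroids, lam=lam, s1=2, s2=5)
            t = task_loss(pred, target, toy_channels, centroids, 2, 5)
            assert np.isclose(h - lam * t, fidelity_loss(pred, target), atol=1e-10)

    def test_negative_lambda_rejected(self, toy_batch, toy_channels):
        pred, target, centroids = toy_batch
        with pytest.raises(ValueError):
            hybrid_loss(pred, target, toy_channels, centroids, lam=-1.0, s1=2, s2=5)

    def test_gradient_matches_finite_differences(self, toy_channels):
        """Analytic gradient of the hybrid loss w.r.t. one predicted voxel."""
        rng = np.random.default_rng(3)
        target = rng.random((2, 16, 16, 8))
        pred = target + 0.05 * rng.standard_normal(target.shape)
        centroids = [(8, 8, 4), (9, 7, 4)]
        ranges = [(2, 6), (2, 6)]
        den = DemistDenoiser(lam=1.7)
        shifted = [shift_channels(toy_channels, c[:2]) for c in centroids]
        _, _, grad = den._loss_and_grad(pred.copy(), target, shifted, ranges)

        def loss(p):
            return hybrid_loss(p, target, toy_channels, centroids, lam=1.7,
                               slice_ranges=ranges)

        eps = 1e-6
        for idx in [(0, 5, 5, 4), (1, 10, 3, 2), (0, 2, 14, 7)]:
            p1, p2 = pred.copy(), pred.copy()
            p1[idx] += eps
            p2[idx] -= eps
            fd = (loss(p1) - loss(p2)) / (2 * eps)
            assert np.isclose(grad[idx], fd, rtol=1e-4, atol=1e-12)


class TestNetworkGradients:
    def test_backward_matches_numeric_weight_gradient(self):
        """Backprop through the full U-net agrees with central finite
        differences on sampled weights (float64, squared-error loss)."""
        from demist._nn import SmallUNet2D

        rng = np.random.default_rng(8)
        net = SmallUNet2D(n_filters=2, dropout=0.0, seed=0)
        for c in net.convs:  # float64 for a clean finite-difference check
            c.W = c.W.astype(np.float64)
            c.b = c.b.astype(np.float64)
            c.dW = np.zeros_like(c.W)
            c.db = np.zeros_like(c.b)
        x = rng.random((2, 1, 8, 8))
        t = rng.random((2, 1, 8, 8))

        def loss():
            return 0.5 * np.sum((net.forward(x) - t) ** 2)

        net.zero_grad()
        out = net.forward(x)
        net.backward(out - t)
        eps = 1e-6
        for conv in (net.c1, net.c4, net.c7):
            idx = tuple(rng.integers(0, s) for s in conv.W.shape)
            keep = conv.W[idx]
            conv.W[idx] = keep + eps
            lp = loss()
            conv.W[idx] = keep - eps
            lm = loss()
            conv.W[idx] = keep
            fd = (lp - lm) / (2 * eps)
            assert np.isclose(conv.dW[idx], fd, rtol=1e-5, atol=1e-8)

    def test_backward_matches_numeric_input_gradient(self):
        from demist._nn import SmallUNet2D

        rng = np.random.default_rng(9)
        net = SmallUNet2D(n_filters=2, dropout=0.0, seed=1)
        for c in net.convs:
            c.W = c.W.astype(np.float64)
            c.b = c.b.astype(np.float64)
            c.dW = np.zeros_like(c.W)
            c.db = np.zeros_like(c.b)
        x = rng.random((1, 1, 8, 8))
        t = rng.random((1, 1, 8, 8))
        net.zero_grad()
        dx = net.backward(net.forward(x) - t)
        eps = 1e-6
        for idx in [(0, 0, 3, 4), (0, 0, 7, 0)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fd = (0.5 * np.sum((net.forward(xp) - t) ** 2)
                  - 0.5 * np.sum((net.forward(xm) - t) ** 2)) / (2 * eps)
            assert np.isclose(dx[idx], fd, rtol=1e-5, atol=1e-8)


class TestTraining:
    def test_identity_data_drives_loss_down(self):
        rng = np.random.default_rng(0)
        X = rng.random((6, 16, 16, 8))
        den = DemistDenoiser(lam=0.0, epochs=15, batch_size=3, dropout=0.0, seed=1)
        den.fit(X, X)
        curve = [e["total"] for e in den.loss_curve_]
        assert curve[-1] < 0.1 * curve[0]

    def test_same_seed_same_training(self):
        rng = np.random.default_rng(1)
        X = rng.random((4, 16, 16, 8))
        y = X + 0.1 * rng.standard_normal(X.shape)
        kw = dict(lam=1.0, epochs=3, dropout=0.1, seed=9)
        cents = [(8, 8, 4)] * 4
        a = DemistDenoiser(**kw).fit(X, y, centroids=cents)
        b = DemistDenoiser(**kw).fit(X, y, centroids=cents)
        assert np.isclose(a.loss_curve_[-1]["total"], b.loss_curve_[-1]["total"],
                          rtol=1e-7)

    def test_tadl_equals_lambda_zero_loss_path(self):
        """lambda=0 training follows the fidelity-only path exactly."""
        rng = np.random.default_rng(2)
        X = rng.random((4, 16, 16, 8))
        y = X + 0.05 * rng.standard_normal(X.shape)
        a = DemistDenoiser(lam=0.0, epochs=2, dropout=0.0, seed=5).fit(X, y)
        for e in a.loss_curve_:
            assert e["task"] == 0.0
            assert e["total"] == e["fidelity"]

    def test_denoising_improves_fidelity_over_lowdose(self):
        """Scaled-down run: denoised volumes closer to the clean target
        than the noisy inputs are."""
        rng = np.random.default_rng(4)
        clean = np.zeros((12, 16, 16, 8))
        clean[:, 5:11, 5:11, 2:6] = 1.0
        noisy = clean + 0.3 * rng.standard_normal(clean.shape)
        noisy = np.clip(noisy, 0, None)
        den = DemistDenoiser(lam=0.0, epochs=25, batch_size=4, dropout=0.0, seed=3)
        den.fit(noisy, clean)
        pred = den.transform(noisy)
        rmse_pred = np.sqrt(np.mean((pred - clean) ** 2))
        rmse_low = np.sqrt(np.mean((noisy - clean) ** 2))
        assert rmse_pred < rmse_low

    def test_inference_is_deterministic_and_finite(self):
        rng = np.random.default_rng(5)
        X = rng.random((2, 16, 16, 8))
        den = DemistDenoiser(lam=0.0, epochs=2, dropout=0.3, seed=0).fit(X, X)
        a, b = den.transform(X), den.transform(X)
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_centroids_required_with_task_loss(self):
        X = np.random.default_rng(6).random((2, 16, 16, 8))
        with pytest.raises(ValueError):
            DemistDenoiser(lam=1.0, epochs=1).fit(X, X)

    def test_nan_data_aborts_with_diagnostic(self):
        X = np.full((2, 16, 16, 8), np.nan)
        with pytest.raises(FloatingPointError):
            DemistDenoiser(lam=0.0, epochs=1, seed=0).fit(
                np.nan_to_num(X), X * 0 + np.inf * 0 + 1)  # finite target, nan input
            # (nan input propagates to a non-finite loss)


class TestSelectLambda:
    def _fitted(self, lam, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((4, 16, 16, 8))
        return DemistDenoiser(lam=lam, epochs=1, seed=seed).fit(
            X, X, centroids=[(8, 8, 4)] * 4)

    def test_single_candidate_returned(self):
        models = {0.5: self._fitted(0.5)}
        vols = np.random.default_rng(1).random((4, 16, 16, 8))
        lam, table = select_lambda(models, vols, [1, 1, 0, 0], [(8, 8, 4)] * 4,
                                   observer_auc=lambda v, l, c: 0.8)
        assert lam == 0.5
        assert table == [(0.5, 0.8)]

    def test_tie_breaks_to_smallest_lambda(self):
        models = {lam: self._fitted(lam) for lam in (0.0, 1.0, 3.0)}
        vols = np.random.default_rng(2).random((4, 16, 16, 8))
        lam, _ = select_lambda(models, vols, [1, 1, 0, 0], [(8, 8, 4)] * 4,
                               observer_auc=lambda v, l, c: 0.7)
        assert lam == 0.0

    def test_returns_argmax_of_logged_table(self):
        models = {lam: self._fitted(lam) for lam in (0.0, 0.5, 5.0)}
        vols = np.random.default_rng(3).random((4, 16, 16, 8))
        aucs = iter([0.6, 0.9, 0.7])
        lam, table = select_lambda(models, vols, [1, 1, 0, 0], [(8, 8, 4)] * 4,
                                   observer_auc=lambda v, l, c: next(aucs))
        best_row = max(table, key=lambda r: r[1])
        assert lam == best_row[0] == 0.5

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_lambda({}, np.zeros((1, 16, 16, 8)), [1], [(8, 8, 4)],
                          observer_auc=lambda v, l, c: 0.5)


def test_slice_range_spans_defect_axial_extent():
    lo, hi = slice_range_for_defect(24, 42.0, 4.42, 48)
    assert (lo, hi) == (24 - 4, 24 + 4)
    assert slice_range_for_defect(1, 42.0, 4.42, 48)[0] == 0  # clipped at edge
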