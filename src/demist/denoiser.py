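"""Detection-task-specific denoising of low-count MPI-SPECT volumes.

The denoiser maps a reconstructed low-dose short-axis volume to a predicted
normal-dose volume with a small residual encoder-decoder applied slice by
slice.  Training minimises a hybrid loss

    L = L_fid + lambda * L_task

where L_fid is the per-voxel mean squared error between the actual and
predicted normal-dose volumes,

    L_fid = (1 / (J * N2D * Z)) sum_j || fND_j - fpred_j ||^2,

and L_task penalises the loss of anthropomorphic-channel features in the
slices around the defect,

    L_task = (1 / (J * C * n_slices)) sum_j sum_s || (S_j U)^T (fND_{j,s} - fpred_{j,s}) ||^2,

with U the rotationally symmetric channel matrix and S_j the acyclic shift
centring the channel profiles on sample j's defect centroid (defect-absent
samples reuse the centroid of their paired inserted-defect location).
Setting lambda = 0 recovers the task-agnostic (TADL) baseline: plain
fidelity-driven denoising.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._nn import Adam, SmallUNet2D
from .channels import ChannelSet, build_rotational_channels, shift_channels

__all__ = [
    "fidelity_loss",
    "task_loss",
    "hybrid_loss",
    "slice_range_for_defect",
    "DemistDenoiser",
    "select_lambda",
]


def _as_batch(x):
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4:
        raise ValueError("expected a batch of 3-D volumes")
    return x


def fidelity_loss(pred, target):
    """Mean squared error per voxel per sample: (1/(J*N2D*Z)) sum_j ||t_j - p_j||^2."""
    pred, target = _as_batch(pred), _as_batch(target)
    if pred.shape != target.shape:
        raise ValueError("pred/target shape mismatch")
    return float(np.sum((target - pred) ** 2) / pred[0].size / pred.shape[0])


def _shifted_matrices(channel_set, centroids):
    return [shift_channels(channel_set, (c[0], c[1])) for c in centroids]


def _resolve_ranges(centroids, s1, s2, slice_ranges, nz):
    if slice_ranges is not None:
        return [(int(a), int(b)) for a, b in slice_ranges]
    if s1 is None or s2 is None:
        raise ValueError("provide either (s1, s2) or slice_ranges")
    return [(int(s1), int(s2))] * len(centroids)


def task_loss(pred, target, channel_set, centroids, s1=None, s2=None,
              slice_ranges=None, shifted=None):
    """Channel-feature MSE over the slices where the channels are applied.

    ``centroids`` holds one (row, col[, slice]) defect centroid per sample;
    the slice span is either a common (s1, s2) pair or a per-sample list of
    inclusive ranges.  Each sample's slice sum is normalised by its own
    slice count and channel count, then averaged over the batch.
    """
    pred, target = _as_batch(pred), _as_batch(target)
    if pred.shape != target.shape:
        raise ValueError("pred/target shape mismatch")
    if centroids is None or len(centroids) != pred.shape[0]:
        raise ValueError("one centroid per sample is required")
    nz = pred.shape[3]
    ranges = _resolve_ranges(centroids, s1, s2, slice_ranges, nz)
    if shifted is None:
        shifted = _shifted_matrices(channel_set, centroids)
    C = shifted[0].shape[1]
    total = 0.0
    for j in range(pred.shape[0]):
        lo, hi = ranges[j]
        if not (0 <= lo <= hi < nz):
            raise ValueError(f"invalid slice range ({lo}, {hi})")
        diff = (target[j, :, :, lo:hi + 1] - pred[j, :, :, lo:hi + 1])
        d2 = diff.reshape(-1, hi - lo + 1)  # (N2D, n_slices)
        v = shifted[j].T @ d2               # (C, n_slices)
        total += np.sum(v**2) / (C * (hi - lo + 1))
    return float(total / pred.shape[0])


def hybrid_loss(pred, target, channel_set, centroids, lam, s1=None, s2=None,
                slice_ranges=None):
    """L_fid + lambda * L_task (lambda = 0 is the TADL baseline)."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    fid = fidelity_loss(pred, target)
    if lam == 0:
        return fid
    return fid + lam * task_loss(pred, target, channel_set, centroids,
                                 s1=s1, s2=s2, slice_ranges=slice_ranges)


def slice_range_for_defect(centroid_slice, axial_length_mm, voxel_size_mm, nz):
    """Inclusive slice range spanning the defect's axial extent."""
    z = int(round(float(centroid_slice)))
    half = int(axial_length_mm / 2.0 / voxel_size_mm)
    return max(0, z - half), min(nz - 1, z + half)


class DemistDenoiser(BaseEstimator, TransformerMixin):
    """Slice-wise residual encoder-decoder denoiser with a hybrid
    fidelity + channel-feature loss.

    Parameters
    ----------
    lam : float, default 1.0
        Weight of the task-specific loss term; 0 gives the task-agnostic
        (fidelity-only) baseline.
    n_filters : int, default 4
        Feature maps at the full-resolution level (doubled at lower levels).
    dropout : float, default 0.05
        Dropout rate at the bottleneck during training.
    epochs, batch_size, lr, betas : ADAM training schedule.
    n_channels, f_start, pixel_size_cm : channel bank used by the task loss,
        built at the slice grid size.
    defect_axial_mm : float, default 42.0
        Axial extent used to derive each sample's task-loss slice range from
        its defect centroid.
    seed : int
        Seeds weight initialisation, batch shuffling and dropout.

    Attributes
    ----------
    net_ : the trained network
    scale_x_, scale_y_ : float intensity normalisations for the low-dose
        input and normal-dose target (volumes are windowed to [0, x_LV]
        upstream; low-dose intensities sit near dose_fraction times the
        normal-dose scale, so the two are normalised separately)
    loss_curve_ : list of per-epoch dicts with fidelity/task/total losses
    """

    def __init__(self, lam=1.0, n_filters=4, dropout=0.05, epochs=20,
                 batch_size=4, lr=1e-3, betas=(0.9, 0.999), n_channels=4,
                 f_start=0.1838, pixel_size_cm=0.442, defect_axial_mm=42.0,
                 seed=0):
        self.lam = lam
        self.n_filters = n_filters
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.betas = betas
        self.n_channels = n_channels
        self.f_start = f_start
        self.pixel_size_cm = pixel_size_cm
        self.defect_axial_mm = defect_axial_mm
        self.seed = seed

    # -- gradient of the hybrid loss w.r.t. the prediction (scaled space) --
    def _loss_and_grad(self, pred, target, shifted, ranges):
        B = pred.shape[0]
        n3d = pred[0].size
        diff = pred - target
        fid = float(np.sum(diff**2) / n3d / B)
        dpred = (2.0 / (B * n3d)) * diff
        task = 0.0
        if self.lam > 0:
            for j in range(B):
                lo, hi = ranges[j]
                ns = hi - lo + 1
                U = shifted[j]
                C = U.shape[1]
                d2 = diff[j, :, :, lo:hi + 1].reshape(-1, ns)
                v = U.T @ d2
                task += np.sum(v**2) / (C * ns)
                dpred[j, :, :, lo:hi + 1] += (
                    (2.0 * self.lam / (B * C * ns)) * (U @ v)
                ).reshape(pred.shape[1], pred.shape[2], ns)
            task /= B
        return fid, task, dpred

    def fit(self, X, y, centroids=None, slice_ranges=None):
        """Train on paired (low-dose, normal-dose) windowed volumes.

        X, y : arrays (J, nr, nc, nz); centroids : per-sample (row, col,
        slice) defect centroids, required when ``lam > 0``.
        """
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        X = _as_batch(X)
        y = _as_batch(y)
        if X.shape != y.shape or X.shape[0] == 0:
            raise ValueError("X and y must be matching nonempty volume batches")
        J, nr, nc, nz = X.shape
        rng = np.random.default_rng(self.seed)

        if self.lam > 0:
            if centroids is None:
                raise ValueError("centroids are required when lam > 0")
            chan = build_rotational_channels(
                self.n_channels, nr, self.pixel_size_cm, self.f_start)
            if slice_ranges is None:
                slice_ranges = [
                    slice_range_for_defect(c[2], self.defect_axial_mm,
                                           self.pixel_size_cm * 10.0, nz)
                    for c in centroids
                ]
            # put the task term in the same per-voxel MSE units as the
            # fidelity term (the task normalisation divides by C*n_s, the
            # fidelity one by N3D), so the lambda grid is a meaningful dial
            ns_nom = int(np.median([hi - lo + 1 for lo, hi in slice_ranges]))
            scale = np.sqrt(self.n_channels * ns_nom / (nr * nc * nz))
            chan = ChannelSet(chan.matrix * scale, chan.grid_size,
                              chan.pixel_size_cm, chan.passbands)
            shifted = _shifted_matrices(chan, centroids)
            self.channel_set_ = chan
        else:
            shifted = [None] * J
            slice_ranges = [(0, nz - 1)] * J

        # low-dose inputs sit near dose_fraction * normal-dose intensity, so
        # input and target are normalised to [0, ~1] separately
        self.scale_x_ = float(np.mean(X.max(axis=(1, 2, 3)))) or 1.0
        self.scale_y_ = float(np.mean(y.max(axis=(1, 2, 3)))) or 1.0
        Xs = (X / self.scale_x_).astype(np.float32)
        ys = (y / self.scale_y_).astype(np.float32)

        self.net_ = SmallUNet2D(self.n_filters, self.dropout, seed=rng.integers(2**31))
        opt = Adam(self.net_.parameters(), lr=self.lr, betas=self.betas)
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(J)
            ep_fid = ep_task = 0.0
            for start in range(0, J, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = Xs[idx]
                # slices as batch of 2-D images: (B*nz, 1, nr, nc)
                xin = np.ascontiguousarray(xb.transpose(0, 3, 1, 2)).reshape(-1, 1, nr, nc)
                pred = self.net_.forward(xin, train=True, rng=rng)
                pred_v = pred.reshape(len(idx), nz, nr, nc).transpose(0, 2, 3, 1)
                fid, task, dpred = self._loss_and_grad(
                    pred_v.astype(np.float64), ys[idx],
                    [shifted[i] for i in idx], [slice_ranges[i] for i in idx])
                if not np.isfinite(fid + task):
                    raise FloatingPointError("non-finite training loss; aborting")
                dnet = np.ascontiguousarray(
                    dpred.transpose(0, 3, 1, 2)).reshape(-1, 1, nr, nc).astype(np.float32)
                self.net_.zero_grad()
                self.net_.backward(dnet)
                opt.step()
                ep_fid += fid * len(idx)
                ep_task += task * len(idx)
            self.loss_curve_.append({
                "epoch": epoch,
                "fidelity": ep_fid / J,
                "task": ep_task / J,
                "total": (ep_fid + self.lam * ep_task) / J,
            })
        return self

    def transform(self, X):
        """Denoise volumes; deterministic (dropout disabled), output >= 0."""
        if not hasattr(self, "net_"):
            raise RuntimeError("denoiser is not fitted")
        X = _as_batch(X)
        nr, nc, nz = X.shape[1:]
        xin = np.ascontiguousarray(
            (X / self.scale_x_).astype(np.float32).transpose(0, 3, 1, 2)
        ).reshape(-1, 1, nr, nc)
        out = []
        # bounded batches keep peak memory flat for large cohorts
        for start in range(0, xin.shape[0], 256):
            out.append(self.net_.forward(xin[start:start + 256], train=False))
        pred = np.concatenate(out, axis=0).reshape(X.shape[0], nz, nr, nc)
        pred = pred.transpose(0, 2, 3, 1).astype(np.float64) * self.scale_y_
        return np.clip(pred, 0.0, None)

    def denoise(self, volume):
        """Single-volume convenience wrapper around :meth:`transform`."""
        return self.transform(np.asarray(volume)[None])[0]

    def save(self, path):
        """Write the checkpoint (weights as .npz + JSON sidecar next to it).

        The sidecar carries the constructor parameters, the intensity
        scales and the training curve, so ``DemistDenoiser.load`` restores
        an inference-identical estimator.
        """
        import json
        from pathlib import Path

        if not hasattr(self, "net_"):
            raise RuntimeError("cannot save an unfitted denoiser")
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        np.savez(path, **self.net_.state_dict())
        sidecar = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "scale_x": self.scale_x_,
            "scale_y": self.scale_y_,
            "loss_curve": [
                {k: float(v) for k, v in e.items()} for e in self.loss_curve_
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path):
        """Restore a saved denoiser checkpoint."""
        import json
        from pathlib import Path

        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        params = sidecar["params"]
        params["betas"] = tuple(params["betas"])
        est = cls(**params)
        est.net_ = SmallUNet2D(est.n_filters, est.dropout, seed=0)
        with np.load(path) as d:
            est.net_.load_state_dict(dict(d))
        est.scale_x_ = sidecar["scale_x"]
        est.scale_y_ = sidecar["scale_y"]
        est.loss_curve_ = sidecar["loss_curve"]
        return est


def select_lambda(models, volumes_lowdose, labels, centroids, observer_auc,
                  lambdas=None):
    """Pick the lambda whose denoised validation images maximise observer AUC.

    Parameters
    ----------
    models : dict lambda -> fitted DemistDenoiser
    volumes_lowdose : (J, nr, nc, nz) validation low-dose volumes
    labels : defect present/absent per case
    centroids : per-case defect centroid (row, col, slice)
    observer_auc : callable(volumes, labels, centroids) -> AUC
    lambdas : optional explicit candidate ordering (defaults to sorted keys)

    Returns
    -------
    (best_lambda, table) where table is a list of (lambda, auc) rows; ties
    break toward the smallest lambda.
    """
    if not models:
        raise ValueError("empty candidate list")
    cand = sorted(models) if lambdas is None else list(lambdas)
    table = []
    for lam in cand:
        den = models[lam].transform(volumes_lowdose)
        table.append((lam, float(observer_auc(den, labels, centroids))))
    best = max(table, key=lambda row: (row[1], -row[0]))
    return best[0], table
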