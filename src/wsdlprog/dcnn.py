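"""3D residual feature extractor and two-class prognosis head.

A compact CPU implementation (NumPy forward and backward passes) of an
18-layer-style residual topology moved to 3D: stem convolution, four stages
of residual blocks with 3x3x3 convolutions and x2 spatial downsampling per
stage, global average pooling, and a fully connected 2-way softmax head.

The stage widths end at 128 so the average-pooling output is exactly the
128-element deep-feature vector; the default widths (16, 32, 64, 128) are
the narrow counterpart of the classic (64, 128, 256, 512).

Tensors are channels-last ``(N, D, H, W, C)`` float32.  All randomness
(initialization, shuffling, augmentation, validation split) derives from the
config seed, so single-threaded runs are bit-for-bit reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkConfig",
    "FeatureVector",
    "PredictedProbability",
    "ResNet3D",
    "build_network",
    "train_supervised",
    "extract_features",
    "predict_probabilities",
    "feature_strip",
]

N_FEATURES = 128


@dataclass
class NetworkConfig:
    input_voxels: int = 32
    input_channels: int = 2
    stage_widths: tuple[int, int, int, int] = (16, 32, 64, 128)
    blocks_per_stage: int = 2
    #: the stem convolution halves resolution by default, as in the classic
    #: residual topology; set to 1 to keep full resolution into stage 1
    stem_stride: int = 2
    dropout_rate: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 60
    early_stop_patience: int = 10
    val_fraction: float = 0.2
    augment: bool = False
    class_balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage_widths[-1] != N_FEATURES:
            raise ValueError(
                f"last stage width must be {N_FEATURES} so the average-pool "
                f"output has {N_FEATURES} elements; got {self.stage_widths}"
            )
        if min(self.stage_widths) <= 0 or self.blocks_per_stage <= 0:
            raise ValueError("stage widths and block counts must be positive")
        if self.input_channels not in (1, 2):
            raise ValueError("input_channels must be 1 (PET) or 2 (PET+CT)")


@dataclass
class FeatureVector:
    patient_id: str
    values: np.ndarray  # length 128

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


@dataclass
class PredictedProbability:
    patient_id: str
    p_pos: float
    p_neg: float


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class _Conv3d:
    """3D convolution, kernel 3 (pad 1) or 1 (pad 0), stride 1 or 2.

    Computed as a sum of per-offset matrix products over the kernel taps,
    which keeps memory at one padded copy of the input (cached for the
    backward pass during training).
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        fan_in = k ** 3 * cin
        self.W = (rng.standard_normal((k, k, k, cin, cout)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.dW = np.zeros_like(self.W)
        self.k, self.stride, self.pad = k, stride, (1 if k == 3 else 0)
        self._xp = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n, d, h, w, cin = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x
        od = (d + 2 * p - k) // s + 1
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        cout = self.W.shape[-1]
        y = np.zeros((n * od * oh * ow, cout), dtype=np.float32)
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    view = xp[
                        :, kd : kd + s * od : s, kh : kh + s * oh : s, kw : kw + s * ow : s, :
                    ]
                    y += view.reshape(-1, cin) @ self.W[kd, kh, kw]
        if train:
            self._xp = xp
            self._xshape = x.shape
        return y.reshape(n, od, oh, ow, cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        xp = self._xp
        n, od, oh, ow, cout = dy.shape
        cin = self.W.shape[3]
        dy2 = dy.reshape(-1, cout)
        dxp = np.zeros_like(xp)
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    sl = (
                        slice(None),
                        slice(kd, kd + s * od, s),
                        slice(kh, kh + s * oh, s),
                        slice(kw, kw + s * ow, s),
                        slice(None),
                    )
                    self.dW[kd, kh, kw] = xp[sl].reshape(-1, cin).T @ dy2
                    dxp[sl] += (dy2 @ self.W[kd, kh, kw].T).reshape(n, od, oh, ow, cin)
        self._xp = None
        return dxp[:, p:-p, p:-p, p:-p, :] if p else dxp

    def params(self):
        return [(self.W, self.dW)]


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            axes = (0, 1, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._cache = (xhat, inv.astype(np.float32))
            return (self.gamma * xhat + self.beta).astype(np.float32)
        inv = 1.0 / np.sqrt(self.run_var + self.eps)
        return (self.gamma * (x - self.run_mean) * inv + self.beta).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = float(np.prod(dy.shape[:4]))
        axes = (0, 1, 2, 3)
        self.dgamma[:] = (dy * xhat).sum(axis=axes)
        self.dbeta[:] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = inv / m * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )
        self._cache = None
        return dx.astype(np.float32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class _ReLU:
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        out = dy * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class _Block:
    """Residual basic block: two 3x3x3 convolutions plus shortcut."""

    def __init__(self, cin, cout, stride, rng):
        self.conv1 = _Conv3d(cin, cout, 3, stride, rng)
        self.bn1 = _BatchNorm(cout)
        self.relu1 = _ReLU()
        self.conv2 = _Conv3d(cout, cout, 3, 1, rng)
        self.bn2 = _BatchNorm(cout)
        self.relu_out = _ReLU()
        if stride != 1 or cin != cout:
            self.proj = _Conv3d(cin, cout, 1, stride, rng)
            self.proj_bn = _BatchNorm(cout)
        else:
            self.proj = None

    def forward(self, x, train):
        idn = x if self.proj is None else self.proj_bn.forward(
            self.proj.forward(x, train), train
        )
        y = self.bn1.forward(self.conv1.forward(x, train), train)
        y = self.relu1.forward(y, train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        return self.relu_out.forward(y + idn, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dy = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d))))
        )
        if self.proj is None:
            return dy + d
        return dy + self.proj.backward(self.proj_bn.backward(d))

    def params(self):
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            out += self.proj.params() + self.proj_bn.params()
        return out


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------

class ResNet3D:
    """Handle returned by :func:`build_network`; holds layers and state."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w0 = config.stage_widths[0]
        self.stem = _Conv3d(config.input_channels, w0, 3, config.stem_stride, rng)
        self.stem_bn = _BatchNorm(w0)
        self.stem_relu = _ReLU()
        self.blocks: list[_Block] = []
        cin = w0
        for width in config.stage_widths:
            for b in range(config.blocks_per_stage):
                stride = 2 if b == 0 else 1  # every stage downsamples once
                self.blocks.append(_Block(cin, width, stride, rng))
                cin = width
        # zero-initialized head: an untrained network is exactly symmetric
        # (p_pos = p_neg = 0.5 for every input)
        self.fc_W = np.zeros((N_FEATURES, 2), dtype=np.float32)
        self.fc_b = np.zeros(2, dtype=np.float32)
        self.d_fc_W = np.zeros_like(self.fc_W)
        self.d_fc_b = np.zeros_like(self.fc_b)
        self._rng = rng  # consumed by dropout/training only
        self.training_log: list[dict] = []

    # -- forward/backward ---------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False):
        """Return (features, probabilities); caches for backward if train."""
        x = np.asarray(x, dtype=np.float32)
        if x.shape[1] != self.config.input_voxels or x.shape[-1] != self.config.input_channels:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match config "
                f"({self.config.input_voxels}^3 x {self.config.input_channels})"
            )
        h = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x, train), train), train)
        for blk in self.blocks:
            h = blk.forward(h, train)
        feats = h.mean(axis=(1, 2, 3))  # global average pool -> (N, 128)
        if train and self.config.dropout_rate > 0:
            keep = 1.0 - self.config.dropout_rate
            mask = (self._rng.random(feats.shape) < keep) / keep
            self._drop_mask = mask.astype(np.float32)
            feats_fc = feats * self._drop_mask
        else:
            self._drop_mask = None
            feats_fc = feats
        logits = (feats_fc @ self.fc_W + self.fc_b).astype(np.float64)
        logits = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        if train:
            self._cache = (h.shape, feats_fc)
        return feats, probs

    def backward(self, dlogits: np.ndarray):
        shape_h, feats_fc = self._cache
        self.d_fc_W[:] = feats_fc.T @ dlogits
        self.d_fc_b[:] = dlogits.sum(axis=0)
        dfeats = dlogits @ self.fc_W.T
        if self._drop_mask is not None:
            dfeats = dfeats * self._drop_mask
        n, d, h, w, c = shape_h
        dh = np.broadcast_to(
            dfeats[:, None, None, None, :] / (d * h * w), shape_h
        ).astype(np.float32)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(dh)))
        self._cache = None

    def params(self):
        out = self.stem.params() + self.stem_bn.params()
        for blk in self.blocks:
            out += blk.params()
        out += [(self.fc_W, self.d_fc_W), (self.fc_b, self.d_fc_b)]
        return out

    def state(self):
        """Copy of all learnable and running-statistic arrays."""
        arrays = [p for p, _ in self.params()]
        bns = [l for l in self._all_bns()]
        return (
            [a.copy() for a in arrays],
            [(bn.run_mean.copy(), bn.run_var.copy()) for bn in bns],
        )

    def load_state(self, state):
        arrays, running = state
        for (p, _), saved in zip(self.params(), arrays):
            p[...] = saved
        for bn, (rm, rv) in zip(self._all_bns(), running):
            bn.run_mean[...] = rm
            bn.run_var[...] = rv

    def _all_bns(self):
        bns = [self.stem_bn]
        for blk in self.blocks:
            bns += [blk.bn1, blk.bn2] + ([blk.proj_bn] if blk.proj is not None else [])
        return bns


def build_network(config: NetworkConfig) -> ResNet3D:
    """Construct the network; initialization is deterministic given the seed."""
    return ResNet3D(config)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _as_tensor_stack(roi_tensors) -> np.ndarray:
    if isinstance(roi_tensors, np.ndarray):
        return roi_tensors.astype(np.float32)
    return np.stack(
        [t.data if hasattr(t, "data") else np.asarray(t) for t in roi_tensors]
    ).astype(np.float32)


def _weighted_ce(probs, labels, weights):
    """Weighted cross-entropy and its logit gradient (normalized by sum w)."""
    n = len(labels)
    eps = 1e-12
    wsum = max(float(weights.sum()), eps)
    ce = -np.log(probs[np.arange(n), labels] + eps)
    loss = float((weights * ce).sum() / wsum)
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (weights / wsum)[:, None]
    return loss, dlogits.astype(np.float32)


def _augment(x: np.ndarray, rng: np.random.Generator, max_shift: int = 5) -> np.ndarray:
    """Random flips along the two axial axes and small integer translations."""
    out = x
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[:, :, ::-1]
    shifts = rng.integers(-max_shift, max_shift + 1, size=3)
    out = np.roll(out, tuple(shifts), axis=(1, 2, 3))
    return np.ascontiguousarray(out)


def train_supervised(
    network: ResNet3D,
    roi_tensors,
    labels,
    sample_weights=None,
    config: NetworkConfig | None = None,
) -> tuple[ResNet3D, list[dict]]:
    """Minimize weighted cross-entropy with Adam and early stopping.

    A held-out fraction of the provided patients (stratified, seeded) is used
    for validation; the returned network carries the best-validation-loss
    checkpoint.  When the set is too small for a two-class validation split,
    training simply runs for ``max_epochs``.  Per-class inverse-frequency
    weights are folded into the sample weights when ``class_balance`` is set.
    """
    config = config or network.config
    X = _as_tensor_stack(roi_tensors)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class; need both")
    w = np.ones(len(y)) if sample_weights is None else np.asarray(sample_weights, dtype=float)
    if (w < 0).any():
        raise ValueError("sample weights must be non-negative")
    if config.class_balance:
        freq = np.bincount(y, weights=w, minlength=2)
        cw = w.sum() / (2.0 * np.maximum(freq, 1e-12))
        w = w * cw[y]

    rng = np.random.default_rng(config.seed + 1)
    n = len(y)
    n_val = int(round(config.val_fraction * n))
    use_val = n_val >= 4
    if use_val:
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        rng.shuffle(idx_pos)
        rng.shuffle(idx_neg)
        nvp = max(1, int(round(config.val_fraction * len(idx_pos))))
        nvn = max(1, int(round(config.val_fraction * len(idx_neg))))
        val_idx = np.concatenate([idx_pos[:nvp], idx_neg[:nvn]])
        tr_idx = np.concatenate([idx_pos[nvp:], idx_neg[nvn:]])
    else:
        tr_idx = np.arange(n)
        val_idx = np.array([], dtype=int)

    opt = _Adam(network.params(), config.learning_rate)
    log: list[dict] = []
    best = (np.inf, network.state())
    patience_left = config.early_stop_patience
    for epoch in range(config.max_epochs):
        order = tr_idx.copy()
        rng.shuffle(order)
        losses, wsum = 0.0, 0.0
        for start in range(0, len(order), config.batch_size):
            b = order[start : start + config.batch_size]
            xb = X[b]
            if config.augment:
                xb = _augment(xb, rng)
            _, probs = network.forward(xb, train=True)
            loss, dlogits = _weighted_ce(probs, y[b], w[b])
            network.backward(dlogits)
            opt.step()
            bw = float(w[b].sum())
            losses += loss * bw
            wsum += bw
        entry = {"epoch": epoch, "train_loss": losses / max(wsum, 1e-12)}
        if use_val:
            _, pv = network.forward(X[val_idx], train=False)
            val_loss, _ = _weighted_ce(pv, y[val_idx], w[val_idx])
            entry["val_loss"] = val_loss
            if val_loss < best[0] - 1e-6:
                best = (val_loss, network.state())
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
        log.append(entry)
        if use_val and patience_left <= 0:
            break
    if use_val and np.isfinite(best[0]):
        network.load_state(best[1])
    network.training_log = log
    return network, log


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def _batched(network, X, batch: int = 16):
    feats, probs = [], []
    for start in range(0, len(X), batch):
        f, p = network.forward(X[start : start + batch], train=False)
        feats.append(f)
        probs.append(p)
    return np.concatenate(feats), np.concatenate(probs)


def _ids(roi_tensors, n):
    ids = []
    for i, t in enumerate(roi_tensors if not isinstance(roi_tensors, np.ndarray) else range(n)):
        ids.append(getattr(t, "patient_id", f"case{i:03d}"))
    return ids


def extract_features(network: ResNet3D, roi_tensors) -> list[FeatureVector]:
    """Deterministic inference-mode 128-vectors, order preserved."""
    X = _as_tensor_stack(roi_tensors)
    feats, _ = _batched(network, X)
    return [
        FeatureVector(pid, f) for pid, f in zip(_ids(roi_tensors, len(X)), feats)
    ]


def predict_probabilities(network: ResNet3D, roi_tensors) -> list[PredictedProbability]:
    X = _as_tensor_stack(roi_tensors)
    _, probs = _batched(network, X)
    return [
        PredictedProbability(pid, float(p[1]), float(p[0]))
        for pid, p in zip(_ids(roi_tensors, len(X)), probs)
    ]


# --------------------------------------------------------------------------
# feature-map strip
# --------------------------------------------------------------------------

def feature_strip(feature: FeatureVector | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Arrange the 128 features as a 16x8 grid (row-major).

    Returns ``(raw, scaled)`` where ``raw[r, c]`` is feature ``8*r + c`` and
    ``scaled`` is min-max rescaled to [0, 1] for rendering (constant strips
    map to zeros).
    """
    values = feature.values if isinstance(feature, FeatureVector) else np.asarray(feature, float)
    if values.shape != (N_FEATURES,):
        raise ValueError(f"expected {N_FEATURES} features, got shape {values.shape}")
    raw = values.reshape(16, 8)
    span = raw.max() - raw.min()
    scaled = (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)
    return raw, scaled
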