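"""Lightweight 1-D CNN backbone for 9-channel, 128-sample activity windows.

Architecture: three Conv1d+BN+ReLU blocks (64, 128, 256 filters, kernel 5,
same padding), max-pooling after the first two blocks, global average pooling
and a fully connected classifier head.  Implemented directly on numpy (im2col
convolutions, explicit backprop, Adam) so the package has no deep-learning
framework dependency; at this scale (<=256 channels, 32-128 time steps) dense
BLAS matmuls are entirely adequate.

Sparse subnetwork activation masks the 256 final-block filters: a binary mask
zeroes a filter's output after BN+ReLU (so batch-norm statistics are never
corrupted by masking), before global pooling.  The 256-dim pooled vector is
also the feature the online-adaptation stage refreshes the FC head on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConvBackbone", "TrainConfig"]


@dataclass
class TrainConfig:
    lr: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    val_fraction: float = 0.0
    verbose: bool = False


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, L) -> (N, L, C*k) patch matrix for stride-1 'same' conv."""
    N, C, L = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    cols = np.empty((N, L, C, k), dtype=x.dtype)
    for j in range(k):
        cols[:, :, :, j] = xp[:, :, j : j + L].transpose(0, 2, 1)
    return cols.reshape(N, L, C * k)


def _col2im(dcols: np.ndarray, C: int, k: int, L: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    N = dcols.shape[0]
    dcols = dcols.reshape(N, L, C, k)
    dxp = np.zeros((N, C, L + 2 * pad), dtype=dcols.dtype)
    for j in range(k):
        dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
    return dxp[:, :, pad : pad + L]


class _ConvBNRelu:
    """Conv1d(k=5, same) + BatchNorm + ReLU block with cached backprop."""

    K = 5
    PAD = 2

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * self.K))
        self.W = rng.normal(0, scale, size=(c_in * self.K, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gamma = np.ones(c_out, dtype=np.float32)
        self.beta = np.zeros(c_out, dtype=np.float32)
        self.run_mean = np.zeros(c_out, dtype=np.float32)
        self.run_var = np.ones(c_out, dtype=np.float32)
        self.momentum = 0.1
        self.eps = 1e-5
        self.c_in, self.c_out = c_in, c_out
        self._cache: dict = {}

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b, self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, L = x.shape
        cols = _im2col(x, self.K, self.PAD)
        z = cols @ self.W + self.b  # (N, L, c_out)
        if train:
            mu = z.mean(axis=(0, 1))
            var = z.var(axis=(0, 1))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        zhat = (z - mu) * inv_std
        a = self.gamma * zhat + self.beta
        out = np.maximum(a, 0.0)
        self._cache = {"cols": cols, "zhat": zhat, "inv_std": inv_std,
                       "relu_mask": a > 0, "L": L, "train": train}
        return out.transpose(0, 2, 1)  # (N, c_out, L)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        c = self._cache
        da = dout.transpose(0, 2, 1) * c["relu_mask"]  # (N, L, c_out)
        dgamma = (da * c["zhat"]).sum(axis=(0, 1))
        dbeta = da.sum(axis=(0, 1))
        if c["train"]:
            m = da.shape[0] * da.shape[1]
            dzhat = da * self.gamma
            dz = (
                dzhat
                - dzhat.mean(axis=(0, 1))
                - c["zhat"] * (dzhat * c["zhat"]).mean(axis=(0, 1))
            ) * c["inv_std"]
            del m
        else:
            dz = da * self.gamma * c["inv_std"]
        cols = c["cols"]
        dW = np.tensordot(cols, dz, axes=([0, 1], [0, 1])).astype(np.float32)
        db = dz.sum(axis=(0, 1)).astype(np.float32)
        dcols = dz @ self.W.T
        dx = _col2im(dcols, self.c_in, self.K, c["L"], self.PAD)
        return dx, [dW, db, dgamma.astype(np.float32), dbeta.astype(np.float32)]


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    N, C, L = x.shape
    xr = x.reshape(N, C, L // 2, 2)
    idx = xr.argmax(axis=3)
    return xr.max(axis=3), idx


def _maxpool2_back(dout: np.ndarray, idx: np.ndarray, L: int) -> np.ndarray:
    N, C, Lh = dout.shape
    dx = np.zeros((N, C, Lh, 2), dtype=dout.dtype)
    np.put_along_axis(dx, idx[..., None], dout[..., None], axis=3)
    return dx.reshape(N, C, L)


class ConvBackbone:
    """Table-style 1-D CNN: 9x128 window -> logits in R^C."""

    N_UNITS = 256  #: maskable final-block filters

    def __init__(self, n_channels: int = 9, n_classes: int = 6, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.block1 = _ConvBNRelu(n_channels, 64, rng)
        self.block2 = _ConvBNRelu(64, 128, rng)
        self.block3 = _ConvBNRelu(128, 256, rng)
        self.W_fc = rng.normal(0, np.sqrt(1.0 / 256), size=(256, n_classes)).astype(
            np.float32
        )
        self.b_fc = np.zeros(n_classes, dtype=np.float32)
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.seed = seed
        self._cache: dict = {}

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return (
            self.block1.params()
            + self.block2.params()
            + self.block3.params()
            + [self.W_fc, self.b_fc]
        )

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        mask: np.ndarray | None = None,
        return_features: bool = False,
    ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
        """``x``: (N, n_channels, 128) windows.  ``mask``: optional binary
        vector over the 256 final-block filters; masked filters contribute
        exactly zero to the pooled feature."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        h = self.block1.forward(x, train)
        h, i1 = _maxpool2(h)
        h = self.block2.forward(h, train)
        h, i2 = _maxpool2(h)
        h = self.block3.forward(h, train)
        if mask is not None:
            mask = np.asarray(mask)
            if mask.shape != (self.N_UNITS,):
                raise ValueError(f"mask must have shape ({self.N_UNITS},)")
            h = h * mask[None, :, None]
        feats = h.mean(axis=2)  # global average pool, (N, 256)
        logits = feats @ self.W_fc + self.b_fc
        self._cache = {"i1": i1, "i2": i2, "L3": h.shape[2], "feats": feats,
                       "mask": mask, "x_shape": x.shape}
        if return_features:
            return logits, feats
        return logits

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        logits = self.forward(x, train=True)
        N = len(y)
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        loss = -np.log(probs[np.arange(N), y] + 1e-12).mean()

        dlogits = probs.copy()
        dlogits[np.arange(N), y] -= 1.0
        dlogits /= N
        c = self._cache
        dW_fc = (c["feats"].T @ dlogits).astype(np.float32)
        db_fc = dlogits.sum(axis=0).astype(np.float32)
        dfeats = dlogits @ self.W_fc.T
        dh = np.repeat(dfeats[:, :, None] / c["L3"], c["L3"], axis=2).astype(np.float32)
        if c["mask"] is not None:
            dh *= c["mask"][None, :, None]
        dh, g3 = self.block3.backward(dh)
        dh = _maxpool2_back(dh, c["i2"], dh.shape[2] * 2)
        dh, g2 = self.block2.backward(dh)
        dh = _maxpool2_back(dh, c["i1"], dh.shape[2] * 2)
        _, g1 = self.block1.backward(dh)
        return float(loss), g1 + g2 + g3 + [dW_fc, db_fc]

    # -- training -----------------------------------------------------------

    def fit(
        self, windows: np.ndarray, labels: np.ndarray, cfg: TrainConfig | None = None
    ) -> list[float]:
        """Adam training on (N, n_channels, 128) windows; returns the
        per-epoch mean loss curve.  Zero epochs leaves the initialization
        untouched."""
        cfg = cfg or TrainConfig()
        x = np.asarray(windows, dtype=np.float32)
        y = np.asarray(labels, dtype=np.int64)
        if len(np.unique(y)) < self.n_classes:
            raise ValueError(
                f"training data must contain all {self.n_classes} classes"
            )
        rng = np.random.default_rng(cfg.seed)
        params = self.parameters()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        curve: list[float] = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(x))
            losses = []
            for s in range(0, len(x), cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                loss, grads = self.loss_and_grads(x[idx], y[idx])
                step += 1
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = b1 * m[i] + (1 - b1) * g
                    v[i] = b2 * v[i] + (1 - b2) * g * g
                    mh = m[i] / (1 - b1**step)
                    vh = v[i] / (1 - b2**step)
                    p -= (cfg.lr * mh / (np.sqrt(vh) + eps)).astype(p.dtype)
                losses.append(loss)
            curve.append(float(np.mean(losses)))
            if cfg.verbose:
                print(f"epoch {_epoch}: loss {curve[-1]:.4f}")
        return curve

    def predict(self, windows: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        return np.argmax(self.forward(np.asarray(windows, np.float32), mask=mask), axis=1)

    # -- (de)serialization ---------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, blk in (("b1", self.block1), ("b2", self.block2), ("b3", self.block3)):
            out[f"{name}_W"], out[f"{name}_b"] = blk.W, blk.b
            out[f"{name}_gamma"], out[f"{name}_beta"] = blk.gamma, blk.beta
            out[f"{name}_rmean"], out[f"{name}_rvar"] = blk.run_mean, blk.run_var
        out["W_fc"], out["b_fc"] = self.W_fc, self.b_fc
        return out

    def save(self, path: str) -> None:
        np.savez(path, n_channels=self.n_channels, n_classes=self.n_classes,
                 **self.state_arrays())

    @classmethod
    def load(cls, path: str) -> "ConvBackbone":
        with np.load(path) as data:
            net = cls(int(data["n_channels"]), int(data["n_classes"]))
            for name, blk in (("b1", net.block1), ("b2", net.block2), ("b3", net.block3)):
                blk.W = data[f"{name}_W"]
                blk.b = data[f"{name}_b"]
                blk.gamma = data[f"{name}_gamma"]
                blk.beta = data[f"{name}_beta"]
                blk.run_mean = data[f"{name}_rmean"]
                blk.run_var = data[f"{name}_rvar"]
            net.W_fc = data["W_fc"]
            net.b_fc = data["b_fc"]
        return net
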