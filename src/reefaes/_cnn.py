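"""A compact convolutional regressor implemented on numpy.

Architecture (for 64x64 RGB input): 5x5 conv (stride 2, 16 channels) ->
ReLU -> 2x2 average pool -> 3x3 conv (32 channels) -> ReLU -> global
average pool, concatenated with the input's per-channel mean and SD,
-> linear head.  Trained with Adam on mean-squared error.  Global
pooling makes the features translation-insensitive summaries of local
colour and texture, which is what an overhead quadrat photograph's
aesthetic signal lives in.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # x: (N, H, W, C) -> (N, OH, OW, kh, kw, C)
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (N, OH, OW, C, kh, kw)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))


def _col2im(dcols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int) -> np.ndarray:
    n, h, w, c = x_shape
    _, oh, ow = dcols.shape[:3]
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :] += dcols[:, :, :, i, j, :]
    return dx


class _Conv:
    def __init__(self, kh, kw, c_in, c_out, stride, rng):
        fan_in = kh * kw * c_in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.kh, self.kw, self.c_in, self.stride = kh, kw, c_in, stride

    def forward(self, x):
        cols = _im2col(x, self.kh, self.kw, self.stride)
        n, oh, ow = cols.shape[:3]
        flat = cols.reshape(n * oh * ow, -1)
        out = flat @ self.w + self.b
        self._cache = (x.shape, flat, (n, oh, ow))
        return out.reshape(n, oh, ow, -1)

    def backward(self, dout):
        x_shape, flat, (n, oh, ow) = self._cache
        dflat = dout.reshape(n * oh * ow, -1)
        self.dw = flat.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.w.T).reshape(n, oh, ow, self.kh, self.kw, self.c_in)
        return _col2im(dcols, x_shape, self.kh, self.kw, self.stride)


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _AvgPool2:
    def forward(self, x):
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dout):
        n, h, w, c = self._shape
        up = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2) / 4.0
        return up[:, :h, :w, :]


class SmallCNN:
    """Two-stage convolutional regressor with a linear head."""

    def __init__(self, in_side: int = 64, seed: int = 0,
                 c1: int = 16, c2: int = 32):
        rng = np.random.default_rng(seed)
        self.in_side = in_side
        self.conv1 = _Conv(5, 5, 3, c1, stride=2, rng=rng)
        self.relu1 = _ReLU()
        self.pool = _AvgPool2()
        self.conv2 = _Conv(3, 3, c1, c2, stride=1, rng=rng)
        self.relu2 = _ReLU()
        n_feat = 2 * c2 + 6  # first+second moment conv pools + input mean/SD
        self.w_out = rng.normal(0.0, 1.0 / np.sqrt(n_feat), size=n_feat)
        self.b_out = 0.0

    # -- forward ----------------------------------------------------------

    def _features(self, x):
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.pool.forward(h)
        h = self.relu2.forward(self.conv2.forward(h))
        self._conv_out_shape = h.shape
        self._conv_out = h
        pooled = h.mean(axis=(1, 2))
        # second-moment pooling: with conv channels acting as soft colour /
        # texture detectors, E[h^2] carries the evenness information that
        # diversity-type statistics (sum of squared bin shares) live in
        pooled_sq = (h * h).mean(axis=(1, 2))
        stats = np.concatenate(
            [x.mean(axis=(1, 2)), x.std(axis=(1, 2))], axis=1
        )
        return np.concatenate([pooled, pooled_sq, stats], axis=1)

    def forward(self, x):
        feats = self._features(x)
        self._feats = feats
        return feats @ self.w_out + self.b_out

    # -- backward (from d(loss)/d(pred)) -----------------------------------

    def backward(self, x, dpred):
        n = x.shape[0]
        feats = self._feats
        self.dw_out = feats.T @ dpred
        self.db_out = dpred.sum()
        dfeats = np.outer(dpred, self.w_out)
        c2 = self._conv_out_shape[3]
        dpooled = dfeats[:, :c2]
        dpooled_sq = dfeats[:, c2 : 2 * c2]
        # input-stat features receive no gradient path back to weights
        _, oh, ow, _ = self._conv_out_shape
        dh = np.broadcast_to(
            dpooled[:, None, None, :], self._conv_out_shape
        ) / (oh * ow)
        dh = dh + 2.0 * self._conv_out * dpooled_sq[:, None, None, :] / (oh * ow)
        dh = self.conv2.backward(self.relu2.backward(dh))
        dh = self.pool.backward(dh)
        self.conv1.backward(self.relu1.backward(dh))

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> dict[str, np.ndarray]:
        return {
            "c1w": self.conv1.w, "c1b": self.conv1.b,
            "c2w": self.conv2.w, "c2b": self.conv2.b,
            "ow": self.w_out, "ob": np.asarray(self.b_out),
        }

    def grads(self) -> dict[str, np.ndarray]:
        return {
            "c1w": self.conv1.dw, "c1b": self.conv1.db,
            "c2w": self.conv2.dw, "c2b": self.conv2.db,
            "ow": self.dw_out, "ob": np.asarray(self.db_out),
        }

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.conv1.w = params["c1w"].copy()
        self.conv1.b = params["c1b"].copy()
        self.conv2.w = params["c2w"].copy()
        self.conv2.b = params["c2b"].copy()
        self.w_out = params["ow"].copy()
        self.b_out = float(params["ob"])

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: np.array(v, copy=True) for k, v in self.params().items()}

    # -- training -----------------------------------------------------------

    def loss_and_grads(self, x, y):
        pred = self.forward(x)
        resid = pred - y
        loss = float(np.mean(resid**2))
        self.backward(x, 2.0 * resid / len(y))
        return loss

    def fit(
        self,
        x_train, y_train, x_val, y_val,
        epochs: int = 40, learning_rate: float = 3e-3, batch_size: int = 32,
        seed: int = 0, augment_fn=None,
    ) -> list[dict]:
        """Adam training; returns the per-epoch curve and restores the
        parameters of the epoch with the best validation loss."""
        rng = np.random.default_rng(seed)
        m = {k: np.zeros_like(v, dtype=float) for k, v in self.params().items()}
        v = {k: np.zeros_like(val, dtype=float) for k, val in self.params().items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        best = (np.inf, self.snapshot())
        history = []
        n = len(x_train)
        for epoch in range(epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, batch_size):
                batch = order[start : start + batch_size]
                xb = x_train[batch]
                if augment_fn is not None:
                    xb = augment_fn(xb, rng)
                loss = self.loss_and_grads(xb, y_train[batch])
                ep_loss += loss * len(batch)
                t += 1
                grads = self.grads()
                params = self.params()
                for k in params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mhat = m[k] / (1 - b1**t)
                    vhat = v[k] / (1 - b2**t)
                    new = params[k] - learning_rate * mhat / (np.sqrt(vhat) + eps)
                    if k == "ob":
                        self.b_out = float(new)
                    else:
                        params[k][...] = new
            val_pred = self.predict(x_val)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
            history.append(
                {"epoch": epoch, "train_mse": ep_loss / n, "val_mse": val_loss}
            )
            if val_loss < best[0]:
                best = (val_loss, self.snapshot())
        self.set_params(best[1])
        return history

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        out = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(out)
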