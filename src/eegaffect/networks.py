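"""The multi-head additive attention classifier and the recurrent baseline.

The attention model maps the 24-dimensional feature vector x through H
parallel heads. Head h computes a softmax weight vector

    alpha_h = softmax(W_h x + b_h),

rescales the input elementwise, o_h = alpha_h (*) x, and the head outputs
are concatenated into the fused representation (72-dimensional for three
full-vector heads). A dense layer (16 units, ReLU), dropout 0.4 and a
sigmoid unit produce the depression probability. Training is mini-batch
Adam (lr 0.001, batch 30, 30 epochs) on binary cross-entropy.

Two head layouts are supported: ``full_vector`` (each head weighs the full
24-vector; 3 x (24*24+24) = 1800 attention parameters; fused dim 72) and
``subspace`` (each head sees only its 8-wide family block; fused dim 24).

Everything is plain numpy with hand-written backpropagation; gradient
correctness is verified against central finite differences in the test
suite. Training is bit-deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


# ---------------------------------------------------------------------------
# Numerics

def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _bce(p, y, eps=1e-12):
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class Adam:
    """Adam optimizer over a dict of numpy parameter arrays."""

    def __init__(self, params: dict, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Multi-head additive attention network

class MultiHeadAttentionClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-compatible binary classifier with additive attention fusion.

    Parameters
    ----------
    attention : {"multi_head", "single_head", "none"}
        Architecture variant. ``multi_head`` is the full model;
        ``single_head`` uses one attention head over the whole vector;
        ``none`` feeds the raw feature vector straight to the dense head.
    head_input_mode : {"full_vector", "subspace"}
        Whether each head weighs the full input vector (default; fused
        dimension = n_heads * input_dim) or only its own feature-family
        block (fused dimension = input_dim).
    subspace_layout : tuple of int
        Widths of the per-head blocks; must sum to the input dimension.
    hidden_units, dropout, learning_rate, batch_size, epochs
        Dense-head width 16, dropout 0.4, Adam lr 0.001, batch 30, 30
        epochs by default.
    standardize : bool
        Z-score features using training-set statistics (stored on the
        model and re-applied at inference).
    random_state : int or None
        Seeds initialization and batch shuffling; fixed seed gives
        bit-identical training on one thread.

    Attributes
    ----------
    params_ : dict of ndarray
        Trained weights.
    n_params_ : dict
        Trainable-parameter count by component (attention / hidden / output).
    history_ : dict
        Per-epoch train (and optional validation) loss and accuracy.
    """

    _estimator_type = "classifier"

    def __init__(
        self,
        attention: str = "multi_head",
        n_heads: int = 3,
        head_input_mode: str = "full_vector",
        subspace_layout: tuple = (8, 8, 8),
        hidden_units: int = 16,
        dropout: float = 0.4,
        learning_rate: float = 0.001,
        batch_size: int = 30,
        epochs: int = 30,
        standardize: bool = True,
        random_state=None,
    ):
        self.attention = attention
        self.n_heads = n_heads
        self.head_input_mode = head_input_mode
        self.subspace_layout = subspace_layout
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.standardize = standardize
        self.random_state = random_state

    # -- architecture -------------------------------------------------------

    def _layout(self, input_dim: int):
        """Resolve head input slices and output dims; returns
        (head_slices, head_dims, fused_dim)."""
        if self.attention == "none":
            return [], [], input_dim
        if self.attention == "single_head":
            return [slice(0, input_dim)], [input_dim], input_dim
        if self.attention != "multi_head":
            raise ValueError(f"unknown attention kind {self.attention!r}")
        if self.head_input_mode == "full_vector":
            slices = [slice(0, input_dim)] * self.n_heads
            dims = [input_dim] * self.n_heads
            return slices, dims, self.n_heads * input_dim
        if self.head_input_mode != "subspace":
            raise ValueError(f"unknown head_input_mode {self.head_input_mode!r}")
        layout = tuple(self.subspace_layout)
        if len(layout) != self.n_heads or sum(layout) != input_dim:
            raise ValueError(
                f"subspace_layout {layout} incompatible with n_heads="
                f"{self.n_heads} and input_dim={input_dim}"
            )
        slices, start = [], 0
        for w in layout:
            slices.append(slice(start, start + w))
            start += w
        return slices, list(layout), input_dim

    def _init_params(self, input_dim: int, rng: np.random.Generator) -> dict:
        slices, dims, fused = self._layout(input_dim)
        params = {}
        for h, d in enumerate(dims):
            scale = np.sqrt(2.0 / (2 * d))
            params[f"Wa{h}"] = rng.normal(0.0, scale, size=(d, d))
            params[f"ba{h}"] = np.zeros(d)
        params["W1"] = rng.normal(0.0, np.sqrt(2.0 / (fused + self.hidden_units)),
                                  size=(self.hidden_units, fused))
        params["b1"] = np.zeros(self.hidden_units)
        params["w2"] = rng.normal(0.0, np.sqrt(2.0 / (self.hidden_units + 1)),
                                  size=self.hidden_units)
        params["b2"] = np.zeros(1)
        return params

    def parameter_counts(self, input_dim: int = 24) -> dict:
        """Trainable-parameter count by component for this configuration."""
        _, dims, fused = self._layout(input_dim)
        return {
            "attention": int(sum(d * d + d for d in dims)),
            "hidden": int(self.hidden_units * fused + self.hidden_units),
            "output": int(self.hidden_units + 1),
        }

    # -- forward / backward -------------------------------------------------

    def _attention_apply(self, params: dict, X: np.ndarray):
        """Per-head softmax weights and the fused representation."""
        slices, dims, fused = self._layout(X.shape[1])
        alphas, outs = [], []
        for h, sl in enumerate(slices):
            xh = X[:, sl]
            a = _softmax(xh @ params[f"Wa{h}"].T + params[f"ba{h}"])
            alphas.append(a)
            outs.append(a * xh)
        F = np.hstack(outs) if outs else X
        return F, alphas

    def _forward(self, params: dict, X: np.ndarray, drop_mask=None):
        F, alphas = self._attention_apply(params, X)
        P = F @ params["W1"].T + params["b1"]
        H = np.maximum(P, 0.0)
        Hd = H * drop_mask if drop_mask is not None else H
        logit = Hd @ params["w2"] + params["b2"][0]
        return _sigmoid(logit), {"F": F, "alphas": alphas, "P": P, "H": H,
                                 "Hd": Hd, "logit": logit}

    def _loss_and_grads(self, params: dict, X, y, drop_mask=None):
        n = len(y)
        p, cache = self._forward(params, X, drop_mask)
        loss = _bce(p, y)
        grads = {}
        dlogit = (p - y) / n
        grads["w2"] = cache["Hd"].T @ dlogit
        grads["b2"] = np.array([dlogit.sum()])
        dHd = np.outer(dlogit, params["w2"])
        dH = dHd * drop_mask if drop_mask is not None else dHd
        dP = dH * (cache["P"] > 0)
        grads["W1"] = dP.T @ cache["F"]
        grads["b1"] = dP.sum(axis=0)
        dF = dP @ params["W1"]
        slices, dims, _ = self._layout(X.shape[1])
        offset = 0
        for h, sl in enumerate(slices):
            d = dims[h]
            dO = dF[:, offset : offset + d]
            offset += d
            xh = X[:, sl]
            a = cache["alphas"][h]
            dA = dO * xh
            dZ = a * (dA - (dA * a).sum(axis=1, keepdims=True))
            grads[f"Wa{h}"] = dZ.T @ xh
            grads[f"ba{h}"] = dZ.sum(axis=0)
        if not slices:
            pass  # attention="none": no attention parameters
        return loss, grads, p

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("training requires both classes to be present")
        y01 = (y == self.classes_[1]).astype(float)

        rng = np.random.default_rng(self.random_state)
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.scale_ = np.where(scale == 0, 1.0, scale)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_

        self.n_features_in_ = X.shape[1]
        self.params_ = self._init_params(X.shape[1], rng)
        self.n_params_ = self.parameter_counts(X.shape[1])
        opt = Adam(self.params_, lr=self.learning_rate)

        if validation_data is not None:
            Xv = (np.asarray(validation_data[0], dtype=float) - self.mean_) / self.scale_
            yv = (np.asarray(validation_data[1]).ravel() == self.classes_[1]).astype(float)

        hist = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
        n = len(y01)
        keep = 1.0 - self.dropout
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xs[idx], y01[idx]
                mask = None
                if self.dropout > 0:
                    mask = (rng.random((len(idx), self.hidden_units)) < keep) / keep
                _, grads, _ = self._loss_and_grads(self.params_, xb, yb, mask)
                opt.step(self.params_, grads)
            p, _ = self._forward(self.params_, Xs)
            hist["train_loss"].append(_bce(p, y01))
            hist["train_acc"].append(float(np.mean((p >= 0.5) == y01)))
            if validation_data is not None:
                pv, _ = self._forward(self.params_, Xv)
                hist["val_loss"].append(_bce(pv, yv))
                hist["val_acc"].append(float(np.mean((pv >= 0.5) == yv)))
        # diagnostic: first epoch whose loss is within 2% of the final loss
        losses = np.asarray(hist["train_loss"])
        hist["converged_epoch"] = int(
            np.argmax(losses <= losses[-1] * 1.02) + 1
        )
        self.history_ = hist
        return self

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Serialize the fitted model to a JSON container: hyperparameters,
        normalization statistics, class labels and all weight arrays."""
        import json

        check_is_fitted(self, "params_")
        payload = {
            "format": "eegaffect-mha-v1",
            "config": self.get_params(),
            "classes": self.classes_.tolist(),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "n_features_in": self.n_features_in_,
            "weights": {k: v.tolist() for k, v in self.params_.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "MultiHeadAttentionClassifier":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "eegaffect-mha-v1":
            raise ValueError("not a serialized attention model")
        config = payload["config"]
        config["subspace_layout"] = tuple(config["subspace_layout"])
        model = cls(**config)
        model.classes_ = np.asarray(payload["classes"])
        model.mean_ = np.asarray(payload["mean"], dtype=float)
        model.scale_ = np.asarray(payload["scale"], dtype=float)
        model.n_features_in_ = int(payload["n_features_in"])
        model.params_ = {
            k: np.asarray(v, dtype=float) for k, v in payload["weights"].items()
        }
        model.n_params_ = model.parameter_counts(model.n_features_in_)
        return model

    def _transform(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected (n, {self.n_features_in_}) input")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return (X - self.mean_) / self.scale_

    def attention_state(self, X):
        """Fused representation and per-head softmax weights for ``X``
        (inference mode, dropout off)."""
        Xs = self._transform(X)
        F, alphas = self._attention_apply(self.params_, Xs)
        return F, alphas

    def decision_function(self, X):
        Xs = self._transform(X)
        _, cache = self._forward(self.params_, Xs)
        return cache["logit"]

    def predict_proba(self, X):
        Xs = self._transform(X)
        p, _ = self._forward(self.params_, Xs)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]


def ablation_variant(kind: str, **kwargs) -> MultiHeadAttentionClassifier:
    """Build one of the ablation models: ``none``, ``single_head`` or
    ``multi_head``, sharing all other hyperparameters."""
    if kind not in ("none", "single_head", "multi_head"):
        raise ValueError(f"unknown ablation kind {kind!r}")
    return MultiHeadAttentionClassifier(attention=kind, **kwargs)


# ---------------------------------------------------------------------------
# Recurrent baseline

class RecurrentBaselineClassifier(ClassifierMixin, BaseEstimator):
    """Vanilla RNN over the feature vector viewed as a short sequence.

    The 24-vector is reshaped to 8 channel steps of 3 features per step
    (``sequence_axis="channels"``; one step per electrode carrying its
    ratio/asymmetry/entropy triple) or alternatively 3 domain steps of 8
    (``sequence_axis="domains"``). A tanh recurrent cell (hidden 16) feeds
    a sigmoid output; training matches the attention network's Adam,
    batch-size and epoch settings.
    """

    _estimator_type = "classifier"

    def __init__(
        self,
        hidden_units: int = 16,
        sequence_axis: str = "channels",
        learning_rate: float = 0.001,
        batch_size: int = 30,
        epochs: int = 30,
        standardize: bool = True,
        random_state=None,
    ):
        self.hidden_units = hidden_units
        self.sequence_axis = sequence_axis
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.standardize = standardize
        self.random_state = random_state

    def _to_sequence(self, X: np.ndarray) -> np.ndarray:
        n, d = X.shape
        if d % 8 != 0:
            raise ValueError("feature dimension must tile into 8 channel steps")
        n_fam = d // 8
        # feature order is family-major (ratio block, asym block, sampen block)
        fam_major = X.reshape(n, n_fam, 8)
        if self.sequence_axis == "channels":
            return fam_major.transpose(0, 2, 1)  # (n, 8 steps, n_fam)
        if self.sequence_axis == "domains":
            return fam_major  # (n, n_fam steps, 8)
        raise ValueError(f"unknown sequence_axis {self.sequence_axis!r}")

    def _forward(self, params, S):
        n, steps, d = S.shape
        hs = np.zeros((n, steps + 1, self.hidden_units))
        pre = np.empty((n, steps, self.hidden_units))
        for t in range(steps):
            pre[:, t] = S[:, t] @ params["Wx"].T + hs[:, t] @ params["Wh"].T + params["bh"]
            hs[:, t + 1] = np.tanh(pre[:, t])
        logit = hs[:, -1] @ params["w"] + params["b"][0]
        return _sigmoid(logit), {"hs": hs, "logit": logit}

    def _loss_and_grads(self, params, S, y):
        n, steps, d = S.shape
        p, cache = self._forward(params, S)
        hs = cache["hs"]
        loss = _bce(p, y)
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dlogit = (p - y) / n
        grads["w"] = hs[:, -1].T @ dlogit
        grads["b"] = np.array([dlogit.sum()])
        dh = np.outer(dlogit, params["w"])
        for t in range(steps - 1, -1, -1):
            dpre = dh * (1 - hs[:, t + 1] ** 2)
            grads["Wx"] += dpre.T @ S[:, t]
            grads["Wh"] += dpre.T @ hs[:, t]
            grads["bh"] += dpre.sum(axis=0)
            dh = dpre @ params["Wh"]
        return loss, grads, p

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int).ravel()
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("training requires both classes to be present")
        y01 = (y == self.classes_[1]).astype(float)
        rng = np.random.default_rng(self.random_state)
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.scale_ = np.where(scale == 0, 1.0, scale)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        self.n_features_in_ = X.shape[1]
        S = self._to_sequence((X - self.mean_) / self.scale_)
        d = S.shape[2]
        h = self.hidden_units
        self.params_ = {
            "Wx": rng.normal(0, np.sqrt(2.0 / (d + h)), size=(h, d)),
            "Wh": rng.normal(0, np.sqrt(1.0 / h), size=(h, h)),
            "bh": np.zeros(h),
            "w": rng.normal(0, np.sqrt(2.0 / (h + 1)), size=h),
            "b": np.zeros(1),
        }
        opt = Adam(self.params_, lr=self.learning_rate)
        hist = {"train_loss": [], "train_acc": []}
        n = len(y01)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                _, grads, _ = self._loss_and_grads(self.params_, S[idx], y01[idx])
                opt.step(self.params_, grads)
            p, _ = self._forward(self.params_, S)
            hist["train_loss"].append(_bce(p, y01))
            hist["train_acc"].append(float(np.mean((p >= 0.5) == y01)))
        self.history_ = hist
        return self

    def _prep(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        return self._to_sequence((X - self.mean_) / self.scale_)

    def decision_function(self, X):
        _, cache = self._forward(self.params_, self._prep(X))
        return cache["logit"]

    def predict_proba(self, X):
        p, _ = self._forward(self.params_, self._prep(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]
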