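"""Pluggable segmentation backends, written as sklearn-style estimators.

Two backends ship with the package:

``NearestCentroidSegmenter``
    A prototype classifier in RGB space: one centroid per class, pixels
    assigned to the nearest centroid. Deliberately capacity-limited — each
    class is unimodal in colour space, so it cannot represent a class whose
    appearance differs across cases. Fits in one pass.

``SoftmaxSegmenter``
    A small per-pixel softmax network (one hidden layer) trained with
    class-weighted cross-entropy, Adam, and a step-decay learning-rate
    schedule; after each epoch the validation mean foreground Dice is
    recorded and the best-scoring epoch's weights are kept. Being multimodal
    in colour space, it can absorb heterogeneous class appearance when the
    training labels are right.

A full-scale convolutional encoder–decoder (e.g. EfficientNetB0 + UNet++)
can be added through the same registry; it is not a dependency of any test.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import json
import numpy as np
from sklearn.base import BaseEstimator

TrainPair = tuple[np.ndarray, np.ndarray]  # (H x W x 3 pixels, H x W codes)


def _flatten_pairs(
    pairs: Sequence[TrainPair], ignore_code: int, rng: np.random.Generator | None = None,
    max_per_patch: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack labelled pixels from (pixels, codes) pairs; ignore pixels dropped."""
    xs, ys = [], []
    for pixels, codes in pairs:
        keep = codes.ravel() != ignore_code
        x = pixels.reshape(-1, 3)[keep]
        y = codes.ravel()[keep]
        if max_per_patch is not None and x.shape[0] > max_per_patch:
            idx = rng.choice(x.shape[0], size=max_per_patch, replace=False)
            x, y = x[idx], y[idx]
        xs.append(x)
        ys.append(y)
    if not xs:
        raise ValueError("no labelled pixels in training pairs")
    return np.concatenate(xs), np.concatenate(ys)


def _mean_foreground_dice(
    backend: "SegmentationBackend", pairs: Sequence[TrainPair],
    background_code: int, ignore_code: int,
) -> float:
    """Mean Dice over foreground classes present in the reference, pooled over
    the validation pairs (checkpoint-selection metric)."""
    preds = [backend.predict_mask(pixels) for pixels, _ in pairs]
    refs = [codes for _, codes in pairs]
    pred = np.concatenate([p.ravel() for p in preds])
    ref = np.concatenate([r.ravel() for r in refs])
    valid = ref != ignore_code
    pred, ref = pred[valid], ref[valid]
    scores = []
    for c in np.unique(ref):
        if c == background_code:
            continue
        p, r = pred == c, ref == c
        denom = p.sum() + r.sum()
        if denom == 0:
            continue
        scores.append(2.0 * np.logical_and(p, r).sum() / denom)
    return float(np.mean(scores)) if scores else 0.0


class SegmentationBackend(BaseEstimator):
    """Contract shared by all backends."""

    backend_id: str = "abstract"

    def fit(
        self,
        train: Sequence[TrainPair],
        val: Sequence[TrainPair],
        codes: Sequence[int],
        class_weights: dict[int, float],
        ignore_code: int,
        background_code: int = 0,
        seed: int = 0,
    ) -> "SegmentationBackend":
        raise NotImplementedError

    def predict_mask(self, pixels: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def save_state(self, path: str | Path) -> None:
        raise NotImplementedError

    @classmethod
    def load_state(cls, path: str | Path) -> "SegmentationBackend":
        raise NotImplementedError


class NearestCentroidSegmenter(SegmentationBackend):
    """Per-class RGB centroid classifier (unimodal by construction)."""

    backend_id = "centroid"

    def fit(self, train, val, codes, class_weights, ignore_code,
            background_code=0, seed=0):
        X, y = _flatten_pairs(train, ignore_code)
        self.codes_ = np.array(sorted({int(c) for c in np.unique(y)}))
        self.centroids_ = np.stack([X[y == c].mean(axis=0) for c in self.codes_])
        score = _mean_foreground_dice(self, val, background_code, ignore_code) if val else 0.0
        self.val_scores_ = [score]
        self.best_val_score_ = score
        return self

    def predict_mask(self, pixels: np.ndarray) -> np.ndarray:
        flat = np.asarray(pixels, dtype=float).reshape(-1, 3)
        # squared distances to each centroid, vectorized
        d2 = ((flat[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)
        return self.codes_[idx].reshape(pixels.shape[:2])

    def save_state(self, path: str | Path) -> None:
        np.savez(path, codes=self.codes_, centroids=self.centroids_,
                 val_scores=np.asarray(self.val_scores_))

    @classmethod
    def load_state(cls, path: str | Path) -> "NearestCentroidSegmenter":
        data = np.load(path)
        obj = cls()
        obj.codes_ = data["codes"]
        obj.centroids_ = data["centroids"]
        obj.val_scores_ = data["val_scores"].tolist()
        obj.best_val_score_ = max(obj.val_scores_)
        return obj


class SoftmaxSegmenter(SegmentationBackend):
    """One-hidden-layer per-pixel softmax network (numpy, Adam, StepLR).

    Parameters
    ----------
    hidden : width of the hidden tanh layer.
    epochs : training epochs (no early stopping; best epoch kept).
    lr, lr_step_size, lr_gamma : Adam base rate and step-decay schedule.
    batch_size : minibatch size.
    max_pixels_per_patch : per-patch pixel subsample cap, keeps epochs cheap.
    """

    backend_id = "softmax"

    def __init__(self, hidden: int = 24, epochs: int = 36, lr: float = 0.05,
                 lr_step_size: int = 10, lr_gamma: float = 0.5,
                 batch_size: int = 1024, max_pixels_per_patch: int = 512):
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.lr_step_size = lr_step_size
        self.lr_gamma = lr_gamma
        self.batch_size = batch_size
        self.max_pixels_per_patch = max_pixels_per_patch

    def _forward(self, X, params):
        W1, b1, W2, b2 = params
        h = np.tanh(X @ W1 + b1)
        logits = h @ W2 + b2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return h, e / e.sum(axis=1, keepdims=True)

    def fit(self, train, val, codes, class_weights, ignore_code,
            background_code=0, seed=0):
        rng = np.random.default_rng(seed)
        X, y = _flatten_pairs(train, ignore_code, rng, self.max_pixels_per_patch)
        X = X.astype(float) / 255.0
        self.codes_ = np.array(sorted({int(c) for c in codes}))
        code_index = {c: i for i, c in enumerate(self.codes_)}
        yi = np.array([code_index[int(c)] for c in y])
        w = np.array([class_weights.get(int(c), 1.0) for c in self.codes_])
        n_out = len(self.codes_)

        W1 = rng.normal(0, 0.5, (3, self.hidden))
        b1 = np.zeros(self.hidden)
        W2 = rng.normal(0, 0.5, (self.hidden, n_out))
        b2 = np.zeros(n_out)
        params = [W1, b1, W2, b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = X.shape[0]
        self.val_scores_ = []
        best = (-np.inf, None)
        for epoch in range(self.epochs):
            lr = self.lr * self.lr_gamma ** (epoch // self.lr_step_size)
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], yi[idx]
                h, p = self._forward(xb, params)
                wb = w[yb]
                grad_logits = p.copy()
                grad_logits[np.arange(len(yb)), yb] -= 1.0
                grad_logits *= wb[:, None] / wb.sum()
                gW2 = h.T @ grad_logits
                gb2 = grad_logits.sum(axis=0)
                dh = grad_logits @ params[2].T * (1 - h**2)
                gW1 = xb.T @ dh
                gb1 = dh.sum(axis=0)
                grads = [gW1, gb1, gW2, gb2]
                step += 1
                for i, g in enumerate(grads):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g**2
                    mhat = m[i] / (1 - beta1**step)
                    vhat = v[i] / (1 - beta2**step)
                    params[i] -= lr * mhat / (np.sqrt(vhat) + eps)
            self.params_ = [p.copy() for p in params]
            score = (
                _mean_foreground_dice(self, val, background_code, ignore_code)
                if val else 0.0
            )
            self.val_scores_.append(score)
            if score > best[0]:
                best = (score, [p.copy() for p in params])
        if best[1] is not None:
            self.params_ = best[1]
            self.best_val_score_ = best[0]
        else:
            self.best_val_score_ = 0.0
        return self

    def predict_mask(self, pixels: np.ndarray) -> np.ndarray:
        flat = np.asarray(pixels, dtype=float).reshape(-1, 3) / 255.0
        _, p = self._forward(flat, self.params_)
        return self.codes_[np.argmax(p, axis=1)].reshape(pixels.shape[:2])

    def save_state(self, path: str | Path) -> None:
        W1, b1, W2, b2 = self.params_
        np.savez(path, codes=self.codes_, W1=W1, b1=b1, W2=W2, b2=b2,
                 val_scores=np.asarray(self.val_scores_),
                 hyper=np.frombuffer(json.dumps(self.get_params()).encode(), dtype=np.uint8))

    @classmethod
    def load_state(cls, path: str | Path) -> "SoftmaxSegmenter":
        data = np.load(path)
        obj = cls(**json.loads(bytes(data["hyper"]).decode()))
        obj.codes_ = data["codes"]
        obj.params_ = [data["W1"], data["b1"], data["W2"], data["b2"]]
        obj.val_scores_ = data["val_scores"].tolist()
        obj.best_val_score_ = max(obj.val_scores_) if obj.val_scores_ else 0.0
        return obj


BACKENDS: dict[str, type[SegmentationBackend]] = {
    NearestCentroidSegmenter.backend_id: NearestCentroidSegmenter,
    SoftmaxSegmenter.backend_id: SoftmaxSegmenter,
}


def make_backend(backend_id: str, **kwargs) -> SegmentationBackend:
    try:
        cls = BACKENDS[backend_id]
    except KeyError:
        raise KeyError(
            f"unknown backend {backend_id!r}; registered: {sorted(BACKENDS)}"
        ) from None
    return cls(**kwargs)
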