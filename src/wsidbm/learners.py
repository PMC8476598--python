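"""Patch learners: the desk-scale surrogate for the study's segmentation CNNs.

Every stage of the workflow trains the same kind of object: something that
maps a field-of-view-sized image context to per-class confidences. Here that
contract is realised with classical patch features — windowed color moments
plus band-pass texture energies — feeding a scikit-learn classifier head
(logistic regression by default, random forest as an alternative backend).

Two equivalent feature paths exist:

* ``patch_features`` computes the statistics on a single zero-padded patch
  raster (the literal patch contract);
* ``dense_feature_maps`` computes the same windowed statistics for every
  pixel of a whole slide at once with separable uniform filters, which is
  what makes per-pixel "semantic segmentation" inference cheap.

The two agree wherever the window does not cross the patch border (the dense
path sees real context beyond the patch; the patch path sees zero padding).

Determinism: fitting is a pure function of (features, labels, params, seed);
the logistic head is fitted in warm-start increments so a genuine
iteration-resolved training-loss log can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss

__all__ = [
    "FEATURE_NAMES",
    "PatchLearner",
    "TrainParams",
    "dense_feature_maps",
    "patch_features",
]

_LUMA = np.array([0.299, 0.587, 0.114])
_BANDS = ((1.0, 3.0), (3.0, 8.0))

FEATURE_NAMES = (
    "mean_r",
    "mean_g",
    "mean_b",
    "std_r",
    "std_g",
    "std_b",
    "grad_energy",
    "band_1_3",
    "band_3_8",
)


def _window_mean(x: np.ndarray, size: int) -> np.ndarray:
    return ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0)


def dense_feature_maps(rgb: np.ndarray, fov_px: int) -> np.ndarray:
    """Per-pixel windowed features of a whole RGB raster.

    Returns an (H, W, F) float array; feature order follows FEATURE_NAMES.
    The window is the field of view: each pixel's features summarize the
    fov_px × fov_px context centered on it (zero context outside the frame,
    matching zero-padded patches).
    """
    img = np.asarray(rgb, dtype=np.float64) / 255.0
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected H×W×3 raster, got {img.shape}")
    feats = []
    for c in range(3):
        ch = img[..., c]
        m = _window_mean(ch, fov_px)
        feats.append(m)
    for c in range(3):
        ch = img[..., c]
        m2 = _window_mean(ch * ch, fov_px)
        var = np.clip(m2 - feats[c] * feats[c], 0.0, None)
        feats.append(np.sqrt(var))
    lum = img @ _LUMA
    gr = np.hypot(ndimage.sobel(lum, axis=0, mode="nearest"), ndimage.sobel(lum, axis=1, mode="nearest")) / 8.0
    feats.append(_window_mean(gr * gr, fov_px))
    for s1, s2 in _BANDS:
        band = ndimage.gaussian_filter(lum, s1, mode="nearest") - ndimage.gaussian_filter(
            lum, s2, mode="nearest"
        )
        feats.append(_window_mean(band * band, fov_px))
    return np.stack(feats, axis=-1)


def patch_features(patch_rgb: np.ndarray, fov_px: int | None = None) -> np.ndarray:
    """Feature vector of one patch raster (window = the whole patch)."""
    patch_rgb = np.asarray(patch_rgb)
    if fov_px is None:
        fov_px = patch_rgb.shape[0]
    maps = dense_feature_maps(patch_rgb, fov_px)
    return maps[patch_rgb.shape[0] // 2, patch_rgb.shape[1] // 2]


def features_at(maps: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Sample dense feature maps at (row, col) centers."""
    centers = np.asarray(centers, dtype=int)
    return maps[centers[:, 0], centers[:, 1]]


@dataclass(frozen=True)
class TrainParams:
    """Learner-agnostic training-parameter table.

    backend: "logistic" (default) or "forest";
    max_iter: optimisation budget for the logistic head (warm-start
    increments of ``checkpoint`` iterations are recorded in the training
    log) or number of trees for the forest;
    C: inverse L2 regularisation strength of the logistic head;
    class_weight: passed through to scikit-learn (e.g. "balanced").
    """

    backend: str = "logistic"
    max_iter: int = 200
    checkpoint: int = 50
    C: float = 1.0
    class_weight: str | dict | None = None

    def to_dict(self) -> dict:
        return {
            "backend": self.backend,
            "max_iter": self.max_iter,
            "checkpoint": self.checkpoint,
            "C": self.C,
            "class_weight": self.class_weight,
        }


class SingleClassError(ValueError):
    """Training data containing only one class."""


@dataclass
class PatchLearner:
    """A fitted (or fittable) patch-to-confidence classifier.

    ``fit``/``predict_confidence`` operate on patch rasters per the learner
    contract; ``fit_features``/``confidence_from_features`` are the
    equivalent feature-space entry points the pipeline uses for dense
    inference. Confidence columns follow ``classes_`` order and sum to 1.
    """

    params: TrainParams = field(default_factory=TrainParams)
    classes_: tuple[str, ...] | None = None
    training_log: list[dict] = field(default_factory=list)
    _model: object | None = None
    _mu: np.ndarray | None = None
    _sd: np.ndarray | None = None

    # -- fitting -----------------------------------------------------------

    def fit_features(
        self, X: np.ndarray, y: Sequence[str], seed: int = 0
    ) -> "PatchLearner":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray([str(v) for v in y])
        classes = tuple(sorted(set(y)))
        if len(classes) < 2:
            raise SingleClassError(
                f"training data contains a single class {classes}; need at least two"
            )
        self.classes_ = classes
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(y))
        X, y = X[order], y[order]
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 1e-12, sd, 1.0)
        Xs = (X - self._mu) / self._sd
        self.training_log = []
        if self.params.backend == "logistic":
            model = LogisticRegression(
                C=self.params.C,
                max_iter=self.params.checkpoint,
                warm_start=True,
                class_weight=self.params.class_weight,
                solver="lbfgs",
            )
            done = 0
            while done < self.params.max_iter:
                model.max_iter = min(self.params.checkpoint, self.params.max_iter - done)
                model.fit(Xs, y)
                done += int(model.n_iter_[0])
                self.training_log.append(
                    {
                        "iterations": done,
                        "train_log_loss": float(
                            log_loss(y, model.predict_proba(Xs), labels=list(model.classes_))
                        ),
                    }
                )
                if model.n_iter_[0] < model.max_iter:
                    break  # converged
            self._model = model
        elif self.params.backend == "forest":
            model = RandomForestClassifier(
                n_estimators=self.params.max_iter,
                random_state=int(seed) & 0x7FFFFFFF,
                class_weight=self.params.class_weight,
                n_jobs=1,
            )
            model.fit(Xs, y)
            self.training_log.append(
                {
                    "iterations": self.params.max_iter,
                    "train_log_loss": float(
                        log_loss(y, model.predict_proba(Xs), labels=list(model.classes_))
                    ),
                }
            )
            self._model = model
        else:
            raise ValueError(f"unknown backend {self.params.backend!r}")
        return self

    def fit(
        self,
        patches: Sequence[np.ndarray],
        labels: Sequence[str],
        seed: int = 0,
    ) -> "PatchLearner":
        X = np.stack([patch_features(p) for p in patches])
        return self.fit_features(X, labels, seed=seed)

    # -- inference ---------------------------------------------------------

    @property
    def is_fitted(self) -> bool:
        return self._model is not None

    def _require_fitted(self) -> None:
        if not self.is_fitted:
            raise RuntimeError("learner is not fitted")

    def confidence_from_features(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) confidences in ``classes_`` order, rows sum to 1."""
        self._require_fitted()
        X = (np.asarray(X, dtype=np.float64) - self._mu) / self._sd
        proba = self._model.predict_proba(X)
        order = [list(self._model.classes_).index(c) for c in self.classes_]
        return proba[:, order]

    def predict_confidence(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        X = np.stack([patch_features(p) for p in patches])
        return self.confidence_from_features(X)

    def confidence_maps(self, rgb: np.ndarray, fov_px: int, stride_px: int = 1) -> np.ndarray:
        """Dense per-pixel confidence rasters, shape (H, W, n_classes).

        For ``stride_px`` > 1 predictions are made on a stride grid and
        rasterized by nearest-center assignment, the sliding-window analogue
        of coarse semantic-segmentation output.
        """
        self._require_fitted()
        maps = dense_feature_maps(rgb, fov_px)
        h, w, f = maps.shape
        if stride_px <= 1:
            conf = self.confidence_from_features(maps.reshape(-1, f))
            return conf.reshape(h, w, -1)
        rows = np.arange(stride_px // 2, h, stride_px)
        cols = np.arange(stride_px // 2, w, stride_px)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        conf = self.confidence_from_features(maps[rr.ravel(), cc.ravel()])
        grid = conf.reshape(len(rows), len(cols), -1)
        # nearest-center assignment: every pixel inherits its closest grid node
        ridx = np.clip(np.round((np.arange(h) - stride_px // 2) / stride_px), 0, len(rows) - 1).astype(int)
        cidx = np.clip(np.round((np.arange(w) - stride_px // 2) / stride_px), 0, len(cols) - 1).astype(int)
        return grid[np.ix_(ridx, cidx)]

    # -- persistence (logistic backend only) -------------------------------

    def to_dict(self) -> dict:
        self._require_fitted()
        if self.params.backend != "logistic":
            raise NotImplementedError("only the logistic backend round-trips to JSON")
        m = self._model
        return {
            "params": self.params.to_dict(),
            "classes": list(self.classes_),
            "model_classes": [str(c) for c in m.classes_],
            "coef": m.coef_.tolist(),
            "intercept": m.intercept_.tolist(),
            "mu": self._mu.tolist(),
            "sd": self._sd.tolist(),
            "training_log": self.training_log,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatchLearner":
        params = TrainParams(**d["params"])
        learner = cls(params=params)
        model = LogisticRegression(C=params.C, solver="lbfgs")
        model.classes_ = np.asarray(d["model_classes"])
        model.coef_ = np.asarray(d["coef"])
        model.intercept_ = np.asarray(d["intercept"])
        learner._model = model
        learner.classes_ = tuple(d["classes"])
        learner._mu = np.asarray(d["mu"])
        learner._sd = np.asarray(d["sd"])
        learner.training_log = list(d.get("training_log", []))
        return learner
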