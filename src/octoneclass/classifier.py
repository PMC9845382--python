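"""One-class SVM over pooled U-Net features.

The classifier is trained only on normal-tissue feature vectors.  Features
are standardized to zero mean / unit variance with training statistics; the
RBF kernel scale is set automatically by the median pairwise distance
heuristic on a (seeded, capped) subsample of the standardized training
rows; the outlier fraction maps to the nu parameter of the nu-formulation
one-class SVM, which upper-bounds the fraction of training points treated
as outliers.  The decision score is the signed distance-like value of the
decision function: positive means normal tissue, negative (or exactly
zero) means abnormal.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.svm import OneClassSVM

from .exceptions import (ParameterError, InputError, DataError,
                         ClassificationError, DegeneratePatchError)
from .features import FeatureGroup, FeatureVector, featurize_patch
from .phantom import OCTImage
from .segmentation import SegmenterModel, split_into_patches

logger = logging.getLogger(__name__)

AUTO = "auto"


@dataclass(frozen=True)
class OneClassSVMConfig:
    """RBF one-class SVM with automatic kernel scale and outlier fraction nu."""

    outlier_fraction: float = 0.08
    kernel_scale: float | str = AUTO   # AUTO -> median-distance heuristic
    feature_group: FeatureGroup = FeatureGroup.EPIDERMIS_AND_DERMIS
    scale_subsample: int = 1000        # rows used by the median heuristic
    scale_seed: int = 0

    def validate(self) -> None:
        if not (0 < self.outlier_fraction < 1):
            raise ParameterError("outlier_fraction must lie in (0, 1)")
        if self.kernel_scale != AUTO:
            if not (isinstance(self.kernel_scale, (int, float))
                    and self.kernel_scale > 0):
                raise ParameterError("explicit kernel_scale must be > 0")


@dataclass
class OneClassModel:
    """Fitted classifier: sklearn estimator + standardization + provenance."""

    svm: OneClassSVM
    mean: np.ndarray
    std: np.ndarray
    kernel_scale: float
    config: OneClassSVMConfig
    n_train: int

    @property
    def n_features(self) -> int:
        return self.mean.size

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "OneClassModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise InputError(f"{path} is not a OneClassModel archive")
        return model


def _median_heuristic(Z: np.ndarray, cap: int, seed: int) -> float:
    """Median pairwise Euclidean distance on a capped, seeded subsample."""
    if Z.shape[0] > cap:
        idx = np.random.default_rng(seed).choice(Z.shape[0], cap, replace=False)
        Z = Z[np.sort(idx)]
    d = pdist(Z)
    d = d[d > 0]
    if d.size == 0:
        return 1.0  # all points coincide; any positive scale is equivalent
    return float(np.median(d))


def train_ocsvm(features: np.ndarray,
                config: OneClassSVMConfig | None = None) -> OneClassModel:
    """Fit a one-class SVM on normal-tissue feature rows.

    ``features`` is (n_rows, n_features) with every row drawn from normal
    tissue.  Roughly a fraction nu of the training rows will score
    negative.  Deterministic: the only randomness is the seeded subsample
    of the kernel-scale heuristic.
    """
    config = config or OneClassSVMConfig()
    config.validate()
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise DataError("features must be a 2D (rows x features) matrix")
    if X.shape[0] < 10:
        raise DataError(f"need >= 10 training rows, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise DataError("features contain non-finite values")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Z = (X - mean) / std
    if config.kernel_scale == AUTO:
        s = _median_heuristic(Z, config.scale_subsample, config.scale_seed)
    else:
        s = float(config.kernel_scale)
    gamma = 1.0 / (2.0 * s * s)
    svm = OneClassSVM(kernel="rbf", nu=config.outlier_fraction, gamma=gamma,
                      tol=1e-6, shrinking=True)
    svm.fit(Z)
    return OneClassModel(svm=svm, mean=mean, std=std, kernel_scale=s,
                         config=config, n_train=X.shape[0])


def _check_vector(model: OneClassModel, x) -> np.ndarray:
    if isinstance(x, FeatureVector):
        if x.group != model.config.feature_group:
            raise InputError(
                f"model expects group {model.config.feature_group.value}, "
                f"got {x.group.value}")
        x = x.values
    v = np.asarray(x, dtype=np.float64).ravel()
    if v.size != model.n_features:
        raise InputError(
            f"model expects {model.n_features} features, got {v.size}")
    return v


def predict_score(model: OneClassModel, x) -> float:
    """Signed decision score: > 0 classifies as normal tissue, <= 0 abnormal."""
    v = _check_vector(model, x)
    z = (v - model.mean) / model.std
    return float(model.svm.decision_function(z[None, :])[0])


def predict_scores(model: OneClassModel, X: np.ndarray) -> np.ndarray:
    """Vectorised scores for a (rows x features) matrix."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise InputError(
            f"expected (n, {model.n_features}) matrix, got {X.shape}")
    Z = (X - model.mean) / model.std
    return model.svm.decision_function(Z)


def classify(model: OneClassModel, x) -> str:
    """"normal" iff the score is strictly positive (score 0 -> abnormal)."""
    return "normal" if predict_score(model, x) > 0 else "abnormal"


def classify_image(model: OneClassModel, segmenter: SegmenterModel,
                   image: OCTImage, patch_width: int = 32):
    """Average patch scores over an image and classify by the sign.

    The image is split into non-overlapping ``patch_width`` A-scan patches
    (a 256-A-scan image gives exactly 8); each patch is featurized with the
    model's feature group and scored; degenerate patches are skipped with a
    logged warning.  Returns ``(mean_score, verdict, per_patch_scores)``.
    """
    patches = split_into_patches(image, patch_width)
    scores = []
    for k, patch in enumerate(patches):
        try:
            fv = featurize_patch(segmenter, patch, model.config.feature_group)
        except DegeneratePatchError as err:
            logger.warning("patch %d at offset %d skipped: %s",
                           k, patch.lateral_offset, err)
            continue
        scores.append(predict_score(model, fv))
    if not scores:
        raise ClassificationError("every patch was degenerate; no score")
    mean_score = float(np.mean(scores))
    verdict = "normal" if mean_score > 0 else "abnormal"
    return mean_score, verdict, scores
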