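"""Annotation preprocessing: flatten, frame-average, PCA, Canny, one-hot.

Turns raw per-stimulus feature annotations into the train / validation / test
predictor matrices consumed by every encoding model.  High-dimensional
features (pixel maps) are reduced to 100 principal components fitted on the
training split only; low-dimensional features (the 14x2 skeleton, 28
predictors, and the length-6 action one-hot) keep their native dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import canny as _skimage_canny
from sklearn.decomposition import PCA as _SkPCA

from .simulate import AnnotationSet

__all__ = [
    "PcaModel",
    "FeatureDesignMatrices",
    "flatten_annotation",
    "average_frames",
    "fit_pca",
    "apply_pca",
    "canny_edges",
    "encode_action",
    "prepare_design_matrices",
]

#: Features with native dimension above this get PCA'd.
PCA_THRESHOLD = 100


@dataclass
class PcaModel:
    """Centered linear PCA fitted on the training split.

    Component sign convention: the largest-|loading| entry of every component
    is positive, so stored models are comparable across runs.
    """

    loadings: np.ndarray  # (n_predictors, n_components), orthonormal columns
    mean: np.ndarray  # (n_predictors,)
    explained_variance: np.ndarray  # (n_components,), non-increasing

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class FeatureDesignMatrices:
    """Per-feature {train, validation, test} predictor matrices."""

    matrices: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    pca_models: dict[str, PcaModel] = field(default_factory=dict)

    def features(self) -> list[str]:
        return list(self.matrices)

    def __getitem__(self, feature: str) -> dict[str, np.ndarray]:
        return self.matrices[feature]


def flatten_annotation(array: np.ndarray) -> np.ndarray:
    """Row-major flatten of one stimulus annotation (RGB fastest-varying)."""
    array = np.asarray(array)
    if array.ndim == 0:
        raise ValueError("scalar is not a recognized annotation shape")
    return array.reshape(-1)


def average_frames(per_frame_arrays: np.ndarray) -> np.ndarray:
    """Element-wise mean over the leading frame axis."""
    arr = np.asarray(per_frame_arrays)
    if arr.ndim < 1 or arr.shape[0] < 1:
        raise ValueError("need at least one frame")
    return arr.mean(axis=0)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


def fit_pca(train_matrix: np.ndarray, n_components: int) -> PcaModel:
    """Fit centered linear PCA (no variance scaling) on the training rows."""
    X = np.asarray(train_matrix, dtype=float)
    n, d = X.shape
    if n_components > min(n - 1, d):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_predictors)="
            f"{min(n - 1, d)}"
        )
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant training matrix has no principal components")
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    loadings = _fix_signs(pca.components_.T)
    return PcaModel(
        loadings=loadings,
        mean=pca.mean_,
        explained_variance=pca.explained_variance_,
    )


def apply_pca(model: PcaModel, matrix: np.ndarray) -> np.ndarray:
    """Project rows onto the fitted components: (X - train_mean) @ loadings."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} predictors, model expects {model.loadings.shape[0]}"
        )
    return (X - model.mean) @ model.loadings


def canny_edges(
    grayscale_image: np.ndarray,
    low_thresh: float = 0.1,
    high_thresh: float = 0.3,
    smoothing_sigma: float = 1.0,
) -> np.ndarray:
    """Binary Canny edge map of a 2-D image.

    Thresholds are fractions of the maximum Gaussian-smoothed gradient
    magnitude, so the operating point is invariant to the image's intensity
    scale.  Returns a boolean H x W array (all False for a constant image).
    """
    img = np.asarray(grayscale_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("canny_edges expects a 2-D grayscale image")
    if not 0 <= low_thresh <= high_thresh:
        raise ValueError("need 0 <= low_thresh <= high_thresh")
    gx = ndimage.gaussian_filter(img, smoothing_sigma, order=(0, 1), mode="nearest")
    gy = ndimage.gaussian_filter(img, smoothing_sigma, order=(1, 0), mode="nearest")
    gmax = float(np.hypot(gx, gy).max())
    if gmax == 0:
        return np.zeros(img.shape, dtype=bool)
    return _skimage_canny(
        img,
        sigma=smoothing_sigma,
        low_threshold=low_thresh * gmax,
        high_threshold=high_thresh * gmax,
    )


def encode_action(action_label: int, n_actions: int = 6) -> np.ndarray:
    """One-hot vector for an action label."""
    if not 0 <= action_label < n_actions:
        raise ValueError(f"action label {action_label} outside [0, {n_actions})")
    vec = np.zeros(n_actions)
    vec[action_label] = 1.0
    return vec


def _stacked_flat(annotations: AnnotationSet, feature: str, mode: str) -> np.ndarray:
    arr = annotations.arrays[feature]
    if mode == "video":
        if annotations.n_frames is None:
            raise ValueError("video mode requires annotations with a frame axis")
        arr = arr.mean(axis=1)
    elif annotations.n_frames is not None:
        # image-mode request on video annotations: average frames first so the
        # two paths agree (averaging and flattening commute)
        arr = arr.mean(axis=1)
    return arr.reshape(len(arr), -1)


def prepare_design_matrices(
    annotations: AnnotationSet,
    design: pd.DataFrame,
    mode: str = "image",
    n_components: int = 100,
) -> FeatureDesignMatrices:
    """Flatten (and frame-average), PCA the high-dimensional features, split.

    PCA (``n_components``, default 100) is fitted on the training stimuli only
    and applied to all splits; features whose native dimension is at most
    ``n_components`` (skeleton: 28, action: 6) keep their native predictors.
    """
    if mode not in ("image", "video"):
        raise ValueError(f"mode must be 'image' or 'video', got {mode!r}")
    splits = {"train", "test", "validation"}
    present = set(design["split"].unique())
    if "train" not in present:
        raise ValueError("design has no training split")

    sid_to_row = {int(s): i for i, s in enumerate(annotations.stimulus_ids)}
    split_rows = {
        s: np.array(
            [sid_to_row[int(i)] for i in design.loc[design["split"] == s, "stimulus_id"]],
            dtype=int,
        )
        for s in splits
    }

    out = FeatureDesignMatrices()
    for feature in annotations.features():
        flat = _stacked_flat(annotations, feature, mode)
        train = flat[split_rows["train"]]
        if flat.shape[1] > n_components:
            # desk-scale designs may have fewer training stimuli than the
            # requested component count; PCA rank is bounded by n_train - 1
            model = fit_pca(train, min(n_components, len(train) - 1))
            out.pca_models[feature] = model
            project = lambda m: apply_pca(model, m)  # noqa: E731
        else:
            project = lambda m: m  # noqa: E731
        out.matrices[feature] = {
            s: project(flat[split_rows[s]]) for s in ("train", "validation", "test")
            if len(split_rows[s])
        }
    return out
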