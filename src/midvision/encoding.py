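"""Linearized encoding models: ridge regression from feature annotations to
whitened EEG responses (per channel x timepoint) or network layer activations
(per principal component x layer).

The ridge solution is computed in closed form on centered data,

    beta = (X^T X + lambda I)^(-1) X^T Y,

evaluated through an SVD of the (centered) training predictors so the whole
regularization grid reuses one factorization.  When predictors outnumber
samples this is algebraically the dual (Gram) form.  The penalty lambda is
selected per feature on the validation split as the grid value maximizing the
mean Pearson correlation between predicted and observed responses; it is
never fitted on test data.  Test accuracy is the Pearson correlation, across
test stimuli, between predictions and repetition-averaged observed responses,
for every (channel, timepoint) or (component, layer) cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from ._rng import substream
from .annotations import FeatureDesignMatrices, _fix_signs
from .simulate import EpochedEEG

__all__ = [
    "EncodingConfig",
    "RidgeModel",
    "EncodingAccuracy",
    "LayerActivationSet",
    "NoiseCeiling",
    "default_lambda_grid",
    "fit_ridge",
    "predict_ridge",
    "select_lambda",
    "encode_eeg",
    "prepare_layer_activations",
    "encode_layers",
    "weighted_mean_correlation",
    "noise_ceiling",
    "pearson_columns",
]


def default_lambda_grid() -> np.ndarray:
    """30 logarithmically spaced penalties from 1e-5 to 1e15."""
    return np.logspace(-5, 15, 30)


@dataclass(frozen=True)
class EncodingConfig:
    """Grid and policies of the encoding fits."""

    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    include_ols: bool = False  # adds lambda = 0 (the OLS reference) to the grid
    average_test_repetitions: bool = True

    def grid(self) -> np.ndarray:
        g = np.asarray(self.lambda_grid, dtype=float)
        if g.size == 0:
            raise ValueError("empty lambda grid")
        if np.any(g <= 0):
            raise ValueError("lambda grid values must be > 0")
        if np.any(np.diff(g) < 0):
            raise ValueError("lambda grid must be sorted ascending")
        if self.include_ols:
            g = np.r_[0.0, g]
        return g


@dataclass
class RidgeModel:
    """Closed-form multivariate ridge fit."""

    weights: np.ndarray  # (n_predictors, n_targets)
    intercept: np.ndarray  # (n_targets,)
    lam: float


@dataclass
class EncodingAccuracy:
    """Per-feature encoding accuracy surfaces and averaged curves."""

    surfaces: dict[str, np.ndarray]  # feature -> (n_channels, n_timepoints) r
    timecourses: dict[str, np.ndarray]  # feature -> channel-averaged r(t)
    selected_lambda: dict[str, float]
    time_ms: np.ndarray


@dataclass
class LayerActivationSet:
    """Dimensionality-reduced layer activations with variance weights."""

    scores: dict[str, dict[str, np.ndarray]]  # layer -> split -> (stimuli x comps)
    explained_variance: dict[str, np.ndarray]  # layer -> per-component variance
    layer_labels: list[str] = field(default_factory=list)


@dataclass
class NoiseCeiling:
    """Split-half (lower) and half-vs-all (upper) correlation bounds."""

    lower: np.ndarray  # (n_channels, n_timepoints)
    upper: np.ndarray
    n_repetitions: int


class _RidgeSolver:
    """One SVD of the centered predictors, reused across the lambda grid."""

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("non-finite values in regression inputs")
        self.x_mean = X.mean(axis=0)
        self.y_mean = Y.mean(axis=0)
        Xc = X - self.x_mean
        self.U, self.s, self.Vt = np.linalg.svd(Xc, full_matrices=False)
        self.UtY = self.U.T @ (Y - self.y_mean)

    def weights(self, lam: float, rcond: float = 1e-12) -> np.ndarray:
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        if lam == 0:
            # pseudoinverse limit (OLS on the row space)
            d = np.where(self.s > rcond * self.s.max(), 1.0 / self.s, 0.0)
        else:
            d = self.s / (self.s**2 + lam)
        return (self.Vt.T * d) @ self.UtY

    def model(self, lam: float) -> RidgeModel:
        w = self.weights(lam)
        return RidgeModel(weights=w, intercept=self.y_mean - self.x_mean @ w, lam=lam)


def fit_ridge(X_train: np.ndarray, Y_train: np.ndarray, lam: float) -> RidgeModel:
    """Fit multivariate ridge on centered data with penalty ``lam``."""
    return _RidgeSolver(X_train, Y_train).model(lam)


def predict_ridge(model: RidgeModel, X: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) @ model.weights + model.intercept


def pearson_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two equally shaped matrices.

    Constant columns (undefined correlation) yield r = 0 with a warning.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("shape mismatch")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    denom = np.sqrt((Ac**2).sum(axis=0) * (Bc**2).sum(axis=0))
    bad = denom == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} constant column(s): correlation set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    denom = np.where(bad, 1.0, denom)
    r = (Ac * Bc).sum(axis=0) / denom
    return np.where(bad, 0.0, r)


def select_lambda(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Pick the grid value maximizing mean validation correlation.

    Returns ``(lambda_star, mean_r_per_grid_value)``; ties resolve to the
    smaller penalty.
    """
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    solver = _RidgeSolver(X_train, Y_train)
    scores = np.empty(grid.size)
    for i, lam in enumerate(grid):
        model = solver.model(float(lam))
        scores[i] = pearson_columns(predict_ridge(model, X_val), Y_val).mean()
    best = int(np.argmax(scores))  # argmax returns the first (smallest-lambda) max
    return float(grid[best]), scores


def _split_mean_responses(
    epochs: EpochedEEG, average: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stimulus responses (sorted by stimulus id).

    Averages over repetitions when ``average`` is true, otherwise keeps each
    stimulus's first repetition.  Returns
    (stimulus_ids, (n_stimuli, n_channels, n_timepoints)).
    """
    table = epochs.trial_table
    codes, uniques = pd.factorize(table["stimulus_id"].to_numpy(), sort=True)
    n_stim = len(uniques)
    if not average:
        first = np.full(n_stim, -1, dtype=int)
        for row, code in enumerate(codes):
            if first[code] < 0:
                first[code] = row
        return uniques, epochs.data[first]
    sums = np.zeros((n_stim, *epochs.data.shape[1:]))
    np.add.at(sums, codes, epochs.data)
    return uniques, sums / np.bincount(codes)[:, None, None]


def encode_eeg(
    design_matrices: FeatureDesignMatrices,
    epochs_train: EpochedEEG,
    epochs_val: EpochedEEG,
    epochs_test: EpochedEEG,
    config: EncodingConfig | None = None,
) -> EncodingAccuracy:
    """Fit per-feature encoding models of the (whitened) EEG responses.

    One lambda per feature is selected on the validation split (shared across
    channels and timepoints); the final model is fitted on the training split
    and evaluated per (channel, timepoint) by correlating predictions with
    repetition-averaged test responses across test stimuli.
    """
    config = config or EncodingConfig()
    grid = config.grid()

    _, y_train = _split_mean_responses(epochs_train)
    _, y_val = _split_mean_responses(epochs_val)
    _, y_test = _split_mean_responses(epochs_test, average=config.average_test_repetitions)

    n_c, n_t = y_train.shape[1], y_train.shape[2]
    Ytr = y_train.reshape(len(y_train), -1)
    Yva = y_val.reshape(len(y_val), -1)
    Yte = y_test.reshape(len(y_test), -1)

    surfaces, curves, lambdas = {}, {}, {}
    for feature in design_matrices.features():
        mats = design_matrices[feature]
        for split in ("train", "validation", "test"):
            if split not in mats:
                raise ValueError(f"feature {feature!r} missing split {split!r}")
        lam, _ = select_lambda(mats["train"], Ytr, mats["validation"], Yva, grid)
        model = fit_ridge(mats["train"], Ytr, lam)
        r = pearson_columns(predict_ridge(model, mats["test"]), Yte).reshape(n_c, n_t)
        surfaces[feature] = r
        curves[feature] = r.mean(axis=0)
        lambdas[feature] = lam
    return EncodingAccuracy(
        surfaces=surfaces,
        timecourses=curves,
        selected_lambda=lambdas,
        time_ms=epochs_train.time_ms.copy(),
    )


def prepare_layer_activations(
    raw_layers: dict[str, np.ndarray],
    design: pd.DataFrame,
    variance_threshold: float = 0.90,
) -> LayerActivationSet:
    """Flatten and PCA-reduce layer activations to >= ``variance_threshold``
    of the training-set variance, per layer.

    ``raw_layers`` maps layer label -> (n_stimuli, ...) activation arrays
    aligned with ``design`` rows (any provider of such matrices is accepted).
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    split_rows = {
        s: (design["split"] == s).to_numpy().nonzero()[0]
        for s in ("train", "validation", "test")
    }
    scores: dict[str, dict[str, np.ndarray]] = {}
    evs: dict[str, np.ndarray] = {}
    for label, arr in raw_layers.items():
        flat = np.asarray(arr, dtype=float).reshape(len(arr), -1)
        train = flat[split_rows["train"]]
        pca = _SkPCA(n_components=variance_threshold, svd_solver="full")
        pca.fit(train)
        loadings = _fix_signs(pca.components_.T)
        project = lambda m: (m - pca.mean_) @ loadings  # noqa: E731
        scores[label] = {
            s: project(flat[rows]) for s, rows in split_rows.items() if len(rows)
        }
        evs[label] = pca.explained_variance_
    return LayerActivationSet(
        scores=scores, explained_variance=evs, layer_labels=list(raw_layers)
    )


def weighted_mean_correlation(correlations: np.ndarray, weights: np.ndarray) -> float:
    """Variance-weighted average of component correlations: sum(w r) / sum(w)."""
    r = np.asarray(correlations, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.shape != w.shape:
        raise ValueError("weights and correlations must align")
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    return float((w * r).sum() / w.sum())


def encode_layers(
    design_matrices: FeatureDesignMatrices,
    activations: LayerActivationSet,
    config: EncodingConfig | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, dict[str, float]]]:
    """Per-feature layer curves of variance-weighted encoding accuracy.

    For every (feature, layer): lambda selected on validation, ridge fitted on
    train, component-wise test correlations combined with the components'
    explained variances as weights.  Returns ``(curves, lambdas)`` where
    ``curves[feature]`` follows ``activations.layer_labels`` order.
    """
    config = config or EncodingConfig()
    grid = config.grid()
    curves: dict[str, np.ndarray] = {}
    lambdas: dict[str, dict[str, float]] = {}
    for feature in design_matrices.features():
        mats = design_matrices[feature]
        per_layer = np.empty(len(activations.layer_labels))
        lambdas[feature] = {}
        for li, label in enumerate(activations.layer_labels):
            sc = activations.scores[label]
            if label not in activations.explained_variance:
                raise ValueError(f"layer {label!r} missing explained-variance weights")
            lam, _ = select_lambda(
                mats["train"], sc["train"], mats["validation"], sc["validation"], grid
            )
            model = fit_ridge(mats["train"], sc["train"], lam)
            r = pearson_columns(predict_ridge(model, mats["test"]), sc["test"])
            per_layer[li] = weighted_mean_correlation(
                r, activations.explained_variance[label]
            )
            lambdas[feature][label] = lam
        curves[feature] = per_layer
    return curves, lambdas


def noise_ceiling(
    test_epochs: EpochedEEG, n_reps: int = 100, seed: int = 0
) -> NoiseCeiling:
    """Split-half noise ceiling of the test-split responses.

    Per repetition: trials of every stimulus are randomly split into two equal
    halves; per (channel, timepoint) the Pearson correlation across stimuli
    between the two half means gives the lower bound, and between one half
    mean and the all-trial mean the upper bound.  Bounds are averaged over
    ``n_reps`` random groupings.
    """
    table = test_epochs.trial_table
    counts = table.groupby("stimulus_id")["trial"].count()
    if counts.nunique() != 1:
        raise ValueError("unequal repetition counts across stimuli")
    n_rep = int(counts.iloc[0])
    if n_rep < 2 or n_rep % 2:
        raise ValueError("need an even repetition count >= 2")
    order = np.argsort(table["stimulus_id"].to_numpy(), kind="stable")
    data = test_epochs.data[order]
    n_stim = len(counts)
    cells = data.reshape(n_stim, n_rep, *data.shape[1:])
    full_mean = cells.mean(axis=1).reshape(n_stim, -1)

    rng = substream(seed, "noise-ceiling")
    n_cols = full_mean.shape[1]
    lower = np.zeros(n_cols)
    upper = np.zeros(n_cols)
    for _ in range(n_reps):
        perm = np.stack([rng.permutation(n_rep) for _ in range(n_stim)])
        half = n_rep // 2
        idx1 = perm[:, :half]
        g1 = np.take_along_axis(cells, idx1[:, :, None, None], axis=1).mean(axis=1)
        g2 = np.take_along_axis(cells, perm[:, half:][:, :, None, None], axis=1).mean(axis=1)
        g1 = g1.reshape(n_stim, -1)
        g2 = g2.reshape(n_stim, -1)
        lower += pearson_columns(g1, g2)
        upper += pearson_columns(g1, full_mean)
    shape = test_epochs.data.shape[1:]
    return NoiseCeiling(
        lower=(lower / n_reps).reshape(shape),
        upper=(upper / n_reps).reshape(shape),
        n_repetitions=n_reps,
    )
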