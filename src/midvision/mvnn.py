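"""Multivariate noise normalization (MVNN) of epoched trials.

Noise is defined as the deviation of each repetition from the mean response
of its stimulus at each timepoint ("stimulus-evoked activity is constant
across repetitions" made operational).  The channel noise covariance is
estimated from these residuals with Ledoit-Wolf shrinkage and its inverse
matrix square root is applied to every trial of every split, decorrelating
the noise and bringing it to unit variance.

Shrinkage modes
---------------
``pooled`` (default): residuals from all (stimulus, timepoint) cells are
pooled into a single Ledoit-Wolf estimate.  This is algebraically the average
of the per-cell sample covariances, shrunk once with the full pooled sample
size, so the shrinkage intensity is negligible whenever many cells exist and
whitening genuinely decorrelates the channels.

``per_cell``: Ledoit-Wolf is applied within every (stimulus, timepoint) cell
and the shrunk estimates are averaged.  With very few repetitions per cell
the per-cell shrinkage is heavy and the average is pulled strongly toward a
scaled identity; the mode is kept for comparison because the *pattern* of
off-diagonal covariance it recovers is unaffected by shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf as _sk_ledoit_wolf

from .simulate import EpochedEEG

__all__ = [
    "NoiseCovariance",
    "baseline_correct",
    "select_channels",
    "estimate_noise_covariance",
    "inverse_sqrt",
    "whiten",
]


@dataclass
class NoiseCovariance:
    """Shrinkage-estimated channel noise covariance with estimator metadata."""

    matrix: np.ndarray  # (n_channels, n_channels), symmetric PD after shrinkage
    shrinkage: float
    n_cells: int  # contributing (stimulus, timepoint) cells
    mode: str = "pooled"


def baseline_correct(epochs: EpochedEEG, window_ms: tuple[float, float] = (-100.0, 0.0)) -> EpochedEEG:
    """Subtract the per-trial, per-channel mean over a pre-stimulus window.

    The window is ``[start, end)`` in ms and must end at or before stimulus
    onset (0 ms).
    """
    start, end = window_ms
    if end > 0:
        raise ValueError("baseline window must end at or before stimulus onset")
    mask = (epochs.time_ms >= start) & (epochs.time_ms < end)
    if not mask.any():
        raise ValueError("baseline window contains no timepoints")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def select_channels(epochs: EpochedEEG, labels: list[str]) -> EpochedEEG:
    """Keep only the listed channels (e.g. a posterior subset), in list order."""
    missing = [c for c in labels if c not in epochs.channels]
    if missing:
        raise ValueError(f"unknown channels: {missing}")
    idx = [epochs.channels.index(c) for c in labels]
    return EpochedEEG(
        data=epochs.data[:, idx],
        time_ms=epochs.time_ms.copy(),
        trial_table=epochs.trial_table.copy(),
        channels=list(labels),
    )


def _residuals(epochs: EpochedEEG) -> np.ndarray:
    """Across-repetition residuals, stacked over (stimulus, timepoint) cells.

    Returns an (n_trials * n_timepoints, n_channels) array where each trial's
    channel vector at each timepoint has the mean over that stimulus's
    repetitions at that timepoint removed.
    """
    table = epochs.trial_table
    counts = table.groupby("stimulus_id")["trial"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"stimuli with fewer than 2 repetitions: {bad[:5]}")
    codes, _ = pd.factorize(table["stimulus_id"].to_numpy())
    n_stim = codes.max() + 1
    sums = np.zeros((n_stim, *epochs.data.shape[1:]))
    np.add.at(sums, codes, epochs.data)
    means = sums / np.bincount(codes)[:, None, None]
    resid = epochs.data - means[codes]
    # (trials, channels, timepoints) -> (trials * timepoints, channels)
    return resid.transpose(0, 2, 1).reshape(-1, epochs.data.shape[1])


def _ledoit_wolf_batch(resid_cells: np.ndarray) -> tuple[np.ndarray, float]:
    """Vectorized per-cell Ledoit-Wolf over (cells, reps, channels) residuals.

    Matches ``sklearn.covariance.ledoit_wolf(assume_centered=True)`` applied
    to each cell.  Returns the mean of the shrunk per-cell estimates and the
    mean shrinkage intensity.
    """
    m, n, p = resid_cells.shape
    S = np.einsum("cij,cik->cjk", resid_cells, resid_cells) / n
    mu = np.trace(S, axis1=1, axis2=2) / p
    eye = np.eye(p)
    delta2 = ((S - mu[:, None, None] * eye) ** 2).sum(axis=(1, 2)) / p
    norms4 = (resid_cells**2).sum(axis=2) ** 2  # ||x_i||^4 per rep
    frob2 = (S**2).sum(axis=(1, 2))
    beta2 = (norms4.sum(axis=1) - n * frob2) / (n**2 * p)
    beta2 = np.minimum(beta2, delta2)
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(delta2 > 0, beta2 / delta2, 0.0)
    shrunk = (
        (1 - shrink)[:, None, None] * S
        + (shrink * mu)[:, None, None] * eye
    )
    return shrunk.mean(axis=0), float(shrink.mean())


def estimate_noise_covariance(
    epochs: EpochedEEG, split: str = "train", mode: str = "pooled"
) -> NoiseCovariance:
    """Estimate the channel noise covariance from repeated trials of a split."""
    sub = epochs.select_split(split)
    if sub.data.shape[0] == 0:
        raise ValueError(f"split {split!r} contains no trials")
    n_timepoints = sub.data.shape[2]
    if mode == "pooled":
        resid = _residuals(sub)
        cov, shrink = _sk_ledoit_wolf(resid, assume_centered=True)
        n_cells = sub.trial_table["stimulus_id"].nunique() * n_timepoints
    elif mode == "per_cell":
        table = sub.trial_table
        counts = table.groupby("stimulus_id")["trial"].count()
        if counts.nunique() != 1:
            raise ValueError("per_cell mode requires equal repetition counts")
        if int(counts.iloc[0]) < 2:
            raise ValueError("need >= 2 repetitions per stimulus")
        n_rep = int(counts.iloc[0])
        order = np.argsort(table["stimulus_id"].to_numpy(), kind="stable")
        data = sub.data[order]
        n_stim = len(counts)
        cells = data.reshape(n_stim, n_rep, data.shape[1], n_timepoints)
        resid = cells - cells.mean(axis=1, keepdims=True)
        # -> (n_stim * n_timepoints, n_rep, n_channels)
        resid = resid.transpose(0, 3, 1, 2).reshape(-1, n_rep, data.shape[1])
        cov, shrink = _ledoit_wolf_batch(resid)
        n_cells = n_stim * n_timepoints
    else:
        raise ValueError(f"unknown shrinkage mode {mode!r}")
    cov = (cov + cov.T) / 2
    return NoiseCovariance(matrix=cov, shrinkage=shrink, n_cells=int(n_cells), mode=mode)


def inverse_sqrt(matrix: np.ndarray, eig_floor: float = 1e-12) -> np.ndarray:
    """Symmetric inverse matrix square root via eigendecomposition.

    For SPD ``Sigma`` returns the symmetric ``M`` with ``M @ Sigma @ M = I``.
    Eigenvalues at or below ``eig_floor * max_eigenvalue`` raise.
    """
    sigma = np.asarray(matrix, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(sigma, sigma.T, atol=1e-10 * max(1.0, np.abs(sigma).max())):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() <= eig_floor * vals.max():
        raise np.linalg.LinAlgError("matrix is not positive-definite within tolerance")
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def whiten(epochs: EpochedEEG, noise_cov: NoiseCovariance) -> EpochedEEG:
    """Left-multiply every (trial, timepoint) channel vector by the whitener.

    The whitening matrix is estimated once (on the training split) and the
    same matrix is applied to all splits contained in *epochs*.
    """
    if noise_cov.matrix.shape[0] != epochs.data.shape[1]:
        raise ValueError("channel count mismatch between data and covariance")
    w = inverse_sqrt(noise_cov.matrix)
    out = epochs.copy()
    out.data = np.einsum("dc,nct->ndt", w, epochs.data)
    return out
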