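"""Time-resolved pairwise scene decoding from pseudotrials.

For every unordered pair of scenes and every timepoint, a linear support
vector machine is trained on channel patterns of pseudotrials (averages of
randomly binned repetitions, default 30 repetitions -> 6 pseudotrials of bin
5) under stratified sixfold cross-validation.  The mean over the lower
triangle of the pairwise accuracy matrix gives one decoding time course per
subject; chance level is 50%.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

from ._rng import substream
from .simulate import EpochedEEG

__all__ = [
    "make_pseudotrials",
    "pairwise_decode_timepoint",
    "decode_subject",
    "difference_timecourse",
    "DecodingTimecourse",
]

CHANCE = 50.0


@dataclass
class DecodingTimecourse:
    """Per-subject pairwise decoding accuracy (%) over time."""

    accuracy: np.ndarray  # (n_timepoints,), in percent
    time_ms: np.ndarray
    n_pairs: int
    chance: float = CHANCE


def make_pseudotrials(
    repetitions: np.ndarray, bin_size: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Average randomly formed bins of repetitions into pseudotrials.

    ``repetitions`` has shape (n_reps, ...); the repetition count must divide
    exactly into bins of ``bin_size``.  Each repetition is used exactly once.
    """
    reps = np.asarray(repetitions)
    n = reps.shape[0]
    if bin_size < 1 or n % bin_size:
        raise ValueError(f"{n} repetitions not divisible into bins of {bin_size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n)
    return reps[order].reshape(n // bin_size, bin_size, *reps.shape[1:]).mean(axis=1)


def pairwise_decode_timepoint(
    pseudotrials_a: np.ndarray,
    pseudotrials_b: np.ndarray,
    n_folds: int = 6,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
) -> float:
    """Cross-validated linear-SVM accuracy (%) for one scene pair.

    Both classes contribute equally many pseudotrials (channel patterns at a
    single timepoint); stratified folds hold out an equal number per class
    (one per class per fold at the defaults: 6 + 6 pseudotrials, 6 folds).
    """
    a = np.atleast_2d(np.asarray(pseudotrials_a, dtype=float))
    b = np.atleast_2d(np.asarray(pseudotrials_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("classes must have equal pseudotrial counts")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pseudotrials per class")
    if n % n_folds:
        raise ValueError(f"{n} pseudotrials per class not divisible into {n_folds} folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fold_a = rng.permutation(n) % n_folds
    fold_b = rng.permutation(n) % n_folds

    X = np.vstack([a, b])
    y = np.r_[np.zeros(n), np.ones(n)]
    folds = np.r_[fold_a, fold_b]
    accs = []
    for k in range(n_folds):
        test = folds == k
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[~test], y[~test])
        accs.append((clf.predict(X[test]) == y[test]).mean())
    return 100.0 * float(np.mean(accs))


def _split_pseudotrials(
    epochs: EpochedEEG, bin_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudotrials per stimulus: (n_stimuli, n_pseudo, channels, timepoints)."""
    table = epochs.trial_table
    counts = table.groupby("stimulus_id")["trial"].count()
    if counts.nunique() != 1:
        raise ValueError("unequal repetition counts across stimuli")
    stim_ids = np.sort(counts.index.to_numpy())
    pseudos = []
    for sid in stim_ids:
        rows = (table["stimulus_id"] == sid).to_numpy()
        pseudos.append(make_pseudotrials(epochs.data[rows], bin_size, rng))
    return stim_ids, np.stack(pseudos)


def decode_subject(
    epochs: EpochedEEG,
    bin_size: int = 5,
    n_folds: int = 6,
    n_repeats: int = 6,
    seed: int = 0,
    timepoints: np.ndarray | None = None,
) -> DecodingTimecourse:
    """Decode every scene pair at every timepoint for one subject.

    The full analysis is repeated ``n_repeats`` times with freshly
    re-partitioned pseudotrial bins and averaged.  Pairs are enumerated in
    ascending stimulus-id order; the returned accuracy is the mean over the
    lower triangle of the pairwise matrix.  ``timepoints`` restricts the
    analysis to a subset of time indices (full axis by default); accuracy is
    NaN outside the subset.
    """
    rng = substream(seed, "decoding")
    n_t = epochs.data.shape[2]
    t_idx = np.arange(n_t) if timepoints is None else np.asarray(timepoints, dtype=int)
    acc = np.full(n_t, np.nan)
    acc_sum = np.zeros(len(t_idx))

    stim_ids = np.sort(epochs.trial_table["stimulus_id"].unique())
    if len(stim_ids) < 2:
        raise ValueError("need at least 2 stimuli for pairwise decoding")
    pairs = list(combinations(range(len(stim_ids)), 2))

    for _ in range(n_repeats):
        _, pseudo = _split_pseudotrials(epochs, bin_size, rng)
        for ti, t in enumerate(t_idx):
            pair_accs = [
                pairwise_decode_timepoint(pseudo[i, :, :, t], pseudo[j, :, :, t], n_folds, rng)
                for i, j in pairs
            ]
            acc_sum[ti] += np.mean(pair_accs)
    acc[t_idx] = acc_sum / n_repeats
    return DecodingTimecourse(
        accuracy=acc, time_ms=epochs.time_ms.copy(), n_pairs=len(pairs)
    )


def difference_timecourse(group_a_mean: np.ndarray, group_b_mean: np.ndarray) -> np.ndarray:
    """Element-wise difference of two group-mean time courses (A - B)."""
    a = np.asarray(group_a_mean, dtype=float)
    b = np.asarray(group_b_mean, dtype=float)
    if a.shape != b.shape:
        raise ValueError("time courses must share the same time axis")
    return a - b
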