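"""Reference evaluation experiments on the synthetic study conditions.

Each function here reruns one verifiable property of the pipeline from
scratch — design arithmetic, whitening quality, planted-latency and
planted-layer recovery, permutation-test calibration, closed-form oracle
equivalences, and false-positive protection under shuffled annotations — and
returns plain numbers.  The functions are shared by the test suite and the
acceptance script so both always measure the same quantities the same way.

Problem sizes: recovery and whitening checks run at the full default
experiment size (1440 stimuli, 5400/5400/900 trials).  The null-protection
check simulates a scaled-down multi-subject group (5 rooms, 5 subjects,
5/6/5 repetitions) so that 20 independent replicates stay desk-scale; see
docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import encoding, inference, mvnn
from ._rng import subseed, substream
from .annotations import flatten_annotation, prepare_design_matrices
from .design import SplitSpec, make_design, sequence_presentation_seconds, split_sizes
from .simulate import (
    ForwardModelSpec,
    LayerModelSpec,
    default_features,
    simulate_annotations,
    simulate_eeg,
    simulate_layer_activations,
)

__all__ = [
    "design_arithmetic",
    "simulate_default_subject",
    "whitening_max_offdiagonal",
    "latency_recovery_spearman",
    "layer_recovery_matches",
    "sign_test_rejection_rate",
    "swap_test_rejection_rate",
    "ridge_ols_max_deviation",
    "inverse_sqrt_identity_error",
    "weighted_correlation_example",
    "null_protection_clean_fraction",
]


def design_arithmetic(seed: int = 0) -> dict[str, float]:
    """Exact counts implied by the factorial design and epoch geometry."""
    design = make_design(seed=seed)
    sizes = split_sizes(design)
    spec = ForwardModelSpec(seed=seed)
    ann = simulate_annotations(design, seed=seed)
    trial_counts = {s: sizes[s] * spec.reps[s] for s in sizes}
    n_pseudo = spec.reps["test"] // 5  # bins of 5 repetitions
    return {
        "n_stimuli": float(len(design)),
        "n_train_stimuli": float(sizes["train"]),
        "n_test_stimuli": float(sizes["test"]),
        "n_validation_stimuli": float(sizes["validation"]),
        "n_train_trials": float(trial_counts["train"]),
        "n_test_trials": float(trial_counts["test"]),
        "n_validation_trials": float(trial_counts["validation"]),
        "pseudotrials_per_scene": float(n_pseudo),
        "pseudotrials_per_pair": float(2 * n_pseudo),
        "n_timepoints": float(spec.n_timepoints),
        "skeleton_predictors": float(flatten_annotation(ann.arrays["skeleton"][0]).size),
        "action_predictors": float(flatten_annotation(ann.arrays["action"][0]).size),
        "hierarchy_permutations": float(
            inference.hierarchy_correlation(
                np.arange(7), np.arange(7)
            ).n_permutations
        ),
        "sequence_presentation_s": sequence_presentation_seconds(),
    }


def simulate_default_subject(seed: int):
    """One full-size subject: design, annotations, epochs, forward spec."""
    design = make_design(seed=subseed(seed, "design"))
    ann = simulate_annotations(design, seed=subseed(seed, "annotations"))
    spec = ForwardModelSpec(seed=subseed(seed, "forward"))
    eeg = simulate_eeg(design, ann, spec)
    return design, ann, spec, eeg


def whitening_max_offdiagonal(seed: int = 0) -> float:
    """Max |off-diagonal| of the residual channel correlation after MVNN.

    The whitener is estimated on the training split; the residual covariance
    is re-estimated on the held-out test split of the whitened data, so the
    check is not circular.
    """
    _, _, _, eeg = simulate_default_subject(seed)
    eeg = mvnn.baseline_correct(eeg)
    cov = mvnn.estimate_noise_covariance(eeg, split="train")
    white = mvnn.whiten(eeg, cov)
    resid = mvnn.estimate_noise_covariance(white, split="test")
    corr = resid.matrix / np.sqrt(
        np.outer(np.diag(resid.matrix), np.diag(resid.matrix))
    )
    off = ~np.eye(corr.shape[0], dtype=bool)
    return float(np.abs(corr[off]).max())


def _encode_subject(design, ann, eeg):
    eeg = mvnn.baseline_correct(eeg)
    cov = mvnn.estimate_noise_covariance(eeg, split="train")
    white = mvnn.whiten(eeg, cov)
    mats = prepare_design_matrices(ann, design)
    return encoding.encode_eeg(
        mats,
        white.select_split("train"),
        white.select_split("validation"),
        white.select_split("test"),
    )


def latency_recovery_spearman(seeds: list[int]) -> list[float]:
    """Spearman correlation, per seed, between planted and recovered EEG peak
    latencies over the seven features (full default experiment size)."""
    out = []
    for seed in seeds:
        design, ann, spec, eeg = simulate_default_subject(seed)
        acc = _encode_subject(design, ann, eeg)
        taus = [f.tau_ms for f in spec.features]
        peaks = [
            inference.peak_location(acc.timecourses[f.name], acc.time_ms)
            for f in spec.features
        ]
        out.append(float(spearmanr(taus, peaks).statistic))
    return out


def layer_recovery_matches(seed: int = 0) -> tuple[int, int]:
    """(n matched, n features): recovered peak layers vs planted peak layers."""
    design = make_design(seed=subseed(seed, "design"))
    ann = simulate_annotations(design, seed=subseed(seed, "annotations"))
    acts = simulate_layer_activations(
        design, ann, LayerModelSpec(seed=subseed(seed, "layers"))
    )
    mats = prepare_design_matrices(ann, design)
    prepared = encoding.prepare_layer_activations(acts, design)
    curves, _ = encoding.encode_layers(mats, prepared)
    features = default_features()
    matched = sum(
        prepared.layer_labels[int(np.argmax(curves[f.name]))] == f.peak_layer
        for f in features
    )
    return int(matched), len(features)


def sign_test_rejection_rate(
    n_replicates: int = 1000,
    n_subjects: int = 15,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null (Gaussian, zero-mean) replicates rejected at alpha."""
    rng = substream(seed, "sign-calibration")
    rejections = 0
    for i in range(n_replicates):
        vals = rng.standard_normal((n_subjects, 1))
        res = inference.sign_permutation_test(
            vals, n_perm=n_perm, seed=subseed(seed, f"sign-{i}")
        )
        rejections += res.p_raw[0] <= alpha
    return rejections / n_replicates


def swap_test_rejection_rate(
    n_replicates: int = 1000,
    group_sizes: tuple[int, int] = (15, 20),
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null two-group replicates rejected at alpha."""
    rng = substream(seed, "swap-calibration")
    rejections = 0
    for i in range(n_replicates):
        a = rng.standard_normal((group_sizes[0], 1))
        b = rng.standard_normal((group_sizes[1], 1))
        res = inference.condition_swap_test(
            a, b, n_perm=n_perm, seed=subseed(seed, f"swap-{i}")
        )
        rejections += res.p_raw[0] <= alpha
    return rejections / n_replicates


def ridge_ols_max_deviation(seed: int = 0) -> float:
    """Max |difference| between the ridge fit at lambda -> 0 and least squares."""
    rng = substream(seed, "ridge-ols")
    X = rng.standard_normal((60, 8))
    Y = rng.standard_normal((60, 5))
    model = encoding.fit_ridge(X, Y, 1e-12)
    Xi = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(Xi, Y, rcond=None)
    ols = np.vstack([model.intercept, model.weights])
    return float(np.abs(ols - beta).max())


def inverse_sqrt_identity_error(seed: int = 0, n: int = 12) -> float:
    """Frobenius error of M @ Sigma @ M - I for a random SPD Sigma."""
    rng = substream(seed, "inverse-sqrt")
    A = rng.standard_normal((n, n))
    sigma = A @ A.T + n * np.eye(n)
    M = mvnn.inverse_sqrt(sigma)
    return float(np.linalg.norm(M @ sigma @ M - np.eye(n)))


def weighted_correlation_example() -> float:
    """Variance-weighted correlation with weights (2, 1) and r (0.9, 0.3)."""
    return encoding.weighted_mean_correlation(np.array([0.9, 0.3]), np.array([2.0, 1.0]))


#: scaled-down group conditions for the null-protection replicates
NULL_PROTECTION = dict(
    n_rooms=5, n_heldout_rooms=2, n_subjects=5, reps={"train": 5, "test": 6, "validation": 5}
)


def null_protection_clean_fraction(
    n_seeds: int = 20,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates where no feature survives FDR after shuffling
    the annotation-stimulus assignment (destroying all true coupling)."""
    clean = 0
    for k in range(n_seeds):
        rep_seed = subseed(seed, f"null-protection-{k}")
        design = make_design(
            NULL_PROTECTION["n_rooms"],
            split_spec=SplitSpec(n_heldout_rooms=NULL_PROTECTION["n_heldout_rooms"]),
            seed=subseed(rep_seed, "design"),
        )
        ann = simulate_annotations(design, seed=subseed(rep_seed, "annotations"))
        spec = ForwardModelSpec(
            reps=dict(NULL_PROTECTION["reps"]), seed=subseed(rep_seed, "forward")
        )
        # break the annotation-stimulus coupling before the encoding analysis
        shuffle = substream(rep_seed, "shuffle").permutation(len(design))
        for name in ann.arrays:
            ann.arrays[name] = ann.arrays[name][shuffle]
        mats = prepare_design_matrices(ann, design)
        curves: dict[str, list[np.ndarray]] = {f: [] for f in mats.features()}
        for s in range(NULL_PROTECTION["n_subjects"]):
            eeg = simulate_eeg(design, ann, spec, subject=s)
            eeg = mvnn.baseline_correct(eeg)
            cov = mvnn.estimate_noise_covariance(eeg, split="train")
            white = mvnn.whiten(eeg, cov)
            acc = encoding.encode_eeg(
                mats,
                white.select_split("train"),
                white.select_split("validation"),
                white.select_split("test"),
            )
            for f, c in acc.timecourses.items():
                curves[f].append(c)
        any_sig = False
        for f, cs in curves.items():
            res = inference.sign_permutation_test(
                np.asarray(cs),
                n_perm=n_perm,
                alpha=alpha,
                seed=subseed(rep_seed, f"sign-{f}"),
            )
            if res.significant.any():
                any_sig = True
        clean += not any_sig
    return clean / n_seeds
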