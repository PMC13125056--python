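"""Synthetic experiment generator with planted, recoverable structure.

This module emulates the structure of a factorial scene-perception experiment:
per-stimulus feature annotations (pixel maps, a 14x2 skeleton, a one-hot
action vector), epoched multi-channel EEG produced by a linear forward model,
and layered network activations with feature-specific peak layers.

The forward model for the EEG signal of stimulus ``s`` at channel ``c`` and
time ``t`` is

    signal(s, c, t) = sum_f  kappa_f(t) * [a_f(s)^T P_f W_f]_c

where ``a_f(s)`` is the flattened annotation of feature ``f``, ``P_f`` a fixed
random projection onto a low-rank latent, ``W_f`` a fixed random channel
mixing, and ``kappa_f(t) = exp(-(t - tau_f)^2 / (2 sigma_f^2))`` a Gaussian
temporal response kernel gated to zero before stimulus onset.  Each trial adds
spatially correlated Gaussian noise with channel covariance ``Sigma_noise``.
Because the response is an exact linear function of the annotations, a linear
encoding model can recover the planted latency ``tau_f`` of every feature, and
the planted layer tuning below can recover every feature's peak layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "FeatureSpec",
    "ForwardModelSpec",
    "LayerModelSpec",
    "AnnotationSet",
    "EpochedEEG",
    "default_features",
    "exponential_channel_covariance",
    "simulate_annotations",
    "simulate_eeg",
    "simulate_group",
    "simulate_layer_activations",
]

#: Recognized annotation shape classes.
SHAPE_CLASSES = ("gray_map", "color_map", "skeleton", "onehot")

#: Canonical layer labels of the eight residual blocks.
LAYER_LABELS = ("1.0", "1.1", "2.0", "2.1", "3.0", "3.1", "4.0", "4.1")


@dataclass(frozen=True)
class FeatureSpec:
    """Planted generative parameters of one annotated stimulus feature."""

    name: str
    kind: str  # one of SHAPE_CLASSES
    tau_ms: float  # planted EEG peak latency
    sigma_ms: float = 30.0  # temporal kernel width
    rank: int = 5  # latent rank of the annotation signal
    amplitude: float = 1.0  # per-channel signal s.d. at the kernel peak
    peak_layer: str = "1.0"  # planted network peak layer

    def __post_init__(self):
        if self.kind not in SHAPE_CLASSES:
            raise ValueError(f"unknown feature shape class {self.kind!r}")


def default_features() -> tuple[FeatureSpec, ...]:
    """The seven default features: one low-, five mid-, one high-level.

    Planted latencies are grid-aligned (20 ms sampling) with >= 40 ms spacing
    and increase from the low-level feature (edges) through the mid-level
    surface/shape features to the high-level feature (action identity),
    mirroring the expected visual processing hierarchy.  Planted peak layers
    increase in the same order.
    """
    spec = [
        ("edges", "gray_map", 80.0, "1.0"),
        ("reflectance", "color_map", 120.0, "1.1"),
        ("lighting", "gray_map", 160.0, "2.1"),
        ("world_normals", "color_map", 200.0, "3.0"),
        ("scene_depth", "gray_map", 240.0, "3.1"),
        ("skeleton", "skeleton", 300.0, "4.0"),
        ("action", "onehot", 420.0, "4.1"),
    ]
    return tuple(
        FeatureSpec(name=n, kind=k, tau_ms=t, peak_layer=pl) for n, k, t, pl in spec
    )


def exponential_channel_covariance(
    n_channels: int, decay: float = 0.5, scale: float = 1.0
) -> np.ndarray:
    """SPD channel covariance with corr(c, c') = decay**|c - c'|."""
    idx = np.arange(n_channels)
    return scale**2 * decay ** np.abs(idx[:, None] - idx[None, :])


@dataclass(frozen=True)
class ForwardModelSpec:
    """Forward model for the synthetic EEG responses.

    Defaults reproduce the geometry of the emulated recordings: 19 posterior
    channels, 70 timepoints from -400 to 980 ms at 50 Hz, and 5 / 30 / 5
    repetitions per stimulus in the train / test / validation splits.
    """

    features: tuple[FeatureSpec, ...] = field(default_factory=default_features)
    n_channels: int = 19
    t_start_ms: float = -400.0
    t_step_ms: float = 20.0
    n_timepoints: int = 70
    reps: dict = field(
        default_factory=lambda: {"train": 5, "test": 30, "validation": 5}
    )
    noise_cov: np.ndarray | None = None  # default exponential 0.5**|dc|
    noise_scale: float = 1.0
    rho: float = 0.0  # cross-feature latent mixing in [0, 1)
    seed: int = 0

    def time_ms(self) -> np.ndarray:
        return self.t_start_ms + self.t_step_ms * np.arange(self.n_timepoints)

    def channel_covariance(self) -> np.ndarray:
        """Base (unit-scale) channel noise covariance; must be SPD."""
        if self.noise_cov is not None:
            cov = np.asarray(self.noise_cov, dtype=float)
        else:
            cov = exponential_channel_covariance(self.n_channels)
        if cov.shape != (self.n_channels, self.n_channels):
            raise ValueError("noise covariance shape does not match channel count")
        if not np.allclose(cov, cov.T):
            raise ValueError("noise covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("noise covariance must be positive-definite")
        return cov

    def noise_covariance(self) -> np.ndarray:
        """Effective trial-noise covariance ``noise_scale**2 * base``."""
        return self.noise_scale**2 * self.channel_covariance()


@dataclass(frozen=True)
class LayerModelSpec:
    """Planted layer tuning of the synthetic network activations."""

    layer_labels: tuple[str, ...] = LAYER_LABELS
    tuning_width: float = 1.0  # in layer-index units
    units_per_layer: int = 200
    noise_scale: float = 1.0
    amplitude: float = 1.0
    seed: int = 0


@dataclass
class AnnotationSet:
    """Per-stimulus annotation arrays, optionally with a frame axis.

    ``arrays[name]`` has shape ``(n_stimuli, *shape)`` in image mode or
    ``(n_stimuli, n_frames, *shape)`` in video mode.
    """

    arrays: dict[str, np.ndarray]
    kinds: dict[str, str]
    stimulus_ids: np.ndarray
    n_frames: int | None = None  # None = image mode

    def features(self) -> list[str]:
        return list(self.arrays)

    def stimulus_array(self, name: str) -> np.ndarray:
        return self.arrays[name]


@dataclass
class EpochedEEG:
    """Trials x channels x timepoints with a stimulus-locked time axis."""

    data: np.ndarray  # (n_trials, n_channels, n_timepoints)
    time_ms: np.ndarray
    trial_table: pd.DataFrame  # columns: trial, stimulus_id, split, repetition
    channels: list[str]

    def select_split(self, split: str) -> "EpochedEEG":
        mask = (self.trial_table["split"] == split).to_numpy()
        return EpochedEEG(
            data=self.data[mask],
            time_ms=self.time_ms,
            trial_table=self.trial_table[mask].reset_index(drop=True),
            channels=list(self.channels),
        )

    def copy(self) -> "EpochedEEG":
        return EpochedEEG(
            data=self.data.copy(),
            time_ms=self.time_ms.copy(),
            trial_table=self.trial_table.copy(),
            channels=list(self.channels),
        )


# ---------------------------------------------------------------------------
# annotations


def _feature_shape(kind: str, map_hw: tuple[int, int], n_actions: int):
    h, w = map_hw
    if kind == "gray_map":
        return (h, w)
    if kind == "color_map":
        return (h, w, 3)
    if kind == "skeleton":
        return (14, 2)
    if kind == "onehot":
        return (n_actions,)
    raise ValueError(f"unknown feature shape class {kind!r}")


def simulate_annotations(
    design: pd.DataFrame,
    features: tuple[FeatureSpec, ...] | None = None,
    rho: float = 0.0,
    map_hw: tuple[int, int] = (36, 27),
    n_frames: int | None = None,
    frame_jitter: float = 0.05,
    pixel_noise: float = 0.05,
    seed: int = 0,
) -> AnnotationSet:
    """Generate per-stimulus annotation arrays with a controllable shared latent.

    Every continuous feature is a low-rank linear image of a stimulus latent
    ``z_f = sqrt(1 - rho) * eta_f + sqrt(rho) * eta_shared`` plus small
    full-rank pixel noise, so the expected between-feature latent correlation
    is ``rho`` (0 = independent features).  The action feature is the exact
    one-hot encoding of the design's action factor.  In video mode each of the
    ``n_frames`` frames is the stimulus annotation plus small per-frame jitter
    (one-hot vectors are constant across frames).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if features is None:
        features = default_features()
    rng = substream(seed, "annotations")
    n_stim = len(design)
    n_actions = int(design["action"].max()) + 1

    max_rank = max(f.rank for f in features)
    eta_shared = rng.standard_normal((n_stim, max_rank))

    arrays: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for f in features:
        shape = _feature_shape(f.kind, map_hw, n_actions)
        if f.kind == "onehot":
            base = np.eye(n_actions)[design["action"].to_numpy()]
        else:
            d = int(np.prod(shape))
            z = np.sqrt(1.0 - rho) * rng.standard_normal((n_stim, f.rank))
            z = z + np.sqrt(rho) * eta_shared[:, : f.rank]
            loadings = rng.standard_normal((f.rank, d)) / np.sqrt(f.rank)
            base = z @ loadings + pixel_noise * rng.standard_normal((n_stim, d))
            base = base.reshape((n_stim, *shape))
        if n_frames is not None:
            if n_frames < 1:
                raise ValueError("n_frames must be >= 1")
            frames = np.repeat(base[:, None], n_frames, axis=1)
            if f.kind != "onehot":
                frames = frames + frame_jitter * rng.standard_normal(frames.shape)
            base = frames
        arrays[f.name] = base
        kinds[f.name] = f.kind
    return AnnotationSet(
        arrays=arrays,
        kinds=kinds,
        stimulus_ids=design["stimulus_id"].to_numpy().copy(),
        n_frames=n_frames,
    )


# ---------------------------------------------------------------------------
# EEG forward model


def _stimulus_matrix(annotations: AnnotationSet, name: str) -> np.ndarray:
    """Flattened (and frame-averaged, in video mode) annotation matrix."""
    arr = annotations.arrays[name]
    if annotations.n_frames is not None:
        arr = arr.mean(axis=1)
    return arr.reshape(len(arr), -1)


def _latent_scores(
    annotations: AnnotationSet, f: FeatureSpec, rng: np.random.Generator
) -> np.ndarray:
    """Standardized low-rank stimulus scores driving feature *f*'s response."""
    a = _stimulus_matrix(annotations, f.name)
    a = a - a.mean(axis=0, keepdims=True)
    d = a.shape[1]
    k = min(f.rank, d)
    proj = rng.standard_normal((d, k)) / np.sqrt(d)
    u = a @ proj
    sd = u.std(axis=0)
    sd[sd == 0] = 1.0
    return u / sd


def _signal_matrix(
    annotations: AnnotationSet,
    features: tuple[FeatureSpec, ...],
    n_channels: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-feature (n_stimuli x n_channels) spatial response patterns."""
    out = {}
    for f in features:
        u = _latent_scores(annotations, f, rng)
        mixing = rng.standard_normal((u.shape[1], n_channels))
        g = u @ mixing / np.sqrt(u.shape[1])
        sd = g.std(axis=0)
        sd[sd == 0] = 1.0
        out[f.name] = g * (f.amplitude / sd)
    return out


def _kernel(spec: ForwardModelSpec, f: FeatureSpec) -> np.ndarray:
    """Onset-gated Gaussian temporal response kernel on the epoch grid."""
    t = spec.time_ms()
    k = np.exp(-((t - f.tau_ms) ** 2) / (2.0 * f.sigma_ms**2))
    return k * (t >= 0)


def simulate_eeg(
    design: pd.DataFrame,
    annotations: AnnotationSet,
    spec: ForwardModelSpec,
    subject: int = 0,
) -> EpochedEEG:
    """Simulate one subject's epoched recordings under the forward model.

    Trials are grouped split-major, then stimulus-major, then by repetition;
    the trial table records the mapping.  ``subject`` selects an independent
    noise (and projection-independent) substream so groups of subjects share
    the planted structure but not the noise.
    """
    missing = set(design["stimulus_id"]) - set(annotations.stimulus_ids.tolist())
    if missing:
        raise ValueError(f"annotations missing {len(missing)} stimuli")
    cov = spec.channel_covariance()
    chol = np.linalg.cholesky(cov)
    time_ms = spec.time_ms()

    # planted projections are shared across subjects (drawn from the run seed)
    proj_rng = substream(spec.seed, "eeg-projections")
    patterns = _signal_matrix(annotations, spec.features, spec.n_channels, proj_rng)
    kernels = {f.name: _kernel(spec, f) for f in spec.features}

    # per-stimulus signal, indexed by stimulus_id position in the design
    n_stim = len(design)
    signal = np.zeros((n_stim, spec.n_channels, spec.n_timepoints))
    for f in spec.features:
        signal += patterns[f.name][:, :, None] * kernels[f.name][None, None, :]
    sid_to_row = {int(s): i for i, s in enumerate(annotations.stimulus_ids)}

    rows = []
    trial_signal_rows = []
    for split in ("train", "test", "validation"):
        sub = design[design["split"] == split]
        if sub.empty:
            continue
        n_rep = int(spec.reps.get(split, 0))
        if n_rep < 1:
            raise ValueError(f"repetition count for split {split!r} must be >= 1")
        for sid in sub["stimulus_id"].to_numpy():
            row = sid_to_row[int(sid)]
            for rep in range(n_rep):
                rows.append((int(sid), split, rep))
                trial_signal_rows.append(row)

    n_trials = len(rows)
    data = signal[np.asarray(trial_signal_rows)].copy()
    if spec.noise_scale > 0:
        noise_rng = substream(spec.seed, f"eeg-noise-subject{subject}")
        noise = noise_rng.standard_normal(
            (n_trials, spec.n_timepoints, spec.n_channels)
        )
        data += spec.noise_scale * (noise @ chol.T).transpose(0, 2, 1)

    trial_table = pd.DataFrame(rows, columns=["stimulus_id", "split", "repetition"])
    trial_table.insert(0, "trial", np.arange(n_trials))
    channels = [f"P{i:02d}" for i in range(spec.n_channels)]
    return EpochedEEG(data=data, time_ms=time_ms, trial_table=trial_table, channels=channels)


def simulate_group(
    design: pd.DataFrame,
    annotations: AnnotationSet,
    spec: ForwardModelSpec,
    n_subjects: int,
) -> list[EpochedEEG]:
    """Simulate a group of subjects sharing design, annotations, and planted
    projections, with independent noise per subject."""
    return [simulate_eeg(design, annotations, spec, subject=i) for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# layered network activations


def simulate_layer_activations(
    design: pd.DataFrame,
    annotations: AnnotationSet,
    layer_spec: LayerModelSpec,
    features: tuple[FeatureSpec, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Simulate per-layer unit activations with feature-specific peak layers.

    Layer ``l`` responds to feature ``f`` with gain
    ``g(f, l) = exp(-(l - l_f)^2 / (2 w^2))`` peaking at the planted layer
    ``l_f``, so an encoding model predicting layer activations from feature
    annotations is most accurate at ``l_f``.

    Returns an ordered mapping layer label -> (n_stimuli x n_units) array.
    """
    if features is None:
        features = default_features()
    if layer_spec.units_per_layer < 1:
        raise ValueError("units_per_layer must be >= 1")
    labels = list(layer_spec.layer_labels)
    for f in features:
        if f.peak_layer not in labels:
            raise ValueError(
                f"planted peak layer {f.peak_layer!r} of feature {f.name!r} "
                f"not in layer labels {labels}"
            )
    rng = substream(layer_spec.seed, "layer-activations")
    n_stim = len(design)

    scores = {f.name: _latent_scores(annotations, f, rng) for f in features}
    unit_maps = {
        f.name: rng.standard_normal((scores[f.name].shape[1], layer_spec.units_per_layer))
        / np.sqrt(scores[f.name].shape[1])
        for f in features
    }

    out: dict[str, np.ndarray] = {}
    for li, label in enumerate(labels):
        act = layer_spec.noise_scale * rng.standard_normal(
            (n_stim, layer_spec.units_per_layer)
        )
        for f in features:
            lf = labels.index(f.peak_layer)
            gain = np.exp(-((li - lf) ** 2) / (2.0 * layer_spec.tuning_width**2))
            act = act + layer_spec.amplitude * gain * (scores[f.name] @ unit_maps[f.name])
        out[label] = act
    return out
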