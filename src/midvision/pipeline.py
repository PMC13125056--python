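"""End-to-end orchestration: simulate -> prep -> mvnn -> decode -> encode ->
stats -> hierarchy, with a resumable manifest and full config serialization.

A run directory contains the HDF5 containers, plain-CSV result tables, a YAML
copy of the configuration, and ``manifest.json`` recording, per stage, the
output files with content hashes and wall time.  Re-running resumes after the
last stage whose outputs are intact; a master seed is fanned out into named
substreams so each stage's randomness is independent.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import containers, decoding, encoding, inference, mvnn
from ._rng import subseed
from .annotations import prepare_design_matrices
from .design import SplitSpec, make_design
from .simulate import (
    ForwardModelSpec,
    LayerModelSpec,
    default_features,
    simulate_annotations,
    simulate_eeg,
    simulate_layer_activations,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES", "load_config", "save_config"]

STAGES = ("simulate", "prep", "mvnn", "decode", "encode", "stats", "hierarchy")

#: the five mid-level features (between edges and action identity)
MID_LEVEL = ("reflectance", "lighting", "world_normals", "scene_depth", "skeleton")


@dataclass
class RunConfig:
    """Fully serializable run configuration (defaults mirror the emulated
    study design; shrink the factor counts and repetitions for desk-scale
    runs)."""

    mode: str = "image"  # image | video
    seed: int = 0
    # stimulus design
    n_rooms: int = 20
    n_actions: int = 6
    n_characters: int = 3
    n_cameras: int = 4
    n_heldout_rooms: int = 5
    test_cameras: list[int] = field(default_factory=lambda: [0, 1])
    # annotations
    map_h: int = 36
    map_w: int = 27
    n_frames: int = 9  # used in video mode only
    rho: float = 0.0
    # recordings
    n_subjects: int = 3
    n_channels: int = 19
    reps_train: int = 5
    reps_test: int = 30
    reps_validation: int = 5
    noise_scale: float = 1.0
    # network activations
    units_per_layer: int = 200
    variance_threshold: float = 0.90
    # analysis parameters
    pca_components: int = 100
    bin_size: int = 5
    n_folds: int = 6
    n_decode_repeats: int = 6
    n_perm: int = 10000
    n_boot: int = 10000
    n_ceiling: int = 100
    alpha: float = 0.05
    decode_on_whitened: bool = True

    def forward_spec(self) -> ForwardModelSpec:
        return ForwardModelSpec(
            n_channels=self.n_channels,
            reps={
                "train": self.reps_train,
                "test": self.reps_test,
                "validation": self.reps_validation,
            },
            noise_scale=self.noise_scale,
            rho=self.rho,
            seed=subseed(self.seed, "simulate"),
        )

    def layer_spec(self) -> LayerModelSpec:
        return LayerModelSpec(
            units_per_layer=self.units_per_layer,
            seed=subseed(self.seed, "layers"),
        )


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig(**data)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.entries = json.loads(path.read_text()) if path.exists() else {}

    def complete(self, stage: str) -> bool:
        entry = self.entries.get(stage)
        if not entry:
            return False
        for out, digest in entry["outputs"].items():
            p = self.path.parent / out
            if not p.exists() or _hash_file(p) != digest:
                return False
        return True

    def record(self, stage: str, outputs: list[Path], wall: float, inputs: list[Path]):
        self.entries[stage] = {
            "outputs": {p.name: _hash_file(p) for p in outputs},
            "inputs": {p.name: _hash_file(p) for p in inputs},
            "wall_time_s": round(wall, 3),
        }
        self.path.write_text(json.dumps(self.entries, indent=2))


def _subject_paths(run_dir: Path, config: RunConfig, prefix: str) -> list[Path]:
    return [run_dir / f"{prefix}_sub{i:02d}.h5" for i in range(config.n_subjects)]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages into *out_dir*, resuming from an intact manifest."""
    if config.mode not in ("image", "video"):
        raise ValueError(f"mode must be 'image' or 'video', got {config.mode!r}")
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, run_dir / "config.yaml")
    manifest = _Manifest(run_dir / "manifest.json")

    for stage in STAGES:
        if manifest.complete(stage):
            continue
        t0 = time.perf_counter()
        try:
            outputs, inputs = _STAGE_FNS[stage](config, run_dir)
        except Exception as err:  # pragma: no cover - error path
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        manifest.record(stage, outputs, time.perf_counter() - t0, inputs)
    return run_dir


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, run_dir: Path):
    design = make_design(
        config.n_rooms,
        config.n_actions,
        config.n_characters,
        config.n_cameras,
        SplitSpec(
            n_heldout_rooms=config.n_heldout_rooms,
            test_cameras=tuple(config.test_cameras),
        ),
        seed=subseed(config.seed, "design"),
    )
    annotations = simulate_annotations(
        design,
        rho=config.rho,
        map_hw=(config.map_h, config.map_w),
        n_frames=config.n_frames if config.mode == "video" else None,
        seed=subseed(config.seed, "annotations"),
    )
    fwd = config.forward_spec()
    activations = simulate_layer_activations(design, annotations, config.layer_spec())
    container = run_dir / "container.h5"
    containers.write_container(
        container,
        design,
        annotations=annotations,
        activations=activations,
        forward_spec=fwd,
        layer_spec=config.layer_spec(),
        seed=config.seed,
    )
    outputs = [container, container.with_suffix(".h5.json")]
    for i, path in enumerate(_subject_paths(run_dir, config, "eeg")):
        eeg = simulate_eeg(design, annotations, fwd, subject=i)
        containers.write_container(path, design, eeg=eeg, seed=config.seed)
        outputs.extend([path, path.with_suffix(".h5.json")])
    return outputs, []


def _stage_prep(config: RunConfig, run_dir: Path):
    container = run_dir / "container.h5"
    design = containers.read_design(container)
    annotations = containers.read_annotations(container)
    mats = prepare_design_matrices(
        annotations, design, mode=config.mode, n_components=config.pca_components
    )
    out = run_dir / "design_matrices.h5"
    if out.exists():
        out.unlink()
    containers.write_design_matrices(out, mats)
    return [out], [container]


def _stage_mvnn(config: RunConfig, run_dir: Path):
    outputs, inputs = [], []
    design = containers.read_design(run_dir / "container.h5")
    for raw_path, white_path in zip(
        _subject_paths(run_dir, config, "eeg"),
        _subject_paths(run_dir, config, "whitened"),
    ):
        eeg = containers.read_eeg(raw_path)
        eeg = mvnn.baseline_correct(eeg)
        cov = mvnn.estimate_noise_covariance(eeg, split="train")
        white = mvnn.whiten(eeg, cov)
        containers.write_container(white_path, design, eeg=white, seed=config.seed)
        outputs.extend([white_path, white_path.with_suffix(".h5.json")])
        inputs.append(raw_path)
    return outputs, inputs


def _decode_source(config: RunConfig, run_dir: Path) -> list[Path]:
    prefix = "whitened" if config.decode_on_whitened else "eeg"
    return _subject_paths(run_dir, config, prefix)


def _stage_decode(config: RunConfig, run_dir: Path):
    rows = []
    paths = _decode_source(config, run_dir)
    for i, path in enumerate(paths):
        eeg = containers.read_eeg(path).select_split("test")
        tc = decoding.decode_subject(
            eeg,
            bin_size=config.bin_size,
            n_folds=config.n_folds,
            n_repeats=config.n_decode_repeats,
            seed=subseed(config.seed, f"decode-sub{i}"),
        )
        for t, a in zip(tc.time_ms, tc.accuracy):
            rows.append({"subject": i, "time_ms": t, "accuracy": a})
    out = run_dir / "decoding.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return [out], paths


def _stage_encode(config: RunConfig, run_dir: Path):
    container = run_dir / "container.h5"
    design = containers.read_design(container)
    mats = containers.read_design_matrices(run_dir / "design_matrices.h5")

    enc_rows, ceil_rows = [], []
    inputs = [container, run_dir / "design_matrices.h5"]
    for i, path in enumerate(_subject_paths(run_dir, config, "whitened")):
        eeg = containers.read_eeg(path)
        acc = encoding.encode_eeg(
            mats,
            eeg.select_split("train"),
            eeg.select_split("validation"),
            eeg.select_split("test"),
        )
        for feature, curve in acc.timecourses.items():
            for t, r in zip(acc.time_ms, curve):
                enc_rows.append(
                    {
                        "subject": i,
                        "feature": feature,
                        "time_ms": t,
                        "r": r,
                        "lambda": acc.selected_lambda[feature],
                    }
                )
        ceiling = encoding.noise_ceiling(
            eeg.select_split("test"),
            n_reps=config.n_ceiling,
            seed=subseed(config.seed, f"ceiling-sub{i}"),
        )
        for t_idx, t in enumerate(eeg.time_ms):
            ceil_rows.append(
                {
                    "subject": i,
                    "time_ms": t,
                    "lower": ceiling.lower[:, t_idx].mean(),
                    "upper": ceiling.upper[:, t_idx].mean(),
                }
            )
        inputs.append(path)

    raw_layers = containers.read_activations(container)
    acts = encoding.prepare_layer_activations(
        raw_layers, design, variance_threshold=config.variance_threshold
    )
    curves, _ = encoding.encode_layers(mats, acts)
    layer_rows = [
        {"feature": feature, "layer": label, "r": curve[li]}
        for feature, curve in curves.items()
        for li, label in enumerate(acts.layer_labels)
    ]

    out_enc = run_dir / "encoding_eeg.csv"
    out_ceil = run_dir / "noise_ceiling.csv"
    out_lay = run_dir / "encoding_layers.csv"
    pd.DataFrame(enc_rows).to_csv(out_enc, index=False)
    pd.DataFrame(ceil_rows).to_csv(out_ceil, index=False)
    pd.DataFrame(layer_rows).to_csv(out_lay, index=False)
    return [out_enc, out_ceil, out_lay], inputs


def _stage_stats(config: RunConfig, run_dir: Path):
    enc = pd.read_csv(run_dir / "encoding_eeg.csv")
    dec = pd.read_csv(run_dir / "decoding.csv")
    time_ms = np.sort(enc["time_ms"].unique())

    stat_rows, peak_rows = [], []
    for feature, sub in enc.groupby("feature"):
        curves = sub.pivot(index="subject", columns="time_ms", values="r").to_numpy()
        res = inference.sign_permutation_test(
            curves,
            n_perm=config.n_perm,
            chance=0.0,
            alpha=config.alpha,
            seed=subseed(config.seed, f"sign-{feature}"),
        )
        for t, p, pa, sig in zip(time_ms, res.p_raw, res.p_adjusted, res.significant):
            stat_rows.append(
                {
                    "analysis": "encoding",
                    "feature": feature,
                    "time_ms": t,
                    "p": p,
                    "p_fdr": pa,
                    "significant": bool(sig),
                }
            )
        pk = inference.bootstrap_peak_ci(
            curves, time_ms, n_boot=config.n_boot, seed=subseed(config.seed, f"peak-{feature}")
        )
        peak_rows.append(
            {
                "feature": feature,
                "peak_ms": pk.peak,
                "ci_lo": pk.ci[0],
                "ci_hi": pk.ci[1],
            }
        )

    dcurves = dec.pivot(index="subject", columns="time_ms", values="accuracy").to_numpy()
    dres = inference.sign_permutation_test(
        dcurves,
        n_perm=config.n_perm,
        chance=decoding.CHANCE,
        alpha=config.alpha,
        seed=subseed(config.seed, "sign-decoding"),
    )
    dtime = np.sort(dec["time_ms"].unique())
    for t, p, pa, sig in zip(dtime, dres.p_raw, dres.p_adjusted, dres.significant):
        stat_rows.append(
            {
                "analysis": "decoding",
                "feature": "",
                "time_ms": t,
                "p": p,
                "p_fdr": pa,
                "significant": bool(sig),
            }
        )

    out_stats = run_dir / "stats.csv"
    out_peaks = run_dir / "peaks.csv"
    pd.DataFrame(stat_rows).to_csv(out_stats, index=False)
    pd.DataFrame(peak_rows).to_csv(out_peaks, index=False)
    return [out_stats, out_peaks], [run_dir / "encoding_eeg.csv", run_dir / "decoding.csv"]


def _stage_hierarchy(config: RunConfig, run_dir: Path):
    peaks = pd.read_csv(run_dir / "peaks.csv").set_index("feature")
    layers = pd.read_csv(run_dir / "encoding_layers.csv")
    labels = [f.name for f in default_features() if f.name in peaks.index]

    layer_order = list(dict.fromkeys(layers["layer"]))
    peak_layers = {}
    for feature, sub in layers.groupby("feature"):
        curve = sub.set_index("layer").loc[layer_order, "r"].to_numpy()
        peak_layers[feature] = float(
            inference.peak_location(curve, np.arange(len(layer_order)))
        )

    def correlate(features: list[str], label: str) -> dict:
        res = inference.hierarchy_correlation(
            np.array([peaks.loc[f, "peak_ms"] for f in features]),
            np.array([peak_layers[f] for f in features]),
            seed=subseed(config.seed, "hierarchy"),
        )
        return {
            "subset": label,
            "r_s": res.r_s,
            "p": res.p_value,
            "n_features": res.n_features,
            "n_permutations": res.n_permutations,
            "exhaustive": res.exhaustive,
            "tail": res.tail,
        }

    results = [correlate(labels, "all")]
    mid = [f for f in labels if f in MID_LEVEL]
    if len(mid) >= 3:
        results.append(correlate(mid, "mid_level"))
    out = run_dir / "hierarchy.json"
    out.write_text(json.dumps({"results": results, "peak_layers": peak_layers}, indent=2))
    return [out], [run_dir / "peaks.csv", run_dir / "encoding_layers.csv"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "mvnn": _stage_mvnn,
    "decode": _stage_decode,
    "encode": _stage_encode,
    "stats": _stage_stats,
    "hierarchy": _stage_hierarchy,
}
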