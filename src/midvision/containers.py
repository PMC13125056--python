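"""HDF5 experiment container: design, annotations, epochs, activations.

Layout::

    /design                      stimulus table (one dataset per column)
    /annotations/<feature>       per-stimulus annotation arrays
    /eeg/data                    trials x channels x timepoints
    /eeg/time_ms                 epoch time axis
    /eeg/trial_table/<column>    trial -> (stimulus_id, split, repetition)
    /activations/<layer>         stimuli x units
    /design_matrices/<feature>/<split>   prepared predictor matrices

A JSON sidecar (same path + ``.json``) records the generating specification
and seed for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .annotations import FeatureDesignMatrices
from .simulate import AnnotationSet, EpochedEEG, ForwardModelSpec, LayerModelSpec

__all__ = [
    "write_container",
    "read_design",
    "read_annotations",
    "read_eeg",
    "read_activations",
    "write_design_matrices",
    "read_design_matrices",
    "validate_container",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_table(group: h5py.Group, table: pd.DataFrame) -> None:
    for col in table.columns:
        vals = table[col].to_numpy()
        if vals.dtype == object or vals.dtype.kind == "U":
            group.create_dataset(
                col, data=np.array([str(v) for v in vals], dtype=object), dtype=_STR
            )
        else:
            group.create_dataset(col, data=vals)
    group.attrs["columns"] = json.dumps(list(table.columns))


def _read_table(group: h5py.Group) -> pd.DataFrame:
    cols = json.loads(group.attrs["columns"])
    data = {}
    for col in cols:
        vals = group[col][()]
        if vals.dtype.kind in ("S", "O"):
            vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
        data[col] = vals
    return pd.DataFrame(data)


def write_container(
    path: str | Path,
    design: pd.DataFrame,
    annotations: AnnotationSet | None = None,
    eeg: EpochedEEG | None = None,
    activations: dict[str, np.ndarray] | None = None,
    forward_spec: ForwardModelSpec | None = None,
    layer_spec: LayerModelSpec | None = None,
    seed: int | None = None,
) -> Path:
    """Write an experiment container plus a JSON provenance sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        _write_table(f.create_group("design"), design)
        if annotations is not None:
            grp = f.create_group("annotations")
            for name, arr in annotations.arrays.items():
                ds = grp.create_dataset(name, data=arr)
                ds.attrs["kind"] = annotations.kinds[name]
            grp.attrs["stimulus_ids"] = annotations.stimulus_ids
            grp.attrs["n_frames"] = -1 if annotations.n_frames is None else annotations.n_frames
        if eeg is not None:
            grp = f.create_group("eeg")
            grp.create_dataset("data", data=eeg.data)
            grp.create_dataset("time_ms", data=eeg.time_ms)
            grp.create_dataset("channels", data=np.array(eeg.channels, dtype=object), dtype=_STR)
            _write_table(grp.create_group("trial_table"), eeg.trial_table)
        if activations is not None:
            grp = f.create_group("activations")
            grp.attrs["layer_order"] = json.dumps(list(activations))
            for label, arr in activations.items():
                grp.create_dataset(label, data=arr)

    sidecar: dict = {"seed": seed}
    if forward_spec is not None:
        d = asdict(forward_spec)
        d["noise_cov"] = None if forward_spec.noise_cov is None else np.asarray(
            forward_spec.noise_cov
        ).tolist()
        d["features"] = [asdict(f) for f in forward_spec.features]
        sidecar["forward_spec"] = d
    if layer_spec is not None:
        sidecar["layer_spec"] = asdict(layer_spec)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_design(path: str | Path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        return _read_table(f["design"])


def read_annotations(path: str | Path) -> AnnotationSet:
    with h5py.File(path, "r") as f:
        grp = f["annotations"]
        arrays = {name: grp[name][()] for name in grp}
        kinds = {name: grp[name].attrs["kind"] for name in grp}
        n_frames = int(grp.attrs["n_frames"])
        return AnnotationSet(
            arrays=arrays,
            kinds=kinds,
            stimulus_ids=np.asarray(grp.attrs["stimulus_ids"]),
            n_frames=None if n_frames < 0 else n_frames,
        )


def read_eeg(path: str | Path) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        grp = f["eeg"]
        channels = [
            c.decode() if isinstance(c, bytes) else str(c) for c in grp["channels"][()]
        ]
        return EpochedEEG(
            data=grp["data"][()],
            time_ms=grp["time_ms"][()],
            trial_table=_read_table(grp["trial_table"]),
            channels=channels,
        )


def read_activations(path: str | Path) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        grp = f["activations"]
        order = json.loads(grp.attrs["layer_order"])
        return {label: grp[label][()] for label in order}


def write_design_matrices(path: str | Path, matrices: FeatureDesignMatrices) -> None:
    with h5py.File(path, "a") as f:
        if "design_matrices" in f:
            del f["design_matrices"]
        grp = f.create_group("design_matrices")
        for feature, splits in matrices.matrices.items():
            fg = grp.create_group(feature)
            for split, mat in splits.items():
                fg.create_dataset(split, data=mat)


def read_design_matrices(path: str | Path) -> FeatureDesignMatrices:
    out = FeatureDesignMatrices()
    with h5py.File(path, "r") as f:
        grp = f["design_matrices"]
        for feature in grp:
            out.matrices[feature] = {s: grp[feature][s][()] for s in grp[feature]}
    return out


def validate_container(path: str | Path) -> dict[str, bool]:
    """Structural checks on a container; returns pass/fail per named check."""
    path = Path(path)
    report: dict[str, bool] = {}
    with h5py.File(path, "r") as f:
        report["has_design"] = "design" in f
        if not report["has_design"]:
            return report
        design = _read_table(f["design"])
        report["splits_disjoint_exhaustive"] = bool(
            design["split"].isin(["train", "test", "validation"]).all()
        )
        report["stimulus_ids_unique"] = design["stimulus_id"].is_unique

        if "annotations" in f:
            grp = f["annotations"]
            n_stim = len(design)
            report["annotations_cover_design"] = all(
                grp[name].shape[0] == n_stim for name in grp
            )
        if "eeg" in f:
            grp = f["eeg"]
            ok_shape = grp["data"].ndim == 3
            time_ms = grp["time_ms"][()]
            steps = np.diff(time_ms)
            report["time_axis_uniform"] = bool(
                len(time_ms) > 1 and np.all(steps > 0) and np.allclose(steps, steps[0])
            )
            trial_table = _read_table(grp["trial_table"])
            report["eeg_shape_consistent"] = bool(
                ok_shape
                and grp["data"].shape[0] == len(trial_table)
                and grp["data"].shape[1] == len(grp["channels"])
                and grp["data"].shape[2] == len(time_ms)
            )
            known = set(design["stimulus_id"].tolist())
            report["trials_reference_known_stimuli"] = bool(
                trial_table["stimulus_id"].isin(known).all()
            )
        if "activations" in f:
            grp = f["activations"]
            report["activations_cover_design"] = all(
                grp[label].shape[0] == len(design) for label in grp
            )
    return report
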