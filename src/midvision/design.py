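"""Factorial stimulus design and train/test/validation split.

The experiment crosses rooms x actions x characters x camera spawn points into
a full factorial stimulus set (defaults 20 x 6 x 3 x 4 = 1440 scenes).  The
split follows the room/camera scheme of the underlying study design: a subset
of rooms is reserved for generalization and shared between the test and
validation sets, which are distinguished by disjoint camera pairs; the
remaining rooms (all cameras) form the training set.  With the default
geometry this yields 1080 / 180 / 180 stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SplitSpec",
    "make_design",
    "split_sizes",
    "sequence_presentation_seconds",
]

#: Canonical factor level defaults.
N_ROOMS, N_ACTIONS, N_CHARACTERS, N_CAMERAS = 20, 6, 3, 4


@dataclass(frozen=True)
class SplitSpec:
    """How rooms and cameras are partitioned into train / test / validation.

    ``n_heldout_rooms`` rooms never appear during training and are shared by
    the test and validation sets.  Cameras are split into one pair for the
    test set and the complementary pair for the validation set (for 4
    cameras: test gets cameras {0, 1}, validation gets {2, 3}).
    """

    n_heldout_rooms: int = 5
    test_cameras: tuple[int, ...] = (0, 1)

    def validation_cameras(self, n_cameras: int) -> tuple[int, ...]:
        return tuple(c for c in range(n_cameras) if c not in self.test_cameras)


DEFAULT_SPLIT = SplitSpec()

#: Degenerate split: everything in train (single-cell designs, smoke tests).
TRAIN_ONLY = SplitSpec(n_heldout_rooms=0, test_cameras=())


def make_design(
    n_rooms: int = N_ROOMS,
    n_actions: int = N_ACTIONS,
    n_characters: int = N_CHARACTERS,
    n_cameras: int = N_CAMERAS,
    split_spec: SplitSpec = DEFAULT_SPLIT,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the full factorial stimulus table with split labels.

    Parameters
    ----------
    n_rooms, n_actions, n_characters, n_cameras
        Factor level counts (all >= 1).
    split_spec
        Room/camera partition; the held-out rooms are chosen deterministically
        from ``seed`` (a random subset, mirroring an arbitrary assignment of
        physical rooms to sets).
    seed
        Seed for the held-out-room draw; identical seeds give identical tables.

    Returns
    -------
    pandas.DataFrame
        One row per stimulus with columns ``stimulus_id``, ``room``,
        ``action``, ``character``, ``camera``, ``split``.
    """
    for name, n in [
        ("n_rooms", n_rooms),
        ("n_actions", n_actions),
        ("n_characters", n_characters),
        ("n_cameras", n_cameras),
    ]:
        if n < 1:
            raise ValueError(f"{name} must be >= 1, got {n}")
    if split_spec.n_heldout_rooms > n_rooms:
        raise ValueError(
            f"cannot hold out {split_spec.n_heldout_rooms} of {n_rooms} rooms"
        )
    if any(c >= n_cameras for c in split_spec.test_cameras):
        raise ValueError("test_cameras outside camera range")

    rooms, actions, characters, cameras = np.meshgrid(
        np.arange(n_rooms),
        np.arange(n_actions),
        np.arange(n_characters),
        np.arange(n_cameras),
        indexing="ij",
    )
    table = pd.DataFrame(
        {
            "room": rooms.ravel(),
            "action": actions.ravel(),
            "character": characters.ravel(),
            "camera": cameras.ravel(),
        }
    )
    table.insert(0, "stimulus_id", np.arange(len(table)))

    rng = np.random.default_rng(seed)
    heldout = set(
        rng.choice(n_rooms, size=split_spec.n_heldout_rooms, replace=False).tolist()
    )
    test_cams = set(split_spec.test_cameras)
    val_cams = set(split_spec.validation_cameras(n_cameras))

    split = np.full(len(table), "train", dtype=object)
    in_heldout = table["room"].isin(heldout).to_numpy()
    split[in_heldout & table["camera"].isin(test_cams).to_numpy()] = "test"
    split[in_heldout & table["camera"].isin(val_cams).to_numpy()] = "validation"
    table["split"] = split
    return table


def split_sizes(design: pd.DataFrame) -> dict[str, int]:
    """Number of stimuli per split, with zero entries for absent splits."""
    counts = design["split"].value_counts().to_dict()
    return {s: int(counts.get(s, 0)) for s in ("train", "test", "validation")}


def sequence_presentation_seconds(
    n_trials: int = 10, stimulus_ms: float = 300.0, iti_ms: float = 100.0
) -> float:
    """Stimulus presentation time of one rapid serial sequence, in seconds.

    Default: 10 trials of 300 ms stimulus + 100 ms intertrial interval = 4 s.
    """
    return n_trials * (stimulus_ms + iti_ms) / 1000.0
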