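"""Small helpers shared across test modules."""

import numpy as np
import pandas as pd

from midvision.simulate import EpochedEEG


def toy_epochs(data, time_ms=None, stimulus_ids=None, split="train"):
    """Wrap a (trials, channels, timepoints) array into an EpochedEEG."""
    n, c, t = data.shape
    time_ms = np.arange(-100, -100 + 20 * t, 20) if time_ms is None else time_ms
    sids = np.zeros(n, dtype=int) if stimulus_ids is None else np.asarray(stimulus_ids)
    table = pd.DataFrame(
        {
            "trial": np.arange(n),
            "stimulus_id": sids,
            "split": [split] * n,
            "repetition": np.arange(n),
        }
    )
    return EpochedEEG(
        data=data,
        time_ms=time_ms,
        trial_table=table,
        channels=[f"P{i:02d}" for i in range(c)],
    )
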