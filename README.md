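# midvision

Time-resolved **linearized encoding models** of low-, mid-, and high-level
visual features, re-implemented as a tested, reusable pipeline with a
synthetic experiment generator standing in for EEG recordings and network
activations.

## Who this is for

Researchers studying when visual features — edges at the low end, action
identity at the high end, and the mid-level surface/shape features in between
(reflectance, lighting, world normals, scene depth, skeleton position) — are
represented in time-resolved neural recordings, and how that temporal
hierarchy aligns with the layer hierarchy of a deep network. The package
implements every analysis stage at desk scale against a forward model with
*known planted structure*, so each stage can be verified against ground truth
before it ever touches real data.

## The model

Stimuli form a full factorial design (20 rooms x 6 actions x 3 characters x
4 cameras = 1440 scenes) split 1080/180/180 into train/test/validation, with
held-out rooms shared between test and validation and disjoint camera pairs.
For each feature *f* with annotation vector $a_f(s)$ per stimulus *s*, the
synthetic EEG response is

$$x(s,c,t) \;=\; \sum_f \kappa_f(t)\,\big[a_f(s)^\top P_f W_f\big]_c \;+\;
\varepsilon(c),\qquad
\kappa_f(t)=e^{-(t-\tau_f)^2/2\sigma_f^2},\;\;
\varepsilon \sim \mathcal N(0,\Sigma_{\text{noise}})$$

on a 50 Hz epoch grid (70 points, −400…980 ms) over 19 posterior channels,
with spatially correlated noise $\mathrm{corr}(c,c') = 0.5^{|c-c'|}$.
The analysis stages are:

1. **Annotation prep** — flatten (frame-average for videos), PCA-100 on the
   five high-dimensional features (train-fitted), native 28/6 predictors for
   skeleton and action.
2. **MVNN** — baseline correction, Ledoit–Wolf-shrunk noise covariance from
   within-stimulus repetition residuals, whitening by the inverse matrix
   square root (train-estimated, applied to all splits).
3. **Decoding** — pairwise linear-SVM classification of scene pairs from
   pseudotrials (6 per scene from 30 repetitions, bins of 5) under stratified
   sixfold cross-validation; lower-triangle mean per timepoint.
4. **Encoding** — multivariate ridge ($\beta = (X^\top X+\lambda I)^{-1}
   X^\top Y$) with $\lambda$ selected per feature on the validation split from
   30 log-spaced values ($10^{-5}…10^{15}$); accuracy is the Pearson $r$
   between predicted and repetition-averaged observed responses per
   (channel, timepoint), or per (component, layer) with variance-weighted
   component averaging; split-half noise ceilings (100 resamplings).
5. **Inference** — sign-permutation and condition-swap tests with
   Benjamini–Hochberg FDR, percentile bootstrap CIs for means, peak latencies
   and peak differences, and the EEG-vs-network hierarchy Spearman
   correlation with an exhaustive 7! = 5040-permutation p-value.

## Worked example

```python
import numpy as np
from midvision import (
    ForwardModelSpec, make_design, simulate_annotations, simulate_eeg,
    prepare_design_matrices, baseline_correct, estimate_noise_covariance,
    whiten, encode_eeg, peak_location,
)

design = make_design(seed=1)                       # 1440 stimuli
ann = simulate_annotations(design, seed=2)         # 7 feature annotation sets
spec = ForwardModelSpec(seed=3)                    # 5/30/5 repetitions
eeg = simulate_eeg(design, ann, spec)              # 11700 trials x 19 x 70

eeg = baseline_correct(eeg)
cov = estimate_noise_covariance(eeg, split="train")
white = whiten(eeg, cov)

mats = prepare_design_matrices(ann, design)        # PCA-100 / native dims
acc = encode_eeg(mats, white.select_split("train"),
                 white.select_split("validation"), white.select_split("test"))
for f in spec.features:
    peak = peak_location(acc.timecourses[f.name], acc.time_ms)
    print(f"{f.name:14s} planted {f.tau_ms:4.0f} ms   recovered {peak:4.0f} ms")
```

Output:

```
edges          planted   80 ms   recovered   60 ms
reflectance    planted  120 ms   recovered  120 ms
lighting       planted  160 ms   recovered  160 ms
world_normals  planted  200 ms   recovered  200 ms
scene_depth    planted  240 ms   recovered  240 ms
skeleton       planted  300 ms   recovered  320 ms
action         planted  420 ms   recovered  420 ms
```

Each feature's encoding time course peaks at (or within one 20 ms sample of)
its planted response latency, and the recovered ordering reproduces the
planted low → mid → high hierarchy exactly (Spearman ρ = 1.0).

A full run — simulation through hierarchy correlation — is one command:

```bash
midvision run-all --seed 7 --out runs/demo        # or: python -m midvision.cli
midvision validate runs/demo/container.h5
```

which writes CSV result tables (`decoding.csv`, `encoding_eeg.csv`,
`encoding_layers.csv`, `stats.csv`, `peaks.csv`), `hierarchy.json`, and a
resumable `manifest.json` into the run directory.

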