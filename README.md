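# cytoemd

Earth Mover's Distance (EMD) comparison of flow-cytometry samples: a
pipeline for scoring how much a cell population's biomarker-expression
distribution changed, and for classifying subjects from those scores.

## Why a transport metric

Cytometry questions are usually comparative — did the stimulated sample
move relative to its unstimulated control? With 10⁴–10⁶ events per sample,
p-value statistics (chi-square on bins, the probability-binning statistic
T(χ)) flag even tiny instrument drift as highly significant, and saturate
once two populations no longer share bins, so a large biological shift
scores no higher than a moderate one. The Earth Mover's Distance fixes both
failure modes. Representing each sample as a signature
P = {(p_i, w_i)} — bin centroids with occupancy weights — EMD solves the
transportation problem

    EMD(P, Q) = min_F Σᵢⱼ d_ij f_ij   subject to
    f_ij ≥ 0,  Σⱼ f_ij = w_pi,  Σᵢ f_ij = w_qj,  Σᵢⱼ f_ij = 1

with d_ij = ‖p_i − q_j‖₂, i.e. the minimum mass × distance needed to turn
one distribution into the other. On unit-mass signatures this is a true
metric (equal to the Mallows / 1-Wasserstein distance): a 0.05-SD drift
scores ≈ 0.05, and a subpopulation of fraction π moving s units scores
≈ π·s, growing linearly forever instead of plateauing.

The package implements the full pipeline:

| module           | role                                                              |
| ---------------- | ----------------------------------------------------------------- |
| `flow_io`        | FCS / delimited reading, asinh & logicle transforms, rect gating  |
| `signatures`     | recursive median-split (probability) binning → signatures         |
| `emd_core`       | transportation LP (HiGHS), 1-D closed form, Hungarian oracle      |
| `alt_metrics`    | baselines: PB statistic, chi-square, Mahalanobis, MFI deltas      |
| `classify`       | linear SVM + exhaustive / random repeated sub-sampling validation |
| `synthetic_data` | Gaussian-mixture populations, shift series, paired cohorts        |
| `cli`            | `cytoemd simulate / signature / compare / shift-series / classify` |

## Worked example

Simulate a control (standard bivariate normal on CD203c/CD63) and a
"stimulated" sample in which a 20% subpopulation sits 3 SD higher on both
markers, then score the pair:

```
$ cytoemd simulate --seed 7 --n-events 5000 --out stimulated.csv
$ cytoemd compare --reference control.csv stimulated.csv --measures emd,md,mfi:cd63
```

gives (abridged) `EMD = 0.845`, `MD = 0.527`, `MFI_delta(CD63) = 0.304`.
The EMD is ≈ 0.2 × 3 × √2 ≈ 0.85 — the moved fraction times how far it
moved — whereas the Mahalanobis distance and the single-channel median
shift compress the same change into fractions of a pooled SD that do not
scale with it.

The saturation contrast in one table — a minor population (π = 0.2) walks
away from a fixed reference in 2-SD steps:

```
$ cytoemd shift-series --shifts 0,2,4,6,8 --n-events 8000 --seed 1 --out series.csv
 shift_sd      emd         pb
      0.0 0.016276  -0.772644
      2.0 0.392738  85.186230
      4.0 0.793488 166.799295
      6.0 1.194238 170.171154
      8.0 1.594988 170.171154
```

EMD climbs linearly with slope ≈ π = 0.2 per SD of separation; the
probability-binning statistic freezes at its maximum once the populations
stop sharing bins (identical values at s = 6 and s = 8), carrying no
further information however much larger the change grows.

Library use mirrors the CLI:

```python
from cytoemd import compute_signature, emd, read_events, transform

control = transform(read_events("control.fcs"), "asinh", cofactor=150)
stimulated = transform(read_events("stimulated.fcs"), "asinh", cofactor=150)
score = emd(compute_signature(control.select_channels(["CD203c", "CD63"])),
            compute_signature(stimulated.select_channels(["CD203c", "CD63"])))
```

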