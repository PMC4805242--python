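# Methods

## Problem and model

Flow cytometry produces, per sample, an N × d table of fluorescence
intensities (events × marker channels). The scientific question is usually
comparative: did a stimulated sample move, relative to its unstimulated
control, in a way that is biologically meaningful? p-value statistics answer
the wrong question at cytometry sample sizes — with 10⁴–10⁶ events, even a
small instrument drift is "significant". cytoemd instead scores sample pairs
with the Earth Mover's Distance (EMD), the minimum cost of rearranging one
distribution into the other, where cost = mass moved × distance moved. On
equal-mass distributions EMD is a true metric (non-negative, symmetric, zero
iff equal, triangle inequality) and equals the Mallows / 1-Wasserstein
distance. Its value scales with *both* the fraction of cells that moved and
how far they moved, so a small drift yields a proportionally small score
rather than a significant one.

## Signatures

Full empirical distributions are summarized as signatures {(m_j, w_j)}:
variable-size hyper-rectangular bins with centroid m_j (mean of member
events) and weight w_j (occupancy fraction; weights sum to 1). Bins come
from probability binning: recursively split the events at the median of the
maximum-variance dimension, while both children would keep at least
`stop_threshold` events. The default threshold is 2 ln N — about 500 bins at
N = 20 000 — giving fine resolution where the data are dense.

Numerical conventions (all deterministic):

* variance is the sample variance (n−1 denominator); ties between
  dimensions go to the lowest index;
* the stored split value is the *lower median*, and new samples are routed
  with "value ≤ split goes left", so a foreign sample bins reproducibly;
* with an odd node count the extra event goes left (first ⌈n/2⌉ sorted
  events), so leaf occupancies differ by at most 1 per split level;
* a node with zero variance in every dimension becomes a leaf; a whole
  sample like this yields a single-leaf schema flagged `degenerate`;
* empty bins are dropped from signatures (they carry no mass).

For EMD each sample is binned with its own schema. For the chi-square–family
statistics both samples are binned with the *control's* schema, as those
statistics require shared bins.

## The transportation LP

Given signatures P (m bins) and Q (n bins) and the Euclidean ground-distance
matrix D = [‖p_i − q_j‖₂], the optimal flow F = [f_ij] minimizes Σ d_ij f_ij
subject to f_ij ≥ 0, row sums w_pi, column sums w_qj, grand sum 1; EMD is
the optimal cost divided by the transported mass (= the cost at unit mass).
The solver is HiGHS via `scipy.optimize.linprog`: interior point with
crossover by default (markedly faster than simplex at ≳250 bins per side),
falling back to dual simplex on failure. One equality constraint is dropped
(the system is rank-deficient by 1); marginal residuals come back at ~1e-10,
and the objective is contracted to 1e-8 of the optimum.

Correctness does not rest on one solver. For signatures whose weights are
rationals k/L, expanding each into L equal-mass atoms turns optimal
transport into an assignment problem, solved exactly by the Hungarian
algorithm (`emd_exact_assignment`, built on `linear_sum_assignment`); the
test suite checks LP/oracle agreement to 1e-8 on random small instances. In
1-D, `emd_1d_exact` (integrated |ΔCDF|, via `scipy.stats.
wasserstein_distance`) is the unbinned gold standard.

Inputs whose weights do not sum to 1 are rejected unless the caller passes
`normalize=True`; EMD with genuinely unequal masses (partial transport) is
out of scope. Ground distances are computed in whatever (transformed) units
the events carry — no per-channel rescaling — so callers must compare like
with like.

## Baseline measures

* **ChS** — symmetric chi-square Σ (p_i − q_i)²/(p_i + q_i) on occupancy
  fractions over control-derived bins, dropping bins empty in both samples.
* **PB** — the standardized probability-binning statistic
  T(χ) = (n_H · ChS − (B−1)) / √(2(B−1)), n_H the harmonic-mean sample
  size: null mean ≈ 0, SD ≈ 1. Once the test sample occupies only the
  unbounded edge bin of the control schema, ChS saturates (just below 2)
  and PB stops growing however far the sample moves — the saturation that
  motivates a transport distance.
* **MD** — Mahalanobis distance between sample means under the pooled
  sample covariance, optionally ridge-regularized.
* **MFI delta** — signed difference of channel medians (lower-median
  convention for even N).

## Axis transforms and gating

Raw intensities are mapped to display scale with asinh(x / cofactor)
(default cofactor 150) or with the logicle biexponential
(parameters T, W, M, A; default 262144 / 0.5 / 4.5 / 0). The logicle
forward transform has no closed form; each value is inverted by bracketed
Brent root-finding on the strictly increasing biexponential, exact to
~1e-12 of display position. asinh is the default because logicle parameter
choice is dataset-dependent. Transforms are not stacked; gates are closed
axis-aligned intervals (boundary inclusive), and a gate that removes every
event is an error, not an empty sample. Compensation and density-based
population finding are out of scope; the package expects pre-gated or
rectangular-gated data.

## Synthetic study conditions

The generators emulate, in transformed units (unit-SD Gaussian
populations), the structure the method is meant to resolve:

* **shift series** — one reference N(0,1) draw versus one mixture draw
  (1−π) N(0,1) + π N(s,1) whose minor component (π = 0.2 by default) is
  *translated* to each s ∈ {0, 2, 4, 6, 8}; sharing the underlying events
  across the series (common random numbers) makes differences along the
  series reflect the separation itself rather than re-draw noise, like a
  dose-response experiment on one cell subset. The population EMD here is
  exactly π·s, so the series should be linear through the origin with
  slope π.
* **paired cohorts** — per subject, a control N(0, I) on (CD203c, CD63)
  and a stimulated sample carrying a nuisance drift (magnitude split
  across both channels) for everyone. Responders up-regulate a π = 0.2
  subpopulation by `effect` on CD203c; only half of them also raise CD63
  (*poorly coordinated* two-marker response, as basophil activation data
  show), and they do so by the same amount — `nonspecific_scale × effect`,
  half magnitude by default — as the nonspecific CD63-only elevation that
  half the non-responders exhibit. The CD63 marginal is therefore
  class-exchangeable by construction (half of each class elevated
  identically), so a single-channel CD63 MFI delta carries no class
  information, while the two-channel EMD still orders the classes by
  transported mass × distance: every responder scores at least π·effect
  (the CD203c component alone), every non-responder at most
  π·effect·nonspecific_scale plus drift.

What these generators do *not* emulate: spectral spillover/compensation,
heavy-tailed or zero-inflated channels, autofluorescence, acquisition-time
effects, or rare (<0.1%) populations. Tests passing on them show the
machinery is correct under the stated statistical structure, not that any
particular clinical dataset will separate.

## Classification protocol

Scores feed a linear SVM (scikit-learn `SVC(kernel="linear")`, no feature
normalization): hard margin C = 1e5 for separable score sets, soft margin
C = 1 otherwise. Validation is repeated sub-sampling with
`train_per_class` subjects per class in training and the rest held out —
either exhaustively over all C(n,k)² splits or randomly with extra targeted
splits so every subject is held out at least once. The headline "best
classification" is the minimum validation error over splits; because a
minimum over tens of thousands of splits is optimistic, the mean error rate
is always reported alongside. Ties exactly on the decision boundary go to
the positive side.

## Experiment sizes and numeric choices

Default experiment sizes (chosen so each stage exercises realistic bin
counts): shift series at N = 20 000 (≈512-bin signatures, 32 coarse bins
for the classical PB statistic — chi-square statistics are conventionally
run on far coarser bins than the EMD signature, and at 2 ln N granularity
the control's edge bins sit deep enough that the plateau only completes
past s ≈ 6); Wasserstein-recovery checks at N = 10 000; drift and
binning-robustness checks at N = 5 000; cohorts of 10 + 10 subjects at
2 000 events per sample with effect 3 SD and drift 0.1 SD. LP tolerance
1e-8; signature weight normalization checked at 1e-9; all generators take
explicit seeds and are reproducible bit-for-bit.

## Known limitations

* The LP is dense: m·n flow variables. A few hundred bins per side solve in
  seconds; the ~1000-bin signatures of million-event samples call for a
  dedicated transportation solver that is not implemented here.
* The FCS reader covers list-mode files with uniform integer widths or
  float data — the common case — and ignores compensation keywords by
  design; it is not a general FCS toolkit.
* PB normalization follows the construction above; published variants
  differ in their standardization, so only relative behavior (null level,
  growth, plateau) should be compared across software.
* `emd_exact_assignment` requires small-denominator rational weights and is
  an oracle for tests, not a production path.
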