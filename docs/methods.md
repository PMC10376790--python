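# Methods

`fuzzymed` implements a single classification method for heterogeneous
medical data built around a fuzzy decision tree (FDT), with a configurable
chain of pre-processing stages selected by data type:

| data type          | stage chain                                    |
|--------------------|------------------------------------------------|
| signal             | segment → FFT → PCA → FCM fuzzification → FDT  |
| large-dimensional  | PCA → FCM fuzzification → FDT                  |
| numeric/categorical| FCM fuzzification → FDT                        |
| expert (fuzzy)     | FDT directly                                   |

A fuzzy naive Bayes classifier is available as a baseline at the final
stage. Evaluation uses a seeded 70:30 hold-out split, optionally repeated
(random subsampling), reporting accuracy, specificity, sensitivity,
precision and F1 from one-vs-rest confusion counts.

## Fuzzy representation

An attribute A_i takes values over m_i ≥ 2 linguistic terms; a sample's
value is a membership vector with one degree in [0, 1] per term. After FCM
fuzzification, degrees sum to 1. The cardinality of a fuzzy set is the sum
of its degrees. Class labels are kept crisp (degenerate one-hot
memberships) for the signal, wide and clinical workflows; genuinely fuzzy
outputs occur only in expert data, where each evaluation carries a
certainty already expressed as membership degrees.

## Fuzzification (fuzzy C-means)

Each numeric column is clustered independently in 1-D by fuzzy C-means
with fuzzifier exponent q (default 2), tolerance 1e-6 on the largest
center shift, and at most 300 iterations. Initialization is deterministic
at the m equally spaced quantiles; optional seeded random restarts keep
the lowest-objective solution. Term membership is the standard FCM
formula μ_j(x) = 1 / Σ_l (d_j/d_l)^(2/(q−1)); a value exactly on a center
is a full member of that term. Centers are sorted ascending, which fixes
the autogenerated term semantics (low … high). Categorical columns are
one-hot encoded as crisp terms. Missing values (numeric or categorical)
and unseen categories receive uniform memberships — maximal ignorance —
with a warning.

## Split score and tree induction

The split score is fuzzy Shannon mutual information in bits, computed on a
joint mass table whose cell (j, k) accumulates the t-norm (default
product, optionally min) of the input-term and class memberships over the
samples reaching the node, each weighted by its accumulated branch mass.
This is the information-theoretic "degree of influence" of an attribute on
the class: zero under independence, H(B) for a determining attribute. On
crisp data the procedure reduces exactly to classical information-gain
(ID3) induction, which the test suite verifies exhaustively on all
two-attribute Boolean truth tables.

Induction is recursive. A node becomes a leaf when any of:

* its dominant-class confidence reaches β (default 0.95);
* its mass fraction of the training total does not exceed α (default
  0.01; at α = 0 only zero-mass nodes are cut, at α = 1 the tree is a
  single root leaf);
* no unused input attribute remains on the path (attributes are never
  reused along a path).

Raising α can only shrink the tree and raising β can only grow it; the
suite asserts both monotonicities on a fixed dataset and parameter grid.
A zero-mass node becomes a leaf inheriting its parent's confidence. All
ties — split scores, predicted classes — break toward the lowest index,
with a 1e-12 tolerance on score comparisons so floating-point noise cannot
override the tie rule.

Inference sums over all root-to-leaf paths the product of branch
memberships times the leaf's confidence vector, then renormalizes; the
crisp decision is the argmax. The decision table enumerates the Cartesian
product of input terms (one crisp row per combination) with the
prediction and confidence for each.

## Fuzzy naive Bayes

Priors are class membership masses over the total; conditionals are
smoothed joint masses per (attribute, term, class) normalized over terms
within each class (Laplace constant, default 1.0). The posterior combines
terms by expectation: posterior(k) ∝ prior(k) · Π_i Σ_j μ_ij ·
cond(i, j, k).

## Pre-processing details

* Segmentation cuts consecutive non-overlapping windows of
  floor(seconds × rate) samples and discards the trailing remainder.
* FFT features are one-sided magnitude spectra (bins 0…N/2) with a
  rectangular window by default so bin-aligned tones are exact; a Hann
  window is available. A Parseval identity over the reassembled two-sided
  spectrum is checked in the tests.
* PCA standardizes columns to z-scores first (spectral bins have wildly
  different scales), drops zero-variance columns with a warning, and
  orients every loading column so its largest-magnitude entry is positive,
  making the projection deterministic. Component variances are the usual
  sample (ddof = 1) eigenvalues, non-increasing.

## Evaluation protocol

Hold-out train size is round-half-up(fraction × K); stratification uses
largest-remainder apportionment of the train budget across classes, and a
class with fewer than two samples falls back to the unstratified pool with
a warning. Metrics with zero denominators are reported as undefined
(`None`) and excluded from macro means, never raised as errors. For
multi-class problems the report is one-vs-rest per class plus the macro
mean. Repetition seeds for random subsampling are drawn deterministically
from the master seed.

## Synthetic archetypes

The generators produce data shaped like the four study designs the
pipeline targets, with every draw determined by the seed:

* **signal** — 500 records of 23.6 s at 200 Hz (the sampling rate is a
  package default; real EEG archives vary), 400 background / 100
  seizure-like. Background is a unit 10 Hz tone in Gaussian noise
  (σ = 0.5); the seizure class adds a 3 Hz component amplitude-modulated
  by a 0.3 Hz burst envelope and scaled by the effect size (default 3.0,
  the burst-to-background amplitude ratio). Effect size 0 makes the
  classes identically distributed.
* **wide** — 78 rows × 186 numeric columns, two balanced classes, 20
  informative columns with class means at ±δ/2 (δ = 2.0), the rest
  standard normal.
* **clinical** — 177 rows, 12 binary comorbidity-style flags with
  class-dependent prevalence plus 17 log-normal biomarker-style columns
  with class-dependent log-mean shift; 60 % survival rate.
* **expert** — 10 samples over inputs with 2/2/4 terms and a 3-class
  output, covering 10 of the 16 possible crisp situations. Memberships are
  Dirichlet draws concentrated on the true term of a monotone ground-truth
  structure function (sharpness 12 by default); as sharpness → ∞ the data
  become exactly crisp and an unpruned tree recovers the structure
  function on all 16 decision-table rows.

These generators emulate marginal structure only — no EEG physiology,
electrode montages, inter-patient variability, missingness mechanisms or
label noise of real cohorts — so passing recovery tests demonstrates that
the pipeline machinery is correct, not that comparable accuracy would be
reached on clinical data.

## Numerical choices and limitations

Joint masses below 1e-12 are treated as zero (0·log 0 = 0 convention);
logs are base 2. Degenerate FCM runs (a starved cluster) re-seed the
empty center at the farthest point, and collapsed centers fall back to
quantile centers. Problem sizes in the tests and the reproduction script
(full-size signal archetype, 4000 segments; 5 hold-out repetitions for
tables) keep a complete run within a few seconds on one CPU.

Known limitations: the mutual-information split score averages over each
attribute's observations; per-observation cumulative variants of the
score exist in the literature and may rank attributes differently on
skewed data. Fuzzy blur around sparsely covered regions can dominate
deep, low-mass branches — the α threshold exists precisely to cut them,
and results on very small expert-style samples are sensitive to it.
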