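# Methods

This note documents the models implemented in `odoradapt`, the assumptions
behind them, the default parameters and why they were chosen, and what the
synthetic generator does and does not emulate.

## Data model

All neural analyses operate on the **trial tensor**: integer spike counts
indexed (neuron *i*, time bin *j*, trial *k*), built from tidy spike-event
tables by half-open binning `[t, t + Δ)` over the odor window. Defaults
mirror the reference experimental design: 4-s odor window, 50-ms bins (80
bins), 25 trials per block, 60-s inter-trial interval, 15-min no-odor reset
between blocks. Spike times are stored relative to odor onset (onset = 0;
pre-stimulus spikes are negative and excluded by the window). Trial
numbering is 1-based everywhere a trial is *named* ("trial 26"); array
positions are 0-based and documented as such. Binning conserves in-window
spike mass exactly; a spike at exactly the window end belongs to no bin by
the half-open convention.

Two reductions collapse a trial slice to a population vector: `sum_window`
(total in-window count per unit; used for clustering/classification) and
`mean_per_bin` (time-averaged count; the time-averaged form used in the
correlation analysis). They differ by the positive constant `n_bins`, so
every Pearson-based quantity is identical under either — this equivalence
is asserted in the test suite. A third option, `concat_bins`, correlates
full unit × bin patterns for users who want within-trial temporal structure
included.

Unit quality control consumes precomputed spike-sorting summary metrics and
applies strict thresholds (separation > 5 noise SD, ISI-violation fraction
< 6.5%, waveform variance < 6.5 noise units). The metrics arrive as
reported by the sorting procedure; the package does not recompute them from
waveforms (raw electrophysiology is out of scope). The waveform-variance
unit is consumed as given, without re-deriving whether it is a variance or
an SD multiple.

## Synthetic generator

The generator exists so that every pipeline stage can be exercised, and
every claim tested, against data whose ground truth is known. It emulates:

- **Tuning**: per odor, each unit is responsive with probability 0.6;
  responsive evoked gains are Gamma(shape 3, scale 10) Hz above a 2-Hz
  baseline — peak evoked rates averaging ~30 Hz, typical of odor-evoked
  projection-neuron responses, and high enough that Poisson noise does not
  dominate per-trial population vectors (the signal-to-noise reasoning is
  spelled out below under "What passing tests show").
- **Intensity**: the low-intensity tuning vector is 0.6 × the high vector
  for a random 70% of units and an independently re-drawn (low-scale) gain
  for the remaining 30% (`rotation_fraction = 0.3`) — so some units prefer
  the lower concentration, and the high/low tuning correlation lands near
  0.7 (range ~0.6–0.85 across seeds), a "subtle rotation" of the active
  ensemble rather than a pure gain change. The size of this rotation is not
  quantified by any reference measurement; it is a free, config-exposed
  parameter whose default was set so that between-intensity trial
  correlations sit visibly below within-intensity ones, the qualitative
  regime the analyses address.
- **Temporal envelope**: a rise–plateau–decay kernel (onset τ 150 ms,
  sustained ~1 s, decay τ 2 s), unit peak, applied per 50-ms bin.
- **Adaptation** (trial-wise multiplier on the evoked rate):
  - `magnitude_only`: `m_k = plateau + (1 − plateau)·e^{−(k−1)/τ}`, shared
    by all units (defaults plateau 0.4, τ 5 trials — ensemble counts fall
    to ~40–50% across a 25-trial block). Vector direction is preserved
    exactly in expectation.
  - `vesicle_depletion`: `m_k(u) = 1 − s·(1 − e^{−(k−1)/τ})·r₁(u)/max r₁`
    (default s 0.6): units depress in proportion to their own drive, so
    the (Δcount vs. first-trial count) regression slope is negative.
  - `lateral_inhibition`: facilitating inhibition progressively silences
    the weakly driven half of the population,
    `m_k(u) = 1 − s·(1 − e^{−(k−1)/τ})·σ((0.5 − q_u)/0.05)` with `q_u` the
    rank quantile of trial-1 drive, applied to the unit's **total**
    in-window rate (baseline included: a silenced neuron stops firing
    altogether during the odor). This form was chosen deliberately. A
    multiplicative weight `(1 − r₁/max r₁)` on the evoked component alone
    produces a *hump-shaped* absolute loss `(1 − r₁/M)·r₁` whose covariance
    with r₁ is positive for any realistically right-skewed gain
    distribution — i.e. it yields a *depletion-like* negative slope and
    cannot produce the inhibition signature it is meant to model. Silencing
    weak responders outright makes the absolute loss a decreasing function
    of drive, which is the defining fingerprint of the mechanism (weak
    responders lose the most, strong responders are spared), and gives the
    positive regression slope in ≥ 99% of 200-unit simulations.
  - A negative effective rate anywhere (e.g. depletion strength > 1) raises
    a model error; rates are never silently clipped.
- **Spiking**: inhomogeneous Poisson realized on 1-ms sub-bins with rates
  piecewise-constant over the 50-ms analysis bins, so closed-form expected
  counts are exact and every moment-based test has an analytic oracle.
  0.5 s of pre- and post-window baseline activity is simulated so the
  window-exclusion logic is exercised by real out-of-window spikes.
- **Catch trials**: the deviant stimulus replaces trial
  `catch_trial_index`; it arrives unadapted by default, with a
  `cross_adaptation` coefficient in [0, 1] linearly interpolating toward
  the repeated stimulus' full adaptation state (to emulate deviants that do
  vs. do not escape cross-adaptation).
- **Behavior**: per animal and trial, POR ~ Bernoulli(p_k) with
  `p_k = p_inf + (p0 − p_inf)·e^{−(k−1)/τ}`; defaults p0 0.2, p_inf 0.8
  (high intensity) / 0.55 (low), τ 2 trials, 36 animals — facilitation that
  stabilizes after about five trials at intensity-dependent levels.
  `p0_catch` sets the deviant's unadapted response probability on a catch
  trial.
- **Rank-selection tensors**: `synthetic_rank3_tensor` builds exactly
  trilinear neural-shaped data — sparse non-negative unit loadings,
  Gaussian temporal bumps at distinct latencies, and three trial trends
  (adapting, stable, facilitating) — plus i.i.d. Gaussian noise at 0.5 ×
  the signal SD. The factor structure matters: with generic symmetric
  Gaussian factors, the best-fit overfactored (F = 4) model often explains
  a clean noise direction and keeps a high core consistency, whereas with
  correlated non-negative neural-like factors the extra factor splits an
  existing one and the diagnostic collapses — which is the behavior seen on
  real recordings and the regime these tensors are meant to emulate.

**What the generator does not emulate**: oscillatory synchronization and
spike-timing coherence; biophysical membrane dynamics; cross-trial
correlations beyond the deterministic adaptation profile (each trial's
Poisson noise is independent); drift, bursting, or non-Poisson count
dispersion; sensory-neuron input dynamics. Consequently, passing tests show
that the *analyses* behave as claimed under the stated generative
assumptions — not that real recordings satisfy those assumptions.

## Tensor decomposition

CP/PARAFAC is fitted by alternating least squares: each loading matrix is
solved in closed form (Khatri–Rao design, Gram-matrix solve with
pseudo-inverse fallback) holding the others fixed, which makes the
reconstruction error non-increasing per sweep — asserted per-iteration in
the tests. Initialization is uniform random non-negative; 10 restarts by
default with the best final fit kept (restart-stability is itself tested:
two independent 10-restart fits agree in fit fraction to 1e-6).
Convergence: change in fit fraction < 1e-8 or 500 sweeps. After fitting,
columns of A and B are unit-normalized with all scale pushed into C, and
signs are fixed by making each A and B column's largest-magnitude element
positive — making serialization and factor matching deterministic up to
factor permutation. No non-negativity constraint is imposed by default
(none is assumed by the analyses); a projected-ALS switch exists for
exploration.

Core consistency uses the standard construction: the least-squares Tucker
core for the fixed loadings via factor pseudo-inverses, scored against the
superdiagonal identity core; 100 is perfect trilinearity, values are
unbounded below. Rank selection scans candidates in ascending order and
stops at the first value below the threshold (default 50%). The stopping
rule matters: the diagnostic is not monotone in F — an overfactored model
can stumble into a clean local solution and rebound (observed directly:
94% at F=5 after 27% at F=4) — so "largest candidate above threshold"
would occasionally select absurd ranks; "largest rank reached before the
first drop" matches how the diagnostic is actually used. If even the first
candidate fails, it is returned with a warning flag. On raw Poisson count
tensors the curve can also dip at intermediate ranks (a two-factor
degeneracy at F=2 is visible in the worked example); the analysis scripts
therefore report the full curve, never just the selected rank.

A second instability sits at the overfactored rank itself: whether the
best-fit F+1 model is a degenerate split (core consistency far below zero)
or a clean "signal plus one noise direction" solution (core consistency
60–99%) is a tensor-specific local-optimum lottery that restart budget can
tip either way. Replicated analyses therefore aggregate before selecting:
the acceptance checks compute the median core-consistency curve over
replicate tensors and apply the first-drop rule to that curve
(`select_from_curve`), which is stable where single-tensor selection is
bimodal.

Factor recovery is scored by congruence (cosine of matched columns) after
permutation matching — Hungarian assignment on the product of per-mode
absolute cosines — and legal sign flips (an even number of negations across
the three modes). The test suite validates this matcher against brute-force
enumeration of all 3! permutations.

## Trajectories

The trajectory analysis operates on the CP-reconstructed (denoised)
tensor: unfold along trials into an (n_units × n_bins·n_trials) time
series, center each time-step vector by the grand mean over steps, project
onto the three leading eigenvectors of the unit-covariance matrix, and
smooth each trial's point sequence with a three-point running average
(edge points use shrunken two-point windows, preserving trajectory length).
Centering uses no variance scaling (covariance, not correlation,
eigenvectors). Fewer than three non-degenerate covariance eigenvalues is an
error — a rank-2 reconstruction cannot span three trajectory dimensions —
except for the exactly-constant case, which legitimately collapses every
trajectory to the origin. Each trajectory also carries the projected grand
mean (`offset`), because direction comparisons are physically meaningful in
raw coordinates: in centered coordinates, early large-amplitude and late
small-amplitude trials sit on opposite sides of the grand mean and a
direction cosine computed there is misleading. Trajectory *size* is
summarized by loop diameter (largest inter-point distance) rather than path
length: path length accumulates high-frequency noise wiggle and so reflects
the noise floor, while the diameter tracks the signal swing and scales with
the adaptation multiplier (the worked example recovers the trial-25
multiplier to three decimals).

## Clustering and classification

Trial similarity is Pearson correlation between per-trial summed-count
vectors; clustering is agglomerative complete linkage on distance 1 − r
(the linkage that minimizes the furthest pairwise distance within each
merged cluster), with deterministic tie-breaking; trees export to Newick
with merge heights as branch lengths. Classification — not procedurally
specified by any reference — is implemented as leave-one-trial-out
nearest-centroid with Pearson similarity, centroids recomputed per fold:
the simplest scheme consistent with the correlation-based framing of
everything else, and it is labeled as an interpretation wherever reported.

## Behavioral statistics

p(POR) is the fraction of responding animals per trial. Intensity
discrimination is a *paired* left-tailed t-test on per-animal mean POR at
low vs. high intensity (pairing on animals; the per-animal statistic is the
mean over the selected trials), with p-values from the t distribution on
n − 1 degrees of freedom and no multiple-testing correction by default
(per-odor reporting; a `bonferroni` helper is provided for callers that
pool odors).
When every pairwise difference is exactly zero the statistic is defined as
t = 0, p = 0.5 rather than NaN, keeping pipelines total on degenerate
fixtures. The early/late split defaults to trial 5 (facilitation stabilizes
after about five trials) and is a parameter, not a constant. The
neural–behavioral link is plain OLS of per-trial p(POR) on per-trial total
ensemble count; under zero response variance R² is defined as 0 with a
degeneracy flag. Test calibration is verified empirically: under the null
generator the paired test's type-I error at α = 0.05 sits within binomial
noise of nominal over 1000 replicates.

## Numerical and design choices

- Text tables are comma-delimited UTF-8 with mandatory headers; binary
  containers (tensors, CP models) are HDF5 with one dataset per axis-label
  vector, so a round trip can never silently transpose axes. Round trips
  are bit-exact and property-tested.
- Validation is total and specific: missing columns, non-numeric values
  (with row numbers), out-of-protocol trials, non-binary POR codes,
  truncated containers, zero-variance vectors, and degenerate regression
  designs each raise a dedicated exception; nothing coerces silently.
- Problem sizes in the test and acceptance suites: 80 × 80 × 25 tensors
  (the reference dataset dimensions), 10 replicates for the
  core-consistency medians, 5 noiseless refits for factor recovery, 20
  sessions for the adaptation-invariance checks, 20 simulations per
  mechanism, 1000 replicates for t-test calibration. CP fits inside the
  replicate loops use 2–3 restarts (the restart-stability test justifies
  the small budget; the library default stays at 10).
- The magnitude-only "count ratio equals the plateau" identity holds
  exactly only at baseline 0, since adaptation multiplies the evoked
  component while baseline firing is unadapted; tests of that identity use
  a baseline-0 configuration, and plateau recovery on full models subtracts
  the known baseline mass before fitting the exponential.

## Known limitations

- CORCONDIA on raw count data is noisy and non-monotone; the selection rule
  is deliberately conservative (first drop), and users should always look
  at the full curve.
- The ALS solver has no missing-data support and no Tucker/constrained
  variants; rank-deficient Gram matrices fall back to pseudo-inverse
  solves.
- The lateral-inhibition model is one member of a family of
  weak-responder-suppression mechanisms; its rank-based silencing form was
  chosen for its clean regression signature, not fitted to any measurement.
- The nearest-centroid classifier is a stand-in; absolute accuracies depend
  on the generator's separation and should not be read as decoding
  performance of real ensembles.
- Behavioral simulation treats animals as exchangeable (no per-animal
  response propensity); between-animal heterogeneity would widen the
  binomial intervals used in the tests.
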