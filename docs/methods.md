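# Methods

This note records the models implemented in `grslogic`, their
assumptions, the defaults and why they were chosen, and the known
limitations — the information a user needs to judge what a green test
suite does and does not establish.

## Forward model

A gene's nascent (chromatin-associated) mRNA is modeled by a single
linear ODE, `dRNA/dt = ksyn·f(t) − kproc·RNA`, over the first hour after
stimulation. The window is deliberately short: secondary transcriptional
responses and feedbacks are excluded by construction, and the
"degradation" term is biologically the processing/release of transcripts
from chromatin. Fractional promoter activity
`f = (1−k0)·G + k0` combines a basal leak `k0` with a thermodynamic gate
`G` over Hill occupancies `h_i = TF_i/(Kd_i + TF_i)` with Hill
coefficient fixed at 1 (no cooperativity within a single TF). AND is
the product of occupancies; OR is the complement of the product of
complements; the mixed triple gates compose the two. TF activities are
normalized fractions in [0, 1]; out-of-range user inputs are clipped
with a warning (noise-perturbed amplitudes in the simulator are *not*
clipped above 1 — see below).

Defaults (representative catalog): `ksyn = 1` RPKM/min, `kproc = 0.1`
/min (≈7 min processing half-time of a short gene), `k0 = 0`, time grid
{0, 15, 30, 60} min. For piecewise-constant inputs the ODE is advanced
with the exact interval-wise solution
`RNA(t) = ss + (RNA(t0) − ss)·e^(−kproc·Δt)`; arbitrary inputs use
adaptive RK45 with relative tolerance 1e-8. Batched catalog simulation
uses exponential stepping on a fine grid (0.125 min for the gradient
waveform), which is exact for piecewise-constant inputs and second-order
otherwise. `RNA(0)` defaults to 0 when `k0 = 0` and to the basal steady
state `ksyn·k0/kproc` otherwise, so unstimulated series are flat.

## Catalog enumeration and reduction

The representative catalog crosses the 8 triple gates with
Strong/Medium/Weak strengths (`Kd` = 0.1/1/10) per TF: 216
configurations. Two filters yield the 93 unique, potentially
identifiable GRSs:

* **Activatability.** A configuration is poorly activated when its
  full-stimulation gate activity does not reach 1/6 of its own maximal
  output (operationally: peak output over 60 min with all TFs at 1).
  This flags 68 configurations — every AND chain containing a Weak TF,
  the all-Medium triple AND, and OR-of-AND gates gated by a Weak
  required arm. The maximum output over the flagged set, 1.66 RPKM, is
  the threshold reused verbatim for randomly sampled catalogs (where
  steady state may not be reached within the hour, the peak over the
  window is used).
* **Redundancy.** Treating Weak as a null regulation, each activatable
  configuration reduces to an effective logic over its non-Weak TFs
  (Weak drops out of an OR; a required Weak arm kills an AND). The 30
  single/dual equivalence classes are represented canonically by the
  *ideal reduced gate*: a host triple logic with exact null strengths
  (`Kd = 1e6`) for the dropped TFs, so a "single TF1" entry is exactly
  `h1` rather than a Weak-Kd approximation. The remaining class members
  (55 configurations, including the all-Weak triple OR whose effective
  logic is empty) are flagged redundant. The split differs from a pure
  output-threshold bookkeeping by one entry (the all-Weak OR gate is
  activatable but logically degenerate); the retained membership —
  63 triples, 24 duals, 6 singles — and the triple-AND survivor set
  (SSS, SSM×3, SMM×3) are invariant to that bookkeeping.

Deduplication is symbolic rather than tolerance-based: it is
deterministic, idempotent, and testable, whereas numeric equivalence of
Weak-Kd members to their ideal gates holds only approximately (relative
response deviations up to ~30 % on the normalized scale).

## Perturbation panels

`simple7` crosses high/low per TF minus the all-low case. Each
26-condition panel assigns {high, modified, low} per TF minus all-low,
where "modified" is a constant 0.5 amplitude, a `t/60` gradient, a
30-min-delayed step, or a 30-min transient pulse. Custom panels are
written as H/M/L signatures (1/0.5/0), e.g. the knockout set
{LHH, HLH, HHL}. Panel responses are normalized per gene to a maximum
of 100 across the whole panel (equivalent to rescaling `ksyn`) before
distance computation; squared-Euclidean distances summed over conditions
and timepoints feed single-linkage trees (average/complete provided for
robustness checks), and "distinguishable clusters" counts cut the tree
at a separation threshold.

## Synthetic replicate data

Six uncertainty sources mimic a replicated caRNA-seq experiment, applied
in causal order (biology → simulation → sampling → assay): TF-amplitude
factors `(1+ε)`, ε∼N(0, 4e-4); gene-response-time shifts N(0, 25 min²);
kinetic-parameter factors `e^ε`, ε∼N(0, 4e-4) on Kd/ksyn/kproc; additive
basal `k0 + U(0, 0.02)`; sample-preparation shifts N(0, 25 min²); and
multiplicative assay noise with variance `0.01·y²`. The second arguments
of the normal distributions are variances (the 25 min² timing sources
correspond to 5-min standard deviations). Both timing sources act as
evaluation-time shifts of the response curve — for an input translated
in time from a pre-stimulus steady state the solution translates
identically, so shifting the input onset and shifting the read-out are
the same operation; the two draws are independent, the t = 0 sample
(unstimulated steady state) is never shifted, and shifted times are
clamped to [0, 80] min. Amplitude factors are not clipped at 1: clipping
would silence the noise source in every "high" condition. Negative
values are truncated at zero. Biology-side draws are made per (gene,
condition, replicate); the preparation shift per collected sample
(condition, timepoint, replicate), shared across genes; assay noise per
value. Five overall uncertainty levels (0.21×–2.66×) scale the six
variance parameters with per-source multipliers.

What the generator does *not* emulate: read-level sequencing effects
(library size, fragment sampling), gene–gene correlations beyond shared
preparation shifts, and any real biological network structure. Passing
tests therefore demonstrate correctness of the inference machinery under
the stated noise anatomy, not performance on arbitrary real data.

## Time–value error model

Observed variance at a timecourse point decomposes as
`σ²_total = α0 + α1·μ + α2·μ² + Slope²·σ_t²`: a polynomial mean–variance
trend (constant, linear and quadratic components suffice for the
simulated and caRNA-like data) plus first-order propagation of Gaussian
timing error through the local slope. Slopes come from a
shape-preserving PCHIP interpolant of the replicate-mean series,
extended flat to 80 min so the last timepoint has a usable neighborhood,
differentiated by central differences over `Δt = 2·σ̂_t`; the slope at
t = 0 is pinned to 0 (pre-stimulus steady state). Because `Δt` depends
on the estimate of `σ_t`, fitting runs two passes: window initialized at
the grid spacing, then refined once from the first-pass estimate.

Low-expression points (μ ≤ η = 3 RPKM) use a gamma distribution with
mode μ and variance `σ²_bg` — solving `(k−1)θ = μ`, `kθ² = σ²_bg` via
the positive root of `θ² + μθ − σ²_bg = 0`, which is feasible for every
μ ≥ 0 (k → 1, an exponential, as μ → 0), so no degenerate fallback is
needed; induced points are Gaussian. The five global parameters are
fitted by pooled maximum likelihood over all genes, conditions and
timepoints (L-BFGS-B on log10 parameters, bounds 1e-8–1e4, moment-based
initialization plus random restarts), then multiplied by N/(N−1) to
unbias the variance scale. The conventional model is the same fit with
`σ_t² = 0` fixed.

Per-point estimates shrink toward the global fit by maximizing
point-likelihood × normal prior centered on the global parameters with
prior variance `σ²_ξprior` (default 1e-5, i.e. prior-dominated — with
two replicates, point-specific information cannot improve on the global
trend; the prior-variance ladder starts at 1e-5 and grows ×10 when more
replicates justify it). Only the parameters a point's branch is
informative about are optimized; the rest stay at the prior exactly.
Likelihood evaluation floors variances at 1e-8 RPKM² and observed values
at 1e-6 RPKM inside the gamma density.

On the duplicate benchmark (93 GRSs × 26 amplitude conditions, base
noise, truth from 1000 independent draws) the time-value model's
posterior variances correlate with truth at r ≈ 0.92 versus ≈ 0.55 for
the conventional model and ≈ 0.45 for raw duplicate variance — the
conventional trend systematically over-estimates flat-segment and
under-estimates steep-segment variance.

## Model fitting and selection

The fitting likelihood plugs the model prediction into the error model:
gamma branch when the *prediction* is ≤ η, Gaussian otherwise with
variance from the fitted trend and the data-derived slopes (held fixed
during optimization). All parameters are optimized in log10 space with
bounds `Kd ∈ [0.01, 100]` (10-fold beyond Strong/Weak, outside which Kd
barely affects the gate), `ksyn ∈ [0.01, 1000]` RPKM/min,
`kproc ∈ [0.01, 10]` /min, `k0 ∈ [1e-6, 1]` (or fixed at 0). Multi-start
search draws log-uniform initializations, rescales each start's `ksyn`
so its prediction matches the data's magnitude (random kd/kproc
otherwise strand most starts on the flat near-zero background-branch
plateau where gradients vanish), screens all starts in one vectorized
likelihood evaluation, and polishes the best eight with bounded
L-BFGS-B (a `refine_all` mode polishes every start and guarantees the
best-so-far property in the number of starts). All gates share one
parameter count, so selection is by likelihood alone; ties within 1e-6
resolve toward fewer effective TFs.

The 8 → 17 mapping calls a TF null when its fitted `Kd` reaches the
upper search bound (a strictly-greater-than-100 rule could never fire at
a bound of 100); two nulls give a single-TF label, one null a dual
label. Recovery benchmarks compare mapped 17-logic labels because a
reduced dual gate is representable by more than one host triple logic.

Two caveats discovered and documented here: (i) with the plug-in
prediction-dependent variance, even noiseless data reward slightly
smaller predictions (lower variance at equal residual), so noiseless
self-consistency checks use a homoscedastic variance; (ii) duplicate
noisy data constrain a Strong `Kd` only to about 2-fold, the resolution
the benchmarks assert.

On the scaled-down recovery benchmark (15 catalog GRSs, duplicate
amplitude26 data, 100 starts — the full-scale study runs all 93 GRSs at
300 starts and is available by raising the two arguments) the
time-value pipeline recovers all 15 logics with 92.5 % of non-null Kds
within 2-fold and a Kd mean absolute percent deviation of 24 %,
with the accuracy ordering time-value ≥ conventional ≥ raw variance.

## Identifiability and experimental design

The identifiability of a catalog GRS under a design
(panel × replicates) is the log2 likelihood ratio between the
ground-truth GRS and the most similar alternative: noisy data are
simulated from the truth, the error model is fitted on those data, and
every catalog member's noiseless representative response is scored as a
candidate explanation — no re-fitting of alternatives, matching the
evaluation-only reading of the design study; a re-fitting variant would
only lower alternative NLLs. Responses are compared on the absolute
RPKM scale of the shared kinetics: response amplitude carries
regulation-strength information, and per-GRS normalization would make
e.g. Strong and Medium single-TF gates indistinguishable under
on/off-only panels. A deterministic variant returns the minimum squared
response distance to any alternative.

Two structural facts shape the results. Under a 4-condition
WT + single-knockout panel, ~20 retained GRSs have *exactly* coincident
responses (strength-permutation twins inside AND groups: the product of
occupancies at TF = 1 is permutation-invariant, and every single-
knockout condition yields zero), so their identifiability is zero for
any noise model and the catalog median under that design is intrinsically
capped. Second, with 10 % multiplicative assay noise plus timing
variance, nearest-pair likelihood ratios for mid-range pairs saturate
near a few tens of log2 units. The qualitative design guidance is
robust and reproduced: more replicates raise identifiability but
spreading a fixed budget over more perturbation conditions raises it
far more, and among 3-condition sets the single-knockout set (HHL) is
the most informative, followed by double knockdowns (HMM), with double
knockouts (HLL) degenerate. Reported medians pool three independent
noise draws to damp Monte-Carlo wobble.

## Measured-data workflow

Band intensities are scaled per condition to [0.01, 1]
(`0.99·(raw−basal)/(peak−basal)+0.01`) and cross-normalized by same-gel
peak ratios against the wild-type reference stimulation. MAPK-driven TF
activity, lacking a direct assay, is inferred by applying the same
scaling to immediate-early genes (Egr1, Fos, Dusp4 — neither NFκB nor
IRF targets) anchored on the reference condition and averaging across
genes (genes missing a condition are skipped with a warning). Induced
genes satisfy (peak > 3 RPKM AND > 10-fold over t = 0 AND p < 0.01,
with significance supplied externally) OR > 5-fold at 15 min; fold
changes over a zero baseline use a 0.1 RPKM denominator floor.
MAPK-inhibitor series are adjusted per timepoint by the
wild-type/vehicle-control ratio. Gene fitting sets `k0 = 0` and adds
the measured per-condition basal expression as a fixed offset, so
fitted curves reproduce the measured basal at t = 0 exactly. Accepted
logics are those with NLL below a threshold (default 100, exposed as a
parameter since it is a quality cut, not a statistic); a gene is
single-TF only if every accepted logic maps to a single-TF label, and
NFκB–IRF synergy is flagged when any accepted logic contains the
NFκB∧IRF conjunction (five of the 17 logics, with TF1 = NFκB,
TF2 = IRF, TF3 = MAPK). Conditions with a single replicate reuse the
error parameters estimated from the reference condition.

## Problem sizes and numerical defaults

Benchmarks in the test suite run at desk scale by the package's own
choice of problem size: 93 GRSs × 26 conditions × 2 replicates with
1000-sample truth for the error model; 15 genes × 8 logics × 100 starts
for fitting recovery; 3 designs × 3 noise draws for the design study.
Key numerical constants: variance floor 1e-8 RPKM²; observed-value floor
1e-6 in gamma densities; ODE relative tolerance 1e-8; batch-integration
step 0.125 min; L-BFGS-B iteration cap 300 (500 for the global error
fit); null-Kd sentinel 1e6; equivalence and tie tolerances 1e-6.

## Known limitations

* The symbolic deduplication reproduces the published retained count,
  but the authoritative membership list of the 93 was not available for
  calibration; borderline representative choices could differ.
* The identifiability medians depend on unpublished details of the
  original design study (noise composition, alternative scoring scale);
  orderings are robust, absolute medians are not.
* The gamma background branch uses mode-matching; likelihoods of exact
  zeros rest on the 1e-6 value floor.
* Gradient-waveform batch simulation is second-order accurate, not
  exact; the reference `simulate_timecourse` path is tolerance-
  controlled.
* The measured-data workflow consumes preprocessed RPKM tables and
  external significance values; alignment, RPKM computation and
  differential testing are out of scope.
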