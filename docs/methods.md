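# Methods

`eegraph` implements a complete group-comparison pipeline for epoched
resting-state EEG: phase-lag-index (PLI) functional connectivity per
frequency band, weighted brain-graph topology with reshuffled-null
normalization, maximum-weight spanning-tree (MST) topology, gated
nonparametric group statistics, and stepwise linear discriminant
classification.  Because no public recording accompanies the study design
the package targets, every stage is driven and validated by a synthetic
phase-coupled cohort generator that is itself first-class, tested code.
This note records the models, the parameter choices and their reasons, the
numerical decisions, and what the synthetic validation does and does not
establish.

## Connectivity model

For channels `x_i(t)`, `x_j(t)` of one epoch, band-pass filtered and
reduced to analytic phases `phi_i(t)`, the phase lag index is

    PLI(x_i, x_j) = | (1/m) sum_t sign(dphi_ij(t)) |,

with the phase difference wrapped to `(-pi, pi]` before the sign — the
estimator is meaningless without wrapping, and `sign(sin dphi)` is the
implementation (exact zeros contribute 0, so two identical phase series
give PLI 0).  PLI is 0 for symmetric (in particular zero-lag) phase
difference distributions and 1 for a consistently one-sided lag, which is
what makes it robust to volume conduction.

Per-epoch PLI matrices are averaged elementwise over epochs (the absolute
value is taken per epoch, matching the classical procedure).  A
consequence worth stating explicitly: the per-epoch `|mean sign|` has a
finite-sample bias that does **not** vanish with more epochs, only with
longer epochs or faster phase-difference decorrelation.  For 2-s epochs in
the delta band the attainable decorrelation is bounded by the band width,
so the uncoupled baseline in our surrogates sits near 0.25–0.30 — higher
than the ~0.14 typical of published resting-state delta values, whose
recordings decorrelate faster than any strictly band-limited stationary
process can.  All group comparisons in this package are relative, so the
elevated baseline affects neither direction-of-effect recovery nor
calibration.

Numerical choices:

* **Filter.** Zero-phase Butterworth band-pass (order 4, applied
  forward–backward with `sosfiltfilt`).  A zero-phase FIR sharp enough to
  resolve the delta band (0.5–4 Hz at 500 Hz) needs ≥ ~1100 taps and
  cannot fit a 1000-sample epoch, so an IIR design is the only per-epoch
  option with near-unit passband gain (2 Hz tone passes within 5%; 20 Hz
  attenuated by far more than 20 dB in the delta band).
* **Edge trim.** The first and last 100 ms of every epoch are excluded
  from the PLI sums (analytic-signal estimates are unreliable at segment
  edges); configurable via `edge_trim`.
* **Artifact rejection** drops epochs whose absolute amplitude exceeds a
  threshold (default 100, in the recording's native unit, conventionally
  microvolts) with a *strict* inequality: an epoch peaking exactly at the
  threshold is kept.
* The 1024-point / 0.488 Hz spectral bookkeeping of classical pipelines is
  exposed only as `spectral_resolution`; PLI itself is computed in the
  time domain.

Regional summaries use a 12-region map of the 64-channel montage.  The
default map pairs the "right frontal" label with odd-numbered electrodes;
it is reproduced as the upstream study prints it and is fully
user-overridable — the package does not guess the intended hemisphere
convention.

## Graph topology

The brain graph is the complete weighted graph on electrodes with PLI
weights.  The average weighted clustering coefficient uses the
triple-sum form (`C_i = sum w_ik w_il w_kl / sum w_ik w_il`, vertices with
zero denominator contribute 0, implemented as `diag(W^3)` over
`rowsum^2 - rowsum-of-squares`); the characteristic path length averages
shortest-path distances with edge lengths `1/w` over ordered pairs
(denominator `n(n-1)`).  Both are normalized by their means over `n_null`
(default 50) null graphs obtained by uniformly permuting the upper-triangle
weights (the only reshuffle that preserves symmetry and the zero
diagonal); the small-world index is `S = C_hat / L_hat`, with `S > 1` read
as small-world organisation.  Whether the null ensemble should be redrawn
per subject or shared per group is not determined by the classical
description; normalization here is per subject.

## Spanning-tree topology

The MST maximizes total PLI weight (equivalently minimizes the sum of
inverse weights) and is extracted with Kruskal's algorithm under a
deterministic tie-break — candidate edges sorted by weight descending,
then smaller, then larger vertex index — because MSTs are not unique under
ties and reproducibility matters more than which optimum is returned.
Edge weights are discarded afterwards; all tree measures are hop-based:
maximum normalized degree `k*max = max k(v)/n`, mean normalized
eccentricity `e*avr`, maximum normalized betweenness `BC*max` (normalized
by `2/((n-1)(n-2))`), degree divergence `kappa = sum k^2 / sum k`,
normalized diameter `D* = D/(n-1)`, leaf fraction `l* = leaves/(n-1)`, and
tree hierarchy `T_h = l* / (2 BC*max)`.  Two conventions printed
ambiguously upstream are resolved by arithmetic: `kappa` as the printed
ratio of identical sums would be identically 1, so the standard
second-moment/first-moment form is used (consistent with reported
magnitudes of 3–3.7); and a path graph attains hop diameter `n-1` (not
`n-2`), which is also what makes `D* = D/(n-1)` reach exactly 1.

Tree dissimilarity between trees `G` and `H` on the same vertices is

    D(G|H) = (1/n) sum_i log10( mean_{j in N_H(i)} d_G(i, j) ),

zero for identical trees and asymmetric in general.  The group pipeline
compares every subject's tree against the MST of the elementwise mean
control PLI matrix, in the direction `D(subject | reference)`; both
directions are available through the API.

## Group statistics

All group differences use a two-sided permutation test of the absolute
difference of group means (the classical description names no statistic;
this is the simplest location statistic), with add-one smoothing
`p = (1 + #{permuted >= observed}) / (n_perm + 1)` so p is never zero and
the test is valid at its nominal level; default 10 000 permutations.
Multiple comparisons within a measure family use Benjamini–Hochberg FDR at
q = 0.05 (via statsmodels).

The batteries are gated: connectivity tests the global band average first
(P < 0.05) and only examines the 12 within-region and 66 between-region
summaries of gated bands, at a fixed P < 0.01 with *no* FDR — an
asymmetry kept deliberately, mirroring the protocol it reimplements.
Topology applies FDR over the three traditional measures per band, gates
the seven tree measures behind the per-band dissimilarity test (P < 0.05),
then applies FDR over the seven.

## Classification

Features are assembled from whatever the batteries flag: significant
regional PLI summaries, significant traditional and tree measures, and
cognitive subtests with permutation P < 0.05.  Three models are fitted —
cognitive-only, EEG-only, combined.  Selection is stepwise in the SPSS
tradition: the candidate minimizing Wilks' lambda enters when its partial
F-to-enter reaches `F_in` (default 3.84), entered features with
F-to-remove below `F_out` (default 2.71) leave; the final lambda is
converted to chi-square by Bartlett's approximation with df equal to the
number of selected features.  Features that make the scatter matrices
singular (exact collinearity) are skipped with a warning.  Performance is
leave-one-out cross-validation of an LDA (scikit-learn) on the *fixed*
selection — the classical reporting convention, which is optimistically
biased; a nested mode that reselects inside every training fold is
provided as the unbiased variant.  Class priors are proportional by
default with an equal-priors switch.  A model with no usable features
falls back to majority-class prediction and is reported as a null model.

## The synthetic cohort generator

The generator is the package's study-condition definition, not a test
fixture.  Defaults: 27 controls and 13 patients, 64 channels in the
12-region montage, 500 Hz, 2-s epochs, 90 epochs per subject (the
published per-subject average; a per-subject range can be configured), the
five classical bands, and cognitive subtest distributions (four CogState,
six NIH-Toolbox-style scores) drawn as independent normals with the
published group means and SDs.

Signals are sums over bands of mixtures of band-limited analytic
oscillators, synthesised in the frequency domain (complex Gaussian spectra
under Gaussian bumps on positive frequencies only, so phase lags applied
as `exp(-i theta)` are exact at every sample; two warm-up seconds are
trimmed at each end).  Per band and channel:

* a **global** oscillator at the off-diagonal minimum of the pairwise
  coupling matrix (default floor 0.15) — the shared baseline;
* one oscillator per **region**, mixed by its own channels at weight 0.5,
  by every remote region's channels at 0.2 (diffuse long-range synchrony),
  and at 0.4 across the two contrast region pairs (right frontal <->
  right parietal, right frontal <-> left central);
* a **dedicated** oscillator for any pairwise coupling above the floor
  (used by sparse custom configurations; the defaults carry their spatial
  structure at the region level, because a dedicated-pair model cannot
  give a channel with k partners more than a 1/k shared fraction per
  pair — a rank constraint, not an implementation detail);
* an **independent** oscillator at one minus the channel's largest shared
  weight, plus white sensor noise (SD 0.5).

Every oscillator occupies its own random sub-band (FWHM one third of the
band; two thirds for dedicated pair oscillators, whose deep envelope nulls
otherwise degrade phase estimation), so phase differences between
*unshared* components drift through whole cycles within an epoch and the
uncoupled baseline stays near the estimator's floor.  Per-channel lags on
shared oscillators are drawn uniformly from (0.25 pi, 0.75 pi): lags near
zero are invisible to (indeed actively suppressed by) PLI, and this range
keeps expected PLI increasing in coupling strength at the default
operating point.  One global seed expands into per-subject substreams by
counter-based spawning, so cohorts are bit-reproducible and individual
subjects stable under reordering.

The patients' delta-band contrast has two parts, emulating the reported
pattern of a broad decrease with a frontally concentrated deficit: every
shared weight is scaled by 0.9 (diffuse hyposynchrony, producing the
global-average decrease), and the right-frontal structure — within-RF and
the two contrast region pairs — is scaled by 0.7 (the localized
disconnection).  Cognitive scores are independent of the signals: the two
feature domains carry independent information by construction.

With these defaults the control arm shows `C_hat ~ 1.01`, `L_hat ~ 1.00`,
`S ~ 1.01`, MST measures in the ranges reported for real cohorts
(`k*max ~ 0.13`, `BC*max ~ 0.7`, `kappa ~ 3`, `l* ~ 0.55`), and the patient
arm reproduces the signed pattern: lower global delta PLI, lower `k*max`,
`kappa` and `l*`, higher `e*avr` and `D*`.

What the generator does **not** emulate: volume conduction and a forward
model (there is no zero-lag common-source confound, which is exactly what
PLI is designed to reject), eye-blink/muscle artifacts beyond white noise,
1/f broadband background (hence the elevated short-epoch PLI baseline
discussed above), nonstationarity, and any signal–cognition coupling.
Passing tests therefore establish that the *pipeline* recovers planted
effects of realistic size and sign under realistic estimator noise — not
that it would detect them in any particular real recording.

## Problem sizes used in validation

Unit tests run on toy channel sets (3–8 channels) and small graphs, with
exhaustive oracles (all spanning trees, all paths, all label assignments,
triple-loop clustering) up to n = 6–8.  The replicated cohort study behind
the direction-of-effect checks uses 25 seeded replicates of the default
27 + 13 cohort at 10 two-second epochs per subject, delta band, 2 000
permutations per test and 15 null graphs per subject; permutation-test
calibration uses 500 null replicates at 999 permutations.  These sizes are
the package's validation defaults; the study-scale configuration (90
epochs, five bands, 10 000 permutations, 50 null graphs) is the library
default for actual use.

## Known limitations

* The delta-band PLI baseline of the surrogates is high relative to real
  recordings (see above); absolute PLI levels should not be compared
  against published tables, only contrasts and ranks.
* LOOCV on a selection made once from the full table is optimistically
  biased; the nested mode is the honest estimate and is slower.
* The EDF reader requires the optional `mne` dependency; no EDF writer is
  provided (the delimited text format is the package's interchange
  format).
* With the published cognitive score distributions, the synthetic
  cognitive domain separates the groups almost perfectly (the printed
  control/patient means of the card-learning subtest are ~4.5 pooled SDs
  apart, which their own printed rank-test P value contradicts); the
  cognitive-only and combined models therefore saturate near accuracy 1.0
  on synthetic cohorts, and comparisons *between* models at the top are
  dominated by ties.
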