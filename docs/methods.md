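# Methods notes

## Scope and data model

The package operates at the *region-time-series* level: inputs are 36
cortical source signals (18 per hemisphere, standard parcellation
abbreviations, L/R-prefixed) sampled at 1 kHz, with event annotations
(target numerals, distractor numerals, syntactic violations, button
presses) and response logs. Electrode-level processing that precedes
region signals in a real study — source reconstruction, ICA artifact
removal, channel interpolation, re-referencing — is deliberately out of
scope; the synthetic generator produces region signals directly.

## Synthetic signals

Per band, every region carries one oscillator. Free-running regions get
a carrier drawn uniformly from the band interior (15% margin) with a
slow Wiener phase drift (0.003 rad/sample), which keeps >90% of their
power inside the nominal band (verified by periodogram integration).
Regions joined by a `CouplingSpec` share one carrier per connected
component; each non-root member's phase is the carrier plus the
accumulated edge lag plus piecewise-constant von Mises jitter resampled
once per carrier cycle with concentration κ = c/(1−c) for coupling
strength c ∈ [0, 1]. Consequences:

- c = 1 ⇒ zero jitter ⇒ constant lag ⇒ downstream PLI exactly 1;
- c = 0 ⇒ uniform jitter ⇒ one independent fair sign per cycle ⇒ the
  epoch PLI follows the |mean of N signs| null law at the phase level;
- PLI is monotone in c (verified at c = 0, 0.5, 1 with fixed seeds).

Band filtering plus the Hilbert transform smooths the per-cycle jitter,
re-correlating adjacent cycles: measured end to end, the effective
number of independent signs per epoch is roughly half the cycle count.
The null-law property test therefore brackets the observed mean PLI
between the exact law at the cycle count and at half of it. Condition
effects are planted through per-condition strength multipliers.

Signals are sums of band oscillators (4 µV amplitude each) plus 1/f
noise scaled to the oscillator RMS (`noise_sd`, default 1.0), keeping
typical epoch peak-to-peak below the 100 µV artifact criterion so that
rejection trims tails rather than gutting the data.

Events: per-block numeral counts are rounded normal draws
(mean 50.7, SD 2.7) resampled into [45, 57]; the truncation shrinks the
realized SD by ~10%, an inconsistency inherited from the printed
range/SD pair. Onsets are uniform with a 2 s minimum gap; syntactic
violations occur only in the distractor stream (~20 per 6-min block).
Responses: each target numeral is answered with probability p_hit at a
lognormal latency (mean 800 ms, SD 250 ms), each distractor numeral
with probability p_fa; per-condition defaults emulate the qualitative
study pattern (best detection at equal loudness, worst at ±10 dB).
Each simulated participant receives an independent event realization;
no downstream statistic pools events across participants, so sharing
streams (as the real study did) would change nothing.

## Matrix-level generator

Calibration and power studies of the network statistics need thousands
of simulated studies; they consume only averaged PLI matrices. The
matrix-level generator draws each per-epoch edge PLI from its exact
finite-sample null law (|mean of `signs_per_epoch` fair signs|, default
12 ≈ cycles of a ~6 Hz carrier in a ~2 s analysis window), averages
`n_epochs` = 90 of them, and adds a stable participant-by-edge offset
(SD 0.02), independent cell noise (SD 0.01), and planted per-condition
PLI increments, clipping to [0, 1]. These noise scales were fixed once
as plausible for epoch-averaged PLI; with 90-epoch averaging a planted
ΔPLI of 0.1 is a strong effect, which is what the recovery criteria
assume.

## Preprocessing

Filtering uses linear-phase Kaiser-window FIRs (β = 5.65, tap count
6.5·fs/low-edge by default) applied by centred convolution — inherently
zero-phase, which matters because PLI is a pure phase statistic. The
default broadband pass is 0.5–80 Hz with an optional 47–53 Hz bandstop.
Epochs are consecutive, non-overlapping, half-open [start, stop) sample
windows (2048 samples; at 1 kHz, milliseconds and samples coincide); a
window is discarded if any event onset falls inside it (configurable
margin, default 0 — onset-only exclusion; event durations are not
modelled). Artifact rejection drops an epoch when any region's
peak-to-peak range exceeds 100 µV; participants with fewer than 90
clean epochs in any condition are excluded. ERP epochs run −200 to
+2200 ms around onsets, baseline-corrected by the −200–0 ms mean, and
are rejected when |amplitude| exceeds 100 µV after correction (the
symmetric-bound reading of a "±100 µV" criterion, vs the peak-to-peak
reading used for the connectivity epochs).

## Connectivity

Phases come from the analytic signal of the band-filtered epoch; the
in-epoch FIR length is capped below the epoch length, so the delta band
gets a relaxed transition at a 2048-sample epoch (an epoch must still
span one full cycle of the band's low edge). 10% of samples at each
epoch edge are discarded after the transform (configurable) to limit
filter/Hilbert edge effects. sign(0) contributes 0, which makes the
self-PLI exactly 0; matrices are built from the upper triangle and
mirrored, so symmetry is exact by construction. Six bands are computed;
per-epoch matrices are arithmetically averaged per participant ×
condition × band.

## Network statistics

Two-level contrasts use the squared paired t (df 1, n−1) as the
edge-wise F; three-level contrasts use one-way repeated-measures ANOVA
F from sums of squares (df 2, 2(n−1)), cross-checked against an
independent implementation. The permutation null re-randomizes
condition labels independently per participant (sign flips for two
levels, label shuffles for three), falling back to exhaustive
enumeration with a warning when the pattern count is below `n_perm`.
Per permutation, the largest supra-threshold component size is obtained
for *all* grid thresholds in one pass: edges are inserted in decreasing
F order into a union-find structure while recording the running maximum
component edge count, and the value after inserting all edges with
F > K is the null maximum at K. One permutation set is shared across
the grid. p_fwe = (1+#{null ≥ observed})/(1+n_perm) (count/total in
exhaustive mode), "significant" means p_fwe < 0.05 strictly, and the
reported threshold is the largest grid value (default grid 3–10, step
0.1 — matching the one-decimal granularity of reported thresholds)
still yielding a significant component. Edge ranking for the top-32
post-hoc breaks ties by (|difference| descending, region indices
ascending) for determinism; post-hoc t tests are two-tailed and
uncorrected. A trend edge is "monotonic" only when its three condition
means are strictly ordered *and* at least one adjacent pairwise paired
t is significant at 0.05; ties flag "none".

### Calibration of the selection rule (measured caveat)

At any fixed threshold K the component test is an exact level-5% test:
over 100 simulated null studies the rejection rate was within binomial
noise of 0.05 (and 0.027/0.073/0.040 at K = 3/5/8 over 150 studies).
The *final-threshold rule* — declare a finding if any K in the grid
yields significance — is an uncorrected union over ~15 strongly
dependent tests: over 200 simulated null studies it declared a network
in 19% of them, even with permutations shared across the grid. The
procedure-level guarantee is therefore per-threshold, not per-scan; a
test asserting scan-level control at ~5% fails by design and is kept
red rather than weakened. Users wanting scan-level control should fix K
a priori or apply a min-p–style correction across the grid.

## Behavior

Latencies pooled over all participants and conditions (responses within
0–2000 ms of a preceding target) are trimmed to their empirical 5–95%
quantiles; the resulting single window applies to every cell (the
retention share is 89–91% by construction on large samples). A press is
matched to the earliest unmatched target whose window contains it and
is consumed by that match; only unconsumed presses are then matched
against distractor numerals — this guarantees that a perfect responder
generates zero false alarms. d′ uses the 1/(2N) extreme-rate
correction. The recognition index drops items with pooled correct rates
above 95% or below 30% and answers judged known from another source,
then averages per cell; cells with an empty item pool are flagged
undefined rather than scored. The d′ recovery check compares the full
event-simulation path against a direct binomial Monte-Carlo of the same
quantile estimator (the estimator has a small positive finite-sample
bias at 50 trials, so the asymptotic closed form is the wrong target at
that n).

## ERP

Component amplitude is the arithmetic mean over the window at one site,
then over epochs — the mean-window reading of an amplitude-over-a-range
measure; no peak picking. The N2b window (120–280 ms) is early for a
classic N2b but is used as given. The synthetic generator plants no
evoked responses by default, so pipeline-level ERP tables show ~0 µV
background; closed-form tests use constructed Gaussian deflections.

## Problem sizes used in tests

Signal-level tests run scaled designs (2–8 regions, 40–210 s, 200–250
Hz) — large enough for the phase statistics to reach their asymptotics,
small enough to iterate on. Statistical calibration runs 100–200
replicate studies at full inferential scale (n = 27, 630 edges, 90
epochs, 1000 permutations); the analysis drivers use the full 10000
permutations. The full-scale raw-signal study (27 × 5 × 4 blocks × 352 s
× 36 regions at 1 kHz) is a config away but is not exercised wholesale;
the epoch-yield property at that shape is verified on the event stream,
which is what determines it.

## Known limitations

- Free-running oscillator pairs are detuned but band-limited, so their
  per-epoch PLI is biased above the iid-sign null level on short
  epochs; planted zero-strength edges, not background pairs, are the
  correct null reference in the generator.
- The jitter coupling model is a phase model only; amplitude dynamics,
  cross-frequency structure and volume-conduction leakage are not
  simulated (PLI's zero-lag insensitivity is tested analytically, not
  via a leakage model).
- Event exclusion is onset-based; real words have extent, which the
  configurable margin can approximate but does not model.
- The behavioral generator ties button presses to targets/distractors
  only; spontaneous presses are not modelled.
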