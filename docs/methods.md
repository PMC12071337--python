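# Methods

This note documents the models, estimators, numerical choices and known
limitations of `tgephys`. Units are mV, ms, pA, pF and µm throughout; time
series are uniformly sampled (default 20 kHz, dt = 50 µs, within the 2–20
kHz range typical for these recordings).

## The synthetic cohort and what it emulates

Raw whole-cell recordings of marmoset TG neurons are not publicly
deposited, so the package treats the published group-level parameter table
as the definition of the study conditions and ships it as the default
parameterization (`tgephys._tables`): nine electrophysiological groups
(S1–S4, M1–M5) totalling 185 neurons, each with mean ± SEM for capacitance,
RMP, AP width at base (dB), falling-phase dV/dt hump metric, AHP₈₀, AHP
peak, rheobase, evoked train rate, and — for the five mechanically
responsive groups — MA displacement threshold, maximal MA current and
inactivation τ.

Per-neuron parameters are drawn as Gaussians around the group means with
SD = SEM·√N (N = the group's sample size), truncated to each group's
defining feature region. The truncation is deliberate and is part of the
generative model, not a convenience: the groups are *defined* by feature
cutoffs (dV/dt shape, dB ≶ 4 ms, AHP₈₀ ≶ 20 ms, …), so an untruncated draw
could produce a neuron whose features contradict its own ground-truth
label, which would make label-recovery experiments meaningless. Bounds sit
a guard distance beyond the classifier cutoffs, sized at roughly twice the
corresponding feature's measurement SD at the default noise levels (e.g.
double-peak humps ≤ −6.5 mV/ms against the −5 mV/ms cut; M4 AHP₈₀ ≥ 23 ms
against the 20 ms cut), so that measurement error on a borderline neuron
rarely crosses a boundary. RMP is truncated below −36.5 mV because the
cohort emulates recordings that already passed quality control. For
double-peak cells a joint feasibility cap additionally limits dB and the
hump so that the main dV/dt lobe stays at least as deep as the hump — both
falling-phase peaks must be physically resolvable within the available
peak-to-trough voltage drop.

### AP waveform model

The waveform family is phenomenological, chosen as the smallest family that
realizes all observed falling-phase archetypes with analytically
controllable features. A sweep is: baseline at RMP (100 ms), a half-cosine
upstroke (0.7 ms rise, peak +30 mV by default), a repolarization whose time
derivative g(t) = dV/dt is a piecewise cosine-blended profile, and an
exponential AHP recovery with time constant τ_AHP = AHP₈₀/ln 5 (so 80%
recovery occurs exactly at AHP₈₀). Profile templates:

- `linear` — a single lobe 0 → −p → 0;
- `double_peak` — 0 → −p → −p/4 → −p/4 − h → 0 (two dV/dt minima separated
  by a saddle; the hump metric −h is hit exactly by construction);
- `deflection` — 0 → −p → −p − h → −p → 0 with steep edges (a wide flat
  plateau with a shallow internal dip, |h| clipped to [0.2, 1.2] mV/ms).

Two scale parameters — total falling duration T and profile depth p — are
solved numerically (bracketed bisection over T; p is linear in the drop)
so that the repolarization (i) spans the full AP peak → AHP trough drop and
(ii) crosses RMP exactly at the requested dB. One published deflection-group
hump value is positive (+0.3 mV/ms), which is geometrically impossible for
a (minimum − intervening maximum) of a smooth profile; the generator
realizes deflection groups with a small *negative* dip of the same
magnitude, reflecting that the printed value derives from "lowest vs
highest point" readings of a noisy flat plateau.

Current-step sweeps place stereotyped spikes (the same waveform, no AHP
tail) at even intervals: none below rheobase, a single spike at and above
it, or a count interpolating up to round(train rate) in the maximal sweep
for train-firing neurons. MA sweeps are baseline noise below the
displacement threshold; at and above it an inward current rises over 2 ms
and decays as ΔI·exp(−t/τ) toward zero (a configurable sustained plateau
fraction defaults to 0). Peak amplitude ramps linearly from the threshold
step to the deepest step; the amplitude at threshold is
max(6×noise SD, 10% of the maximum) so the fivefold positivity rule can
detect the first responsive sweep. Thresholds of 17–24 µm exceed the 15 µm
reach of the 10-step acquisition protocol, so cohort generation defaults to
a 20-step (30 µm) protocol while `make_piezo_protocol()` keeps the
10 × 1.5 µm acquisition default.

Trace noise is band-limited Gaussian noise (white noise box-filtered over
0.5 ms, rescaled to the requested SD; defaults 0.3 mV on voltage, 2 pA on
current), emulating the low-pass character of filtered recordings. What
the generator does **not** emulate: conductance-based spike dynamics,
stochastic channel gating, electrode/seal artifacts, sweep-to-sweep
sensitization or rundown, slow drift, and any within-neuron correlation
structure beyond shared parameters. Passing recovery tests therefore show
that the estimators invert this waveform family under realistic noise —
not that they are robust to every artifact of real recordings.

## Feature estimators

**RMP** is the mean over the declared pre-stimulus baseline (≥ 10 ms).
**Spike detection** takes the earliest excursion beyond min(RMP + 40 mV,
0 mV); within current-step sweeps, spikes are counted as upward 0 mV
crossings with a 1 ms refractory lockout. **dB** interpolates the last
upward and first downward RMP crossings around the peak linearly between
samples (a 10⁻⁶ mV tolerance guards against baseline/mean rounding at the
ULP level).

**Falling-phase shape.** The dV/dt profile between the AP peak and the AHP
trough is estimated with Savitzky–Golay derivatives (cubic) at two scales:
a *light* window (segment length/16) for reported values and a *heavy*
window (length/4) for extremum detection; both scale with the falling-phase
duration, making the shape decision invariant to uniform time rescaling.
The trough itself is located as the earliest entry into the trough basin
(first sample within 0.5 mV of the smoothed post-AP minimum), because slow
AHPs are nearly flat around their minimum and a plain argmin jitters by
milliseconds under noise. dV/dt minima are accepted above a prominence
threshold of max(2.5 mV/ms, 12% of profile depth). A profile is
`double_peak` when two minima exist whose hump (second minimum minus
intervening maximum, on the heavy profile) is ≤ −5 mV/ms **and** at least
25% of the second minimum's depth — a genuine hump rises well toward zero
between the peaks, whereas differentiation ripple on a steep plateau does
not. Otherwise the fraction of the falling phase spent below half the
profile minimum separates `deflection` (flat-bottomed; measured ≥ ~0.78 on
clean plateaus) from `linear` (single lobe; ~0.47–0.54), with the cut at
0.68. Reported hump values come from the light profile at the robustly
detected locations. A fixed small smoothing window (the first design
considered) leaves ~1.2 mV/ms of derivative noise at the default 0.3 mV
voltage noise and produces spurious extrema; the two-scale scheme keeps the
shape assignment stable in ≥ 95% of noisy draws (measured: no flips in
504).

**AHP.** The post-AP segment is box-smoothed with a window adapted to a
rough first-pass recovery time (AHP₈₀/40, capped at 2 ms), the trough value
is refined parabolically, and the trough *time* is refined by extrapolating
the early rising branch back to the trough level — the falling phase enters
the trough with zero slope while the recovery leaves with finite slope, so
the kink, not a parabola vertex, marks the trough. AHP₈₀ is the
interpolated crossing of the 80%-recovery level measured from that time;
undershoots shallower than 1 mV report (0, 0); recoveries cut off by the
sweep end are censored and flagged. The closed form AHP₈₀ = τ·ln 5 is
recovered within 0.5% across τ ∈ [2, 100] ms at 20 kHz.

**MA measurements.** Baseline noise is the SD of the detrended (least
squares line removed) pre-stimulus window. A sweep is responsive when its
baseline-subtracted inward peak within the stimulus hold window is
≥ 5 × noise SD (boundary inclusive) *and* strictly positive — the strict
positivity keeps the rule meaningful at exactly zero noise, where 0 ≥ 5·0
would otherwise label flat sweeps responsive. At the neuron level,
responsiveness requires *persistence*: at least two responsive sweeps, with
the threshold taken at the first responsive sweep that is followed by
another (or is the deepest). A genuine response persists at every deeper
displacement, whereas a single noise excursion (measured per-sweep
false-positive rate ≈ 10⁻³ under default noise, fat-tailed because the
noise estimate itself fluctuates) trips one sweep; persistence drops the
per-neuron false-positive rate by three orders of magnitude. On noise-free
or single-sweep data this reduces to the plain first-responsive-sweep rule.
Decay fitting is nonlinear least squares of ΔI·exp(−t/τ) from the current
peak to stimulus offset, initialized from a log-domain linear regression
and bounded positive; a non-decaying window (nonnegative trend slope)
raises a no-decay error instead of returning a meaningless τ. τ is fitted
on the deepest responsive sweep (largest signal-to-noise; the source
protocol does not state which sweep was fitted). Current density is the
per-neuron ratio peak/capacitance; group densities are means of per-neuron
ratios, not ratios of group means (the two differ, and published densities
are consistent with the former).

## Quality control

Four discard rules: measured RMP more depolarized than −35 mV
(reading "less than −35 mV" as *less hyperpolarized*; the literal numeric
reading would discard every healthy neuron), |Rs drift| > 20% of the
starting access resistance, leak > 100 pA, input resistance < 100 MΩ. All
comparisons are strict, so exactly-at-threshold recordings pass; reasons
accumulate rather than short-circuit.

## Classification

The decision tree splits on dV/dt shape first, because the published dB
ranges of the groups overlap (S-groups "> 5 ms", S4 "> 4 ms", M1 "< 6 ms")
while the shape classes partition the table consistently:

1. `double_peak` → S3 if MA-responsive, else S2 if it fires trains, else S1;
2. `deflection` → M2 if MA-responsive, else M1;
3. `linear`, dB > 4 ms → S4, which must be MA-negative and train-negative
   (else `UNCLASSIFIED`);
4. `linear`, dB ≤ 4 ms, MA-responsive → M3 if the AHP is negligible
   (AHP₈₀ < 5 ms and |AHP peak| < 5 mV), else M4 if AHP₈₀ > 20 ms, else M5;
5. anything else → `UNCLASSIFIED` — an explicit output, never an error
   (the taxonomy does not cover, e.g., narrow-AP nonresponders).

All cutoffs are estimator parameters. Train firing requires ≥ 3 spikes in
a sweep (two-spike neurons are not trains, matching how the source table
footnotes such cells while reporting no train rate). S3's occasional train
firing is not used as a gate — MA-responsiveness already separates S3 from
S1/S2. The classification report also tallies responders, because the
source's text (72/185) and table (82/185 summing the MA-positive rows)
disagree; the package reproduces the table logic and surfaces the count
rather than resolving the discrepancy.

On noise-free default cohorts the extracted features recover 100% of
generating labels across seeds; at default noise, concordance is 96.8–99.5%
over seeds 1–10 (the residual errors are M4/M5 flips within ~2 ms of the
AHP₈₀ = 20 ms cutoff, where the recovery slope of a ~8 mV AHP limits timing
accuracy to ~1–2 ms at 0.3 mV noise).

## Statistics

Group summaries are mean ± SEM (SD/√n; single-member groups carry no SEM).
One-way ANOVA uses the classical F statistic with explicit degenerate-case
handling (all values identical → F = 0, p = 1; zero within-group variance
with distinct means → F = ∞, p = 0). Post hoc comparisons are Tukey HSD
(default) or pooled-variance pairwise t tests with Bonferroni correction
(p × number of pairs, capped at 1); the report names the method used. The
type-I error rate of the omnibus test calibrates to 5% ± 2% over 1,000 null
replicates in the test suite.

IHC composition works on per-section counts: class percentages per section,
averaged into biological replicates (one replicate = one animal's ganglion,
3–5 sections each), mean ± SEM across replicates. Marginal marker
percentages are sums of the joint classes containing the marker
(CGRP = CGRP⁺/trpV1⁻ + CGRP⁺/trpV1⁺; trpV1 = CGRP⁺/trpV1⁺ + CGRP⁻/trpV1⁺),
exact per replicate. The MrgprD and PV panels have no published joint
structure with CGRP/trpV1 and are treated as independent — an assumption,
not an inference. The multinomial section generator draws each section
independently; overdispersion between animals is not modeled.

## Problem sizes and determinism

Default test and acceptance runs use the full 185-neuron cohort at 20 kHz
(the study's own scale); the heaviest check — label concordance at default
noise across ten seeds — regenerates and reanalyzes ten such cohorts.
Every stochastic step derives from a single integer seed through
`numpy.random.default_rng`; identical seeds yield bit-identical bundles and
byte-identical CSV artifacts.

## Known limitations

- The waveform family is a measurement testbed, not a biophysical model;
  parameters like the upstroke rise time and spike shape within trains are
  stylized.
- AHP₈₀ near the 20 ms cutoff is information-limited at default noise (see
  above); classification of genuinely borderline M4/M5 cells is noisy in
  real data too.
- The deflection/linear split relies on a flat-fraction statistic
  calibrated on this waveform family; very short deflection APs (dB < 3 ms)
  are not generated and were not validated.
- ABF reading maps sweeps only (no epoch/stimulus interpretation) and
  requires the optional `pyabf` dependency.
- Between-panel IHC correlations and per-animal overdispersion are not
  modeled.
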