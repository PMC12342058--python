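# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic-data generator does and does not
emulate, and the limitations that follow.

## Synthetic polysomnography model

**Hypnogram process.** Vigilance states follow a semi-Markov chain over
{WAKE, NREM, REM} on 10 s epochs. Dwell times are geometric per epoch
with a mean that depends on state and light phase (12:12 LD, ZT0 =
lights-on), which is the simplest process matching exponential-like
bout-duration statistics. REM is entered only from NREM — the standard
rodent staging constraint — and parameter validation rejects any direct
WAKE→REM weight. Forced-wake windows (sleep restriction over ZT0–6;
defeat sessions early in the dark period) clamp every epoch to WAKE.

Light-phase dwell means are calibrated so that expected light-phase
sleep matches the reported sleep-lost magnitudes for a 6 h restriction
(~153 min NREM / ~20 min REM for males, ~147 / ~19 for females per 6 h).
Dark-phase dwells encode the qualitative sex contrasts: males cycle
through more, shorter NREM bouts (especially in the dark); females hold
REM longer. Four presets (`male/female × resilient/susceptible`) add the
stress phenomenology: susceptible females and resilient males lengthen
NREM bouts on the post-defeat day (dwell × 1.5 and × 1.4), post-defeat
arena bias is +0.25 cm/step (resilient) or −0.25 (susceptible), males
carry 18% higher NREM delta amplitude, and resilient males a larger
parietal/frontal delta ratio (1.3 vs 1.1). A rebound multiplier
(NREM dwell × 1.2) applies to the 18 h following forced wake. Defeat-day
and post-defeat multipliers are calibration knobs: the study design they
emulate reports only baseline, post-restriction and post-defeat sleep,
so their values are chosen once to produce clear qualitative contrasts
and are not themselves empirical claims.

**Homeostat.** A Process-S variable s ∈ [0.1, 1.0] rises toward the
upper bound during wake with τ_rise = 8 h and discharges toward the
lower bound during NREM with τ_fall = 2 h (exponential closed forms per
epoch; REM holds s by default, `rem_s_mode="decay"` gives a slow 4·τ_fall
decay). s at epoch onset scales NREM delta amplitude linearly
(amp = 45 µV · delta_scale · (0.4 + 0.6·s_norm)), which produces the SWA
rebound after restriction and the early-light-phase SWA peak.

**Signals.** EEG (100 Hz, two leads) is a per-epoch sum of unit-rms
Gaussian noise confined to delta (0.5–4 Hz), theta (6–10 Hz) and
broadband (10.5–30 Hz) bands, scaled to state-dependent amplitudes
(wake: 6/5/14 µV rms; NREM: s-scaled delta/8/7; REM: 4/8/5 plus a 15 µV
rms theta sinusoid on an exact 0.1 Hz bin). EMG is white noise with
state-ordered scale 20/7/2 µV (wake/NREM/REM). Artifact epochs carry
±800 µV clipping bursts. Because each band component is normalised to an
exact per-epoch rms, band powers are analytically known
(`truth_band_powers`), enabling a fast signal-free route for
Monte-Carlo replicate studies. No 1/f background, spindles or
micro-arousals are modelled: the signals are sufficient for a
band-power pipeline, not for waveform-level analyses.

**Arena.** Trajectories are biased random walks at 10 Hz (step σ =
0.8 cm) in a 30×30 cm arena with wall reflection and a solid 9×9 cm cage
footprint against one wall; the target trial adds a constant drift
toward the cage. Expected interaction ratio is increasing in the bias,
and zero bias gives statistically identical trials.

**Determinism.** Every generator output is a pure function of
(parameters, schedule, seed). Cohorts derive per-subject child seeds
from `numpy.random.SeedSequence(master_seed).spawn`, so manifests and
files reproduce byte-identically.

## Automatic staging

The stager encodes the classical visual criteria as an ordered rule:
artifact screens, then EMG RMS above the wake threshold → WAKE, then
theta/delta > 1.5 with sub-threshold delta → REM, then delta above the
NREM threshold → NREM, else WAKE. Thresholds default to per-recording
quantiles (EMG 0.60, delta 0.55 of the epoch feature distributions),
making decisions invariant to amplitude scale. Because the generator's
exact-rms synthesis creates point masses in the feature distributions, a
raw quantile can coincide with such a mass and split it on
floating-point noise; calibration therefore moves each threshold to the
midpoint of the empirical gap above the quantile value — a negligible
adjustment for continuously distributed features. Artifact screens flag
epochs whose absolute amplitude exceeds 500 µV on any channel or whose
total power sits more than 6 SD above the recording mean. No transition
smoothing is applied by default (scoring is epoch-wise); a 3-epoch
majority filter is available behind a flag. Trailing partial epochs are
dropped, never padded. The frontal lead stages; the parietal lead feeds
lead-specific SWA tables.

The ~100% truth agreement the acceptance run reports reflects the clean
state separation of the synthetic signals. It validates the pipeline
plumbing and the rule logic, not performance on real EEG, where
state-ambiguous epochs, drift and 1/f background would lower agreement;
the 95% bar mirrors the inter-scorer criterion used for human scorers.

## Spectral conventions

10 s epochs at any fs give native 0.1 Hz FFT resolution; no zero
padding. The default window is rectangular (raw FFT), with a
power-corrected Hann option. Power is a one-sided density satisfying
Parseval (band integrals in µV²). Band edges are half-open [lo, hi) so
delta + (4–30) partitions the 0.5–30 Hz total exactly; `closed=True`
restores closed intervals. Normalized SWA divides per-epoch delta power
by the baseline day's **NREM-only** mean — SWA is defined during NREM
throughout — so the baseline self-normalizes to exactly 100%; callers
wanting an all-epoch divisor can pass any baseline series. Slow-wave
energy accumulates delta power × 10 s over NREM epochs only, and is
reported both raw and as % of baseline-day SWE. Artifact epochs are
excluded from every spectral aggregate.

## Architecture and behavior conventions

All ZT windows are half-open [start, end); an epoch belongs to the
window containing its onset. Bouts are maximal same-state runs; artifact
epochs break bouts and are excluded from state minutes (reported
separately, so minutes always partition the window). A bout spanning the
light/dark boundary belongs to its onset phase — per-phase minute totals
use epoch-level phase and are unaffected. Empty bout groups report n = 0
with missing (never zero) mean duration. "Total sleep" is NREM + REM.
Negative sleep lost is possible and warned about, not clipped.

The interaction zone measures 15 cm from the cage *boundary*: a 15 cm
radius from the centre of a 9 cm cage would barely clear the cage
itself; centre-distance mode is available. Trajectories are resampled to
a uniform 10 Hz grid (inclusive of the final sample) before time
integration. The tracked point is the supplied coordinate stream; no
body-part model.

## Statistics

The mixed RM-ANOVA supports 0–2 between factors crossed with one within
factor. Sums of squares come from the equal-weighted factorial (Möbius)
decomposition of the cell × time mean grid scaled by the harmonic mean
cell size — the unweighted-means solution, exact for balanced designs
(verified against a GLM projection oracle and against an independent
mixed-ANOVA implementation). Between effects test against the
subjects-within-groups stratum, within effects against the
time × subjects stratum. No sphericity correction is applied, matching
the reporting style the pipeline reproduces; the output flags this.
Degenerate all-equal data returns F = 0, p = 1.

Holm–Šídák compares the i-th smallest of k p-values to
1 − (1−α)^(1/(k−i+1)) and stops at the first failure. Mann–Whitney U
uses midranks; p is exact by full enumeration for combined n ≤ 8,
otherwise a tie-corrected, continuity-corrected normal approximation
(the method used is reported). The sample-size calculation uses the
two-sample, two-sided normal approximation
n = ⌈(z_{1−α/2} + z_{1−β})² · 2σ²/δ²⌉ with a floor of 2 — the variant
that yields exactly 6 per group at σ = 14.6, δ = 25; the exact
noncentral-t iteration (`method="exact-t"`) is one animal more
conservative (7) and is provided for comparison. Shapiro–Wilk delegates
to scipy; constant samples gate False with NaN p. All tests are
two-sided at α = 0.05.

## Workflow

`run_study` chains generate → behavior → stage → spectral →
architecture → statistics and is bit-reproducible from (config, seed);
any stage failure raises a stage-named error. Exclusions (artifact
fraction > 5%, strict; post-defeat SIR in the closed band [0.9, 1.1])
remove subjects from sleep tables only — behavioral tables keep
everyone — and every exclusion is traceable in the audit table. The
ANOVA block degrades its between-factor set (sex × phenotype → sex →
none) when a cell has fewer than 2 subjects so small cohorts still
report statistics. Light/dark panels use [ZT0, 12) / [ZT12, 24) and
hourly bins. Signal-free mode (`synthesize_signals=False`) substitutes
truth hypnograms and analytic band powers for rendered EEG; the
replicate power analysis in the acceptance suite runs 50 cohorts this
way with 2 subjects per sex × phenotype cell, while the full-signal path
is exercised on smaller smoke cohorts — problem sizes chosen to keep the
default runs quick on a single CPU.

## Known limitations

* Synthetic EEG separability overstates real-world staging accuracy (no
  1/f background, no ambiguous transitional epochs).
* Dwell times are geometric; real bout-duration distributions are
  heavier-tailed.
* Defeat-day and post-defeat generator multipliers are qualitative
  calibration knobs, not fitted parameters.
* No estrous-cycle modulation, no aggressor-behavior model, no
  sleep-onset/REM-latency metrics, no spindle or slow-oscillation event
  detection, and no EDF writing (EDF reading is available via mne).
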