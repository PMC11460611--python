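# Methods

## Scope and design

The package has three layers: deterministic signal synthesis from an
audiogram, stochastic simulation (virtual listeners, longitudinal cohorts),
and a statistics engine. The synthesis and statistics layers are exact
computations; the simulation layer defines the study conditions under which
the statistics are exercised. Everything is reproducible from a single
seed: root seeds are split into named substreams (outcome draws, resolved
subjects, ages; the two noise generators of the synthesizer) via
`numpy.random.SeedSequence`, so changing one consumer never perturbs the
others.

## Audiogram rules

An audiogram is a strictly ascending set of at least two test frequencies
in 0.125–20 kHz with thresholds in [−10, 120] dB HL; rows are canonically
sorted on construction. The inclusion screen passes iff every threshold is
≤ 90 dB HL (the bound is on exclusion, so 90 exactly passes).

**Hearing-loss band.** The band runs from the lowest to the highest test
frequency whose threshold exceeds 25 dB HL; interior dips below the
criterion do not split it. The 25 dB criterion is the standard clinical
boundary between normal hearing and mild loss, and is configurable — no
published rule pins it down. A single-frequency band is widened to a
half-octave around that frequency, since a zero-width passband cannot carry
noise energy.

**Smoothing parameter.** The filter-sharpness value s ∈ [1, 100] is mapped
from the absolute difference d between adjacent thresholds:

* d < 20 dB: s = round(100 − 2d) — slight differences get proportionally
  high smoothing (d = 0 ↦ 100, d = 10 ↦ 80);
* d ≥ 20 dB (a "significant" step): s = clamp(round(10·(40 − d)/20), 1, 10)
  — the conventional low range 1–10.

The map is monotone non-increasing, anchored at the d = 10 ↦ 80 worked
example, and deliberately discontinuous at d = 20 to mirror the
significant/slight dichotomy it encodes. Differences use |d|; the direction
of a threshold step does not change how sharp the filter should be.

## Synthesis

Filters are realized as frequency-domain gains (FFT multiply), which makes
the passband exactly unity and the stop band exactly zero, and keeps
repeated application idempotent. Skirts are Hann-shaped in log-frequency
with transition width (s/100)·(1/3 octave) per side, i.e. 1/3 octave at
s = 100 down to 1/300 octave at s = 1; the outermost audiogram-derived
smoothing values govern the two skirts of the hearing-loss band.

The v1 envelope applies gain (threshold(f) − 25) dB, interpolated linearly
in log-frequency between audiogram points and clamped beyond them. Because
gain is applied to amplitude, the PSD difference between two in-band
regions equals the threshold difference in dB.

The tinnitus band (0.9·pitch, 1.1·pitch) uses *inner* skirts: the
transition sits inside the band edges (shrunk if both sides cannot fit), so
v2 carries zero energy outside the ±10 % limits. This is what guarantees
the composite's PSD argmax stays inside the pitch band: with outer skirts a
steeply rising audiogram envelope pushes the summed spectrum's maximum just
past the upper edge.

**Mixing.** v3 = v1 + g·v2 with g² = (P_ref·10^(b/10) − P_band(v1)) /
P_band(v2), b = 6 dB by default. In `mix_v3` the reference P_ref is v1's
own level inside the pitch band (so the band boost is b dB exactly); the
end-to-end synthesizer instead references v1's global PSD maximum, which
makes "peaks at the tinnitus pitch" hold for every audiogram shape, at the
cost of a larger-than-b in-band boost when the loss keeps rising above the
pitch. No published value exists for the v2:v1 ratio; 6 dB is the package's
choice and configurable. Output is peak-normalized to −1 dBFS; absolute
presentation level is a playback-device matter and out of scope. A 50 ms
equal-power crossfade blends the tail into the head for seamless looping.
PSD estimation everywhere is Welch, 4096-point segments, 50 % overlap —
fixed so spectrum reports are reproducible.

Complex (non-tonal) tinnitus is handled identically to tonal: the pitch
match frequency serves as the band center.

## Virtual listener and procedures

The observer model is minimal signal-detection psychophysics: on each 2AFC
trial the listener picks the option whose attribute is closer to ground
truth after adding N(0, σ²) noise to each distance, and with probability
`lapse_prob` answers uniformly at random. Level distances are in dB
(σ = `comparison_noise_db`); pitch distances are in log-frequency with one
octave treated as 10 dB-equivalent units, so one σ covers both tasks.
Contralateral 30 dB SL presentation and 1 s tone durations are recorded in
traces for protocol fidelity but do not enter the decision model.

**Pitch match.** Half-octave grid 125·2^(k/2) Hz, k = 0…14 (top point
16 kHz, the last half-octave step inside the 20 kHz test bound — behavior
at the upper boundary is grid-clamped, a package choice). First pair
0.5/4 kHz; the chosen frequency is then paired one octave onward in the
direction of choice; a rejected step (or grid boundary) switches to
half-octave bracketing with reversals. Termination: the same frequency
re-chosen against three alternatives (not necessarily consecutively).
Travel choices do not count toward termination — this guarantees both
neighbors of the percept are probed, and makes the noiseless procedure
provably return the grid point nearest the true pitch (verified
exhaustively in tests). Cap: 200 trials, then a convergence error.

**TLL.** Ascending pairs (L, L+5) from threshold level; choosing the upper
tone advances L. Three choices of one level terminate; a listener whose
tinnitus is at threshold yields 0, and absent tinnitus scores 0 by
convention. **MML.** Ascending from 0 dB in 5 dB steps; the first level at
or above the (noise-perturbed) true masking level is returned; above 120 dB
the listener is declared unmaskable. **RI.** One 60 s narrowband stimulus
at MML + 10 dB; the post-offset report (decreased / same / increased) maps
to positive/negative; a lapse substitutes a uniform draw over the three
responses, so ground-truth recovery at lapse λ is (1−λ) + λ/3 for RI+
listeners.

## Cohort generator

Per subject and outcome, the four timepoint values are one draw from
N(μ, Σ) with the published cell means/SDs and Σ = D·R·D, R compound
symmetry with ρ (default 0.5 — the study reports no covariance
information, so ρ is a config knob and the acceptance checks sweep
0.3/0.5/0.7). Draw → round to grid → clamp, in that order: TLL/MML to the
5-dB audiometric grid with floor 0; THI to even integers in [0, 100]; VAS
to 0.1 in [0, 10]. Eleven randomly chosen RI+ subjects get TLL = MML = 0 at
month 6 (the study zeroed exactly these two measures for subjects whose
tinnitus resolved; their questionnaire scores remain drawn). Audiograms are
per-frequency Gaussian draws from the group threshold table, truncated to
[−10, 90] and rounded to 5 dB. Ages are Gaussian draws clipped to each
group's reported range; the tinnitus-frequency table's mean/SD is used with
clipping to its printed 1–8 kHz range (the printed mean 7.2 ± 0.7 and range
are mutually inconsistent; the generator keeps both as stated).

**What the generator does and does not emulate.** It reproduces cell means,
SDs, group sizes, discretization and the resolved-subject coding; it does
not model dropout (none was reported), learning/placebo dynamics beyond the
printed means, floor/ceiling response styles, or any true covariance
structure beyond compound symmetry. Two consequences matter for
interpreting tests:

* cells whose mean sits within ~2 SD of a scale bound (e.g. VAS
  7.3 ± 1.9 against the ceiling of 10) lose up to ~0.07 of their mean to
  clamping; moment-recovery tests therefore check raw draws for all cells
  and discretized draws only away from the bounds;
* the published RI− cell means imply a real, if modest, within-group
  decline. A pooled time ANOVA computed from those means has expected
  F ≈ 6.4 (TLL) and ≈ 14.8 (MML) at df (3, 112), so simulated RI− cohorts
  produce *significant* within-group tests for TLL, MML and the
  severity/discomfort scales in most replicates — the original report's
  non-significant RI− F values cannot be obtained from its own printed
  means under any ρ. The corresponding acceptance check is left failing
  with this analysis rather than tuned around; THI, attention and sleep do
  come out non-significant in the majority of replicates.

## Statistics

All sums of squares are computed from cell totals (weighted-means
split-plot), which handles the unequal group sizes; the decomposition is
exact (SS conservation tested to 1e-9 relative) and matches
`pingouin.mixed_anova` to machine precision. Between-group F uses
subjects-within-groups as error, df (1, N−2); time and interaction use the
within-subject residual, df (3, 3(N−2)). No sphericity correction is
applied (none was used in the source analysis); α = .05 two-sided
throughout.

Both the proper mixed decomposition and the pooled one-way time ANOVA
(timepoint as a between-cell factor, error df 4n−4) are provided. The
pipeline uses the mixed design for between-group effects and the pooled
convention for within-group effects, because the latter's df pattern
(3, 148)/(3, 112) is what the published within-group statistics print —
kept as a convention, not endorsed as the better test. Tukey HSD refers
q = |mᵢ−mⱼ|/√(MSE/n) to `scipy.stats.studentized_range` (its numerical
integration matches published table values, e.g. q₀.₀₅(4, 60) = 3.74);
in the pipeline it is applied to the four timepoint means within each group
using the pooled ANOVA's error term. The effect size is
r = √(F/(F+df₂)); the published r values alongside the study's F statistics
match no standard formula (e.g. F(1,65) = 15.45 would give r = 0.44, not
.51), so the package reports its own and makes no attempt to match them.

**Degenerate inputs.** Zero pooled variance with equal means returns
t = 0, p = 1; with unequal means it is an error. Zero error mean-squares
yield F = 0 when the effect SS is also zero, else F = ∞ with p = 0.
Missing timepoints raise an unbalanced-design error rather than being
imputed.

## Problem sizes

Replicate counts are chosen to keep Monte-Carlo error well below the
margins being tested: 200 cohorts per ρ for the headline-inference checks
(binomial SE ≈ 1.5 % at a 95 % criterion), 5000 cohorts for the type-I
error check (SE ≈ 0.3 % against a ±1 % band), 1000 seeds for the RI
recovery rate, 100 randomized audiograms at 1 s duration for the spectral
peak property, and 300 staircase repetitions per noise level for the
monotone-robustness check.

## Known limitations

* The observer model has no octave confusion, loudness recruitment, or
  threshold microstructure; real pitch-match distributions are broader.
* dB SPL calibration, headphone transfer functions and the phone-volume
  dosing protocol are out of scope; levels are dB HL/SL abstractions.
* Compound symmetry is an assumption of convenience; real longitudinal
  covariance likely decays with lag, which would mainly affect the
  within-subject error terms.
* The pooled time ANOVA treats repeated observations as independent and is
  anticonservative under positive ρ; it is included as the published
  convention and clearly labeled.
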