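# Methods

## The beat-train model

Sinus rhythm is generated by integral pulse frequency modulation (IPFM): a
beat is emitted at every unit crossing of ∫m(t)dt with

    m(t) = (HR/60) · (1 + d_vlf sin(2π f_vlf t + φ₀)
                        + d_lf  sin(2π f_lf  t + φ₁)
                        + d_hf  sin(2π f_hf  t + φ₂)),

followed by multiplicative white RR jitter with coefficient of variation
`rr_jitter_cv`. The integral is evaluated in closed form and crossings are
refined by vectorized Newton iteration, so the unmodulated train is exact
to floating-point precision (a 300 bpm, 60 s train is exactly 300 beats of
200 ms). Phases are drawn uniformly per seed; the generator is a pure
function of its parameters and seed.

IPFM was chosen because the physiological literature for this preparation
specifies only the band locations (rat LF 0.3–0.6 Hz, HF 0.6–2.5 Hz), not
a generative model, and IPFM gives directly controllable band powers: a
rate-modulation depth d at frequency f yields an RR modulation of amplitude
≈ d·RR₀ and band power ≈ (d·RR₀)²/2.

**Why a VLF term.** Published rat HRV values are internally informative:
SDNN ≈ 21 ms coexists with LF ≈ 2 ms², HF ≈ 6–9 ms² and RMSSD ≈ 4.5 ms at
RR₀ ≈ 175–190 ms. Two in-band sinusoids plus white jitter cannot produce
that joint pattern — LF+HF+jitter account for ~14 ms² of the ~430 ms²
total variance. Most rat RR variance sits below 0.3 Hz, so the generator
carries a very-low-frequency drift term (default 0.05 Hz) whose depth is
solved from the SDNN target after the in-band and jitter contributions are
subtracted (`autonomic_from_targets`). With the defaults this reproduces
SDNN ≈ 21 ms, RMSSD ≈ 4.6 ms, LF/HF ≈ 0.28 simultaneously.

## Arrhythmia injection

*APBs*: Poisson counts at `apb_rate` events/h. A chosen sinus beat is
advanced to `apb_prematurity` × the preceding sinus RR (default 0.6), its P
morphology flagged mismatched; the following beat keeps its original time,
i.e. a full, non-resetting compensatory pause. This keeps all downstream
sinus times unchanged, so ground truth stays simple.

*AF episodes*: Poisson counts at `af_rate` episodes/24 h (an explicit
`n_episodes` override exists for fixtures), durations lognormal with
configurable mean/sd. Within an episode RR = `af_rr_scale` × local sinus RR
× lognormal(CV = `af_rr_cv`); defaults 0.7 and 0.15 operationalize "rapid,
irregular". No quantitative rat AF RR statistics are published for this
preparation, so these are exposed defaults, not measurements. Episodes
shorter than 3 beats are extended to 3. The local sinus reference is the
median of an equal number of sinus intervals flanking the episode window on
each side: slow VLF drift across an episode then biases the generator's
reference and the classifier's reference identically, which is what makes
exact round-trip recovery on clean data possible. Ground-truth episodes are
re-derived from the final label array after every injection, so their end
times always follow the first-subsequent-sinus-beat rule, whatever the
injection order.

Stimulation-induced episodes (the pacing protocol simulator) default to
the duration statistics 123.2 ± 36.4 s; spontaneous episodes in the cohort
defaults are shorter (15 ± 5 s) to fit desk-scale recordings.

## Compressed-day convention

Real telemetry covers 72 h per period; desk-scale recordings default to
600 s, with each recording standing for one 24 h interval. Injection rates
are multiplied by the compression factor (86400/600 = 144) so per-24 h
event counts are preserved, and burden counts are normalized by the
represented duration. One side effect is that the arrhythmic *time
fraction* of a compressed recording is exaggerated ~144-fold relative to a
real day. Two desk-scale choices follow:

- `BurdenSummary` reports both the raw `mean_hr_24h`
  (60·(n_beats−1)/duration) and `mean_sinus_hr`, computed over
  sinus-bounded RR intervals only. The report tables and trend tests use
  the sinus metric, because at compressed scale the raw metric is inflated
  in the paced arm by the fast AF beats — an artifact of compression, not
  of the physiology being emulated.
- `HRVConfig.min_nn_fraction` defaults to 0.4: paced-arm epochs can be
  20–35% AF by time, and 0.4 of a 300 s rat epoch still leaves >500 NN
  intervals per epoch.

## Waveform rendering and detection

Beats are rendered as Gaussian P/Q/R/S/T templates (R = 1 mV, σ = 4 ms;
P = 0.2 mV at −40 ms; T = 0.15 mV at +30 ms; rat-narrow QRS ≈ 16 ms). AF
beats omit the P template; APBs carry an inverted P (an ectopic atrial
focus in lead II), which makes "P present but morphologically different"
a signed-correlation property rather than a fragile width difference.

QRS detection is the classic chain — band-pass (10–80 Hz, zero-phase),
differentiate, square, 20 ms moving-window integral, adaptive two-level
thresholding with a 60 ms refractory — with fiducials refined to the
band-passed R maximum. On clean rendered traces detection is exact in
count and within ±5 ms; at SNR 20 dB (noise sd 0.1 mV) sensitivity and
PPV stay ≥ 0.99.

P assessment compares the pre-QRS window (−72…−24 ms, ±2 ms lag search)
with a median sinus P template learned from rhythm-regular beats of the
same recording. Two statistics are combined: the fitted template amplitude
on the raw trace (a matched filter, the noise-optimal estimate) and the
normalized correlation on a 12 ms boxcar-smoothed trace (shape check).
Presence requires |corr| ≥ 0.5 and |amplitude| ≥ 0.55 of the sinus P;
morphology matches only when the signed correlation ≥ 0.8. At rat AF rates
the previous beat's T wave can occupy the entire pre-QRS window, so window
samples within 72 ms after the previous R are masked out, and a beat whose
window retains < 75% of its samples is scored "no assessable P" — which at
those rates is the physiologically correct reading. Consequence: an APB
needs a coupling interval ≥ ~130 ms for its P to be assessable; at the
default sinus rates APB coupling (~105–120 ms) reads absent-P, and the
classifier still labels such beats APB through the short-run rule.

## Classification

Candidate AF runs are maximal runs of absent-P beats. A run is AF iff it
has ≥ 3 beats (fixed by the definition), its median within-run RR is
< 0.75 × the local sinus median, and its within-run RR CV is > 0.08. The
coupling interval from the last sinus beat is *excluded* from both run
statistics — including it would bias a perfectly regular fast run toward
"irregular". The local sinus reference is a two-sided flanking median over
11 morphologically normal intervals (P present *and* matching — APB
coupling/compensatory intervals would otherwise contaminate it), with a
global-median fallback. Absent-P runs failing the AF criteria are labelled
APB beat-by-beat; isolated premature (RR < 0.85 × local median) beats with
mismatched morphology are APBs; RR < 50 ms flags an artifact.

*Gap tolerance*: per-beat P detection is noisy (~1% false presence per AF
beat at SNR 20 dB), and a single spurious flag would otherwise split one
episode into two. Gaps of ≤ 2 beats between two validated AF runs are
absorbed into the episode when every gap beat's RR is below 1.25 × the
local sinus median. On clean data this pass never fires; it is disabled by
`max_bridge_beats=0`. With it, waveform-mode episode recall/precision at
SNR 20 dB averages ≥ 0.99 over seeds.

Episode duration runs from the first arrhythmic beat to the first
subsequent sinus beat (recording end if none). 24 h metrics are pooled over
the recording and scaled, rather than computed per calendar day and
averaged — with a single compressed recording per period the two coincide.

## HRV

Intervals touching any non-sinus beat are excluded with a ±1-interval
margin, timestamps retained (no gap splicing). SDNN uses the n−1
denominator; pNN5 uses a strict ">5 ms". Spectra are estimated by
Lomb–Scargle on the native uneven time base — interpolation to an even
grid at rat rates biases HF power — on a grid from 1/span to
min(3 Hz, mean Nyquist) with resolution 1/(2·span), rescaled by one
constant so the full-grid integral equals the sample variance (ddof = 1).
Band powers are then plain integrals; LF/HF is reported in absolute ms²
(published LF/HF values ~0.2–0.35 are consistent with a ms² ratio; no
normalized-unit variant is implemented). An interpolation+FFT path
(`spectral_method="interp_fft"`, 10 Hz resampling) exists for comparison
and for bulk simulations, where it is ~30× faster. Recordings are epoched
(default 300 s), epochs failing the NN-count floor are rejected and
counted, and per-recording values are medians over valid epochs.

## Statistics

Between-group: Shapiro–Wilk (α = 0.05, per group) gates Welch's t (with
Welch–Satterthwaite df) versus Mann–Whitney U. The Mann–Whitney p is exact
by full enumeration of all C(n,nx) assignments of the pooled mid-ranks for
pooled n ≤ 14 — covering the study's 5+7 design, ties handled by mid-ranks
with the two-sided region defined by |U − nxny/2| — and a tie-corrected
normal approximation with continuity correction beyond that. Within-group:
one-way repeated-measures ANOVA (F = MS_period/MS_error, no sphericity
correction, omnibus only) or tie-corrected Friedman, gated the same way; a
fully tied matrix is reported degenerate (χ² = 0, p undefined) rather than
forced. All p-values are two-sided; no multiple-testing correction, and
SEM uses n−1, matching the reporting conventions of this literature.

Expression is normalized per animal as raw_gene/raw_GAPDH (values near 1
are consistent with ratio units; a log2 path exists behind `method`).
Animals without a positive GAPDH level are excluded with a warning.

## Synthetic-cohort defaults (the simulated study conditions)

Paced arm (n = 7): mean HR 344.7 → 330.6 → 320.4 → 318.0 bpm across the
four periods; SDNN targets 20.7 → 21.4 → 23.1 → 26.1 ms; LF ~2.1–2.6 ms²,
HF ~8.6 → 5.8 ms²; APBs 20 → 60 → 100 → 120 per 24 h; AF 0 → 6 → 9 → 10
episodes per 24 h (zero before pacing). Control arm (n = 5): flat at
322 bpm, SDNN 21.5 ms, 20 APBs/24 h, zero AF — flat because the emulated
control group showed no significant trend in any metric. Between-animal
spread: HR offsets constant per animal (sd 24.6 bpm paced, 8.5 bpm
control, from reported SEM·√n), SDNN multipliers lognormal (CV 0.10),
arrhythmia-rate multipliers gamma (CV 0.3); within-animal period noise
4 bpm and 5% SDNN. Expression defaults: per-gene group means/SEMs around
1.2–1.5 with GAPDH ~1000 a.u.; raw levels are built as normalized × GAPDH
so ratio normalization recovers the programmed means exactly.

What the generator does *not* emulate: electrode artifacts and baseline
wander, circadian rhythm, pacing stimulus artifacts, atrial flutter,
ventricular arrhythmias, detailed ECG morphology changes, or correlations
between HRV and arrhythmic burden beyond the programmed trends. Passing
tests therefore demonstrate correctness of the analysis chain under the
stated generative assumptions, not clinical-grade performance on real
telemetry.

## Numerical and degenerate-input choices

- Fixed seed ⇒ bitwise-identical outputs everywhere (NumPy `SeedSequence`
  spawning; report JSON is byte-stable).
- Undefined metrics are NaN with flags, never silent zeros (insufficient
  NN counts, zero-variance spectra, fully tied matrices, zero-variance
  Welch inputs in the expression table).
- Flat/NaN waveforms yield an empty detection with a warning, not an
  error; an all-absent-P recording is classified against the global median
  RR with a warning.
- Problem sizes: recordings default to 600 s (300 s in bulk simulations),
  epochs to 300 s, the trend study to 20 seeds of a 12-animal, 4-period
  cohort, and null calibration to 2000 replicates at n = 7, k = 4 — sizes
  chosen so the whole suite runs on a laptop core in well under half an
  hour while keeping Monte-Carlo error far from every decision threshold.

## Known limitations

- The P-wave pipeline assumes the rendered template family; real rat ECG
  P detection is harder and the original study's LabVIEW criteria
  (visual vs automated) are not public, so the detector is validated only
  against synthetic truth.
- Induced-vs-spontaneous AF is distinguished by protocol bookkeeping, not
  morphology; sinus-node recovery time is bookkept, not computed.
- Inducibility heterogeneity across animals is modelled with a Beta
  distribution around the mean cycle-induction probability; the true
  between-animal distribution is unknown.
- At compressed desk scale, absolute per-24 h burden values are faithful
  but burden *time fractions* are not (see the compressed-day convention).
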