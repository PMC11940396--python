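"""Synthetic rat ECG / RR cohorts with ground-truth arrhythmia annotations.

The generator emulates the structure of telemetry recordings from a rat
atrial-pacing study: sinus rhythm around 310–345 bpm with autonomic
modulation in the rat LF (0.3–0.6 Hz) and HF (0.6–2.5 Hz) bands, premature
atrial beats (APBs) with altered P-wave morphology, AF episodes (at least
three rapid, irregular beats with absent P waves), and the programmed
between-period trends of the study design (declining heart rate and rising
arrhythmic burden in the paced arm; a flat control arm with no AF).

Sinus beat trains come from an integral pulse frequency modulation (IPFM)
model: an instantaneous rate

    m(t) = (mean_hr/60) * (1 + d_vlf sin(2*pi*f_vlf t + ph0)
                             + d_lf  sin(2*pi*f_lf  t + ph1)
                             + d_hf  sin(2*pi*f_hf  t + ph2))

emits a beat at each unit crossing of its running integral, after which
multiplicative white jitter perturbs each RR interval.  A very-low-frequency
(VLF, < 0.3 Hz) term is included alongside the two study bands because in
rats most RR variance sits below the LF band: SDNN ~21 ms coexists with
LF+HF band powers of only ~10 ms^2, which two in-band sinusoids plus white
jitter cannot jointly produce.

Everything is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .recordings import (
    AF,
    APB,
    PERIODS,
    SINUS,
    AnnotatedRecording,
    Waveform,
    derive_true_episodes,
)

__all__ = [
    "AutonomicParams",
    "ArrhythmiaParams",
    "StimulationProtocol",
    "PeriodSpec",
    "CohortSpec",
    "autonomic_from_targets",
    "generate_nn_times",
    "inject_apbs",
    "inject_af_episodes",
    "render_ecg",
    "generate_cohort",
    "default_period_specs",
    "generate_expression_cohort",
    "simulate_stimulation",
    "sample_af_durations",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_finite(**kwargs) -> None:
    for name, val in kwargs.items():
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val!r}")


# ---------------------------------------------------------------------------
# parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AutonomicParams:
    """Sinus-rhythm rate and autonomic modulation parameters.

    Modulation depths are dimensionless fractions of the mean rate; the LF
    and HF carrier frequencies must sit inside the rat bands (0.3–0.6 Hz and
    0.6–2.5 Hz respectively).  ``rr_jitter_cv`` is the coefficient of
    variation of multiplicative white RR noise; ``vlf_*`` parametrize the
    sub-LF drift that dominates rat SDNN.
    """

    mean_hr: float = 330.0
    lf_mod_depth: float = 0.012
    hf_mod_depth: float = 0.024
    lf_freq: float = 0.45
    hf_freq: float = 1.2
    rr_jitter_cv: float = 0.01
    vlf_mod_depth: float = 0.16
    vlf_freq: float = 0.05

    def validate(self) -> None:
        _check_finite(
            mean_hr=self.mean_hr,
            lf_mod_depth=self.lf_mod_depth,
            hf_mod_depth=self.hf_mod_depth,
            lf_freq=self.lf_freq,
            hf_freq=self.hf_freq,
            rr_jitter_cv=self.rr_jitter_cv,
            vlf_mod_depth=self.vlf_mod_depth,
            vlf_freq=self.vlf_freq,
        )
        if self.mean_hr <= 0:
            raise ValueError("mean_hr must be positive")
        for name, d in (
            ("lf_mod_depth", self.lf_mod_depth),
            ("hf_mod_depth", self.hf_mod_depth),
            ("vlf_mod_depth", self.vlf_mod_depth),
        ):
            if not 0 <= d < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.lf_mod_depth + self.hf_mod_depth + self.vlf_mod_depth >= 1:
            raise ValueError("total modulation depth must stay below 1")
        if not 0.3 <= self.lf_freq <= 0.6:
            raise ValueError("lf_freq must lie in the rat LF band [0.3, 0.6] Hz")
        if not 0.6 <= self.hf_freq <= 2.5:
            raise ValueError("hf_freq must lie in the rat HF band [0.6, 2.5] Hz")
        if not 0 < self.vlf_freq < 0.3:
            raise ValueError("vlf_freq must lie below the LF band (0, 0.3) Hz")
        if self.rr_jitter_cv < 0:
            raise ValueError("rr_jitter_cv must be non-negative")


def autonomic_from_targets(
    mean_hr: float,
    sdnn_ms: float,
    lf_ms2: float,
    hf_ms2: float,
    rr_jitter_cv: float = 0.01,
    lf_freq: float = 0.45,
    hf_freq: float = 1.2,
    vlf_freq: float = 0.05,
) -> AutonomicParams:
    """Build modulation depths that hit target SDNN and band powers.

    A sinusoidal RR modulation of amplitude ``A`` contributes ``A^2/2`` to
    RR variance, and a rate-modulation depth ``d`` produces RR amplitude
    ``d * RR0`` to first order.  The VLF depth absorbs whatever variance the
    two in-band terms and the white jitter do not account for.
    """
    rr0 = 60000.0 / mean_hr  # ms
    lf_d = math.sqrt(2.0 * lf_ms2) / rr0
    hf_d = math.sqrt(2.0 * hf_ms2) / rr0
    jitter_var = (rr_jitter_cv * rr0) ** 2
    resid = max(sdnn_ms**2 - lf_ms2 - hf_ms2 - jitter_var, 0.0)
    vlf_d = math.sqrt(2.0 * resid) / rr0
    return AutonomicParams(
        mean_hr=mean_hr,
        lf_mod_depth=lf_d,
        hf_mod_depth=hf_d,
        lf_freq=lf_freq,
        hf_freq=hf_freq,
        rr_jitter_cv=rr_jitter_cv,
        vlf_mod_depth=vlf_d,
        vlf_freq=vlf_freq,
    )


@dataclass(frozen=True)
class ArrhythmiaParams:
    """Rates and shapes of injected APBs and AF episodes.

    ``apb_rate`` is in events/hour and ``af_rate`` in episodes/24 h.
    Episode durations are lognormal with the given mean and sd; the default
    duration matches the study's stimulation-induced episodes
    (123.2 +/- 36.4 s).  Within an episode RR ~ ``af_rr_scale`` x the local
    sinus RR with lognormal coefficient of variation ``af_rr_cv`` ("rapid,
    irregular").
    """

    apb_rate: float = 0.0
    apb_prematurity: float = 0.6
    af_rate: float = 0.0
    af_duration_mean: float = 123.2
    af_duration_sd: float = 36.4
    af_rr_scale: float = 0.7
    af_rr_cv: float = 0.15

    def validate(self) -> None:
        _check_finite(
            apb_rate=self.apb_rate,
            apb_prematurity=self.apb_prematurity,
            af_rate=self.af_rate,
            af_duration_mean=self.af_duration_mean,
            af_duration_sd=self.af_duration_sd,
            af_rr_scale=self.af_rr_scale,
            af_rr_cv=self.af_rr_cv,
        )
        if self.apb_rate < 0 or self.af_rate < 0:
            raise ValueError("event rates must be non-negative")
        if not 0 < self.apb_prematurity < 1:
            raise ValueError("apb_prematurity must be in (0, 1)")
        if not 0 < self.af_rr_scale < 1:
            raise ValueError("af_rr_scale must be in (0, 1)")
        if self.af_rr_cv <= 0:
            raise ValueError("af_rr_cv must be positive")
        if self.af_rate > 0 and self.af_duration_mean <= 0:
            raise ValueError("af_duration_mean must be positive when af_rate > 0")
        if self.af_duration_sd < 0:
            raise ValueError("af_duration_sd must be non-negative")


@dataclass(frozen=True)
class StimulationProtocol:
    """Transesophageal burst-pacing schedule (bookkeeping only).

    Defaults follow the study protocol: 15 cycles of 20 s per day with 5 min
    free intervals, 4000 stimuli/min of 6 ms each, for 10 days.
    ``per_cycle_induction_prob`` drives the Bernoulli per-cycle induction
    outcomes of :func:`simulate_stimulation`; the study-wide mean cycle
    inducibility was 44.0%.
    """

    cycles_per_day: int = 15
    cycle_duration: float = 20.0
    inter_cycle_interval: float = 300.0
    stim_rate: float = 4000.0
    stim_duration_ms: float = 6.0
    n_days: int = 10
    per_cycle_induction_prob: float = 0.44

    def validate(self) -> None:
        if self.cycles_per_day < 1 or self.n_days < 1:
            raise ValueError("cycle and day counts must be >= 1")
        if not 0 <= self.per_cycle_induction_prob <= 1:
            raise ValueError("per_cycle_induction_prob must be in [0, 1]")

    @property
    def total_cycles(self) -> int:
        return self.cycles_per_day * self.n_days


@dataclass(frozen=True)
class PeriodSpec:
    """One ECG monitoring period (before / week1 / week2 / after)."""

    label: str
    autonomic: AutonomicParams
    arrhythmia: ArrhythmiaParams
    recording_duration: float = 600.0

    def validate(self) -> None:
        if self.label not in PERIODS:
            raise ValueError(f"period label must be one of {PERIODS}")
        self.autonomic.validate()
        self.arrhythmia.validate()
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Full two-arm simulated cohort (control n=5, paced/AF n=7 by default).

    Each recording stands for one compressed 24 h interval:
    ``time_compression`` (default ``86400 / recording_duration``) multiplies
    the injection rates so that per-24 h event counts are preserved at desk
    scale.  Downstream burden metrics must then normalize counts by the
    represented duration ``recording_duration * time_compression``.
    """

    n_control: int = 5
    n_af: int = 7
    periods_control: tuple[PeriodSpec, ...] = ()
    periods_af: tuple[PeriodSpec, ...] = ()
    seed: int = 0
    time_compression: float | None = None
    hr_between_animal_sd_af: float = 24.6
    hr_between_animal_sd_control: float = 8.5
    hr_within_animal_sd: float = 4.0
    sdnn_between_animal_cv: float = 0.10
    sdnn_within_animal_cv: float = 0.05
    rate_between_animal_cv: float = 0.3

    def __post_init__(self):
        if not self.periods_control:
            object.__setattr__(self, "periods_control", default_period_specs("control"))
        if not self.periods_af:
            object.__setattr__(self, "periods_af", default_period_specs("af"))

    def validate(self) -> None:
        if self.n_control < 0 or self.n_af < 0:
            raise ValueError("arm sizes must be non-negative")
        labels_c = tuple(p.label for p in self.periods_control)
        labels_a = tuple(p.label for p in self.periods_af)
        if labels_c != labels_a:
            raise ValueError("both arms must share the same period labels")
        for p in self.periods_control + self.periods_af:
            p.validate()

    def compression(self) -> float:
        if self.time_compression is not None:
            return self.time_compression
        return 86400.0 / self.periods_af[0].recording_duration


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

# Per-period targets for the paced (AF) and control arms: mean heart rate
# (bpm, group means of Table-1-like values), SDNN (ms), LF and HF band powers
# (ms^2) emulating the reported HRV medians, APB rate (events/h) and AF rate
# (episodes/24 h) encoding the rising-burden trends.  Control values are flat
# with zero AF; spontaneous AF durations are desk-scale (20 +/- 8 s).
_AF_ARM = {
    "hr": (344.7, 330.6, 320.4, 318.0),
    "sdnn": (20.7, 21.4, 23.1, 26.1),
    "lf": (2.1, 2.3, 2.6, 2.6),
    "hf": (8.6, 6.2, 5.9, 5.8),
    "apb_per_h": (0.85, 2.5, 4.2, 5.0),
    "af_per_24h": (0.0, 6.0, 9.0, 10.0),
}
_CONTROL_ARM = {
    "hr": (322.0, 322.0, 322.0, 322.0),
    "sdnn": (21.5, 21.5, 21.5, 21.5),
    "lf": (2.1, 2.1, 2.1, 2.1),
    "hf": (7.5, 7.5, 7.5, 7.5),
    "apb_per_h": (0.85, 0.85, 0.85, 0.85),
    "af_per_24h": (0.0, 0.0, 0.0, 0.0),
}


def default_period_specs(arm: str, recording_duration: float = 600.0) -> tuple[PeriodSpec, ...]:
    """Default four-period parameter tables for one study arm."""
    table = {"af": _AF_ARM, "control": _CONTROL_ARM}[arm]
    specs = []
    for i, label in enumerate(PERIODS):
        autonomic = autonomic_from_targets(
            mean_hr=table["hr"][i],
            sdnn_ms=table["sdnn"][i],
            lf_ms2=table["lf"][i],
            hf_ms2=table["hf"][i],
        )
        arrhythmia = ArrhythmiaParams(
            apb_rate=table["apb_per_h"][i],
            af_rate=table["af_per_24h"][i],
            af_duration_mean=15.0,
            af_duration_sd=5.0,
        )
        specs.append(
            PeriodSpec(
                label=label,
                autonomic=autonomic,
                arrhythmia=arrhythmia,
                recording_duration=recording_duration,
            )
        )
    return tuple(specs)


# ---------------------------------------------------------------------------
# sinus beat trains (IPFM)
# ---------------------------------------------------------------------------

def generate_nn_times(
    params: AutonomicParams, duration: float, seed=0
) -> AnnotatedRecording:
    """Generate a sinus-only recording from the IPFM model.

    A beat is emitted at each unit crossing of the integrated instantaneous
    rate; the integral is evaluated in closed form and crossings are refined
    by Newton iteration, so unmodulated trains are exact.  Multiplicative
    white jitter (CV ``rr_jitter_cv``) is then applied to each RR interval.
    """
    params.validate()
    if not math.isfinite(duration) or duration < 0:
        raise ValueError(f"duration must be a non-negative finite number, got {duration!r}")
    rng = _as_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=3)  # vlf, lf, hf

    r0 = params.mean_hr / 60.0
    comps = [
        (params.vlf_mod_depth, 2 * np.pi * params.vlf_freq, phases[0]),
        (params.lf_mod_depth, 2 * np.pi * params.lf_freq, phases[1]),
        (params.hf_mod_depth, 2 * np.pi * params.hf_freq, phases[2]),
    ]
    comps = [(d, w, p) for d, w, p in comps if d > 0]

    def big_m(t):
        out = r0 * np.asarray(t, dtype=float)
        for d, w, p in comps:
            out = out - (r0 * d / w) * (np.cos(w * np.asarray(t) + p) - np.cos(p))
        return out

    def little_m(t):
        out = np.full_like(np.asarray(t, dtype=float), r0)
        for d, w, p in comps:
            out = out + r0 * d * np.sin(w * np.asarray(t) + p)
        return out

    n_beats = int(np.floor(big_m(duration) + 1e-9))
    if n_beats <= 0:
        empty = np.array([])
        return AnnotatedRecording(
            beat_times=empty,
            beat_labels=np.array([], dtype="<U8"),
            p_present=np.array([], dtype=bool),
            p_morph_match=np.array([], dtype=bool),
            duration=duration,
        )

    # bracket each integer crossing on a coarse grid, then Newton-refine
    grid = np.arange(0.0, duration + 0.01, 0.01)
    mg = big_m(grid)
    ks = np.arange(1, n_beats + 1, dtype=float)
    idx = np.clip(np.searchsorted(mg, ks, side="left"), 1, len(grid) - 1)
    t = grid[idx - 1]
    for _ in range(3):
        t = t + (ks - big_m(t)) / little_m(t)
    t = np.clip(t, 0.0, duration)

    if params.rr_jitter_cv > 0 and n_beats > 1:
        rr = np.diff(t)
        rr = rr * np.clip(
            1.0 + params.rr_jitter_cv * rng.standard_normal(len(rr)), 0.3, None
        )
        t = np.concatenate([[t[0]], t[0] + np.cumsum(rr)])
        t = t[t <= duration]

    n = len(t)
    return AnnotatedRecording(
        beat_times=t,
        beat_labels=np.full(n, SINUS, dtype="<U8"),
        p_present=np.ones(n, dtype=bool),
        p_morph_match=np.ones(n, dtype=bool),
        duration=duration,
    )


# ---------------------------------------------------------------------------
# arrhythmia injection
# ---------------------------------------------------------------------------

def inject_apbs(
    rec: AnnotatedRecording, params: ArrhythmiaParams, seed=0
) -> AnnotatedRecording:
    """Insert Poisson-count premature atrial beats into sinus rhythm.

    Each APB advances a sinus beat to ``apb_prematurity`` x the preceding
    sinus RR and flags its P morphology as mismatched; the following beat is
    left at its original time, which acts as a full (non-resetting)
    compensatory pause and keeps all downstream sinus times unchanged.
    """
    params.validate()
    if int(np.sum(rec.beat_labels == SINUS)) < 2:
        raise ValueError("recording must contain at least 2 sinus beats")
    out = rec.copy()
    if params.apb_rate <= 0:
        return out
    rng = _as_rng(seed)
    n_events = rng.poisson(params.apb_rate * rec.duration / 3600.0)
    if n_events == 0:
        return out

    labels = out.beat_labels
    sinus = labels == SINUS
    # candidate beat i needs sinus neighbours on both sides so the coupling
    # interval and compensatory pause are well defined
    cand = np.where(
        sinus[1:-1] & sinus[:-2] & sinus[2:]
    )[0] + 1
    rng.shuffle(cand)
    chosen: list[int] = []
    taken = np.zeros(out.n_beats, dtype=bool)
    for i in cand:
        if len(chosen) >= n_events:
            break
        if taken[i - 1] or taken[i] or taken[i + 1]:
            continue
        chosen.append(int(i))
        taken[i - 1 : i + 2] = True

    times = out.beat_times
    for i in chosen:
        coupling = params.apb_prematurity * (times[i] - times[i - 1])
        times[i] = times[i - 1] + coupling
        labels[i] = APB
        out.p_morph_match[i] = False
    out.true_episodes = derive_true_episodes(times, labels, out.duration)
    out.validate()
    return out


def sample_af_durations(params: ArrhythmiaParams, n: int, rng) -> np.ndarray:
    """Draw episode durations (s): lognormal matched to mean/sd, or constant."""
    rng = _as_rng(rng)
    mean, sd = params.af_duration_mean, params.af_duration_sd
    if sd <= 0:
        return np.full(n, mean)
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def inject_af_episodes(
    rec: AnnotatedRecording,
    params: ArrhythmiaParams,
    seed=0,
    n_episodes: int | None = None,
) -> AnnotatedRecording:
    """Replace sinus segments with AF episodes at Poisson times.

    Within an episode RR ~ ``af_rr_scale`` x the local sinus RR with
    lognormal CV ``af_rr_cv``; all episode beats are labelled ``af`` with
    absent P waves, and episodes shorter than 3 beats are extended to 3.
    ``n_episodes`` overrides the Poisson count (used by fixtures that need a
    guaranteed number of episodes).  Ground truth is re-derived from the
    final labels so episode ends follow the first-subsequent-sinus-beat rule.
    """
    params.validate()
    out = rec.copy()
    if params.af_rate <= 0 and n_episodes is None:
        return out
    if params.af_duration_mean <= 0:
        raise ValueError("af_duration_mean must be positive when injecting AF")
    rng = _as_rng(seed)
    n = int(n_episodes) if n_episodes is not None else rng.poisson(
        params.af_rate * rec.duration / 86400.0
    )
    if n == 0 or out.n_beats < 8:
        return out

    durations = sample_af_durations(params, n, rng)
    sigma2 = math.log1p(params.af_rr_cv**2)
    sig, mu = math.sqrt(sigma2), -sigma2 / 2.0

    placed: list[tuple[float, float]] = []  # (start, end) incl. guard gap
    margin = 1.0
    plan: list[tuple[float, float]] = []
    for dur in durations:
        hi = rec.duration - margin - dur
        if hi <= margin:
            continue
        for _ in range(40):
            s = rng.uniform(margin, hi)
            if all(s + dur + 2.0 < a or s > b + 2.0 for a, b in placed):
                placed.append((s, s + dur))
                plan.append((s, dur))
                break

    times = out.beat_times
    labels = out.beat_labels
    p_pres = out.p_present
    p_morph = out.p_morph_match
    debug_info: list[dict] = []
    for s, dur in sorted(plan, reverse=True):
        i0 = int(np.searchsorted(times, s))
        j0 = int(np.searchsorted(times, s + dur))
        if i0 < 8 or j0 >= len(times) - 8:
            continue
        # reference sinus RR from an equal number of intervals flanking the
        # episode window on each side, so slow (VLF) rate drift across the
        # episode biases the reference symmetrically
        lo, hi = i0 - 7, j0 + 7
        if np.any(labels[lo:i0] != SINUS) or np.any(labels[j0:hi] != SINUS):
            continue
        flank = np.concatenate([np.diff(times[lo:i0]), np.diff(times[j0:hi])])
        local_rr = float(np.median(flank))
        debug_info.append({"start": s, "local_rr_s": local_rr})
        base = params.af_rr_scale * local_rr
        t0 = max(s, times[i0 - 1] + 0.4 * local_rr)
        af_times = [t0]
        while (af_times[-1] - t0) < dur or len(af_times) < 3:
            af_times.append(af_times[-1] + base * rng.lognormal(mu, sig))
            if len(af_times) > 200000:
                raise RuntimeError("runaway AF episode generation")
        j = int(np.searchsorted(times, af_times[-1] + 0.6 * local_rr))
        if j >= len(times) - 1:
            continue
        k = len(af_times)
        times = np.concatenate([times[:i0], af_times, times[j:]])
        labels = np.concatenate(
            [labels[:i0], np.full(k, AF, dtype="<U8"), labels[j:]]
        )
        p_pres = np.concatenate([p_pres[:i0], np.zeros(k, dtype=bool), p_pres[j:]])
        p_morph = np.concatenate([p_morph[:i0], np.zeros(k, dtype=bool), p_morph[j:]])

    out.beat_times = times
    out.beat_labels = labels
    out.p_present = p_pres
    out.p_morph_match = p_morph
    out.meta.setdefault("af_injection", []).extend(debug_info)
    out.true_episodes = derive_true_episodes(times, labels, out.duration)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

# Rat lead-II template timing (s relative to the R peak) and amplitudes (mV).
# The QRS is narrow (~16 ms), the P wave sits ~40 ms before R, and the T wave
# follows closely as is typical in rat ECG.  APBs carry an inverted P wave
# (ectopic atrial focus); AF beats carry no P wave at all.
_WAVES_SINUS = (
    ("P", 0.20, -0.040, 0.007),
    ("Q", -0.15, -0.008, 0.002),
    ("R", 1.00, 0.000, 0.004),
    ("S", -0.25, 0.008, 0.002),
    ("T", 0.15, 0.030, 0.010),
)


def _beat_waves(label: str):
    if label == AF:
        return [w for w in _WAVES_SINUS if w[0] != "P"]
    if label == APB:
        return [("P", -0.20, -0.040, 0.007)] + [w for w in _WAVES_SINUS if w[0] != "P"]
    if label == ARTIFACT_LABEL:
        return []
    return list(_WAVES_SINUS)


ARTIFACT_LABEL = "artifact"


def render_ecg(
    rec: AnnotatedRecording, fs: float = 1000.0, noise_sd: float = 0.0, seed=0
) -> Waveform:
    """Render a recording as a single-lead trace of Gaussian wave templates.

    Each beat contributes P (absent for AF, inverted for APB), QRS and T
    bumps centred on its beat time, plus additive white Gaussian noise of
    standard deviation ``noise_sd`` mV.
    """
    if fs < 500:
        raise ValueError("fs must be >= 500 Hz to resolve the rat QRS")
    rng = _as_rng(seed)
    n = int(round(rec.duration * fs)) + 1
    sig = np.zeros(n)
    half = int(0.08 * fs)
    for tb, label in zip(rec.beat_times, rec.beat_labels):
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) / fs - tb
        for _, amp, center, width in _beat_waves(label):
            sig[lo:hi] += amp * np.exp(-0.5 * ((tt - center) / width) ** 2)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return Waveform(samples=sig, fs=fs)


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------

def _animal_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def generate_cohort(spec: CohortSpec) -> dict[tuple[str, str], AnnotatedRecording]:
    """Simulate every (animal, period) recording of a two-arm cohort.

    Per-animal parameters are drawn around the period means: a constant
    heart-rate offset and SDNN multiplier per animal (repeated-measures
    structure) plus small per-period noise, and gamma-distributed arrhythmia
    rate multipliers.  Injection rates are multiplied by the cohort
    compression factor so each desk-scale recording carries one 24 h
    interval's worth of events.  Fully reproducible for a fixed seed.
    """
    spec.validate()
    compression = spec.compression()
    root = np.random.SeedSequence(spec.seed)
    arm_seeds = root.spawn(2)

    cohort: dict[tuple[str, str], AnnotatedRecording] = {}
    arms = (
        ("control", spec.n_control, spec.periods_control, arm_seeds[0]),
        ("af", spec.n_af, spec.periods_af, arm_seeds[1]),
    )
    for arm, n_animals, periods, arm_seed in arms:
        prefix = "ctl" if arm == "control" else "af"
        animal_seeds = arm_seed.spawn(max(n_animals, 1))
        hr_sd = (
            spec.hr_between_animal_sd_control
            if arm == "control"
            else spec.hr_between_animal_sd_af
        )
        for a, animal in enumerate(_animal_ids(prefix, n_animals)):
            rng = np.random.default_rng(animal_seeds[a])
            hr_offset = rng.normal(0.0, hr_sd)
            sdnn_mult = rng.lognormal(0.0, spec.sdnn_between_animal_cv)
            apb_mult = rng.gamma(
                1 / spec.rate_between_animal_cv**2, spec.rate_between_animal_cv**2
            )
            af_mult = rng.gamma(
                1 / spec.rate_between_animal_cv**2, spec.rate_between_animal_cv**2
            )
            for period in periods:
                hr = period.autonomic.mean_hr + hr_offset + rng.normal(
                    0.0, spec.hr_within_animal_sd
                )
                rr0 = 60000.0 / period.autonomic.mean_hr
                base_sdnn = math.sqrt(
                    (period.autonomic.vlf_mod_depth * rr0) ** 2 / 2
                    + (period.autonomic.lf_mod_depth * rr0) ** 2 / 2
                    + (period.autonomic.hf_mod_depth * rr0) ** 2 / 2
                    + (period.autonomic.rr_jitter_cv * rr0) ** 2
                )
                sdnn = base_sdnn * sdnn_mult * rng.lognormal(
                    0.0, spec.sdnn_within_animal_cv
                )
                autonomic = autonomic_from_targets(
                    mean_hr=hr,
                    sdnn_ms=sdnn,
                    lf_ms2=(period.autonomic.lf_mod_depth * rr0) ** 2 / 2,
                    hf_ms2=(period.autonomic.hf_mod_depth * rr0) ** 2 / 2,
                    rr_jitter_cv=period.autonomic.rr_jitter_cv,
                    lf_freq=period.autonomic.lf_freq,
                    hf_freq=period.autonomic.hf_freq,
                    vlf_freq=period.autonomic.vlf_freq,
                )
                arr = replace(
                    period.arrhythmia,
                    apb_rate=period.arrhythmia.apb_rate * apb_mult * compression,
                    af_rate=period.arrhythmia.af_rate * af_mult * compression,
                )
                rec = generate_nn_times(autonomic, period.recording_duration, rng)
                rec = inject_af_episodes(rec, arr, rng)
                rec = inject_apbs(rec, arr, rng)
                rec.meta = {
                    "animal": animal,
                    "group": arm,
                    "period": period.label,
                    "represented_duration_s": period.recording_duration * compression,
                    "programmed_hr": hr,
                    "programmed_sdnn_ms": sdnn,
                }
                cohort[(animal, period.label)] = rec
    return cohort


# ---------------------------------------------------------------------------
# gene expression and stimulation outcomes
# ---------------------------------------------------------------------------

# Group means +/- SEM of GAPDH-normalized expression (Table-3-like defaults).
_EXPRESSION = {
    # gene: ((af_mean, af_sem, n_af_ref), (ctl_mean, ctl_sem, n_ctl_ref))
    "Hcn1": ((1.42, 0.09), (1.48, 0.11)),
    "Hcn2": ((1.39, 0.03), (1.33, 0.01)),
    "Hcn4": ((1.42, 0.02), (1.35, 0.01)),
    "Pitx2": ((1.22, 0.04), (1.40, 0.04)),
}
EXPRESSION_GENES = tuple(_EXPRESSION)


def generate_expression_cohort(
    seed=0, n_af: int = 7, n_control: int = 5
) -> pd.DataFrame:
    """Simulate raw qPCR-style expression levels for the study gene panel.

    Normalized levels are drawn per animal around the group means with
    between-animal sd = SEM * sqrt(n); a GAPDH level in arbitrary units is
    drawn per animal and raw target levels are its product with the
    normalized value, so that GAPDH normalization recovers the programmed
    ratios exactly.
    """
    rng = _as_rng(seed)
    rows = []
    for group, n, ref_n, col in (
        ("af", n_af, 7, 0),
        ("control", n_control, 5, 1),
    ):
        prefix = "af" if group == "af" else "ctl"
        for animal in _animal_ids(prefix, n):
            gapdh = rng.normal(1000.0, 100.0)
            gapdh = max(gapdh, 100.0)
            rows.append({"animal": animal, "group": group, "gene": "GAPDH", "raw_level": gapdh})
            for gene, params in _EXPRESSION.items():
                mean, sem = params[col]
                sd = sem * math.sqrt(ref_n)
                level = max(rng.normal(mean, sd), 0.05)
                rows.append(
                    {
                        "animal": animal,
                        "group": group,
                        "gene": gene,
                        "raw_level": level * gapdh,
                    }
                )
    return pd.DataFrame(rows)


def simulate_stimulation(
    protocol: StimulationProtocol,
    n_animals: int = 7,
    seed=0,
    between_animal_dispersion: float = 6.0,
) -> list[dict]:
    """Simulate per-cycle AF induction outcomes for a paced arm.

    Per-animal induction probabilities are Beta-distributed around the
    protocol's ``per_cycle_induction_prob`` (the study reported marked
    inter-individual variability); each cycle is an independent Bernoulli
    trial and induced episodes get lognormal durations with the study's
    123.2 +/- 36.4 s statistics.
    """
    protocol.validate()
    rng = _as_rng(seed)
    a = protocol.per_cycle_induction_prob * between_animal_dispersion
    b = (1 - protocol.per_cycle_induction_prob) * between_animal_dispersion
    dur_params = ArrhythmiaParams(af_rate=1.0)
    out = []
    for animal in _animal_ids("af", n_animals):
        p = rng.beta(a, b)
        outcomes = rng.random(protocol.total_cycles) < p
        n_induced = int(outcomes.sum())
        durations = sample_af_durations(dur_params, n_induced, rng)
        out.append(
            {
                "animal": animal,
                "cycle_outcomes": outcomes.tolist(),
                "induced_af_durations": durations.tolist(),
            }
        )
    return out
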