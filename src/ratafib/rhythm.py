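"""Rule-based arrhythmia classification, episode segmentation and burden.

The operational definitions follow the study: an AF episode is a run of at
least three consecutive beats with absent P waves whose rhythm is rapid
(median RR below a fraction of the local sinus median) and irregular (RR
coefficient of variation above a floor); its duration runs from the first
arrhythmic beat to the first subsequent sinus beat.  An APB is an isolated
premature beat whose P morphology differs from sinus.  "Rapid" and
"irregular" are quantified here by configurable thresholds because the
source definitions are qualitative.

Burden metrics are reported per 24 h; inducibility is the percentage of
pacing cycles followed by an AF episode, with an animal counted inducible
if any cycle induced AF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .recordings import AF, APB, ARTIFACT, SINUS, Episode

__all__ = [
    "ClassifierConfig",
    "BurdenSummary",
    "InducibilityRecord",
    "classify_beats",
    "segment_episodes",
    "burden_24h",
    "inducibility",
    "episode_recall_precision",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds quantifying the qualitative arrhythmia definitions.

    ``min_af_beats`` is fixed at 3 by the AF definition itself; the rapid /
    irregularity / prematurity factors are this module's defaults and are
    deliberately config-exposed.
    """

    min_af_beats: int = 3
    af_rapid_factor: float = 0.75
    af_irregularity_cv: float = 0.08
    apb_prematurity_factor: float = 0.85
    sinus_median_window: int = 11
    artifact_min_rr_ms: float = 50.0
    max_bridge_beats: int = 2
    bridge_rr_factor: float = 1.25

    def validate(self) -> None:
        if self.min_af_beats < 3:
            raise ValueError("min_af_beats cannot be below 3 (AF definition)")
        for name, v in (
            ("af_rapid_factor", self.af_rapid_factor),
            ("apb_prematurity_factor", self.apb_prematurity_factor),
        ):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.af_irregularity_cv <= 0:
            raise ValueError("af_irregularity_cv must be positive")
        if self.sinus_median_window < 3:
            raise ValueError("sinus_median_window must be >= 3")


@dataclass(frozen=True)
class BurdenSummary:
    """Per-recording arrhythmic burden normalized to a 24 h interval.

    ``mean_hr_24h`` is the raw beat count over the physical duration;
    ``mean_sinus_hr`` is computed over sinus-bounded RR intervals only, so
    it tracks the underlying sinus rate even in compressed desk-scale
    recordings whose arrhythmic time fraction is exaggerated relative to a
    real telemetry day.
    """

    mean_hr_24h: float
    mean_sinus_hr: float
    apbs_per_24h: float
    af_episodes_per_24h: float
    mean_af_duration: float
    af_present: bool

    def __post_init__(self):
        if self.af_present != (self.af_episodes_per_24h > 0):
            raise ValueError("af_present must mirror af_episodes_per_24h > 0")


@dataclass(frozen=True)
class InducibilityRecord:
    """Per-animal pacing outcomes and cycle-level inducibility."""

    animal: str
    cycle_outcomes: tuple[bool, ...]
    induced_af_durations: tuple[float, ...]

    @property
    def cycle_inducibility_pct(self) -> float:
        return 100.0 * sum(self.cycle_outcomes) / len(self.cycle_outcomes)

    @property
    def animal_inducible(self) -> bool:
        return any(self.cycle_outcomes)


# ---------------------------------------------------------------------------
# beat classification
# ---------------------------------------------------------------------------

def _local_sinus_median(
    rr: np.ndarray,
    sinus_interval: np.ndarray,
    left: int,
    right: int,
    window: int,
) -> float:
    """Median of sinus-bounded RR intervals flanking the span ``[left, right)``.

    Up to ``ceil(window/2)`` nearest sinus intervals are taken from each
    side (more from one side when the other is short), so a slow rate drift
    across the span biases the reference symmetrically.  Falls back to the
    global median RR when no sinus reference exists.
    """
    idx = np.where(sinus_interval)[0]
    if len(idx) == 0:
        return float(np.median(rr)) if len(rr) else np.nan
    half = (window + 1) // 2
    before = idx[idx < left]
    after = idx[idx >= right]
    take_b = before[-(half + max(0, half - len(after))):] if len(before) else before
    take_a = after[: half + max(0, half - len(before))] if len(after) else after
    take = np.concatenate([take_b, take_a])
    if len(take) == 0:
        take = idx[np.argsort(np.abs(idx - (left + right) // 2), kind="stable")[:window]]
    return float(np.median(rr[take]))


def classify_beats(
    beat_times: np.ndarray,
    p_present: np.ndarray,
    p_morph_match: np.ndarray,
    cfg: ClassifierConfig | None = None,
) -> np.ndarray:
    """Label every beat as sinus / apb / af / artifact.

    Candidate AF runs are maximal runs of absent-P beats; a run is AF iff it
    has at least ``min_af_beats`` beats, its median RR is below
    ``af_rapid_factor`` x the local sinus median, and its RR CV exceeds
    ``af_irregularity_cv``.  Absent-P runs failing the AF criteria are
    labelled APB beat-by-beat, as are isolated premature beats with
    mismatched P morphology.  Implausibly short RR (< ``artifact_min_rr_ms``)
    marks an artifact.
    """
    cfg = cfg or ClassifierConfig()
    cfg.validate()
    t = np.asarray(beat_times, dtype=float)
    p_present = np.asarray(p_present, dtype=bool)
    p_morph = np.asarray(p_morph_match, dtype=bool)
    n = len(t)
    if not (len(p_present) == len(p_morph) == n):
        raise ValueError("flag arrays must align with beat times")
    if n < cfg.min_af_beats + 1:
        raise ValueError(f"need at least {cfg.min_af_beats + 1} beats to classify")

    labels = np.full(n, SINUS, dtype="<U8")
    rr = np.diff(t) * 1000.0  # rr[i] precedes beat i+1

    if not p_present.any():
        warnings.warn(
            "no P waves anywhere: labelling the whole recording AF against the "
            "global median RR"
        )

    # artifacts first: impossible RR flags the later beat of the pair
    art = np.where(rr < cfg.artifact_min_rr_ms)[0] + 1
    labels[art] = ARTIFACT

    # provisional normal beats for the local reference rhythm: P present AND
    # morphologically matching, so APB coupling/compensatory intervals do not
    # contaminate the sinus median
    provisional_sinus = p_present & p_morph & (labels == SINUS)
    sinus_interval = provisional_sinus[:-1] & provisional_sinus[1:]

    # absent-P runs
    i = 0
    while i < n:
        if p_present[i] or labels[i] == ARTIFACT:
            i += 1
            continue
        j = i
        while j + 1 < n and (not p_present[j + 1]) and labels[j + 1] != ARTIFACT:
            j += 1
        run_len = j - i + 1
        # intervals strictly within the run: the coupling interval from the
        # preceding sinus beat would bias both the median and the CV
        run_rr = rr[i:j] if j > i else rr[max(i - 1, 0) : i]
        is_af = False
        if run_len >= cfg.min_af_beats and len(run_rr) >= 2:
            # run beats i..j own intervals i-1..j-1; flanks are < i-1 and >= j
            local = _local_sinus_median(
                rr, sinus_interval, left=max(i - 1, 0), right=j,
                window=cfg.sinus_median_window,
            )
            med = float(np.median(run_rr))
            cv = float(np.std(run_rr) / np.mean(run_rr)) if np.mean(run_rr) > 0 else 0.0
            is_af = (
                np.isfinite(local)
                and med < cfg.af_rapid_factor * local
                and cv > cfg.af_irregularity_cv
            )
        labels[i : j + 1] = AF if is_af else APB
        i = j + 1

    # gap tolerance: per-beat P detection is noisy, so a short gap (up to
    # max_bridge_beats) between two validated AF runs is absorbed into the
    # episode as long as every gap beat's RR stays below the local sinus
    # median — rhythm continuity outranks one or two spurious P flags
    if cfg.max_bridge_beats > 0:
        af_idx = np.where(labels == AF)[0]
        for a, b in zip(af_idx[:-1], af_idx[1:]):
            gap = b - a - 1
            if gap == 0 or gap > cfg.max_bridge_beats:
                continue
            local = _local_sinus_median(
                rr, sinus_interval, left=a, right=b,
                window=cfg.sinus_median_window,
            )
            gap_rr = rr[a : b - 1]
            if np.isfinite(local) and np.all(gap_rr < cfg.bridge_rr_factor * local):
                labels[a + 1 : b] = AF

    # isolated premature beats with mismatched morphology
    for i in range(1, n):
        if labels[i] != SINUS or not p_present[i] or p_morph[i]:
            continue
        local = _local_sinus_median(
            rr, sinus_interval, left=i - 1, right=i + 1,
            window=cfg.sinus_median_window,
        )
        if np.isfinite(local) and rr[i - 1] < cfg.apb_prematurity_factor * local:
            labels[i] = APB
    return labels


# ---------------------------------------------------------------------------
# episodes and burden
# ---------------------------------------------------------------------------

def segment_episodes(
    labels: np.ndarray, beat_times: np.ndarray, duration: float | None = None
) -> list[Episode]:
    """Turn per-beat labels into an ordered, non-overlapping episode list.

    Maximal AF runs become AF episodes ending at the first subsequent sinus
    beat (recording end when none); APBs become single-beat episodes.
    """
    labels = np.asarray(labels)
    t = np.asarray(beat_times, dtype=float)
    if len(labels) != len(t):
        raise ValueError("labels must align with beat times")
    end_of_record = duration if duration is not None else (t[-1] if len(t) else 0.0)
    episodes: list[Episode] = []
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] == AF:
            j = i
            while j + 1 < n and labels[j + 1] == AF:
                j += 1
            end = end_of_record
            for k in range(j + 1, n):
                if labels[k] == SINUS:
                    end = float(t[k])
                    break
            episodes.append(Episode(type=AF, start_s=float(t[i]), end_s=end, n_beats=j - i + 1))
            i = j + 1
        else:
            if labels[i] == APB:
                episodes.append(Episode(type=APB, start_s=float(t[i]), end_s=float(t[i]), n_beats=1))
            i += 1
    return episodes


def burden_24h(
    episodes: list[Episode],
    labels: np.ndarray,
    beat_times: np.ndarray,
    duration: float,
    represented_duration: float | None = None,
) -> BurdenSummary:
    """Summarize a recording's burden over a 24 h interval.

    Event counts are scaled by ``86400 / represented_duration`` (defaulting
    to the physical ``duration``); mean heart rate always uses the physical
    duration.  The distinction matters for compressed desk-scale recordings
    that stand for a full telemetry day.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rep = represented_duration if represented_duration is not None else duration
    if rep <= 0:
        raise ValueError("represented duration must be positive")
    t = np.asarray(beat_times, dtype=float)
    labels = np.asarray(labels)
    scale = 86400.0 / rep
    n_apb = sum(1 for e in episodes if e.type == APB)
    af_eps = [e for e in episodes if e.type == AF]
    mean_hr = 60.0 * max(len(t) - 1, 0) / duration
    sinus_pair = (labels[:-1] == SINUS) & (labels[1:] == SINUS) if len(t) > 1 else np.array([], bool)
    if sinus_pair.any():
        mean_sinus_hr = 60.0 / float(np.mean(np.diff(t)[sinus_pair]))
    else:
        mean_sinus_hr = mean_hr
    mean_af_dur = float(np.mean([e.duration_s for e in af_eps])) if af_eps else 0.0
    return BurdenSummary(
        mean_hr_24h=mean_hr,
        mean_sinus_hr=mean_sinus_hr,
        apbs_per_24h=n_apb * scale,
        af_episodes_per_24h=len(af_eps) * scale,
        mean_af_duration=mean_af_dur,
        af_present=len(af_eps) > 0,
    )


# ---------------------------------------------------------------------------
# inducibility
# ---------------------------------------------------------------------------

def inducibility(animals: list[dict]) -> tuple[list[InducibilityRecord], dict]:
    """Per-animal inducibility records plus the cohort-level summary.

    Input: one dict per animal with ``cycle_outcomes`` (bool list, AF
    followed the cycle) and optionally ``induced_af_durations`` and
    ``animal``.  The cohort summary reports the percentage of animals with
    at least one induced episode (one decimal) and the mean +/- SEM of the
    per-animal cycle inducibility percentages.
    """
    if not animals:
        raise ValueError("empty cohort")
    records = []
    for i, a in enumerate(animals):
        outcomes = tuple(bool(x) for x in a["cycle_outcomes"])
        if not outcomes:
            raise ValueError("each animal needs at least one stimulation cycle")
        records.append(
            InducibilityRecord(
                animal=str(a.get("animal", f"af{i + 1:02d}")),
                cycle_outcomes=outcomes,
                induced_af_durations=tuple(a.get("induced_af_durations", ())),
            )
        )
    pct = np.array([r.cycle_inducibility_pct for r in records])
    n_ind = sum(r.animal_inducible for r in records)
    sem = float(np.std(pct, ddof=1) / np.sqrt(len(pct))) if len(pct) > 1 else float("nan")
    durations = [d for r in records for d in r.induced_af_durations]
    summary = {
        "n_animals": len(records),
        "n_inducible": n_ind,
        "percent_animals_inducible": round(100.0 * n_ind / len(records), 1),
        "mean_cycle_inducibility_pct": float(np.mean(pct)),
        "sem_cycle_inducibility_pct": sem,
        "mean_induced_af_duration_s": float(np.mean(durations)) if durations else 0.0,
    }
    return records, summary


# ---------------------------------------------------------------------------
# evaluation helper
# ---------------------------------------------------------------------------

def episode_recall_precision(
    true_episodes: list[Episode],
    detected_episodes: list[Episode],
    episode_type: str = AF,
) -> dict:
    """Greedy one-to-one overlap matching of detected vs ground-truth episodes.

    Two episodes match when their time intervals overlap.  Returns recall,
    precision and the matched pairs' start/end discrepancies (s).
    """
    truth = [e for e in true_episodes if e.type == episode_type]
    det = [e for e in detected_episodes if e.type == episode_type]
    used = set()
    matches = []
    for te in truth:
        best, best_ov = None, 0.0
        for k, de in enumerate(det):
            if k in used:
                continue
            ov = min(te.end_s, de.end_s) - max(te.start_s, de.start_s)
            if ov > best_ov:
                best, best_ov = k, ov
        if best is not None and best_ov > 0:
            used.add(best)
            de = det[best]
            matches.append((abs(de.start_s - te.start_s), abs(de.end_s - te.end_s)))
    recall = len(matches) / len(truth) if truth else 1.0
    precision = len(matches) / len(det) if det else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_true": len(truth),
        "n_detected": len(det),
        "start_errors_s": [m[0] for m in matches],
        "end_errors_s": [m[1] for m in matches],
    }
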