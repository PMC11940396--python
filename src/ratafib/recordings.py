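"""Core containers for annotated beat-train recordings.

A recording is a strictly increasing series of beat times with per-beat
rhythm labels and P-wave flags, plus the ground-truth (or detected) list of
arrhythmic episodes.  Everything downstream — injection, detection,
classification, burden and HRV — speaks this vocabulary.

On disk a recording is two small CSV files (``beats.csv`` with columns
``time_s,label,p_present,p_morph_match`` and ``episodes.csv`` with
``start_s,end_s,type,n_beats``) plus an optional ``waveform.csv``
(``time_s,mV``); cohorts carry a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical per-beat labels
SINUS = "sinus"
APB = "apb"
AF = "af"
ARTIFACT = "artifact"
LABELS = (SINUS, APB, AF, ARTIFACT)

PERIODS = ("before", "week1", "week2", "after")


@dataclass(frozen=True)
class Episode:
    """One contiguous arrhythmic event.

    ``end_s`` follows the study convention: the episode runs from the first
    arrhythmic beat to the first subsequent sinus beat (recording end if
    none).  APB "episodes" are single beats with zero duration.
    """

    type: str
    start_s: float
    end_s: float
    n_beats: int

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("episode end precedes start")
        if self.type == AF and self.n_beats < 3:
            raise ValueError("AF episode must contain at least 3 beats")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Waveform:
    """Single-lead ECG trace in mV, uniformly sampled at ``fs`` Hz."""

    samples: np.ndarray
    fs: float

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class AnnotatedRecording:
    """Beat times + labels + P-wave flags + ground-truth episodes."""

    beat_times: np.ndarray
    beat_labels: np.ndarray
    p_present: np.ndarray
    p_morph_match: np.ndarray
    duration: float
    true_episodes: list[Episode] = field(default_factory=list)
    waveform: Waveform | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.beat_labels = np.asarray(self.beat_labels, dtype="<U8")
        self.p_present = np.asarray(self.p_present, dtype=bool)
        self.p_morph_match = np.asarray(self.p_morph_match, dtype=bool)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n = len(self.beat_times)
        for arr, name in (
            (self.beat_labels, "beat_labels"),
            (self.p_present, "p_present"),
            (self.p_morph_match, "p_morph_match"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != beat count {n}")
        if n and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat times must be strictly increasing")
        if n and (self.beat_times[0] < 0 or self.beat_times[-1] > self.duration + 1e-9):
            raise ValueError("beat times outside [0, duration]")
        af = self.beat_labels == AF
        if np.any(af & self.p_present):
            raise ValueError("AF beats must have p_present = False")
        for ep in self.true_episodes:
            if ep.type == AF and ep.n_beats < 3:
                raise ValueError("ground-truth AF episode shorter than 3 beats")

    # -- convenience ----------------------------------------------------
    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    def rr_ms(self) -> np.ndarray:
        """Successive RR intervals in ms (length ``n_beats - 1``)."""
        return np.diff(self.beat_times) * 1000.0

    def copy(self) -> "AnnotatedRecording":
        return replace(
            self,
            beat_times=self.beat_times.copy(),
            beat_labels=self.beat_labels.copy(),
            p_present=self.p_present.copy(),
            p_morph_match=self.p_morph_match.copy(),
            true_episodes=list(self.true_episodes),
            meta=dict(self.meta),
        )

    def beats_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.beat_times,
                "label": self.beat_labels,
                "p_present": self.p_present,
                "p_morph_match": self.p_morph_match,
            }
        )

    def episodes_frame(self) -> pd.DataFrame:
        return episodes_to_frame(self.true_episodes)


def episodes_to_frame(episodes: list[Episode]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [e.start_s for e in episodes],
            "end_s": [e.end_s for e in episodes],
            "type": [e.type for e in episodes],
            "n_beats": [e.n_beats for e in episodes],
        }
    )


def episodes_from_frame(df: pd.DataFrame) -> list[Episode]:
    return [
        Episode(type=r.type, start_s=float(r.start_s), end_s=float(r.end_s), n_beats=int(r.n_beats))
        for r in df.itertuples()
    ]


def derive_true_episodes(
    beat_times: np.ndarray, beat_labels: np.ndarray, duration: float
) -> list[Episode]:
    """Rebuild the ground-truth episode list from per-beat labels.

    AF episodes are maximal runs of ``af`` beats; the end time is the first
    subsequent sinus beat (recording end when none follows).  APBs become
    single-beat episodes.
    """
    episodes: list[Episode] = []
    labels = np.asarray(beat_labels)
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] == AF:
            j = i
            while j + 1 < n and labels[j + 1] == AF:
                j += 1
            end = duration
            for k in range(j + 1, n):
                if labels[k] == SINUS:
                    end = float(beat_times[k])
                    break
            episodes.append(
                Episode(type=AF, start_s=float(beat_times[i]), end_s=end, n_beats=j - i + 1)
            )
            i = j + 1
        else:
            if labels[i] == APB:
                t = float(beat_times[i])
                episodes.append(Episode(type=APB, start_s=t, end_s=t, n_beats=1))
            i += 1
    return episodes


# ---------------------------------------------------------------------------
# on-disk dialects
# ---------------------------------------------------------------------------

def write_recording(rec: AnnotatedRecording, outdir: str | Path, stem: str = "") -> dict:
    """Write a recording in the beats/episodes(/waveform) CSV dialect.

    Returns a manifest fragment (relative file names, duration, beat count).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = f"{stem}_" if stem else ""
    beats_name = f"{prefix}beats.csv"
    eps_name = f"{prefix}episodes.csv"
    rec.beats_frame().to_csv(outdir / beats_name, index=False)
    rec.episodes_frame().to_csv(outdir / eps_name, index=False)
    entry = {
        "beats": beats_name,
        "episodes": eps_name,
        "duration_s": rec.duration,
        "n_beats": rec.n_beats,
    }
    if rec.waveform is not None:
        wf_name = f"{prefix}waveform.csv"
        pd.DataFrame(
            {"time_s": rec.waveform.times, "mV": rec.waveform.samples}
        ).to_csv(outdir / wf_name, index=False, float_format="%.6f")
        entry["waveform"] = wf_name
        entry["fs"] = rec.waveform.fs
    return entry


def read_recording(outdir: str | Path, entry: dict) -> AnnotatedRecording:
    outdir = Path(outdir)
    beats = pd.read_csv(outdir / entry["beats"])
    episodes = episodes_from_frame(pd.read_csv(outdir / entry["episodes"]))
    waveform = None
    if "waveform" in entry:
        wf = pd.read_csv(outdir / entry["waveform"])
        waveform = Waveform(samples=wf["mV"].to_numpy(), fs=float(entry["fs"]))
    return AnnotatedRecording(
        beat_times=beats["time_s"].to_numpy(),
        beat_labels=beats["label"].to_numpy(),
        p_present=beats["p_present"].to_numpy(dtype=bool),
        p_morph_match=beats["p_morph_match"].to_numpy(dtype=bool),
        duration=float(entry["duration_s"]),
        true_episodes=episodes,
        waveform=waveform,
    )


def write_manifest(manifest: dict, outdir: str | Path) -> Path:
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest(outdir: str | Path) -> dict:
    return json.loads((Path(outdir) / "manifest.json").read_text())
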