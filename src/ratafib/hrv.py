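"""Heart rate variability on normal-to-normal (NN) intervals, rat bands.

Time domain: SDNN, RMSSD and pNN5 (the rodent-scaled analogue of pNN50 —
the proportion of successive NN differences strictly exceeding 5 ms).
Frequency domain: band powers in the rat LF (0.3–0.6 Hz) and HF
(0.6–2.5 Hz) bands from a Lomb–Scargle periodogram evaluated on the native
uneven time base of the NN series, normalized so that the integrated
spectrum equals the series variance.  An interpolation + FFT path is kept
behind a config flag for comparison.

Intervals touching any non-sinus beat (arrhythmic events, artifacts) are
excluded before analysis, with a configurable safety margin of neighbouring
intervals, mirroring manual artifact editing of telemetry traces.
Undefined metrics are reported as NaN with flags, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import binary_dilation

from .recordings import SINUS

__all__ = [
    "HRVConfig",
    "TimeDomainResult",
    "FreqDomainResult",
    "exclude_non_normal",
    "time_domain",
    "frequency_domain",
    "aggregate_recording",
    "hrv_per_recording",
]

_POWER_FLOOR = 1e-6  # ms^2, numerical floor for "no power"


@dataclass(frozen=True)
class HRVConfig:
    lf_band: tuple[float, float] = (0.3, 0.6)
    hf_band: tuple[float, float] = (0.6, 2.5)
    pnn_threshold_ms: float = 5.0
    epoch_length: float = 300.0
    min_nn_fraction: float = 0.4
    exclusion_margin: int = 1
    spectral_method: str = "lombscargle"  # or "interp_fft"
    oversample: int = 2

    def validate(self) -> None:
        for name, (lo, hi) in (("lf_band", self.lf_band), ("hf_band", self.hf_band)):
            if not 0 < lo < hi:
                raise ValueError(f"{name} edges must satisfy 0 < low < high")
        if self.pnn_threshold_ms <= 0:
            raise ValueError("pnn_threshold_ms must be positive")
        if self.min_nn_fraction <= 0 or self.min_nn_fraction > 1:
            raise ValueError("min_nn_fraction must be in (0, 1]")
        if self.spectral_method not in ("lombscargle", "interp_fft"):
            raise ValueError("spectral_method must be 'lombscargle' or 'interp_fft'")


@dataclass(frozen=True)
class TimeDomainResult:
    sdnn_ms: float
    rmssd_ms: float
    pnn5_pct: float
    n_nn: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.sdnn_ms)


@dataclass(frozen=True)
class FreqDomainResult:
    lf_ms2: float
    hf_ms2: float
    lf_hf: float
    total_power_ms2: float
    out_of_band_ms2: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.lf_ms2)


# ---------------------------------------------------------------------------
# NN extraction
# ---------------------------------------------------------------------------

def exclude_non_normal(
    rr_ms: np.ndarray,
    rr_times: np.ndarray,
    beat_labels: np.ndarray,
    cfg: HRVConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop every interval touching a non-sinus beat, plus a margin.

    Interval ``i`` is bounded by beats ``i`` and ``i+1`` and inherits the
    worst label of the two; excluded intervals take ``exclusion_margin``
    neighbours on each side with them.  Original timestamps are retained —
    gaps are left in place rather than spliced, which the Lomb–Scargle
    estimator handles natively.
    """
    cfg = cfg or HRVConfig()
    cfg.validate()
    rr = np.asarray(rr_ms, dtype=float)
    t = np.asarray(rr_times, dtype=float)
    labels = np.asarray(beat_labels)
    if len(labels) != len(rr) + 1:
        raise ValueError("need one beat label per interval bound (n_rr + 1)")
    bad = (labels[:-1] != SINUS) | (labels[1:] != SINUS)
    if cfg.exclusion_margin > 0 and bad.any():
        bad = binary_dilation(bad, iterations=cfg.exclusion_margin)
    return rr[~bad], t[~bad]


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def time_domain(nn_ms: np.ndarray, cfg: HRVConfig | None = None) -> TimeDomainResult:
    """SDNN (n-1 denominator), RMSSD and pNN5 (strict > threshold)."""
    cfg = cfg or HRVConfig()
    nn = np.asarray(nn_ms, dtype=float)
    n = len(nn)
    sdnn = float(np.std(nn, ddof=1)) if n >= 2 else float("nan")
    if n >= 3:
        d = np.diff(nn)
        rmssd = float(np.sqrt(np.mean(d**2)))
        pnn = 100.0 * np.sum(np.abs(d) > cfg.pnn_threshold_ms) / len(d)
    else:
        rmssd = float("nan")
        pnn = float("nan")
    return TimeDomainResult(sdnn_ms=sdnn, rmssd_ms=rmssd, pnn5_pct=float(pnn), n_nn=n)


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def _band_power(freqs, psd, band):
    lo, hi = band
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        return 0.0
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[mask]) * df)


def frequency_domain(
    nn_ms: np.ndarray, nn_times: np.ndarray, cfg: HRVConfig | None = None
) -> FreqDomainResult:
    """LF / HF band powers (ms^2) and their ratio from the NN spectrum.

    The periodogram is evaluated on the uneven native time base and rescaled
    by a single constant so its full-grid integral equals the sample
    variance of the NN series; band powers are then plain integrals over the
    configured bands.  Requires at least 64 NN intervals spanning >= 30 s.
    """
    cfg = cfg or HRVConfig()
    cfg.validate()
    nn = np.asarray(nn_ms, dtype=float)
    t = np.asarray(nn_times, dtype=float)
    if len(nn) < 64:
        raise ValueError("need at least 64 NN intervals for spectral analysis")
    span = t[-1] - t[0]
    if span < 30.0:
        raise ValueError("NN series must span at least 30 s")

    var = float(np.var(nn, ddof=1))
    if var < _POWER_FLOOR:
        return FreqDomainResult(
            lf_ms2=0.0, hf_ms2=0.0, lf_hf=float("nan"),
            total_power_ms2=0.0, out_of_band_ms2=0.0,
        )

    fmax = min(3.0, 0.5 * len(nn) / span)
    df = 1.0 / (cfg.oversample * span)
    freqs = np.arange(df, fmax, df)
    y = nn - nn.mean()

    if cfg.spectral_method == "lombscargle":
        psd = sps.lombscargle(t, y, 2 * np.pi * freqs)
    else:
        fs_r = 10.0
        tg = np.arange(t[0], t[-1], 1.0 / fs_r)
        yg = np.interp(tg, t, y)
        fg, pg = sps.periodogram(yg, fs=fs_r, window="boxcar", detrend="constant")
        psd = np.interp(freqs, fg, pg)

    total_raw = float(np.sum(psd) * df)
    if total_raw <= 0:
        return FreqDomainResult(
            lf_ms2=0.0, hf_ms2=0.0, lf_hf=float("nan"),
            total_power_ms2=0.0, out_of_band_ms2=0.0,
        )
    psd = psd * (var / total_raw)

    lf = _band_power(freqs, psd, cfg.lf_band)
    hf = _band_power(freqs, psd, cfg.hf_band)
    in_band = ((freqs >= cfg.lf_band[0]) & (freqs < cfg.lf_band[1])) | (
        (freqs >= cfg.hf_band[0]) & (freqs < cfg.hf_band[1])
    )
    oob = float(np.sum(psd[~in_band]) * df)
    lf_hf = lf / hf if hf > _POWER_FLOOR else float("nan")
    return FreqDomainResult(
        lf_ms2=lf, hf_ms2=hf, lf_hf=lf_hf,
        total_power_ms2=float(np.sum(psd) * df), out_of_band_ms2=oob,
    )


# ---------------------------------------------------------------------------
# epochs and aggregation
# ---------------------------------------------------------------------------

def aggregate_recording(
    epoch_metrics: list[dict], valid: list[bool]
) -> tuple[dict, int]:
    """Per-metric median across valid epochs; returns (summary, n_rejected).

    With zero valid epochs every metric is NaN (undefined-flagged).
    """
    if len(epoch_metrics) != len(valid):
        raise ValueError("validity flags must align with epochs")
    keep = [m for m, v in zip(epoch_metrics, valid) if v]
    n_rejected = len(epoch_metrics) - len(keep)
    if not keep:
        keys = set().union(*(m.keys() for m in epoch_metrics)) if epoch_metrics else set()
        return {k: float("nan") for k in keys}, n_rejected
    keys = keep[0].keys()
    summary = {
        k: float(np.nanmedian([m[k] for m in keep])) for k in keys
    }
    return summary, n_rejected


def hrv_per_recording(
    rr_ms: np.ndarray,
    rr_times: np.ndarray,
    beat_labels: np.ndarray,
    duration: float,
    cfg: HRVConfig | None = None,
) -> dict:
    """Epoch a recording, compute HRV per epoch, and aggregate by median.

    An epoch is valid when its NN count reaches ``min_nn_fraction`` x the
    count expected from the overall median NN.  Returns the aggregate
    metric dict plus epoch bookkeeping.
    """
    cfg = cfg or HRVConfig()
    cfg.validate()
    nn, t = exclude_non_normal(rr_ms, rr_times, beat_labels, cfg)
    n_epochs = max(int(duration // cfg.epoch_length), 1)
    med_nn = np.median(nn) if len(nn) else float("nan")
    epoch_metrics: list[dict] = []
    valid: list[bool] = []
    for k in range(n_epochs):
        lo, hi = k * cfg.epoch_length, (k + 1) * cfg.epoch_length
        mask = (t >= lo) & (t < hi)
        nn_e, t_e = nn[mask], t[mask]
        expected = cfg.epoch_length / (med_nn / 1000.0) if med_nn > 0 else np.inf
        ok = len(nn_e) >= cfg.min_nn_fraction * expected
        td = time_domain(nn_e, cfg) if len(nn_e) >= 2 else None
        metrics = {
            "sdnn_ms": td.sdnn_ms if td else float("nan"),
            "rmssd_ms": td.rmssd_ms if td else float("nan"),
            "pnn5_pct": td.pnn5_pct if td else float("nan"),
        }
        try:
            fd = frequency_domain(nn_e, t_e, cfg)
            metrics.update(
                {"lf_ms2": fd.lf_ms2, "hf_ms2": fd.hf_ms2, "lf_hf": fd.lf_hf}
            )
        except ValueError:
            metrics.update(
                {"lf_ms2": float("nan"), "hf_ms2": float("nan"), "lf_hf": float("nan")}
            )
            ok = False
        epoch_metrics.append(metrics)
        valid.append(bool(ok))
    summary, n_rejected = aggregate_recording(epoch_metrics, valid)
    summary["n_epochs"] = float(n_epochs)
    summary["n_epochs_rejected"] = float(n_rejected)
    summary["n_nn"] = float(len(nn))
    return summary
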