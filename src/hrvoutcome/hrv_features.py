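"""Per-epoch heart-rate-variability (HRV) features from RR-interval series.

An RR-interval series is the sequence of times between consecutive heart
beats, in milliseconds.  The series is cut into consecutive fixed-length
epochs (30 minutes by default) and, for each complete epoch, twenty HRV
parameters are computed:

* time domain — mean heart rate (HR), mean RR, SDNN, RMSSD, CVRR;
* frequency domain — peak frequency, absolute power (ms²), relative power
  (% of total) for the VLF / LF / HF bands, normalized-unit LF and HF
  power, total spectral power and the LF/HF ratio, all from a Welch
  periodogram of the cubic-spline-resampled tachogram;
* Poincaré plot — SD1 and SD2, the short- and long-term dispersion of the
  lag-1 return map.

The resulting table (one row per 30-minute time point, time points
numbered from 1) is the input to the sliding-window distance features in
:mod:`hrvoutcome.distance_features`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import detrend as _linear_detrend
from scipy.signal import welch

__all__ = [
    "FEATURE_NAMES",
    "RRSeries",
    "Epoch",
    "SpectralConfig",
    "segment_epochs",
    "time_domain",
    "resample_rr",
    "spectral_features",
    "poincare_features",
    "compute_feature_table",
    "filter_artifacts",
]

#: The 20 per-epoch HRV parameters, in canonical column order.
FEATURE_NAMES: tuple[str, ...] = (
    "HR", "RR", "SDNN", "RMSSD", "CVRR",
    "VLF_Hz", "LF_Hz", "HF_Hz",
    "VLF_ms_sq", "LF_ms_sq", "HF_ms_sq",
    "VLF_perc", "LF_perc", "HF_perc",
    "LF_nu", "HF_nu",
    "Total_ms_sq", "LF_HF",
    "SD1", "SD2",
)

_TIME_DOMAIN = ("HR", "RR", "SDNN", "RMSSD", "CVRR")
_SPECTRAL = (
    "VLF_Hz", "LF_Hz", "HF_Hz", "VLF_ms_sq", "LF_ms_sq", "HF_ms_sq",
    "VLF_perc", "LF_perc", "HF_perc", "LF_nu", "HF_nu", "Total_ms_sq", "LF_HF",
)
_POINCARE = ("SD1", "SD2")


@dataclass(frozen=True)
class RRSeries:
    """One patient's RR-interval sequence.

    Parameters
    ----------
    patient_id
        Opaque identifier.
    intervals
        RR durations in milliseconds, one per beat-to-beat interval.
    start_offsets
        Onset time of each interval in seconds from the record start;
        ``start_offsets[k+1] - start_offsets[k] == intervals[k] / 1000``.
    """

    patient_id: str
    intervals: np.ndarray
    start_offsets: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        off = np.asarray(self.start_offsets, dtype=float)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "start_offsets", off)
        if iv.size == 0:
            raise ValueError("no beats")
        if iv.shape != off.shape:
            raise ValueError("intervals and start_offsets must have equal length")
        if np.any(iv <= 0):
            raise ValueError("all RR intervals must be positive")
        gaps = np.diff(off)
        if np.any(gaps <= 0):
            raise ValueError("start_offsets must be strictly increasing")
        if not np.allclose(gaps, iv[:-1] / 1000.0, rtol=1e-6, atol=1e-6):
            raise ValueError("start_offsets inconsistent with intervals")

    @classmethod
    def from_intervals(cls, patient_id: str, intervals_ms, start: float = 0.0) -> "RRSeries":
        """Build a series from intervals alone, placing the first onset at *start*."""
        iv = np.asarray(intervals_ms, dtype=float)
        if iv.size == 0:
            raise ValueError("no beats")
        offsets = start + np.concatenate(([0.0], np.cumsum(iv[:-1]) / 1000.0))
        return cls(patient_id, iv, offsets)

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def duration(self) -> float:
        """Record length in seconds (end of the last interval)."""
        return float(self.start_offsets[-1] + self.intervals[-1] / 1000.0)


@dataclass(frozen=True)
class Epoch:
    """RR intervals whose onsets fall in the half-open span [start, end)."""

    index: int
    start: float
    end: float
    intervals: np.ndarray
    onsets: np.ndarray

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def span(self) -> float:
        """Time covered by the beats themselves (first to last onset), seconds."""
        if self.intervals.size == 0:
            return 0.0
        return float(self.onsets[-1] - self.onsets[0])


@dataclass(frozen=True)
class SpectralConfig:
    """Frequency-analysis settings.

    Band limits follow the short-term Task-Force convention: VLF [0, 0.04),
    LF [0.04, 0.15), HF [0.15, 0.4] Hz.  The tachogram is resampled at
    ``fs`` Hz, linearly detrended per epoch, and the PSD estimated by
    Welch's method with Hann windows of ``window_seconds`` and 50% overlap.
    """

    fs: float = 4.0
    vlf: tuple[float, float] = (0.0, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)
    window_seconds: float = 256.0
    overlap: float = 0.5
    detrend: str = "linear"  # "linear" | "none"


DEFAULT_SPECTRAL = SpectralConfig()


def segment_epochs(series: RRSeries, epoch_minutes: float = 30.0) -> list[Epoch]:
    """Cut a series into consecutive complete epochs of *epoch_minutes*.

    Intervals are assigned to epochs by beat-onset time with half-open
    spans ``[k*T, (k+1)*T)``.  A trailing partial epoch is dropped: only
    epochs entirely covered by the record are returned.
    """
    if series.intervals.size == 0:  # defensive; RRSeries forbids this
        raise ValueError("no beats")
    span = float(epoch_minutes) * 60.0
    n_complete = int(series.duration // span)
    epochs: list[Epoch] = []
    idx = np.floor(series.start_offsets / span).astype(int)
    for k in range(n_complete):
        mask = idx == k
        epochs.append(
            Epoch(
                index=k,
                start=k * span,
                end=(k + 1) * span,
                intervals=series.intervals[mask],
                onsets=series.start_offsets[mask],
            )
        )
    return epochs


def time_domain(epoch: Epoch, hr_method: str = "instantaneous") -> dict[str, float]:
    """Time-domain parameters of one epoch.

    ``RR`` is the arithmetic mean interval (ms); ``HR`` is by default the
    mean of per-beat instantaneous rates ``60000 / RR_k`` (beats/min), the
    convention of common HRV software; ``hr_method="mean_rr"`` uses
    ``60000 / mean(RR)`` instead.  ``SDNN`` is the sample standard
    deviation (n−1 denominator), ``RMSSD`` the root mean squared
    successive difference and ``CVRR = SDNN / RR``.
    """
    x = epoch.intervals
    if x.size < 2:
        raise ValueError("epoch too short")
    rr = float(np.mean(x))
    if hr_method == "instantaneous":
        hr = float(np.mean(60000.0 / x))
    elif hr_method == "mean_rr":
        hr = 60000.0 / rr
    else:
        raise ValueError(f"unknown hr_method {hr_method!r}")
    sdnn = float(np.std(x, ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    return {"HR": hr, "RR": rr, "SDNN": sdnn, "RMSSD": rmssd, "CVRR": sdnn / rr}


def resample_rr(epoch: Epoch, fs: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resample RR(t) onto a uniform grid at *fs* Hz.

    Returns ``(times, rr_ms)``.  Requires at least 4 beats spanning at
    least 60 s, so the tachogram is long enough for spectral estimation.
    """
    if epoch.n_beats < 4 or epoch.span < 60.0:
        raise ValueError("epoch unusable for spectral analysis")
    t = epoch.onsets
    spline = CubicSpline(t, epoch.intervals)
    n = int(np.floor((t[-1] - t[0]) * fs)) + 1
    grid = t[0] + np.arange(n) / fs
    return grid, spline(grid)


def _band_power(f: np.ndarray, psd: np.ndarray, lo: float, hi: float,
                closed_hi: bool) -> tuple[float, float]:
    mask = (f >= lo) & ((f <= hi) if closed_hi else (f < hi))
    if mask.sum() < 2:
        return 0.0, np.nan
    fb, pb = f[mask], psd[mask]
    return float(np.trapezoid(pb, fb)), float(fb[int(np.argmax(pb))])


def spectral_features(tachogram: np.ndarray, config: SpectralConfig = DEFAULT_SPECTRAL
                      ) -> dict[str, float]:
    """Welch-PSD band features of a uniformly sampled tachogram (ms).

    Absolute band power is the integral of the PSD over the band (ms²);
    relative power is band power as % of the full-spectrum total;
    normalized units follow the Task-Force convention, dividing by total
    power up to the HF upper limit minus VLF — i.e. LF + HF — so
    ``LF_nu + HF_nu == 100`` whenever both are defined.  ``LF_HF`` is
    missing (NaN) when HF power is zero.
    """
    x = np.asarray(tachogram, dtype=float)
    if config.detrend == "linear":
        x = _linear_detrend(x, type="linear")
    nperseg = min(x.size, int(round(config.window_seconds * config.fs)))
    f, psd = welch(
        x,
        fs=config.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * config.overlap),
        detrend=False,
    )
    total = float(np.trapezoid(psd, f))
    vlf, vlf_pk = _band_power(f, psd, *config.vlf, closed_hi=False)
    lf, lf_pk = _band_power(f, psd, *config.lf, closed_hi=False)
    hf, hf_pk = _band_power(f, psd, *config.hf, closed_hi=True)
    out = {
        "VLF_Hz": vlf_pk, "LF_Hz": lf_pk, "HF_Hz": hf_pk,
        "VLF_ms_sq": vlf, "LF_ms_sq": lf, "HF_ms_sq": hf,
        "Total_ms_sq": total,
    }
    if total > 0:
        out["VLF_perc"] = vlf / total * 100.0
        out["LF_perc"] = lf / total * 100.0
        out["HF_perc"] = hf / total * 100.0
    else:
        out["VLF_perc"] = out["LF_perc"] = out["HF_perc"] = np.nan
    denom = lf + hf  # total power inside the LF+HF range, i.e. TP(≤HF) − VLF
    if denom > 0:
        out["LF_nu"] = lf / denom * 100.0
        out["HF_nu"] = hf / denom * 100.0
    else:
        out["LF_nu"] = out["HF_nu"] = np.nan
    out["LF_HF"] = lf / hf if hf > 0 else np.nan
    return out


def poincare_features(epoch: Epoch) -> dict[str, float]:
    """Poincaré-plot SD1/SD2 of one epoch.

    SD1 = sqrt(SDSD²/2) with SDSD the sample standard deviation of
    successive differences; SD2 = sqrt(2·SDNN² − SDSD²/2), with the
    radicand clamped at 0.  These equal the dispersion of the lag-1
    return map perpendicular to and along the identity line.
    """
    x = epoch.intervals
    if x.size < 3:
        raise ValueError("epoch too short for Poincaré analysis")
    sdsd = float(np.std(np.diff(x), ddof=1))
    sdnn = float(np.std(x, ddof=1))
    sd1 = float(np.sqrt(0.5 * sdsd**2))
    sd2 = float(np.sqrt(max(2.0 * sdnn**2 - 0.5 * sdsd**2, 0.0)))
    return {"SD1": sd1, "SD2": sd2}


def compute_feature_table(
    series: RRSeries,
    epoch_minutes: float = 30.0,
    spectral: SpectralConfig = DEFAULT_SPECTRAL,
    hr_method: str = "instantaneous",
) -> pd.DataFrame:
    """The per-epoch HRV feature table for one patient.

    One row per complete epoch, ``time_point`` numbered from 1.  Epochs
    that fail a sub-analysis precondition (too few beats, insufficient
    span for spectral estimation) keep their row with the affected
    columns missing — rows are never silently dropped.
    """
    epochs = segment_epochs(series, epoch_minutes=epoch_minutes)
    if not epochs:
        raise ValueError("record yields zero complete epochs")
    rows = []
    for ep in epochs:
        row: dict[str, float] = {name: np.nan for name in FEATURE_NAMES}
        if ep.n_beats >= 2:
            row.update(time_domain(ep, hr_method=hr_method))
        if ep.n_beats >= 3:
            row.update(poincare_features(ep))
        try:
            _, tach = resample_rr(ep, fs=spectral.fs)
        except ValueError:
            pass
        else:
            row.update(spectral_features(tach, config=spectral))
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    table.insert(0, "time_point", np.arange(1, len(rows) + 1))
    table.insert(0, "patient_id", series.patient_id)
    return table


def filter_artifacts(
    series: RRSeries,
    min_ms: float = 300.0,
    max_ms: float = 2000.0,
    max_rel_diff: float = 0.2,
) -> RRSeries:
    """Optional ectopic/artifact pre-filter (off by default in the pipeline).

    Drops intervals outside ``[min_ms, max_ms]`` or differing by more than
    ``max_rel_diff`` from the previously accepted interval, then rebuilds
    the series from the surviving intervals.  Note that removal compacts
    the time axis; the filter is intended for lightly contaminated records.
    """
    kept: list[float] = []
    last: float | None = None
    for v in series.intervals:
        if not (min_ms <= v <= max_ms):
            continue
        if last is not None and abs(v - last) / last > max_rel_diff:
            continue
        kept.append(float(v))
        last = float(v)
    if not kept:
        raise ValueError("no beats survive artifact filtering")
    n_dropped = series.n_beats - len(kept)
    if n_dropped:
        warnings.warn(f"artifact filter dropped {n_dropped} of {series.n_beats} intervals")
    return RRSeries.from_intervals(series.patient_id, kept, start=float(series.start_offsets[0]))
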