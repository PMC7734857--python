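"""Synthetic ICU cohorts with outcome-dependent autonomic structure.

The generator is a stand-in for bedside ECG recordings: each patient's
instantaneous RR interval is a sum of sinusoidal autonomic oscillations
(an LF component near 0.1 Hz and an HF component near 0.25 Hz), a slow
circadian-scale drift and per-beat Gaussian broadband noise, integrated
into beat times.  It is deliberately not a physiological ECG simulator —
it exists to give the time- and frequency-domain HRV features real,
controllable structure.

Cohorts mirror the structure of a small TBI study population: 21
survivors and 5 non-survivors with up to 48 half-hour epochs each, two
non-survivors with truncated records.  Non-survivors receive reduced LF
/ HF / broadband variability (multiplicative effect sizes) and an
hourly multiplicative variability decay, consistent with reports of
depressed heart-rate variability after severe brain injury.  Severity
scores (APACHE II / III, SAPS surrogates) are Gaussian with
group-shifted means, with overlap chosen so a score-only classifier
reaches an AUC around 0.7.  Every sampled parameter is recorded in a
ground-truth log so recovery experiments have an unambiguous answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance_features import DistanceFeatureConfig, sliding_dist
from .hrv_features import DEFAULT_SPECTRAL, RRSeries, SpectralConfig, compute_feature_table
from .model_selection import CohortDataset, Patient

__all__ = ["RRGeneratorParams", "CohortConfig", "gen_rr_series", "gen_cohort",
           "gen_planted_cohort"]


@dataclass(frozen=True)
class RRGeneratorParams:
    """Parameters of one synthetic RR-interval record.

    Amplitudes are in milliseconds.  ``variability_decay`` is the hourly
    multiplier applied to the LF/HF amplitudes and the broadband noise
    (1.0 = stationary record; 0.95 = 5% amplitude loss per hour).
    """

    mean_rr: float = 900.0
    lf_amp: float = 30.0
    hf_amp: float = 20.0
    vlf_amp: float = 15.0
    broadband_sd: float = 25.0
    slow_trend_amp: float = 12.0
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    vlf_freq: float = 0.015
    trend_period_s: float = 86400.0
    variability_decay: float = 1.0

    def __post_init__(self) -> None:
        if not (300.0 <= self.mean_rr <= 2000.0):
            raise ValueError("mean_rr must lie in [300, 2000] ms")
        for name in ("lf_amp", "hf_amp", "vlf_amp", "broadband_sd", "slow_trend_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.variability_decay <= 1.0):
            raise ValueError("variability_decay must be in (0, 1]")


def gen_rr_series(params: RRGeneratorParams, duration_hours: float, seed,
                  patient_id: str = "synthetic") -> RRSeries:
    """Generate one RR-interval record of the requested duration.

    Beats are emitted at cumulative RR times; modulation phases are drawn
    from the seed.  The last beat crosses the requested duration so the
    record always yields ``floor(duration / epoch)`` complete epochs.
    Identical seeds give identical series.
    """
    if duration_hours <= 0:
        raise ValueError("duration must be positive")
    duration_s = duration_hours * 3600.0
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=4)
    n = int(duration_s / (params.mean_rr / 1000.0) * 1.25) + 32
    noise = rng.normal(0.0, 1.0, size=n) * params.broadband_sd

    def rr_at(t: np.ndarray, nz: np.ndarray) -> np.ndarray:
        dec = params.variability_decay ** (t / 3600.0)
        rr = (
            params.mean_rr
            + dec * params.lf_amp * np.sin(2 * np.pi * params.lf_freq * t + phi[0])
            + dec * params.hf_amp * np.sin(2 * np.pi * params.hf_freq * t + phi[1])
            + params.vlf_amp * np.sin(2 * np.pi * params.vlf_freq * t + phi[3])
            + params.slow_trend_amp * np.sin(2 * np.pi * t / params.trend_period_s + phi[2])
            + dec * nz
        )
        return np.clip(rr, 250.0, None)

    # beat times feed back into the modulators; one fixed-point refinement
    # of the nominal beat grid is accurate to well under a beat.
    t_nominal = np.arange(n) * params.mean_rr / 1000.0
    rr = rr_at(t_nominal, noise)
    onsets = np.concatenate(([0.0], np.cumsum(rr[:-1]) / 1000.0))
    rr = rr_at(onsets, noise)
    onsets = np.concatenate(([0.0], np.cumsum(rr[:-1]) / 1000.0))
    ends = onsets + rr / 1000.0
    if ends[-1] < duration_s:  # noise made beats run fast; extend deterministically
        extra = int((duration_s - ends[-1]) / (params.mean_rr / 1000.0)) + 8
        noise = np.concatenate([noise, rng.normal(0.0, 1.0, size=extra) * params.broadband_sd])
        t_all = np.concatenate([onsets, ends[-1] + np.arange(extra) * params.mean_rr / 1000.0])
        rr = rr_at(t_all, noise[: t_all.size])
        onsets = np.concatenate(([0.0], np.cumsum(rr[:-1]) / 1000.0))
        ends = onsets + rr / 1000.0
    last = int(np.searchsorted(ends, duration_s))  # first beat ending >= duration
    last = min(last, rr.size - 1)
    rr = rr[: last + 1]
    return RRSeries.from_intervals(patient_id, rr)


def _default_score_params() -> dict[str, tuple[float, float, float]]:
    # name -> (survivor mean, sd, non-survivor mean shift)
    return {
        "APACHE_II": (15.0, 6.0, 4.5),
        "APACHE_III": (55.0, 20.0, 15.0),
        "SAPS": (40.0, 12.0, 9.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition, effect sizes and per-group distributions.

    Defaults reproduce the study-like conditions: 21 survivors, 5
    non-survivors (2 truncated to 6–12 h), 24-hour records in 30-minute
    epochs.  The non-survivor signature is multiplicative — LF/HF
    amplitudes and broadband noise scaled by the ``*_multiplier`` effect
    sizes plus an hourly variability decay.  Setting all multipliers to 1
    and the decay to 1 makes the groups exchangeable (a null cohort).
    """

    n_survivors: int = 21
    n_non_survivors: int = 5
    record_hours: float = 24.0
    epoch_minutes: float = 30.0
    n_truncated_non_survivors: int = 2
    truncated_hours_range: tuple[float, float] = (6.0, 12.0)
    rng_seed: int = 0
    lf_amp_multiplier: float = 0.5
    hf_amp_multiplier: float = 0.5
    sdnn_multiplier: float = 0.5  # scales broadband noise, hence SDNN
    ns_variability_decay: float = 0.97
    n_window: int = 8
    score_params: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_score_params)
    # survivor-population parameter distributions: (mean, sd)
    mean_rr_dist: tuple[float, float] = (900.0, 70.0)
    lf_amp_dist: tuple[float, float] = (30.0, 6.0)
    hf_amp_dist: tuple[float, float] = (20.0, 4.0)
    vlf_amp_dist: tuple[float, float] = (15.0, 4.0)
    broadband_sd_dist: tuple[float, float] = (25.0, 5.0)
    slow_trend_amp_dist: tuple[float, float] = (12.0, 3.0)

    def __post_init__(self) -> None:
        if min(self.n_survivors, self.n_non_survivors) < 0:
            raise ValueError("cohort counts must be non-negative")
        if self.n_truncated_non_survivors > self.n_non_survivors:
            raise ValueError("more truncated non-survivors than non-survivors")
        lo, hi = self.truncated_hours_range
        if lo > hi or lo <= 0:
            raise ValueError("invalid truncated_hours_range")
        # a truncated record must still hold at least one distance window
        if lo * 60.0 / self.epoch_minutes < self.n_window:
            raise ValueError("truncated records would be shorter than the distance window")

    def null(self) -> "CohortConfig":
        """A copy with all group effects switched off (exchangeable groups)."""
        from dataclasses import replace
        return replace(self, lf_amp_multiplier=1.0, hf_amp_multiplier=1.0,
                       sdnn_multiplier=1.0, ns_variability_decay=1.0,
                       score_params={k: (m, s, 0.0) for k, (m, s, _) in
                                     self.score_params.items()})


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     floor: float = 1e-3) -> float:
    return float(max(rng.normal(mean, sd), floor))


def gen_cohort(config: CohortConfig,
               spectral: SpectralConfig = DEFAULT_SPECTRAL
               ) -> tuple[CohortDataset, dict]:
    """Generate a labelled cohort with feature and distance tables.

    Returns the dataset and a ground-truth log mapping each patient to
    the exact generator parameters, record length and label used.
    """
    rng = np.random.default_rng(config.rng_seed)
    patients: list[Patient] = []
    truth: dict[str, dict] = {}
    dconf = DistanceFeatureConfig(n_window=config.n_window)
    specs = [("S", 0, config.n_survivors), ("N", 1, config.n_non_survivors)]
    for prefix, label, count in specs:
        for i in range(count):
            pid = f"{prefix}{i + 1:02d}"
            base = {
                "mean_rr": float(np.clip(rng.normal(*config.mean_rr_dist), 400.0, 1800.0)),
                "lf_amp": _positive_normal(rng, *config.lf_amp_dist),
                "hf_amp": _positive_normal(rng, *config.hf_amp_dist),
                "vlf_amp": _positive_normal(rng, *config.vlf_amp_dist),
                "broadband_sd": _positive_normal(rng, *config.broadband_sd_dist),
                "slow_trend_amp": _positive_normal(rng, *config.slow_trend_amp_dist),
            }
            decay = 1.0
            hours = config.record_hours
            if label == 1:
                base["lf_amp"] *= config.lf_amp_multiplier
                base["hf_amp"] *= config.hf_amp_multiplier
                base["broadband_sd"] *= config.sdnn_multiplier
                decay = config.ns_variability_decay
                if i < config.n_truncated_non_survivors:
                    hours = float(rng.uniform(*config.truncated_hours_range))
            params = RRGeneratorParams(variability_decay=decay, **base)
            series_seed = int(rng.integers(0, 2**31 - 1))
            series = gen_rr_series(params, hours, seed=series_seed, patient_id=pid)
            features = compute_feature_table(series, epoch_minutes=config.epoch_minutes,
                                             spectral=spectral)
            distf = sliding_dist(features, dconf)
            scores = {
                name: round(float(mean + shift * label + rng.normal(0.0, sd)), 1)
                for name, (mean, sd, shift) in config.score_params.items()
            }
            patients.append(Patient(patient_id=pid, label=label, scores=scores,
                                    features=features, distf=distf))
            truth[pid] = {
                "label": label,
                "record_hours": hours,
                "seed": series_seed,
                "variability_decay": decay,
                "scores": scores,
                **base,
            }
    return CohortDataset(patients), truth


#: Candidate distance features for the planted-recovery experiment: the two
#: planted band-power features plus eight that carry no group signal under
#: the planted balance shift (see :func:`gen_planted_cohort`).
PLANTED_FEATURES = ("DistLF_ms_sq", "DistHF_ms_sq")
PLANTED_CANDIDATES = (
    "DistHR", "DistRR", "DistVLF_Hz", "DistLF_Hz", "DistHF_Hz",
    "DistVLF_ms_sq", "DistSDNN", "DistVLF_perc",
    "DistLF_ms_sq", "DistHF_ms_sq",
)


def gen_planted_cohort(
    seed,
    n_survivors: int = 45,
    n_non_survivors: int = 15,
    record_hours: float = 8.0,
    n_window: int = 8,
    survivor_balance_deg: tuple[float, float] = (36.0, 55.0),
    non_survivor_balance_deg: tuple[float, float] = (15.0, 34.0),
) -> tuple[CohortDataset, dict]:
    """Cohort with a sympathovagal balance shift planted in the two band powers.

    Each patient's LF and HF oscillation amplitudes are ``A·cos(θ)`` and
    ``A·sin(θ)``: the combined oscillatory power ``A²/2`` is drawn from
    the same distribution in both groups, while the balance angle θ is
    drawn from ``survivor_balance_deg`` for survivors and from the
    LF-dominant ``non_survivor_balance_deg`` for non-survivors — the
    sympathetic-predominance signature reported for critically ill
    patients.  Because the shift moves power *between* the bands and
    leaves every variance aggregate unchanged, the outcome signal lives
    in exactly two of the :data:`PLANTED_CANDIDATES`: the LF power (up)
    and HF power (down) distance features.  Either band alone overlaps
    between groups; their combination — effectively the LF/HF balance —
    separates them, so a sound feature-selection wrapper must keep both.
    Ratio features, which encode the balance directly, are excluded from
    the candidate list.

    The cohort is larger than the study-sized default so that recovery
    reflects the selection machinery rather than small-sample chance.
    """
    rng = np.random.default_rng(seed)
    dconf = DistanceFeatureConfig(n_window=n_window)
    patients: list[Patient] = []
    truth: dict[str, dict] = {}
    for prefix, label, count in (("S", 0, n_survivors), ("N", 1, n_non_survivors)):
        for i in range(count):
            pid = f"{prefix}{i + 1:02d}"
            amp = float(np.clip(rng.normal(35.0, 4.0), 27.0, 43.0))
            lo, hi = survivor_balance_deg if label == 0 else non_survivor_balance_deg
            theta = float(np.radians(rng.uniform(lo, hi)))
            params = RRGeneratorParams(
                mean_rr=float(np.clip(rng.normal(900.0, 70.0), 400.0, 1800.0)),
                lf_amp=amp * np.cos(theta), hf_amp=amp * np.sin(theta),
                vlf_amp=float(rng.uniform(10.0, 40.0)),
                broadband_sd=float(np.clip(rng.normal(8.0, 1.0), 6.0, 10.0)),
                slow_trend_amp=0.0,
            )
            series_seed = int(rng.integers(0, 2**31 - 1))
            series = gen_rr_series(params, record_hours, seed=series_seed, patient_id=pid)
            features = compute_feature_table(series)
            patients.append(Patient(patient_id=pid, label=label, scores={},
                                    features=features,
                                    distf=sliding_dist(features, dconf)))
            truth[pid] = {"label": label, "balance_deg": float(np.degrees(theta)),
                          "osc_amp": amp, "lf_amp": params.lf_amp,
                          "hf_amp": params.hf_amp, "seed": series_seed}
    return CohortDataset(patients), truth
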