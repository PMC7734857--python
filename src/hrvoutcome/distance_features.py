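"""Sliding-window Euclidean-distance features over consecutive HRV epochs.

For each HRV parameter F and each time point t, the distance feature is
the Euclidean norm of the window of n consecutive values starting at t,

    DistF(t) = sqrt(F_t² + F_{t+1}² + … + F_{t+n−1}²),

i.e. the distance of the window vector from an all-zero baseline.  It
summarises the magnitude of the parameter over the following n epochs; a
record with T epochs yields T − n + 1 distance rows (48 epochs and n = 8
give 41).  Raw, unstandardised values enter the norm by default, so
distance features inherit each parameter's physical scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .hrv_features import FEATURE_NAMES

__all__ = ["DIST_PREFIX", "DistanceFeatureConfig", "dist_feature", "sliding_dist", "dist_name"]

DIST_PREFIX = "Dist"


def dist_name(feature: str) -> str:
    """Column name of the distance feature derived from *feature*."""
    return DIST_PREFIX + feature


@dataclass(frozen=True)
class DistanceFeatureConfig:
    """Window length and the subset of HRV parameters to transform.

    ``n_window`` is the number of consecutive time points entering each
    norm (8 in the default analysis, chosen so that even heavily
    truncated records contribute at least one window).  ``zscore``
    standardises each parameter over the patient's rows before the norm;
    it is off by default because the distance is defined on raw values.
    """

    n_window: int = 8
    feature_names: tuple[str, ...] = FEATURE_NAMES
    zscore: bool = False

    def __post_init__(self) -> None:
        if self.n_window < 2:
            raise ValueError("n_window must be at least 2")
        unknown = set(self.feature_names) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")


def dist_feature(values) -> float:
    """Euclidean norm of one complete window of feature values.

    Raises if any value is missing or non-finite; the caller decides the
    skip policy for incomplete windows.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("window must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("incomplete window")
    return float(np.linalg.norm(x))


def sliding_dist(table: pd.DataFrame, config: DistanceFeatureConfig | None = None) -> pd.DataFrame:
    """Distance-feature table for one patient's epoch-feature table.

    Row t (1-based) covers the inclusive time-point window
    [t, t + n − 1].  Windows containing missing feature values produce a
    missing distance but keep their row, so time-point indices stay
    aligned across patients.
    """
    config = config or DistanceFeatureConfig()
    n = config.n_window
    if "time_point" not in table.columns:
        raise ValueError("table must carry a time_point column")
    table = table.sort_values("time_point").reset_index(drop=True)
    tp = table["time_point"].to_numpy()
    if not np.array_equal(tp, np.arange(1, len(tp) + 1)):
        raise ValueError("time points must be consecutive starting at 1")
    T = len(table)
    if T < n:
        raise ValueError("record shorter than window")
    out = pd.DataFrame(
        {
            "time_point": np.arange(1, T - n + 2),
            "window_start": np.arange(1, T - n + 2),
            "window_end": np.arange(n, T + 1),
        }
    )
    if "patient_id" in table.columns:
        out.insert(0, "patient_id", table["patient_id"].iloc[0])
    for name in config.feature_names:
        col = table[name].to_numpy(dtype=float)
        if config.zscore:
            sd = np.nanstd(col, ddof=1)
            col = (col - np.nanmean(col)) / sd if sd > 0 else col - np.nanmean(col)
        windows = sliding_window_view(col, n)
        dist = np.sqrt(np.sum(windows**2, axis=1))
        dist[~np.all(np.isfinite(windows), axis=1)] = np.nan
        out[dist_name(name)] = dist
    return out
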