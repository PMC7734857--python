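"""Plain-text readers and writers for the pipeline's tabular formats.

Formats:

* RR series — text file, one RR interval in milliseconds per line,
  ``#`` comment lines allowed; or CSV with ``patient_id, rr_ms`` columns
  (several patients per file).
* Epoch feature table — CSV: ``patient_id, time_point`` then the 20 HRV
  parameter columns.
* Distance feature table — CSV: ``patient_id, time_point, window_start,
  window_end`` then the ``Dist*`` columns.
* Labels — CSV: ``patient_id, outcome`` (``survivor`` / ``non-survivor``)
  and optional severity-score columns ``APACHE_II, APACHE_III, SAPS``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .hrv_features import FEATURE_NAMES, RRSeries
from .model_selection import SEVERITY_NAMES, CohortDataset, Patient

__all__ = [
    "read_rr_text",
    "read_rr_csv",
    "write_rr_text",
    "read_feature_csv",
    "read_distf_csv",
    "read_labels_csv",
    "write_labels_csv",
    "assemble_cohort",
    "write_selection_json",
]

OUTCOME_LABELS = {"survivor": 0, "non-survivor": 1}


def read_rr_text(path, patient_id: str | None = None) -> RRSeries:
    """Read one patient's RR intervals (ms, one per line, '#' comments)."""
    path = Path(path)
    values = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        values.append(float(line))
    return RRSeries.from_intervals(patient_id or path.stem, values)


def write_rr_text(path, series: RRSeries) -> None:
    lines = [f"# patient_id: {series.patient_id}", "# rr_ms"]
    lines += [f"{v:.3f}" for v in series.intervals]
    Path(path).write_text("\n".join(lines) + "\n")


def read_rr_csv(path) -> dict[str, RRSeries]:
    """Read a multi-patient RR CSV with columns patient_id, rr_ms."""
    df = pd.read_csv(path)
    missing = {"patient_id", "rr_ms"} - set(df.columns)
    if missing:
        raise ValueError(f"RR CSV missing columns: {sorted(missing)}")
    return {
        str(pid): RRSeries.from_intervals(str(pid), grp["rr_ms"].to_numpy(dtype=float))
        for pid, grp in df.groupby("patient_id", sort=False)
    }


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"patient_id", "time_point", *FEATURE_NAMES} - set(df.columns)
    if missing:
        raise ValueError(f"feature CSV missing columns: {sorted(missing)}")
    return df


def read_distf_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"patient_id", "time_point"} - set(df.columns)
    if missing:
        raise ValueError(f"distance CSV missing columns: {sorted(missing)}")
    return df


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"patient_id", "outcome"} - set(df.columns)
    if missing:
        raise ValueError(f"labels CSV missing columns: {sorted(missing)}")
    bad = set(df["outcome"]) - set(OUTCOME_LABELS)
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    return df


def write_labels_csv(path, dataset: CohortDataset) -> None:
    rows = []
    inv = {v: k for k, v in OUTCOME_LABELS.items()}
    for p in dataset.patients:
        row = {"patient_id": p.patient_id, "outcome": inv[p.label]}
        row.update({k: p.scores.get(k) for k in SEVERITY_NAMES if k in p.scores})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def assemble_cohort(features: pd.DataFrame, distf: pd.DataFrame,
                    labels: pd.DataFrame) -> CohortDataset:
    """Join per-patient feature, distance and label tables into a cohort."""
    patients = []
    for _, row in labels.iterrows():
        pid = str(row["patient_id"])
        feat = features[features["patient_id"].astype(str) == pid].reset_index(drop=True)
        dist = distf[distf["patient_id"].astype(str) == pid].reset_index(drop=True)
        if feat.empty:
            raise ValueError(f"no feature rows for patient {pid}")
        scores = {k: float(row[k]) for k in SEVERITY_NAMES
                  if k in labels.columns and pd.notna(row[k])}
        patients.append(Patient(patient_id=pid, label=OUTCOME_LABELS[row["outcome"]],
                                scores=scores, features=feat,
                                distf=dist if not dist.empty else None))
    return CohortDataset(patients)


def write_selection_json(path, result) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")
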