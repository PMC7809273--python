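"""Delimited-text readers/writers for cohorts, manifests, and clinical tables.

Time-series files are ROI-major (rows = ROIs, columns = timepoints, no
header); a ``transposed`` flag accepts T x R files. The cohort manifest is
a CSV with columns subject_id, group, path; the clinical table a CSV keyed
by subject_id. All serialization is plain text so runs diff cleanly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CohortTimeSeries, GroundTruth, RoiTimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "read_clinical",
    "write_cohort",
    "read_cohorts",
    "RunRecord",
]


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.17g")
    return path


def read_timeseries(path: str | Path, subject_id: str | None = None, transposed: bool = False) -> RoiTimeSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time-series file missing: {path}")
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    if transposed:
        values = values.T
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite cell at row {bad[0]}, column {bad[1]} in {path}")
    return RoiTimeSeries(subject_id=subject_id or path.stem, values=values)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "group", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing column(s) {sorted(missing)}")
    dupes = df["subject_id"][df["subject_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicated subject id(s): {sorted(dupes.unique().tolist())}")
    base = path.parent
    for _, row in df.iterrows():
        f = base / row["path"]
        if not f.exists():
            raise FileNotFoundError(f"manifest references missing file: {f}")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("clinical table must have a subject_id column")
    numeric = df.drop(columns=["subject_id", "group"], errors="ignore")
    if numeric.isna().any().any():
        col = numeric.columns[numeric.isna().any()][0]
        row = int(numeric[col].isna().idxmax())
        raise ValueError(f"NaN cell in clinical table: column {col!r}, row {row}")
    dupes = df["subject_id"][df["subject_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicated subject id(s): {sorted(dupes.unique().tolist())}")
    return df


def write_cohort(
    cohort_a: CohortTimeSeries,
    cohort_b: CohortTimeSeries,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Serialize a generated cohort: per-subject series, manifest, clinical CSV, truth JSON."""
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cohort in (cohort_a, cohort_b):
        for s in cohort.subjects:
            p = ts_dir / f"{s.subject_id}.tsv"
            write_timeseries(s, p)
            rows.append(
                {"subject_id": s.subject_id, "group": cohort.group_label, "path": str(p.relative_to(out))}
            )
    manifest_path = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    clinical_path = out / "clinical.csv"
    truth.clinical_table.to_csv(clinical_path, index=False)
    truth_path = out / "ground_truth.json"
    truth_payload = {
        "common_map": truth.common_map.tolist(),
        "base_partition": {g: v.tolist() for g, v in truth.base_partition.items()},
        "subject_partitions": {g: v.tolist() for g, v in truth.subject_partitions.items()},
        "true_diff_edges": sorted(list(e) for e in truth.true_diff_edges),
        "behavior_weights": {f"{i},{j}": w for (i, j), w in truth.behavior_weights.items()},
    }
    truth_path.write_text(json.dumps(truth_payload, indent=1))
    return {"manifest": manifest_path, "clinical": clinical_path, "ground_truth": truth_path}


def read_cohorts(manifest_path: str | Path, transposed: bool = False) -> dict[str, CohortTimeSeries]:
    """Load all groups referenced by a manifest into CohortTimeSeries objects."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    cohorts = {}
    for group, sub in manifest.groupby("group", sort=True):
        subjects = [
            read_timeseries(base / row["path"], row["subject_id"], transposed)
            for _, row in sub.iterrows()
        ]
        cohorts[str(group)] = CohortTimeSeries(group_label=str(group), subjects=subjects)
    return cohorts


@dataclass
class RunRecord:
    """Snapshot that makes a pipeline run reproducible."""

    config: dict
    package_version: str
    seeds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    stages_completed: list = field(default_factory=list)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunRecord":
        return cls(**json.loads(Path(path).read_text()))
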