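"""Subject records and the cohort manifest (CSV) read/written by every stage."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

__all__ = ["SubjectRecord", "read_manifest", "write_manifest", "GROUPS"]

GROUPS = ("patient", "control")

_REQUIRED = ["subject_id", "group", "hamd", "ts_path", "fa_path"]


@dataclass(frozen=True)
class SubjectRecord:
    """One row of the cohort manifest."""

    subject_id: str
    group: str  # 'patient' | 'control'
    hamd: float | None = None  # HAMD-like clinical score, >= 0
    ts_path: str | None = None  # regions x timepoints TSV
    fa_path: str | None = None  # FA-weighted symmetric matrix TSV

    def with_score(self, score: float) -> "SubjectRecord":
        return replace(self, hamd=score)


def read_manifest(path, check_files: bool = True) -> list[SubjectRecord]:
    """Read and validate a manifest CSV.

    Requires columns subject_id, group, hamd, ts_path, fa_path; rejects
    duplicate ids, unknown group labels and (optionally) missing data files.
    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing required columns: {missing_cols}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id in manifest: {sorted(set(dup))}")
    bad_groups = sorted(set(df["group"]) - set(GROUPS))
    if bad_groups:
        raise ValueError(
            f"unknown group labels {bad_groups}; allowed labels are {list(GROUPS)}"
        )
    records = []
    for row in df.itertuples(index=False):
        rec = SubjectRecord(
            subject_id=str(row.subject_id),
            group=str(row.group),
            hamd=float(row.hamd) if pd.notna(row.hamd) else None,
            ts_path=_resolve(path.parent, row.ts_path),
            fa_path=_resolve(path.parent, row.fa_path),
        )
        if check_files:
            for p in (rec.ts_path, rec.fa_path):
                if p is not None and not Path(p).is_file():
                    raise FileNotFoundError(
                        f"data file for subject {rec.subject_id} not found: {p}"
                    )
        records.append(rec)
    if not records:
        raise ValueError("manifest contains no subjects")
    return records


def _resolve(base: Path, value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    p = Path(str(value))
    return str(p if p.is_absolute() else base / p)


def write_manifest(path, records: list[SubjectRecord]) -> None:
    base = Path(path).parent
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "hamd": "" if r.hamd is None else r.hamd,
                "ts_path": _relativize(base, r.ts_path),
                "fa_path": _relativize(base, r.fa_path),
            }
        )
    pd.DataFrame(rows, columns=_REQUIRED).to_csv(path, index=False)


def _relativize(base: Path, value: str | None) -> str:
    if value is None:
        return ""
    p = Path(value)
    try:
        return str(p.relative_to(base))
    except ValueError:
        return str(p)
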