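"""Delimited-text readers, writers, and report formatting.

Two input layouts are supported:

* **RFV matrix** — one row per patient with columns
  ``patient_id, grade_1, ..., grade_K`` (header required).
* **Long AE table** — one row per AE occurrence with columns
  ``patient_id, treatment, grade`` and optional ``ae_term, cycle``;
  grade-0 rows are accepted but contribute nothing to the RFVs.

Patient RFVs are formed by counting AE records at each grade 1..K.  By
default records are pooled (summed) across all cycles; ``worst-cycle``
instead keeps, for each patient, the single cycle whose RFV has the
highest T-rank.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import Cohort, RateVector
from .summaries import RFV, t_rank_sort

__all__ = [
    "TrialTable",
    "read_long_ae",
    "read_rfv_matrix",
    "write_rfv_matrix",
    "profiles_from_table",
    "write_report",
    "write_table1_fixtures",
]

logger = logging.getLogger("toxindex")

_LONG_REQUIRED = ["patient_id", "treatment", "grade"]
_LONG_OPTIONAL = ["ae_term", "cycle"]


@dataclass(frozen=True)
class AERecord:
    patient_id: str
    treatment: str
    grade: int
    ae_term: str | None = None
    cycle: int | None = None


@dataclass
class TrialTable:
    """Validated long-format AE records plus the grade cap K."""

    records: list[AERecord]
    K: int = 5

    def __len__(self) -> int:
        return len(self.records)


def read_long_ae(path: "str | Path", delimiter: str = ",", K: int = 5) -> TrialTable:
    """Read a long-format AE file, validating every row.

    Malformed rows are reported with their line number (header = line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in _LONG_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header
        pid = str(row["patient_id"]).strip() if pd.notna(row["patient_id"]) else ""
        if not pid:
            raise ValueError(f"{path}:{line}: empty patient_id")
        treatment = str(row["treatment"]).strip()
        if not treatment or pd.isna(row["treatment"]):
            raise ValueError(f"{path}:{line}: empty treatment")
        try:
            grade = int(row["grade"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}:{line}: grade {row['grade']!r} is not an integer")
        if not 0 <= grade <= K:
            raise ValueError(f"{path}:{line}: grade {grade} outside [0, {K}]")
        ae_term = str(row["ae_term"]) if "ae_term" in df.columns and pd.notna(row["ae_term"]) else None
        cycle = None
        if "cycle" in df.columns and pd.notna(row["cycle"]):
            try:
                cycle = int(row["cycle"])
            except (TypeError, ValueError):
                raise ValueError(f"{path}:{line}: cycle {row['cycle']!r} is not an integer")
        records.append(AERecord(pid, treatment, grade, ae_term, cycle))
    logger.info("read %d AE records from %s", len(records), path)
    return TrialTable(records, K=K)


def profiles_from_table(
    table: TrialTable, cycle_policy: str = "sum"
) -> dict[str, Cohort]:
    """Aggregate a long AE table into one cohort per treatment.

    Each patient contributes one RFV counting their AE records at each
    grade 1..K.  ``cycle_policy='sum'`` pools records across cycles;
    ``'worst-cycle'`` keeps the per-cycle RFV with the highest T-rank.
    A patient listed under two treatments is an error.
    """
    if cycle_policy not in ("sum", "worst-cycle"):
        raise ValueError(f"unknown cycle policy {cycle_policy!r}")
    K = table.K
    arm_of: dict[str, str] = {}
    # patient -> cycle -> counts
    per_cycle: dict[str, dict[int | None, list[int]]] = {}
    for rec in table.records:
        if rec.patient_id in arm_of and arm_of[rec.patient_id] != rec.treatment:
            raise ValueError(
                f"patient {rec.patient_id!r} appears under treatments "
                f"{arm_of[rec.patient_id]!r} and {rec.treatment!r}"
            )
        arm_of[rec.patient_id] = rec.treatment
        cycles = per_cycle.setdefault(rec.patient_id, {})
        cyc = rec.cycle if cycle_policy == "worst-cycle" else None
        counts = cycles.setdefault(cyc, [0] * K)
        if rec.grade > 0:
            counts[rec.grade - 1] += 1

    cohorts: dict[str, list[RFV]] = {}
    for pid, cycles in per_cycle.items():
        if cycle_policy == "sum":
            rfv = RFV(next(iter(cycles.values())))
        else:
            candidates = [RFV(c) for c in cycles.values()]
            worst = t_rank_sort(candidates, descending=True)[0]
            rfv = candidates[worst]
        cohorts.setdefault(arm_of[pid], []).append(rfv)
    return {
        arm: Cohort(rfvs, treatment_label=arm) for arm, rfvs in sorted(cohorts.items())
    }


def read_rfv_matrix(path: "str | Path", delimiter: str = ",") -> Cohort:
    """Read an RFV matrix file (columns patient_id, grade_1..grade_K)."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter)
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'patient_id'")
    grade_cols = [c for c in df.columns if c.startswith("grade_")]
    expected = [f"grade_{k}" for k in range(1, len(grade_cols) + 1)]
    if not grade_cols or grade_cols != expected:
        raise ValueError(
            f"{path}: grade columns must be grade_1..grade_K in order, got {grade_cols}"
        )
    if df[grade_cols].isna().any().any():
        raise ValueError(f"{path}: missing grade values (truncated file?)")
    rfvs = []
    for idx, row in df.iterrows():
        try:
            rfvs.append(RFV(int(row[c]) for c in grade_cols))
        except ValueError as exc:
            raise ValueError(f"{path}:{idx + 2}: {exc}") from exc
    cohort = Cohort(rfvs, metadata={"patient_ids": [str(p) for p in df["patient_id"]]})
    logger.info("read %d RFVs (K=%d) from %s", len(cohort), cohort.K, path)
    return cohort


def write_rfv_matrix(
    cohort: Cohort, path: "str | Path", delimiter: str = ","
) -> None:
    """Write a cohort as an RFV matrix file (round-trips exactly)."""
    path = Path(path)
    ids = cohort.metadata.get(
        "patient_ids", [f"P{i+1}" for i in range(len(cohort))]
    )
    rows = {"patient_id": ids}
    mat = cohort.to_matrix().astype(int)
    for k in range(cohort.K):
        rows[f"grade_{k+1}"] = mat[:, k]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def _as_jsonable(value):
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(value).items()}
    if isinstance(value, RateVector):
        return list(value.rates)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if hasattr(value, "value") and value.__class__.__module__.startswith("toxindex"):
        return value.value  # enums
    return value


def write_report(
    result, path: "str | Path", format: str = "kv", delimiter: str = ","
) -> None:
    """Write a result object as structured text.

    ``kv`` emits deterministic ``key: value`` lines (dataclass field
    order); ``delimited`` emits a two-column table.  Sequences of results
    become a delimited table with one row per element.
    """
    path = Path(path)
    try:
        if isinstance(result, (list, tuple)):
            records = [_flatten(_as_jsonable(r)) for r in result]
            pd.DataFrame(records).to_csv(path, sep=delimiter, index=False)
            return
        flat = _flatten(_as_jsonable(result))
        if format == "kv":
            text = "".join(f"{k}: {v}\n" for k, v in flat.items())
            path.write_text(text)
        elif format == "delimited":
            pd.DataFrame([flat]).to_csv(path, sep=delimiter, index=False)
        else:
            raise ValueError(f"unknown report format {format!r}")
    except OSError as exc:
        raise OSError(f"could not write report to {path}: {exc}") from exc


def _flatten(obj: Mapping | object, prefix: str = "") -> dict:
    if not isinstance(obj, Mapping):
        return {prefix or "value": obj}
    out: dict = {}
    for k, v in obj.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, Mapping):
            out.update(_flatten(v, key))
        else:
            out[key] = v
    return out


def write_table1_fixtures(directory: "str | Path", delimiter: str = ",") -> list[Path]:
    """Write the worked-example trial in both file layouts.

    Emits ``table1_rfv_arm1.csv`` / ``table1_rfv_arm2.csv`` (RFV matrices)
    and ``table1_long.csv`` (a long AE file that aggregates back to the
    same cohorts).  Returns the paths written.
    """
    from .model import table1_fixture

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    c1, c2 = table1_fixture()
    paths = []
    for arm, cohort in (("1", c1), ("2", c2)):
        p = directory / f"table1_rfv_arm{arm}.csv"
        cohort.metadata["patient_ids"] = [
            f"P{i + 1 + (5 if arm == '2' else 0)}" for i in range(len(cohort))
        ]
        write_rfv_matrix(cohort, p, delimiter)
        paths.append(p)
    rows = []
    for arm, cohort in (("1", c1), ("2", c2)):
        for i, rfv in enumerate(cohort.rfvs):
            pid = f"P{i + 1 + (5 if arm == '2' else 0)}"
            for grade, count in enumerate(rfv.counts, start=1):
                rows.extend(
                    {"patient_id": pid, "treatment": arm, "grade": grade}
                    for _ in range(count)
                )
    long_path = directory / "table1_long.csv"
    pd.DataFrame(rows).to_csv(long_path, sep=delimiter, index=False)
    paths.append(long_path)
    return paths
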