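"""File readers/writers: cohort CSV, trajectory CSV, percentile-table JSON.

Record-level data travel as CSV (comma-separated, dot decimal, UTF-8);
models and reports as JSON.  Readers validate ranges and report offending
lines; writers round-trip exactly what the readers accept.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from flipnorms.cohort import ChildTrajectory
from flipnorms.growth import AGE_MAX, SCORE_MAX, PercentileTable
from flipnorms.quantile import CohortRecord

COHORT_COLUMNS = ["child_id", "age_months", "score"]


class ValidationError(ValueError):
    """Malformed input file; the message lists offending lines."""


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read cohort CSV with header ``child_id,age_months,score``."""
    df = pd.read_csv(path, dtype={"child_id": str}, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    problems = []
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            age = float(row.age_months)
            score = float(row.score)
        except (TypeError, ValueError):
            problems.append(f"line {pos}: non-numeric age or score")
            continue
        if not 0 < age <= AGE_MAX:
            problems.append(f"line {pos}: age {age} outside (0, {AGE_MAX}]")
            continue
        if not 0 <= score <= SCORE_MAX:
            problems.append(f"line {pos}: score {score} outside [0, {SCORE_MAX}]")
            continue
        records.append(CohortRecord(child_id=str(row.child_id), age=age, score=score))
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return records


def write_cohort(records, path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.child_id, r.age, r.score) for r in records], columns=COHORT_COLUMNS)
    df.to_csv(path, index=False)


def read_trajectory(path: str | Path) -> ChildTrajectory:
    """Read one child's trajectory CSV (``child_id,age_months,score[,event]``)."""
    df = pd.read_csv(path, dtype={"child_id": str}, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    ids = df["child_id"].unique()
    if len(ids) != 1:
        raise ValidationError(f"{path}: expected exactly one child, found {len(ids)}")
    df = df.sort_values("age_months")
    points = [(float(a), float(s)) for a, s in zip(df["age_months"], df["score"])]
    annotations = []
    if "event" in df.columns:
        for a, ev in zip(df["age_months"], df["event"]):
            if isinstance(ev, str) and ev.strip():
                annotations.append((float(a), ev.strip()))
    return ChildTrajectory(child_id=str(ids[0]), points=points,
                           annotations=annotations)


def write_table(table: PercentileTable, path: str | Path, **metadata) -> None:
    payload = dict(metadata)
    payload.update(table.to_dict())
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_table(path: str | Path) -> PercentileTable:
    with open(path) as fh:
        return PercentileTable.from_dict(json.load(fh))
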