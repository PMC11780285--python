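"""CSV round-trip for cohort tables.

Schema (all files have headers; an empty weight cell means missing):

* ``members.csv`` — member_id, sex, age_years, age_group, state,
  seifa_quintile, start_weight_kg, height_m, start_bmi, membership_days,
  employer_paid, overseas, pseudo_member
* ``weights.csv`` — member_id, time_point in {baseline, w12, m6, m9, m12},
  weight_kg
* ``activity.csv`` — member_id, interval in {b1..b4}, seven stream counts,
  total_activity
* ``true_patterns.csv`` (optional, generator ground truth) — member_id, label
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._grid import INTERVALS, TIME_POINTS
from .cohort import ACTIVITY_STREAMS, MEMBER_COLUMNS, Cohort

__all__ = ["write_cohort", "read_cohort", "CohortParseError"]

_BOOL_COLS = ["employer_paid", "overseas", "pseudo_member"]


class CohortParseError(ValueError):
    """Malformed cohort file; the message names the file, row and column."""


def write_cohort(cohort: Cohort, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.members.to_csv(path / "members.csv", index=False)
    long = (cohort.weights.reset_index()
            .melt(id_vars="member_id", var_name="time_point", value_name="weight_kg"))
    long["time_point"] = pd.Categorical(long["time_point"], categories=list(TIME_POINTS),
                                        ordered=True)
    long = long.sort_values(["member_id", "time_point"], ignore_index=True)
    long.to_csv(path / "weights.csv", index=False)
    cohort.activity.to_csv(path / "activity.csv", index=False)
    if cohort.assigned_patterns is not None:
        (cohort.assigned_patterns.rename("label").rename_axis("member_id")
         .reset_index().to_csv(path / "true_patterns.csv", index=False))


def _check_numeric(df: pd.DataFrame, raw: pd.Series, col: str, fname: str) -> None:
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, counting the header line
        raise CohortParseError(
            f"{fname}: non-numeric value {raw[bad.idxmax()]!r} at row {row}, "
            f"column {col!r}")
    df[col] = converted


def read_cohort(path) -> Cohort:
    path = Path(path)
    members = pd.read_csv(path / "members.csv", dtype={"member_id": str})
    missing_cols = set(MEMBER_COLUMNS) - set(members.columns)
    if missing_cols:
        raise CohortParseError(f"members.csv: missing columns {sorted(missing_cols)}")
    for col in ("start_weight_kg", "height_m", "start_bmi"):
        _check_numeric(members, members[col], col, "members.csv")
    for col in _BOOL_COLS:
        members[col] = members[col].astype(bool)

    wlong = pd.read_csv(path / "weights.csv", dtype={"member_id": str, "time_point": str})
    bad_tp = ~wlong["time_point"].isin(TIME_POINTS)
    if bad_tp.any():
        row = int(bad_tp.idxmax()) + 2
        raise CohortParseError(
            f"weights.csv: unknown time point {wlong['time_point'][bad_tp.idxmax()]!r} "
            f"at row {row}, column 'time_point'")
    _check_numeric(wlong, wlong["weight_kg"], "weight_kg", "weights.csv")
    weights = (wlong.pivot(index="member_id", columns="time_point", values="weight_kg")
               .reindex(columns=list(TIME_POINTS))
               .reindex(members["member_id"].to_numpy()))
    weights.index.name = "member_id"
    weights.columns.name = None

    activity = pd.read_csv(path / "activity.csv", dtype={"member_id": str, "interval": str})
    for col in ACTIVITY_STREAMS + ["total_activity"]:
        _check_numeric(activity, activity[col], col, "activity.csv")
        neg = activity[col] < 0
        if neg.any():
            row = int(neg.idxmax()) + 2
            raise CohortParseError(
                f"activity.csv: negative count at row {row}, column {col!r}")
        activity[col] = activity[col].astype(np.int64)
    activity["interval"] = pd.Categorical(activity["interval"],
                                          categories=list(INTERVALS), ordered=True)

    patterns = None
    pfile = path / "true_patterns.csv"
    if pfile.exists():
        pdf = pd.read_csv(pfile, dtype={"member_id": str, "label": str},
                          keep_default_na=False)
        patterns = pdf.set_index("member_id")["label"]
    return Cohort(members=members, weights=weights, activity=activity,
                  assigned_patterns=patterns)
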