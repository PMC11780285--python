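"""Per-member weight-loss outcomes.

Weight loss is baseline minus current weight, in kilograms, so a larger
number means greater loss; percentage loss is expressed relative to
starting body weight (%TBW).  Losses fall into four categories: gain (or
no change), loss of >0% and <5% TBW, 5% to <10% TBW, and >=10% TBW —
5% being the accepted threshold for clinically significant loss.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._grid import POST_BASELINE
from .cohort import Cohort

__all__ = ["weight_loss", "pct_tbw", "categorize_loss", "bmi_class",
           "weekly_use", "round_half_up", "compute_outcomes",
           "LOSS_CATEGORIES"]

LOSS_CATEGORIES = ("gain_or_zero", "loss_0_to_5", "loss_5_to_10", "loss_ge_10")

#: lower-inclusive BMI bands at the standard WHO cutoffs
_BMI_EDGES = (18.5, 25.0, 30.0, 35.0, 40.0)
_BMI_CLASSES = ("underweight", "normal", "overweight", "obese_1", "obese_2", "obese_3")


def weight_loss(baseline_kg, weight_kg):
    """Loss in kg (positive = loss); missing inputs propagate to NaN."""
    return np.subtract(baseline_kg, weight_kg)


def pct_tbw(loss_kg, baseline_kg):
    """Loss as a percentage of starting body weight."""
    baseline = np.asarray(baseline_kg, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline weight must be positive")
    return 100.0 * np.asarray(loss_kg, dtype=float) / baseline


def round_half_up(x, decimals: int = 1):
    """Round with ties away from zero at positive values (reporting rule)."""
    factor = 10.0 ** decimals
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


def categorize_loss(loss_pct):
    """Map %TBW loss to its category; NaN stays missing."""
    arr = np.asarray(loss_pct, dtype=float)
    out = np.select(
        [arr <= 0, arr < 5.0, arr < 10.0, arr >= 10.0],
        list(LOSS_CATEGORIES), default=None)
    out = np.where(np.isnan(arr), None, out)
    if np.ndim(loss_pct) == 0:
        return out.item()
    return out


def bmi_class(bmi):
    """Weight-status class from BMI at the standard cutoffs."""
    if np.ndim(bmi) == 0:
        if math.isnan(bmi):
            return None
        return _BMI_CLASSES[int(np.searchsorted(_BMI_EDGES, bmi, side="right"))]
    arr = np.asarray(bmi, dtype=float)
    idx = np.searchsorted(_BMI_EDGES, arr, side="right")
    out = np.array(_BMI_CLASSES, dtype=object)[idx]
    return np.where(np.isnan(arr), None, out)


def weekly_use(total_activity, membership_days):
    """Average platform actions per week of paid membership."""
    days = np.asarray(membership_days, dtype=float)
    if np.any(days <= 0):
        raise ValueError("membership duration must be positive")
    return np.asarray(total_activity, dtype=float) / (days / 7.0)


def compute_outcomes(cohort: Cohort) -> pd.DataFrame:
    """Long outcome table: one row per member per post-baseline point.

    Columns: member_id, time_point, loss_kg, loss_pct, category.  Missing
    weigh-ins yield missing outcomes (rows are kept, values NaN).
    """
    w = cohort.weights
    rows = []
    for tp in POST_BASELINE:
        loss = weight_loss(w["baseline"], w[tp])
        pct = 100.0 * loss / w["baseline"]
        rows.append(pd.DataFrame({
            "member_id": w.index,
            "time_point": tp,
            "loss_kg": loss.to_numpy(),
            "loss_pct": pct.to_numpy(),
            "category": categorize_loss(pct.to_numpy()),
        }))
    out = pd.concat(rows, ignore_index=True)
    out["time_point"] = pd.Categorical(out["time_point"],
                                       categories=list(POST_BASELINE), ordered=True)
    return out.sort_values(["member_id", "time_point"], ignore_index=True)
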