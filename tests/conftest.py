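import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from weightpatterns._grid import INTERVALS, TIME_POINTS

# property-based tests run deterministically
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from weightpatterns.cohort import ACTIVITY_STREAMS, Cohort
from weightpatterns.params import SimulationParams

MEMBER_DEFAULTS = {
    "sex": "female",
    "age_years": 45,
    "age_group": "31-50",
    "state": "NSW",
    "seifa_quintile": 3,
    "start_weight_kg": 90.0,
    "height_m": 1.65,
    "start_bmi": 33.1,
    "membership_days": 400,
    "employer_paid": False,
    "overseas": False,
    "pseudo_member": False,
}


def make_cohort(member_rows, weight_rows=None, activity_rows=None) -> Cohort:
    """Build a small in-memory cohort from partial row dicts.

    ``member_rows`` is a list of dicts overriding MEMBER_DEFAULTS (ids are
    generated when absent); ``weight_rows`` maps member_id -> 5-tuple of
    grid weights (None = missing), defaulting to a flat series at the
    starting weight; ``activity_rows`` maps member_id -> 4-tuple of
    per-block total activity, defaulting to zeros.
    """
    members = []
    for i, row in enumerate(member_rows):
        rec = dict(MEMBER_DEFAULTS)
        rec.setdefault("member_id", f"T{i:03d}")
        rec.update(row)
        if "start_bmi" not in row:
            rec["start_bmi"] = rec["start_weight_kg"] / rec["height_m"] ** 2
        members.append(rec)
    from weightpatterns.cohort import MEMBER_COLUMNS
    mdf = pd.DataFrame(members, columns=MEMBER_COLUMNS if not members else None)

    weight_rows = weight_rows or {}
    wdata = {}
    for rec in members:
        mid = rec["member_id"]
        series = weight_rows.get(mid)
        if series is None:
            series = (rec["start_weight_kg"],) * 5
        wdata[mid] = [np.nan if v is None else float(v) for v in series]
    weights = pd.DataFrame.from_dict(wdata, orient="index",
                                     columns=list(TIME_POINTS))
    weights.index.name = "member_id"

    activity_rows = activity_rows or {}
    arecs = []
    for rec in members:
        mid = rec["member_id"]
        totals = activity_rows.get(mid, (0, 0, 0, 0))
        for b, total in enumerate(totals):
            arec = {"member_id": mid, "interval": INTERVALS[b]}
            arec.update({s: 0 for s in ACTIVITY_STREAMS})
            arec["food_diary"] = int(total)  # park the total in one stream
            arec["total_activity"] = int(total)
            arecs.append(arec)
    activity_cols = (["member_id", "interval"] + ACTIVITY_STREAMS
                     + ["total_activity"])
    activity = pd.DataFrame(arecs, columns=activity_cols if not arecs else None)
    activity["interval"] = pd.Categorical(activity["interval"],
                                          categories=list(INTERVALS), ordered=True)
    return Cohort(members=mdf, weights=weights, activity=activity)


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort generated with default-shaped parameters."""
    from weightpatterns.cohort import generate_cohort
    return generate_cohort(SimulationParams(n_members=2000, seed=42))


@pytest.fixture(scope="session")
def clean_params():
    """Defaults without planted ineligible records (all members analyzable)."""
    fracs = {k: 0.0 for k in ("underage", "underweight_bmi", "invalid_weight",
                              "missing_start", "employer_paid", "overseas",
                              "pseudo_member")}
    return SimulationParams(n_members=1500, seed=11, ineligible_fracs=fracs)


@pytest.fixture(scope="session")
def clean_cohort(clean_params):
    from weightpatterns.cohort import generate_cohort
    return generate_cohort(clean_params)
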