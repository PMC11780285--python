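"""Seeded synthetic cohort generation.

The generator emulates the statistical structure a longitudinal
weight-management analysis assumes, so the downstream pipeline is
testable without proprietary member data:

* demographic marginals (sex, age group, state, SEIFA quintile, starting
  weight/BMI) drawn from configurable distributions;
* per-member 4-symbol L/M/G trajectory patterns drawn from a mixture over
  the common named sequences plus a catch-all "other" class;
* block weight changes drawn truncated to the symbol's region relative to
  the 1.4 kg maintenance band, so classifying the realized series always
  reproduces the assigned label;
* platform-use counts whose weekly rate is positively coupled to a
  standardized latent loss propensity;
* monotone, informative weigh-in missingness: a per-time-point first-miss
  hazard inflated when the preceding fully-observed block was a gain.

All draws descend from one root seed via ``numpy.random.SeedSequence``
spawning, one child stream per generation stage, in a fixed order
(members, patterns, trajectories, engagement, missingness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._grid import BLOCK_WEEKS, INTERVALS, MAINTENANCE_BAND_KG, TIME_POINTS
from .params import (
    AGE_GROUP_RANGES,
    AGE_GROUPS,
    OTHER_PATTERN,
    STATES,
    ConfigurationError,
    SimulationParams,
)

__all__ = [
    "Cohort",
    "generate_members",
    "assign_patterns",
    "generate_trajectories",
    "generate_engagement",
    "apply_missingness",
    "generate_cohort",
    "expected_total_loss",
]

MEMBER_COLUMNS = [
    "member_id", "sex", "age_years", "age_group", "state", "seifa_quintile",
    "start_weight_kg", "height_m", "start_bmi", "membership_days",
    "employer_paid", "overseas", "pseudo_member",
]

ACTIVITY_STREAMS = [
    "weigh_ins", "food_diary", "menu_plan_views", "exercise_plan_views",
    "content_views", "forum_views", "food_search",
]

#: fixed split of total platform activity across the seven feature streams
_STREAM_SHARES = np.array([0.05, 0.45, 0.12, 0.05, 0.12, 0.08, 0.13])

_PLANT_KEYS = ("underage", "underweight_bmi", "invalid_weight",
               "missing_start", "employer_paid", "overseas", "pseudo_member")


@dataclass
class Cohort:
    """In-memory cohort: member, weigh-in and platform-activity tables.

    ``weights`` is wide (index member_id, one column per grid time point,
    NaN = missing).  ``assigned_patterns`` and ``weights_premask`` are
    generator-side ground truth carried for validation; they are absent on
    cohorts read from files that lack them.
    """

    members: pd.DataFrame
    weights: pd.DataFrame
    activity: pd.DataFrame
    assigned_patterns: pd.Series | None = None
    weights_premask: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.members)

    def subset(self, member_ids) -> "Cohort":
        """Restrict every table to the given member ids (order preserved)."""
        ids = pd.Index(member_ids)
        return Cohort(
            members=self.members[self.members["member_id"].isin(ids)].reset_index(drop=True),
            weights=self.weights.loc[self.weights.index.intersection(ids, sort=False)],
            activity=self.activity[self.activity["member_id"].isin(ids)].reset_index(drop=True),
            assigned_patterns=(None if self.assigned_patterns is None
                               else self.assigned_patterns.loc[self.assigned_patterns.index.intersection(ids, sort=False)]),
            weights_premask=(None if self.weights_premask is None
                             else self.weights_premask.loc[self.weights_premask.index.intersection(ids, sort=False)]),
        )


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def _truncnorm(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    mass = stats.norm.cdf(b) - stats.norm.cdf(a)
    if mass < 1e-12:
        raise ConfigurationError(
            f"truncation region [{lo}, {hi}] has no mass under N({mean}, {sd}^2)")
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# members
# ---------------------------------------------------------------------------

def generate_members(params: SimulationParams,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the member table, including planted ineligible records.

    Deterministic given ``params.seed`` (when ``rng`` is not supplied).
    Ineligible records are planted as disjoint fractions of the cohort and
    carry the flags or out-of-range values that the eligibility cascade
    later removes.
    """
    if rng is None:
        rng = _spawn_rngs(params.seed, 5)[0]
    n = params.n_members
    member_id = np.array([f"M{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < params.sex_split, "female", "male")
    grp_idx = rng.choice(len(AGE_GROUPS), size=n, p=np.asarray(params.age_group_probs))
    age_group = np.array(AGE_GROUPS)[grp_idx]
    lo = np.array([AGE_GROUP_RANGES[g][0] for g in age_group])
    hi = np.array([AGE_GROUP_RANGES[g][1] for g in age_group])
    age_years = rng.integers(lo, hi + 1)
    state = rng.choice(np.array(STATES), size=n, p=np.asarray(params.state_probs))
    seifa = rng.choice(np.arange(1, 6), size=n, p=np.asarray(params.seifa_probs))
    weight = _truncnorm(rng, params.start_weight_mean_kg, params.start_weight_sd_kg,
                        lo=40.0, hi=249.0, size=n)
    bmi = _truncnorm(rng, params.start_bmi_mean, params.start_bmi_sd,
                     lo=16.0, hi=60.0, size=n)
    height = np.sqrt(weight / bmi)
    membership = np.round(
        _truncnorm(rng, params.membership_mean_days, params.membership_sd_days,
                   lo=84.0, size=n)).astype(int)

    employer_paid = np.zeros(n, bool)
    overseas = np.zeros(n, bool)
    pseudo = np.zeros(n, bool)

    # plant disjoint ineligible records
    fracs = np.array([params.ineligible_fracs.get(k, 0.0) for k in _PLANT_KEYS])
    if fracs.sum() > 1.0:
        raise ConfigurationError("ineligible_fracs sum to more than 1")
    plant = rng.choice(len(_PLANT_KEYS) + 1, size=n,
                       p=np.append(fracs, 1.0 - fracs.sum()))
    m = plant == _PLANT_KEYS.index("underage")
    age_years = np.where(m, rng.integers(14, 18, size=n), age_years)
    m = plant == _PLANT_KEYS.index("underweight_bmi")
    if m.any():
        bmi_low = rng.uniform(16.5, 18.4, size=int(m.sum()))
        bmi[m] = bmi_low
        weight[m] = bmi_low * height[m] ** 2
    m = plant == _PLANT_KEYS.index("invalid_weight")
    if m.any():
        k = int(m.sum())
        bad = np.where(rng.random(k) < 0.5,
                       rng.uniform(2.0, 12.9, size=k),
                       rng.uniform(251.0, 400.0, size=k))
        weight[m] = bad
        bmi[m] = bad / height[m] ** 2
    m = plant == _PLANT_KEYS.index("missing_start")
    weight = np.where(m, np.nan, weight)
    bmi = np.where(m, np.nan, bmi)
    employer_paid[plant == _PLANT_KEYS.index("employer_paid")] = True
    overseas[plant == _PLANT_KEYS.index("overseas")] = True
    pseudo[plant == _PLANT_KEYS.index("pseudo_member")] = True

    return pd.DataFrame({
        "member_id": member_id,
        "sex": sex,
        "age_years": age_years,
        "age_group": age_group,
        "state": state,
        "seifa_quintile": seifa,
        "start_weight_kg": weight,
        "height_m": height,
        "start_bmi": bmi,
        "membership_days": membership,
        "employer_paid": employer_paid,
        "overseas": overseas,
        "pseudo_member": pseudo,
    })


# ---------------------------------------------------------------------------
# patterns and trajectories
# ---------------------------------------------------------------------------

def assign_patterns(n: int, params: SimulationParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` pattern-class labels from the configured mixture."""
    labels = np.array(list(params.pattern_probs))
    probs = np.array([params.pattern_probs[k] for k in labels])
    return rng.choice(labels, size=n, p=probs)


def assign_pattern(member, params: SimulationParams, rng) -> str:
    """Single-member convenience wrapper over :func:`assign_patterns`."""
    return str(assign_patterns(1, params, rng)[0])


def _symbol_regions(params: SimulationParams) -> dict[str, tuple[float, float]]:
    b = MAINTENANCE_BAND_KG
    return {"L": (-np.inf, -b), "M": (-b, b), "G": (b, np.inf)}


def _draw_block_changes(labels: np.ndarray, params: SimulationParams,
                        rng: np.random.Generator) -> np.ndarray:
    """(n, 4) block changes; rows obey the symbol regions of their label.

    ``other``-class rows draw symbol-free changes, rejection-sampled so the
    realized sequence does not collide with a named pattern class.
    """
    n = len(labels)
    changes = np.empty((n, 4))
    regions = _symbol_regions(params)
    named = labels != OTHER_PATTERN
    if named.any():
        sym = np.array([lab.split("|") for lab in labels[named]])
        idx = np.flatnonzero(named)
        for b in range(4):
            for s in "LMG":
                rows = idx[sym[:, b] == s]
                if rows.size:
                    lo, hi = regions[s]
                    changes[rows, b] = _truncnorm(
                        rng, params.block_change_means[s], params.block_change_sd,
                        lo=lo, hi=hi, size=rows.size)
    other_rows = np.flatnonzero(~named)
    named_set = {k for k in params.pattern_probs if k != OTHER_PATTERN}
    pending = other_rows
    for _ in range(1000):
        if pending.size == 0:
            break
        draw = rng.normal(params.other_change_mean, params.other_change_sd,
                          size=(pending.size, 4))
        seqs = classify_changes(draw)
        ok = np.array([s not in named_set for s in seqs])
        changes[pending[ok]] = draw[ok]
        pending = pending[~ok]
    else:  # pragma: no cover - rejection always terminates in practice
        raise ConfigurationError("could not draw non-named 'other' sequences")
    return changes


def classify_changes(changes: np.ndarray) -> np.ndarray:
    """Vectorized L/M/G labelling of an (n, 4) block-change array."""
    band = MAINTENANCE_BAND_KG + 1e-9  # same edge tolerance as the classifier
    sym = np.where(changes < -band, "L", np.where(changes > band, "G", "M"))
    return np.array(["|".join(row) for row in sym])


def generate_trajectories(members: pd.DataFrame, labels: np.ndarray,
                          params: SimulationParams,
                          rng: np.random.Generator
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Realize the 5-point weigh-in series for each member.

    Returns the wide weights table (pre-missingness) and the realized
    4-symbol label per member.  For named classes the realized label equals
    the assigned one by construction; for ``other`` it is the concrete
    (non-named) sequence drawn.  Members with a planted missing starting
    weight get an all-missing series.
    """
    n = len(members)
    start = members["start_weight_kg"].to_numpy(float)
    changes = _draw_block_changes(labels, params, rng)
    # planted records with implausibly low starting weights cannot support
    # loss-block changes; they get a flat jittered series and no label
    # (the eligibility cascade removes them before any analysis)
    with np.errstate(invalid="ignore"):
        implausible = start < 40.0
    if implausible.any():
        changes[implausible] = rng.uniform(-0.2, 0.2, size=(int(implausible.sum()), 4))
    # guard against plausible trajectories dipping to implausible weights
    for _ in range(100):
        with np.errstate(invalid="ignore"):
            series = start[:, None] + np.concatenate(
                [np.zeros((n, 1)), np.cumsum(changes, axis=1)], axis=1)
            bad = np.min(series, axis=1) < 15.0
        bad &= ~np.isnan(start) & ~implausible
        if not bad.any():
            break
        changes[bad] = _draw_block_changes(labels[bad], params, rng)
    else:  # pragma: no cover
        raise ConfigurationError("could not keep trajectories above 15 kg")
    series[np.isnan(start)] = np.nan
    weights = pd.DataFrame(series, columns=list(TIME_POINTS))
    weights.index = pd.Index(members["member_id"], name="member_id")
    realized = pd.Series(classify_changes(changes), index=weights.index,
                         name="pattern")
    realized[np.isnan(start) | implausible] = ""
    return weights, realized


def generate_trajectory(member, label: str, params: SimulationParams, rng):
    """Single-member wrapper over :func:`generate_trajectories`."""
    mdf = pd.DataFrame([member]) if not isinstance(member, pd.DataFrame) else member
    weights, _ = generate_trajectories(mdf, np.array([label]), params, rng)
    return weights.iloc[0]


# ---------------------------------------------------------------------------
# engagement
# ---------------------------------------------------------------------------

def generate_engagement(members: pd.DataFrame, weights: pd.DataFrame,
                        params: SimulationParams,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-block platform-activity ledger.

    Each member's weekly-use rate is ``base + coupling * z`` floored at 0,
    where ``z`` is the cohort-standardized 12-month weight loss (the latent
    loss propensity).  Per-block totals are Poisson at that rate scaled by
    the block's within-year decay and length in weeks, then split across
    the seven feature streams in fixed proportions; ``total_activity`` is
    the drawn total, so it always dominates every component stream.
    """
    loss12 = (weights["baseline"] - weights["m12"]).to_numpy(float)
    sd = np.nanstd(loss12)
    if np.isnan(loss12).all() or sd == 0:
        z = np.zeros(len(members))
    else:
        z = (loss12 - np.nanmean(loss12)) / sd
    z = np.nan_to_num(z)
    rate = np.maximum(
        0.0, params.engagement_base_per_week + params.engagement_loss_coupling * z)
    rows = []
    for b, interval in enumerate(INTERVALS):
        lam = rate * params.engagement_block_decay[b] * BLOCK_WEEKS[b]
        total = rng.poisson(lam)
        split = rng.multinomial(total, _STREAM_SHARES)
        rec = {"member_id": members["member_id"].to_numpy(),
               "interval": np.repeat(interval, len(members))}
        rec.update({s: split[:, i] for i, s in enumerate(ACTIVITY_STREAMS)})
        rec["total_activity"] = total
        rows.append(pd.DataFrame(rec))
    out = pd.concat(rows, ignore_index=True)
    out["interval"] = pd.Categorical(out["interval"], categories=list(INTERVALS),
                                     ordered=True)
    return out.sort_values(["member_id", "interval"], ignore_index=True)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def apply_missingness(weights: pd.DataFrame, params: SimulationParams,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Impose monotone, informative first-miss dropout on the weigh-in grid.

    At each post-baseline point, members still fully observed face a
    Bernoulli first-miss hazard; from the 6-month point on the hazard is
    multiplied by ``dropout_gain_multiplier`` when the member's last fully
    observed block (the one ending at the previous grid point) was a gain.
    Once a member first goes missing, all later points are missing too.
    The baseline value is never removed.
    """
    out = weights.copy()
    vals = weights.to_numpy(float)
    n = vals.shape[0]
    missing_from = np.full(n, vals.shape[1])  # column index of first miss
    for j, h in enumerate(params.dropout_hazards):
        col = j + 1  # grid column of this post-baseline point
        at_risk = missing_from > col - 1  # not yet missing before this point
        hazard = np.full(n, h)
        if col >= 2:
            prev_change = vals[:, col - 1] - vals[:, col - 2]
            hazard = np.where(prev_change > 0,
                              np.minimum(1.0, h * params.dropout_gain_multiplier),
                              hazard)
        hit = at_risk & (rng.random(n) < hazard)
        missing_from = np.where(hit & (missing_from > col), col, missing_from)
    mask = np.arange(vals.shape[1])[None, :] >= missing_from[:, None]
    arr = out.to_numpy(float)
    arr[mask] = np.nan
    return pd.DataFrame(arr, index=out.index, columns=out.columns)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_cohort(params: SimulationParams) -> Cohort:
    """Generate a full cohort: members, masked weights, activity ledger.

    The pre-missingness weights and the realized pattern labels are kept on
    the returned :class:`Cohort` as generator ground truth.
    """
    rng_members, rng_pat, rng_traj, rng_eng, rng_miss = _spawn_rngs(params.seed, 5)
    members = generate_members(params, rng_members)
    classes = assign_patterns(len(members), params, rng_pat)
    weights_full, realized = generate_trajectories(members, classes, params, rng_traj)
    activity = generate_engagement(members, weights_full, params, rng_eng)
    weights = apply_missingness(weights_full, params, rng_miss)
    return Cohort(members=members, weights=weights, activity=activity,
                  assigned_patterns=realized, weights_premask=weights_full)


def expected_total_loss(params: SimulationParams) -> float:
    """Analytic expected 12-month loss (kg) under the pattern mixture.

    Exact only when the ``other`` class has zero probability (its
    rejection-sampled changes have no closed-form mean); raises otherwise.
    """
    if params.pattern_probs.get(OTHER_PATTERN, 0.0) > 0:
        raise ValueError("closed form requires zero 'other'-class probability")
    regions = _symbol_regions(params)
    sym_mean = {}
    for s in "LMG":
        lo, hi = regions[s]
        mu, sd = params.block_change_means[s], params.block_change_sd
        a, b = (lo - mu) / sd, (hi - mu) / sd
        sym_mean[s] = stats.truncnorm.mean(a, b, loc=mu, scale=sd)
    total = 0.0
    for label, p in params.pattern_probs.items():
        if label == OTHER_PATTERN:
            continue
        total += p * sum(sym_mean[s] for s in label.split("|"))
    return -total  # loss is the negative of the summed change
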