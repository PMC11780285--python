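"""L/M/G trajectory-pattern classification and per-pattern summaries.

Each 3-month block of a complete 5-point weigh-in series is labelled
Loss, Maintenance or Gain relative to a 1.4 kg maintenance band: a change
within +/-1.4 kg of the previous weight is maintenance, anything greater
is loss or gain.  The four symbols concatenate into labels such as
``L|L|M|M`` (six months of loss, then six of maintenance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._grid import BLOCK_WEEKS, BLOCKS, INTERVALS, MAINTENANCE_BAND_KG
from .cohort import Cohort

__all__ = ["PatternSeq", "classify_block", "classify_sequence",
           "classify_cohort", "pattern_table", "render_pattern_table"]

#: tolerance for band comparisons, so weights printed to 0.1 kg that land
#: exactly on the +/-1.4 kg boundary classify as maintenance
_BAND_EPS = 1e-9


@dataclass(frozen=True)
class PatternSeq:
    """A 4-symbol trajectory pattern."""

    symbols: tuple[str, str, str, str]

    def __post_init__(self):
        if len(self.symbols) != 4 or any(s not in "LMG" for s in self.symbols):
            raise ValueError("pattern needs exactly 4 symbols over {L, M, G}")

    @property
    def label(self) -> str:
        return "|".join(self.symbols)

    @classmethod
    def from_label(cls, label: str) -> "PatternSeq":
        return cls(tuple(label.split("|")))

    def __str__(self) -> str:
        return self.label


def classify_block(prev_kg: float, next_kg: float,
                   band_kg: float = MAINTENANCE_BAND_KG) -> str:
    """Label one block's change: L below -band, G above +band, else M.

    The band boundary itself (|change| == band) counts as maintenance.
    """
    if np.isnan(prev_kg) or np.isnan(next_kg):
        raise ValueError("cannot classify a block with a missing weight")
    delta = next_kg - prev_kg
    band = band_kg + _BAND_EPS  # absorb float representation error at the edge
    if delta < -band:
        return "L"
    if delta > band:
        return "G"
    return "M"


def classify_sequence(series, band_kg: float = MAINTENANCE_BAND_KG) -> PatternSeq:
    """Classify a complete 5-point series into its 4-symbol pattern.

    ``series`` is indexable by the grid time points (a pandas Series or
    mapping); any missing value raises, as patterns are defined only on
    complete cases.
    """
    symbols = tuple(classify_block(series[a], series[b], band_kg)
                    for a, b in BLOCKS)
    return PatternSeq(symbols)


def classify_cohort(weights: pd.DataFrame,
                    band_kg: float = MAINTENANCE_BAND_KG) -> pd.Series:
    """Vectorized pattern labels for a wide complete-case weights table."""
    if weights.isna().to_numpy().any():
        raise ValueError("pattern classification requires complete series")
    cols = [c for c, _ in BLOCKS] + [BLOCKS[-1][1]]
    vals = weights[cols].to_numpy(float)
    deltas = np.diff(vals, axis=1)
    band = band_kg + _BAND_EPS
    sym = np.where(deltas < -band, "L", np.where(deltas > band, "G", "M"))
    labels = np.array(["|".join(row) for row in sym])
    return pd.Series(labels, index=weights.index, name="label")


def pattern_table(cohort: Cohort, outcomes: pd.DataFrame,
                  band_kg: float = MAINTENANCE_BAND_KG) -> pd.DataFrame:
    """Per-pattern summary of a complete-case cohort, ordered by size.

    One row per observed label with: n, share of the sample (%), mean
    starting weight, mean platform use per week within each block, mean
    cumulative loss (kg) at each grid point, and mean %TBW loss at 12
    months.  No rows are suppressed here; report rendering applies the
    >=2% visibility threshold (see :func:`render_pattern_table`).
    """
    if cohort.n == 0:
        return pd.DataFrame(columns=_TABLE_COLUMNS)
    labels = classify_cohort(cohort.weights, band_kg)
    members = cohort.members.set_index("member_id")
    loss = outcomes.pivot(index="member_id", columns="time_point",
                          values="loss_kg").reindex(labels.index)
    pct = outcomes.pivot(index="member_id", columns="time_point",
                         values="loss_pct").reindex(labels.index)
    act = cohort.activity.pivot(index="member_id", columns="interval",
                                values="total_activity").reindex(labels.index)
    use = act[list(INTERVALS)].to_numpy(float) / np.array(BLOCK_WEEKS)

    df = pd.DataFrame({
        "label": labels.to_numpy(),
        "start_weight_kg": members["start_weight_kg"].reindex(labels.index).to_numpy(),
        "use_b1": use[:, 0], "use_b2": use[:, 1],
        "use_b3": use[:, 2], "use_b4": use[:, 3],
        "loss_w12": loss["w12"].to_numpy(), "loss_m6": loss["m6"].to_numpy(),
        "loss_m9": loss["m9"].to_numpy(), "loss_m12": loss["m12"].to_numpy(),
        "loss_pct_m12": pct["m12"].to_numpy(),
    })
    grouped = df.groupby("label", sort=False)
    out = grouped.mean()
    out.insert(0, "n", grouped.size())
    out.insert(1, "share_pct", 100.0 * out["n"] / cohort.n)
    out = (out.sort_values(["n", "label"], ascending=[False, True])
           .reset_index()
           .rename(columns={
               "start_weight_kg": "mean_start_weight_kg",
               "use_b1": "mean_weekly_use_w12", "use_b2": "mean_weekly_use_m6",
               "use_b3": "mean_weekly_use_m9", "use_b4": "mean_weekly_use_m12",
               "loss_w12": "mean_loss_kg_w12", "loss_m6": "mean_loss_kg_m6",
               "loss_m9": "mean_loss_kg_m9", "loss_m12": "mean_loss_kg_m12",
               "loss_pct_m12": "mean_loss_pct_m12"}))
    return out


_TABLE_COLUMNS = [
    "label", "n", "share_pct", "mean_start_weight_kg",
    "mean_weekly_use_w12", "mean_weekly_use_m6", "mean_weekly_use_m9",
    "mean_weekly_use_m12", "mean_loss_kg_w12", "mean_loss_kg_m6",
    "mean_loss_kg_m9", "mean_loss_kg_m12", "mean_loss_pct_m12",
]


def render_pattern_table(table: pd.DataFrame,
                         min_share_pct: float = 2.0) -> pd.DataFrame:
    """Report view: drop pattern groups below the visibility share."""
    return table[table["share_pct"] >= min_share_pct].reset_index(drop=True)
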