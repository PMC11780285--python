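"""End-to-end pipeline: simulate -> filter -> outcomes -> patterns ->
impute -> analyze -> report, with a manifest tying outputs to the seed.

Configuration is a single JSON document with per-stage sections::

    {
      "simulate": { ... SimulationParams fields ... },
      "impute":   {"m": 20, "seed": 1, "logit_proportions": false},
      "patterns": {"min_share_pct": 2.0},
      "analyze":  {"use_complete_case": true, "groups": ["sex"]}
    }

Unknown sections or keys are rejected so a run is fully described by its
config.  The manifest records the config hash, the seed, and a SHA-256
digest of every stage output; re-running with the same config reproduces
identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import generate_cohort
from .eligibility import apply_exclusions, select_complete_case, select_longer_term
from .estimation import (available_case_table, complete_case_table,
                         engagement_association, subgroup_summaries)
from .io import write_cohort
from .mi import ImputationSpec, estimate_all, impute
from .outcomes import compute_outcomes, round_half_up
from .params import ConfigurationError, SimulationParams
from .patterns import classify_cohort, pattern_table, render_pattern_table

log = logging.getLogger("weightpatterns")

_KNOWN_SECTIONS = {"simulate", "impute", "patterns", "analyze"}
_IMPUTE_KEYS = {"m", "seed", "logit_proportions"}
_PATTERN_KEYS = {"min_share_pct"}
_ANALYZE_KEYS = {"use_complete_case", "groups"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = json.load(fh)
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    for section, allowed in (("impute", _IMPUTE_KEYS), ("patterns", _PATTERN_KEYS),
                             ("analyze", _ANALYZE_KEYS)):
        extra = set(cfg.get(section, {})) - allowed
        if extra:
            raise ConfigurationError(
                f"unknown keys in config section {section!r}: {sorted(extra)}")
    # SimulationParams.from_dict validates the simulate section
    SimulationParams.from_dict(cfg.get("simulate", {}))
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest_tree(root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): _digest(p)
            for p in sorted(root.rglob("*")) if p.is_file()}


def run_pipeline(config_path, out_dir) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    On stage failure, outputs of completed stages stay in place and the
    manifest records the failing stage and error before the exception is
    re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    params = SimulationParams.from_dict(cfg.get("simulate", {}))
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    manifest: dict = {"tool": "weightpatterns", "version": __version__,
                      "config_hash": cfg_hash, "seed": params.seed, "stages": []}

    def _record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["stages"].append({
            "stage": stage,
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {str(p.relative_to(out)): (_digest(p) if p.is_file()
                                                  else _digest_tree(p))
                        for p in paths},
        })
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        cohort = generate_cohort(params)
        write_cohort(cohort, out / "cohort")
        _record("simulate", [out / "cohort"], t0)

        stage = "filter"
        t0 = time.perf_counter()
        filtered, report = apply_exclusions(cohort)
        longer_term = select_longer_term(filtered)
        report.add("not_longer_term", filtered.n - longer_term.n, longer_term.n)
        write_cohort(longer_term, out / "filtered")
        report.to_json(out / "filters.json")
        _record("filter", [out / "filtered", out / "filters.json"], t0)

        stage = "outcomes"
        t0 = time.perf_counter()
        outc = compute_outcomes(longer_term)
        outc.to_csv(out / "outcomes.csv", index=False)
        _record("outcomes", [out / "outcomes.csv"], t0)

        stage = "patterns"
        t0 = time.perf_counter()
        complete = select_complete_case(longer_term)
        cc_outcomes = outc[outc["member_id"].isin(complete.members["member_id"])]
        labels = classify_cohort(complete.weights)
        labels.rename("label").rename_axis("member_id").reset_index().to_csv(
            out / "patterns.csv", index=False)
        ptable = pattern_table(complete, cc_outcomes)
        ptable.to_csv(out / "pattern_table.csv", index=False)
        _record("patterns", [out / "patterns.csv", out / "pattern_table.csv"], t0)

        stage = "impute"
        t0 = time.perf_counter()
        icfg = cfg.get("impute", {})
        spec = ImputationSpec(m=icfg.get("m", 20),
                              seed=icfg.get("seed", params.seed),
                              logit_proportions=icfg.get("logit_proportions", False))
        completed = impute(longer_term, spec)
        ipaths = []
        for k, d in enumerate(completed, start=1):
            p = out / f"imputed_{k}.csv"
            (d.reset_index().melt(id_vars="member_id", var_name="time_point",
                                  value_name="weight_kg")
             .to_csv(p, index=False))
            ipaths.append(p)
        pooled = estimate_all(longer_term, spec, completed=completed)
        pooled.to_csv(out / "pooled.csv", index=False)
        _record("impute", ipaths + [out / "pooled.csv"], t0)

        stage = "analyze"
        t0 = time.perf_counter()
        acfg = cfg.get("analyze", {})
        comparison = pd.concat([
            pooled_to_comparison(pooled),
            available_case_table(longer_term),
            complete_case_table(longer_term),
        ], ignore_index=True)
        for grp in acfg.get("groups", []):
            sub = subgroup_summaries(longer_term, grp)
            comparison = pd.concat([comparison, sub.drop(columns=["group_by"])],
                                   ignore_index=True)
        comparison.to_csv(out / "comparison.csv", index=False)
        assoc = engagement_association(
            longer_term, use_complete_case=acfg.get("use_complete_case", True))
        with open(out / "association.json", "w") as fh:
            json.dump({"r": assoc.r, "n": assoc.n, "p_value": assoc.p_value,
                       "threshold_groups": assoc.threshold_groups.to_dict("records")},
                      fh, indent=2)
        _record("analyze", [out / "comparison.csv", out / "association.json"], t0)

        stage = "report"
        t0 = time.perf_counter()
        render_report(out, min_share_pct=cfg.get("patterns", {})
                      .get("min_share_pct", 2.0))
        _record("report", [out / "report.txt"], t0)
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def pooled_to_comparison(pooled: pd.DataFrame) -> pd.DataFrame:
    """Reshape the pooled MI table into comparison-table rows."""
    rows = []
    for (stratum, tp), grp in pooled.groupby(["stratum", "time_point"], sort=False):
        g = grp.set_index("estimand")
        rows.append({
            "approach": "imputed", "stratum": stratum, "time_point": tp,
            "n": int(g["n"].iloc[0]),
            "mean_loss_kg": g.loc["mean_loss_kg", "q_bar"],
            "se_loss_kg": g.loc["mean_loss_kg", "se"],
            "mean_loss_pct": g.loc["mean_loss_pct", "q_bar"],
            "se_loss_pct": g.loc["mean_loss_pct", "se"],
            "prop_ge5": g.loc["prop_ge5", "q_bar"],
            "prop_ge10": g.loc["prop_ge10", "q_bar"],
        })
    return pd.DataFrame(rows)


def render_report(out_dir, min_share_pct: float = 2.0) -> Path:
    """Render a plain-text report from the pipeline's CSV outputs."""
    out = Path(out_dir)
    lines = ["Weight-loss analysis report", "=" * 27, ""]

    comparison = pd.read_csv(out / "comparison.csv")
    lines.append("Mean weight loss by estimation approach (total stratum)")
    total = comparison[comparison["stratum"] == "total"]
    for approach, grp in total.groupby("approach", sort=False):
        lines.append(f"  {approach}:")
        for _, row in grp.iterrows():
            lines.append(
                f"    {row['time_point']:>4}: n={int(row['n'])}, "
                f"loss {round_half_up(row['mean_loss_kg']):.1f} kg "
                f"({round_half_up(row['mean_loss_pct']):.1f}% TBW), "
                f">=5% TBW {round_half_up(100 * row['prop_ge5']):.1f}%, "
                f">=10% TBW {round_half_up(100 * row['prop_ge10']):.1f}%")
    lines.append("")

    ptable = pd.read_csv(out / "pattern_table.csv")
    visible = render_pattern_table(ptable, min_share_pct) if len(ptable) else ptable
    lines.append(f"Weight-loss patterns (groups >= {min_share_pct:g}% of sample)")
    if len(visible) == 0:
        lines.append("  no pattern group reaches the minimum share")
    else:
        for _, row in visible.iterrows():
            lines.append(
                f"  {row['label']}: n={int(row['n'])} "
                f"({round_half_up(row['share_pct']):.1f}%), "
                f"start {round_half_up(row['mean_start_weight_kg']):.1f} kg, "
                f"12-mo loss {round_half_up(row['mean_loss_kg_m12']):.1f} kg "
                f"({round_half_up(row['mean_loss_pct_m12']):.1f}% TBW)")
    lines.append("")

    with open(out / "association.json") as fh:
        assoc = json.load(fh)
    lines.append("Engagement-outcome association (complete cases)")
    lines.append(f"  Pearson r = {assoc['r']:.3f} (n={assoc['n']}, "
                 f"p = {assoc['p_value']:.3g})")
    for grp in assoc["threshold_groups"]:
        lines.append(
            f"  {grp['group']}: n={grp['n']}, mean use "
            f"{grp['mean_weekly_use']:.1f}/week, 12-mo loss "
            f"{grp['mean_loss_kg_m12']:.1f} kg, lost first 6 mo in "
            f"{100 * grp['share_loss_first_6mo']:.1f}% of members")
    path = out / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
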