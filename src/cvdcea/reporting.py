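"""Scenario-suite runner and delimited-text report generation.

Produces the analysis tables as TSV files: per-intervention evaluation
against the do-nothing comparator (individually and as additions to the
optimal package), the expansion path, the acceptability frontier, and
the lifetime cost/health-gain ledger for current practice and the
optimal package.  A run is fully reproducible: the same configuration
and seed produce byte-identical outputs (no timestamps are written).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import (
    ModelContext,
    Scenario,
    build_default_context,
    default_candidates,
    evaluate_vs_null,
    expansion_path,
    package_ledger,
    package_scenario,
    acceptability_frontier,
    run_psa,
)
from .config import RunConfig, validate_config
from .markov import DiscountSpec, MarkovConfig

_FLOAT_FMT = "%.6g"


def context_from_config(cfg: RunConfig) -> ModelContext:
    seed = cfg.seed if cfg.seed is not None else 0
    return build_default_context(
        seed=seed,
        n_per_cell=cfg.generator.n_per_cell,
        gp_attendance=cfg.coverage.gp_attendance,
        assessment_participation=cfg.coverage.assessment_participation,
        discount=DiscountSpec(rate=cfg.economics.discount_rate),
        markov=MarkovConfig(
            trend_enabled=cfg.analysis.trend_enabled,
            unrelated_cost_per_life_year=(
                cfg.analysis.unrelated_cost_per_life_year)),
        threshold=cfg.economics.threshold,
    )


def individual_evaluation_table(ctx: ModelContext, candidates) -> pd.DataFrame:
    """Each candidate evaluated individually against do-nothing."""
    null = ctx.null_totals()
    rows = []
    for c in candidates:
        sc = Scenario(label=f"{c.intervention.name} ({c.band or 'all'})",
                      entries=(c.entry(),))
        o = evaluate_vs_null(ctx, sc, null_totals=null)
        rows.append({
            "intervention": c.intervention.name,
            "band": c.band or "all",
            "health_gain": o.health_gain,
            "net_cost": o.net_cost,
            "icer": o.icer_display(),
        })
    return pd.DataFrame(rows)


def run_scenario_suite(cfg: RunConfig | str | Path, out_dir=None) -> dict:
    """Run the full analysis described by a configuration and write the
    result bundle to disk.  Returns the paths written."""
    if not isinstance(cfg, RunConfig):
        cfg = validate_config(cfg)
    out = Path(out_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx = context_from_config(cfg)
    candidates = default_candidates(
        ctx, statin_price=cfg.analysis.statin_price,
        behaviour_effectiveness_scale=(
            cfg.analysis.behaviour_effectiveness_scale))

    paths: dict[str, Path] = {}

    # -- per-intervention evaluation vs null ------------------------------
    individual = individual_evaluation_table(ctx, candidates)
    paths["individual"] = out / "interventions_individual.tsv"
    individual.to_csv(paths["individual"], sep="\t", index=False,
                      float_format=_FLOAT_FMT)

    # -- expansion path ---------------------------------------------------
    path = expansion_path(ctx, candidates, threshold=cfg.economics.threshold,
                          metric=cfg.economics.metric)
    path_frame = path.to_frame()
    paths["expansion_path"] = out / "expansion_path.tsv"
    path_frame.to_csv(paths["expansion_path"], sep="\t", index=False,
                      float_format=_FLOAT_FMT)
    skipped = pd.DataFrame(path.skipped,
                           columns=["intervention", "band", "reason"])
    paths["skipped"] = out / "skipped_candidates.tsv"
    skipped.to_csv(paths["skipped"], sep="\t", index=False)

    # -- package ledger ---------------------------------------------------
    package = package_scenario(ctx, path)
    current = ctx.current_practice
    psa = None
    if cfg.psa.enabled:
        scenarios = {current.label: current, package.label: package}
        # packages along the path for the acceptability frontier
        prefixes = {}
        entries = []
        for step in path.package_under_threshold()[
                :cfg.psa.max_frontier_packages]:
            matching = [e for e in path.package.entries
                        if e.name == step.name
                        and (step.band == "all" or
                             (e.bands and e.bands[0] == step.band))]
            entries.extend(matching)
            label = f"+{step.name} ({step.band})"
            prefixes[label] = Scenario(label=label, entries=tuple(entries),
                                       metric=cfg.economics.metric)
        scenarios.update(prefixes)
        psa = run_psa(ctx, scenarios, n_draws=cfg.psa.n_draws,
                      seed=cfg.seed, threshold=cfg.economics.threshold)
        summaries = pd.DataFrame([
            _flatten_summary(psa.summary(label)) for label in scenarios])
        paths["psa_summary"] = out / "psa_summary.tsv"
        summaries.to_csv(paths["psa_summary"], sep="\t", index=False,
                         float_format=_FLOAT_FMT)
        grid = np.arange(0.0, cfg.analysis.frontier_max_threshold + 1,
                         cfg.analysis.frontier_step)
        frontier = acceptability_frontier(
            {label: psa.gain_net(label) for label in prefixes}, grid)
        paths["frontier"] = out / "acceptability_frontier.tsv"
        frontier.to_csv(paths["frontier"], sep="\t",
                        float_format=_FLOAT_FMT)

    ledgers = []
    for sc in (current, package):
        frame = package_ledger(ctx, sc, psa=psa)
        frame.insert(0, "scenario", sc.label)
        frame.insert(1, "quantity", frame.index)
        ledgers.append(frame.reset_index(drop=True))
    paths["ledger"] = out / "package_ledger.tsv"
    pd.concat(ledgers, ignore_index=True).to_csv(
        paths["ledger"], sep="\t", index=False, float_format=_FLOAT_FMT)

    # -- run log ----------------------------------------------------------
    log_lines = [
        f"cvdcea version: {__version__}",
        f"seed: {cfg.seed}",
        f"survey n_per_cell: {cfg.generator.n_per_cell}",
        f"discount_rate: {cfg.economics.discount_rate}",
        f"threshold: {cfg.economics.threshold}",
        f"metric: {cfg.economics.metric}",
        f"statin_price: {cfg.analysis.statin_price}",
        "behaviour_effectiveness_scale: "
        f"{cfg.analysis.behaviour_effectiveness_scale}",
        f"trend_enabled: {cfg.analysis.trend_enabled}",
        "unrelated_cost_per_life_year: "
        f"{cfg.analysis.unrelated_cost_per_life_year}",
        f"psa_enabled: {cfg.psa.enabled}",
        f"psa_n_draws: {cfg.psa.n_draws}",
        f"pc_coverage: {ctx.pc_coverage:.6g}",
        f"markov: {ctx.markov}",
        f"threshold_cut_step: {path.threshold_cut}",
    ]
    paths["log"] = out / "run_log.txt"
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return {k: str(v) for k, v in paths.items()}


def _flatten_summary(s: dict) -> dict:
    flat = {"label": s["label"]}
    for key in ("health_gain", "net_cost", "cost_gov", "cost_patient",
                "treatment_cost_change"):
        for stat, v in s[key].items():
            flat[f"{key}_{stat}"] = v
    for key in ("icer_lo95", "icer_median", "icer_hi95",
                "prob_cost_effective"):
        flat[key] = s[key]
    return flat
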