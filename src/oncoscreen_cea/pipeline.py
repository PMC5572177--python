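"""End-to-end orchestration: simulate, estimate, extrapolate, model, render.

``run_pipeline`` executes the whole analysis from one config and master
seed: synthetic trial generation, per-arm discounted restricted mean
survival, censoring-adjusted costs, within-trial ICERs with Fieller
intervals, the test-cost sensitivity sweep, parametric extrapolation, and
the Markov cohort model with PSA.  The master seed fans out to named
sub-seeds (generator, bootstrap, PSA) so each stage is independently
reproducible, and all tables are carried at full precision — rounding
happens only in ``render_tables``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .censored_costs import table3_frame
from .config import PipelineConfig
from .extrapolation import extrapolated_icer
from .icer_stats import univariate_sweep, within_trial_icer
from .markov_cohort import (compare_strategies, default_markov_specs, psa,
                            synthetic_life_table, LifeTable)
from .survival_effects import common_horizon, table2_frame
from .synthetic_trial import generate_trial

logger = logging.getLogger("oncoscreen_cea")

__all__ = ["ReportBundle", "run_pipeline", "render_tables"]

TABLE4_FOOTNOTE = ("Note: ICER values differ from straight division of cost "
                   "difference by effect difference due to rounding.")


@dataclass
class ReportBundle:
    config: PipelineConfig
    tables: dict[str, pd.DataFrame]
    summary: dict


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ("generator", "bootstrap", "psa")
    return {name: int(child.generate_state(1)[0] % 2**31)
            for name, child in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> ReportBundle:
    """Run the configured stages and return all table-shaped outputs.

    ``stages`` may restrict to a subset of
    ``("within_trial", "sweep", "extrapolation", "markov")``; the
    simulation always runs since everything downstream consumes it.
    """
    all_stages = ("within_trial", "sweep", "extrapolation", "markov")
    stages = all_stages if stages is None else stages
    seeds = _stage_seeds(config.seed)
    hazard = config.resolved_hazard()
    logger.info("simulate: seed=%s design=%s", seeds["generator"], config.design)
    records = generate_trial(config.design, hazard, config.costs, seeds["generator"])
    horizon = common_horizon(records)

    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"config_digest": config.digest(), "seeds": seeds,
                     "n_patients": int(len(records)), "trial_horizon": horizon}

    if "within_trial" in stages:
        rates = config.analysis.discount_rates
        tables["table2_effects"] = table2_frame(records, rates, horizon)
        tables["table3_costs"] = table3_frame(records, rates)
        rows = []
        for arm in ("mms", "uss"):
            for rate in [r for r in rates if r > 0] or list(rates):
                res = within_trial_icer(records, arm, rate, horizon,
                                        config.analysis.alpha,
                                        config.analysis.n_bootstrap,
                                        seeds["bootstrap"])
                rows.append({"comparison": f"{arm}_vs_control", "discount_rate": rate,
                             "delta_cost": res.delta_cost, "delta_effect": res.delta_effect,
                             "icer": res.ratio, "ci_low": res.ci_low, "ci_high": res.ci_high,
                             "unbounded": res.unbounded,
                             "classification": res.classification})
        tables["table4_icers"] = pd.DataFrame(rows)
        summary["within_trial"] = {
            f"{r['comparison']}@{r['discount_rate']}": {
                "delta_cost": r["delta_cost"], "delta_effect": r["delta_effect"],
                "icer": r["icer"]}
            for r in rows}

    if "sweep" in stages:
        frames = []
        for rate in [r for r in config.analysis.discount_rates if r > 0] or [0.0]:
            sweep = univariate_sweep(config.design, hazard, config.costs,
                                     seeds["generator"],
                                     config.analysis.test_cost_sweep, rate)
            sweep.insert(0, "discount_rate", rate)
            frames.append(sweep)
        tables["table5_sweep"] = pd.concat(frames, ignore_index=True)

    if "extrapolation" in stages:
        rows = []
        for rate in [r for r in config.analysis.discount_rates if r > 0] or [0.0]:
            res = extrapolated_icer(records, "mms", config.extrapolation.horizon,
                                    rate, config.extrapolation.df_grid,
                                    config.extrapolation.screen_active_years)
            rows.append({"comparison": "mms_vs_control", "discount_rate": rate,
                         "horizon": res.horizon, "delta_cost": res.delta_cost,
                         "delta_lyg": res.delta_lyg, "icer": res.icer})
            if "extrapolation_yearly" not in tables:
                tables["extrapolation_yearly"] = res.yearly
        tables["table4_extrapolated"] = pd.DataFrame(rows)
        summary["extrapolated"] = {str(r["discount_rate"]): {
            "delta_cost": r["delta_cost"], "delta_lyg": r["delta_lyg"], "icer": r["icer"]}
            for r in rows}

    if "markov" in stages:
        m = config.markov
        table = (LifeTable.from_csv(m.life_table_csv) if m.life_table_csv
                 else synthetic_life_table())
        rows, psa_rows = [], []
        for rate in [r for r in config.analysis.discount_rates if r > 0] or [0.0]:
            spec_s, spec_n = default_markov_specs(
                rate, config.costs.test_cost, m.incidence,
                m.early_fraction_screened, m.early_fraction_none)
            spec_s = replace(spec_s, start_age=m.start_age)
            spec_n = replace(spec_n, start_age=m.start_age)
            cmp_ = compare_strategies(spec_s, spec_n, table)
            rows.append({"discount_rate": rate, "delta_ly": cmp_.delta_ly,
                         "delta_qaly": cmp_.delta_qaly, "delta_cost": cmp_.delta_cost,
                         "icer_per_qaly": cmp_.icer.ratio,
                         "classification": cmp_.icer.classification})
            psa_res = psa(spec_s, spec_n, table, m.psa_test_cost_range,
                          m.psa_draws, seeds["psa"], config.costs.test_cost)
            psa_rows.append({"discount_rate": rate, "icer_min": psa_res.icer_min,
                             "icer_max": psa_res.icer_max, "icer_base": psa_res.icer_base})
        tables["markov"] = pd.DataFrame(rows)
        tables["markov_psa"] = pd.DataFrame(psa_rows)
        summary["markov"] = {str(r["discount_rate"]): {
            "delta_qaly": r["delta_qaly"], "delta_cost": r["delta_cost"],
            "icer_per_qaly": r["icer_per_qaly"]} for r in rows}

    return ReportBundle(config=config, tables=tables, summary=summary)


_CURRENCY_COLS = {"delta_cost", "icer", "ci_low", "ci_high",
                  "icer_per_qaly", "icer_min", "icer_max", "icer_base"}
_EFFECT_COLS = {"delta_effect", "delta_lyg", "delta_ly", "delta_qaly", "se"}
# per-table overrides where a generic column name carries different units
_TABLE_FORMATS = {
    "table2_effects": {"mean": 5, "se": 5},       # years
    "table3_costs": {"mean": 0, "variance": 0},   # pounds
}


def render_tables(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write each table as CSV (currency to the pound, effects to 5 dp).

    Every file starts with a comment header carrying the config digest;
    the ICER table additionally carries the rounding footnote.  Missing
    stages are skipped with a warning rather than failing the render.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    expected = ("table2_effects", "table3_costs", "table4_icers",
                "table5_sweep", "table4_extrapolated", "markov", "markov_psa")
    for name in expected:
        if name not in bundle.tables:
            logger.warning("render: stage output %r missing, table omitted", name)
    for name, frame in bundle.tables.items():
        frame = frame.copy()
        overrides = _TABLE_FORMATS.get(name, {})
        for col in frame.columns:
            if not pd.api.types.is_float_dtype(frame[col]):
                continue
            if col in overrides:
                frame[col] = frame[col].round(overrides[col])
            elif col in _CURRENCY_COLS:
                frame[col] = frame[col].round(0)
            elif col in _EFFECT_COLS:
                frame[col] = frame[col].round(5)
        path = out_dir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# config: {bundle.config.digest()}\n")
            if name.startswith("table4"):
                fh.write(f"# {TABLE4_FOOTNOTE}\n")
            frame.to_csv(fh, index=False)
        written[name] = path

    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["summary"] = summary_path
    return written
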