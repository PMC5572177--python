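"""Markov cohort model of an ovarian-cancer screening programme.

A deterministic annual-cycle state-transition model follows a cohort of
well 60-year-old women through benign oophorectomy (a one-cycle surgical
tunnel state returning to well), early-stage ovarian cancer, advanced
ovarian cancer, death from ovarian cancer and death from competing causes.
Competing mortality comes from a life table of annual death probabilities
applied at the cohort's current age in every alive state; disease
transitions act on the mass that survives competing mortality, so each
state's outgoing probabilities sum to one.

Screening does not change cancer incidence in the model; it shifts the
stage split at diagnosis toward early disease (the survival benefit) and
adds an annual screening cost to every well woman under the screening
strategy.  Cancer states persist until death and accrue their utility
each cycle; their one-off weighted treatment cost is charged on entry.
Life-years, QALYs and costs accrue from state-at-cycle-start occupancy,
discounted by (1+d)^{-k} with cycle 0 undiscounted (the same annual-step
convention as the within-trial estimators); a half-cycle correction is
available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .icer_stats import ICERResult, icer_with_ci

__all__ = [
    "STATES",
    "LifeTable",
    "MarkovSpec",
    "CohortTrace",
    "CEAOutput",
    "StrategyComparison",
    "hazard_to_probability",
    "synthetic_life_table",
    "default_markov_specs",
    "run_cohort",
    "compare_strategies",
    "psa",
]

STATES = ("well", "benign_ooph", "early_oc", "advanced_oc", "oc_death", "other_death")
_ALIVE = ("well", "benign_ooph", "early_oc", "advanced_oc")


def hazard_to_probability(rate: float) -> float:
    """Annual transition probability implied by a constant annual hazard."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return 1.0 - math.exp(-rate)


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(age) over a contiguous age range."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.qx):
            raise ValueError("ages and qx must have equal length")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")
        if np.any(np.diff(self.ages) != 1):
            raise ValueError("ages must be contiguous")

    def q(self, age: float) -> float:
        idx = int(age) - int(self.ages[0])
        if idx < 0:
            raise ValueError(f"age {age} below life-table range")
        if idx >= len(self.qx):
            return 1.0  # beyond the table everyone dies
        return float(self.qx[idx])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        frame = pd.read_csv(path)
        return cls(ages=frame["age"].to_numpy(dtype=int),
                   qx=frame["qx"].to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)


def synthetic_life_table(start_age: int = 50, end_age: int = 110,
                         target_e60: float = 25.22, shape: float = 0.095) -> LifeTable:
    """Gompertz life table calibrated to a target life expectancy at 60.

    Synthetic stand-in for a national female life table: the annual
    mortality hazard grows exponentially with age, with the level solved so
    that remaining life expectancy at age 60 (approximated as the sum of
    yearly survival probabilities plus half a year) hits ``target_e60``,
    the published remaining life expectancy of a 60-year-old UK woman.
    """
    ages = np.arange(start_age, end_age + 1)

    def expectancy(level: float) -> float:
        haz = level * np.exp(shape * (np.arange(60, end_age + 1) - 60))
        q = 1 - np.exp(-haz)
        surv = np.cumprod(1 - q)
        return float(surv.sum()) + 0.5

    level = brentq(lambda a: expectancy(a) - target_e60, 1e-6, 0.2)
    haz = level * np.exp(shape * (ages - 60))
    return LifeTable(ages=ages, qx=1 - np.exp(-haz))


@dataclass(frozen=True)
class MarkovSpec:
    """One strategy's transition probabilities, state costs and utilities.

    Probabilities are annual and conditional on surviving competing
    mortality that cycle.  ``screen_cost_per_well_year`` is charged to the
    well state only when ``screening`` is true; ``benign_ooph_cost`` and the
    two treatment costs are one-off entry costs.
    """

    screening: bool
    start_age: int = 60
    discount_rate: float = 0.015
    # annual transition probabilities (conditional on no competing death)
    p_well_to_benign_ooph: float = 0.0002
    p_well_to_early_oc: float = 0.0002
    p_well_to_advanced_oc: float = 0.0008
    p_early_to_oc_death: float = 0.0209
    p_advanced_to_oc_death: float = 0.45
    # state costs (GBP)
    screen_cost_per_well_year: float = 132.0   # test 20 + phlebotomy 3 + outpatient 109
    benign_ooph_cost: float = 2275.0 + 139.0
    early_oc_cost: float = 3422.0
    advanced_oc_cost: float = 5666.0
    # utilities
    utility_well: float = 1.0
    utility_benign_ooph: float = 1.0
    utility_early_oc: float = 0.718
    utility_advanced_oc: float = 0.649
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        probs = (self.p_well_to_benign_ooph, self.p_well_to_early_oc,
                 self.p_well_to_advanced_oc, self.p_early_to_oc_death,
                 self.p_advanced_to_oc_death)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if sum(probs[:3]) > 1:
            raise ValueError("well-state outgoing probabilities exceed 1")
        for u in (self.utility_well, self.utility_benign_ooph,
                  self.utility_early_oc, self.utility_advanced_oc):
            if not 0 <= u <= 1:
                raise ValueError("utilities must lie in [0, 1]")
        for c in (self.screen_cost_per_well_year, self.benign_ooph_cost,
                  self.early_oc_cost, self.advanced_oc_cost):
            if c < 0:
                raise ValueError("costs must be >= 0")


def default_markov_specs(discount_rate: float = 0.015, test_cost: float = 20.0,
                         incidence: float = 0.001, early_fraction_screened: float = 0.39,
                         early_fraction_none: float = 0.26) -> tuple[MarkovSpec, MarkovSpec]:
    """(screening, no-screening) strategy pair with trial-style defaults.

    Screening shifts the early/advanced split at diagnosis and adds the
    annual screen cost (test + phlebotomy 3 + outpatient 109) plus a higher
    benign-surgery rate from false-positive referrals.
    """
    common = dict(discount_rate=discount_rate)
    screen = MarkovSpec(
        screening=True,
        p_well_to_early_oc=incidence * early_fraction_screened,
        p_well_to_advanced_oc=incidence * (1 - early_fraction_screened),
        p_well_to_benign_ooph=0.0014,
        screen_cost_per_well_year=test_cost + 3.0 + 109.0,
        **common,
    )
    none = MarkovSpec(
        screening=False,
        p_well_to_early_oc=incidence * early_fraction_none,
        p_well_to_advanced_oc=incidence * (1 - early_fraction_none),
        p_well_to_benign_ooph=0.0002,
        screen_cost_per_well_year=0.0,
        **common,
    )
    return screen, none


@dataclass(frozen=True)
class CohortTrace:
    occupancy: pd.DataFrame  # one row per cycle, one column per state


@dataclass(frozen=True)
class CEAOutput:
    life_years: float
    qalys: float
    cost: float
    discount_rate: float


@dataclass(frozen=True)
class StrategyComparison:
    screening: CEAOutput
    no_screening: CEAOutput
    delta_ly: float
    delta_qaly: float
    delta_cost: float
    icer: ICERResult


def run_cohort(spec: MarkovSpec, life_table: LifeTable,
               max_cycles: int = 200, tol: float = 1e-9) -> tuple[CohortTrace, CEAOutput]:
    """Cycle the cohort to extinction; return the trace and discounted totals."""
    occ = {s: 0.0 for s in STATES}
    occ["well"] = 1.0
    rows = [dict(occ)]
    ly = qaly = cost = 0.0
    utilities = {"well": spec.utility_well, "benign_ooph": spec.utility_benign_ooph,
                 "early_oc": spec.utility_early_oc, "advanced_oc": spec.utility_advanced_oc}

    for k in range(max_cycles):
        alive = sum(occ[s] for s in _ALIVE)
        if alive < tol:
            break
        age = spec.start_age + k
        q = life_table.q(age)
        w = (1 + spec.discount_rate) ** (-k)

        # state-at-cycle-start accrual
        cycle_ly = alive
        cycle_qaly = sum(occ[s] * utilities[s] for s in _ALIVE)
        cycle_cost = occ["well"] * (spec.screen_cost_per_well_year if spec.screening else 0.0)

        new = {s: 0.0 for s in STATES}
        new["oc_death"] = occ["oc_death"]
        new["other_death"] = occ["other_death"]

        # competing mortality first, then disease transitions on survivors
        for s in _ALIVE:
            new["other_death"] += occ[s] * q
        well = occ["well"] * (1 - q)
        new["benign_ooph"] += well * spec.p_well_to_benign_ooph
        inflow_early = well * spec.p_well_to_early_oc
        inflow_adv = well * spec.p_well_to_advanced_oc
        new["well"] += well * (1 - spec.p_well_to_benign_ooph
                               - spec.p_well_to_early_oc - spec.p_well_to_advanced_oc)
        # benign oophorectomy is a one-cycle tunnel back to well
        new["well"] += occ["benign_ooph"] * (1 - q)
        early = occ["early_oc"] * (1 - q)
        new["early_oc"] += early * (1 - spec.p_early_to_oc_death) + inflow_early
        new["oc_death"] += early * spec.p_early_to_oc_death
        adv = occ["advanced_oc"] * (1 - q)
        new["advanced_oc"] += adv * (1 - spec.p_advanced_to_oc_death) + inflow_adv
        new["oc_death"] += adv * spec.p_advanced_to_oc_death

        # one-off entry costs for this cycle's inflows
        cycle_cost += well * spec.p_well_to_benign_ooph * spec.benign_ooph_cost
        cycle_cost += inflow_early * spec.early_oc_cost
        cycle_cost += inflow_adv * spec.advanced_oc_cost

        if spec.half_cycle_correction:
            alive_next = sum(new[s] for s in _ALIVE)
            cycle_ly = 0.5 * (cycle_ly + alive_next)
            qaly_next = sum(new[s] * utilities[s] for s in _ALIVE)
            cycle_qaly = 0.5 * (cycle_qaly + qaly_next)

        ly += w * cycle_ly
        qaly += w * cycle_qaly
        cost += w * cycle_cost

        occ = new
        total = sum(occ.values())
        if abs(total - 1.0) > 1e-9:
            raise RuntimeError(f"occupancy not conserved at cycle {k}: {total}")
        rows.append(dict(occ))

    trace = CohortTrace(occupancy=pd.DataFrame(rows))
    return trace, CEAOutput(life_years=ly, qalys=qaly, cost=cost,
                            discount_rate=spec.discount_rate)


def compare_strategies(spec_screen: MarkovSpec, spec_none: MarkovSpec,
                       life_table: LifeTable, alpha: float = 0.05) -> StrategyComparison:
    """Screening vs no screening: discounted deltas and the cost-per-QALY ICER."""
    if not math.isclose(spec_screen.discount_rate, spec_none.discount_rate):
        raise ValueError("discount rates differ between strategies")
    if spec_screen.start_age != spec_none.start_age:
        raise ValueError("start ages differ between strategies")
    _, out_s = run_cohort(spec_screen, life_table)
    _, out_n = run_cohort(spec_none, life_table)
    dq = out_s.qalys - out_n.qalys
    dc = out_s.cost - out_n.cost
    icer = icer_with_ci(dc, 0.0, dq, 0.0, 0.0, alpha)
    return StrategyComparison(screening=out_s, no_screening=out_n,
                              delta_ly=out_s.life_years - out_n.life_years,
                              delta_qaly=dq, delta_cost=dc, icer=icer)


@dataclass(frozen=True)
class PSAResult:
    draws: pd.DataFrame  # test_cost, icer
    icer_min: float
    icer_max: float
    icer_base: float | None


def psa(spec_screen: MarkovSpec, spec_none: MarkovSpec, life_table: LifeTable,
        test_cost_range: tuple[float, float] = (15.0, 50.0), n_draws: int = 100,
        seed: int = 0, base_test_cost: float = 20.0,
        phlebotomy_cost: float = 3.0, outpatient_cost: float = 109.0) -> PSAResult:
    """Probabilistic sensitivity analysis over the per-screen test cost.

    Each draw resamples the test cost uniformly over ``test_cost_range``,
    rebuilds the screening strategy's well-state annual cost, and reruns
    the comparison.  Deterministic under a fixed seed.
    """
    lo, hi = test_cost_range
    if lo > hi:
        raise ValueError("test cost range is inverted")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, n_draws)

    def icer_for(tc: float) -> float:
        s = replace(spec_screen,
                    screen_cost_per_well_year=tc + phlebotomy_cost + outpatient_cost)
        return compare_strategies(s, spec_none, life_table).icer.ratio

    icers = np.array([icer_for(tc) for tc in draws])
    base = icer_for(base_test_cost)
    return PSAResult(draws=pd.DataFrame({"test_cost": draws, "icer": icers}),
                     icer_min=float(icers.min()), icer_max=float(icers.max()),
                     icer_base=base)
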