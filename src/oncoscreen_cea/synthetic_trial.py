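"""Synthetic patient-level screening-trial data.

Emulates a three-arm ovarian-cancer screening trial (no screening, annual
multimodal serum screening [MMS], annual ultrasound screening [USS]) at the
patient level: staggered entry, administrative censoring, a rare primary
event (death from ovarian cancer) whose hazard is reduced by screening only
after a lead time, and yearly cost accrual from screening and treatment.

The event-time model is piecewise exponential with a change-point at the
lead time.  Because the trial outcomes the generator is calibrated against
(arm-level death proportions, the overall mortality reduction, and the
larger reduction over the late follow-up window) jointly over-determine a
single post-lead hazard ratio, each screened arm carries two reduction
parameters: a small pre-lead reduction and the dominant post-lead
reduction.  :func:`calibrate_hazard` solves both from the target outcome
rates in closed form (expectations over the uniform censoring window reduce
to differences of exponentials).

Alongside the generator, :func:`true_rmst` provides the exact discounted
restricted mean survival implied by the generating hazard, as an analytic
oracle for the nonparametric estimators downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, fsolve

ARMS = ("control", "mms", "uss")

__all__ = [
    "ARMS",
    "TrialDesign",
    "HazardSpec",
    "CostModel",
    "PatientRecord",
    "calibrate_hazard",
    "default_design",
    "default_costs",
    "default_hazard",
    "generate_trial",
    "true_rmst",
    "true_event_probability",
    "records_to_frame",
    "records_to_csv",
    "records_from_csv",
]


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class TrialDesign:
    """Arm sizes and follow-up structure of the trial.

    Entry is staggered uniformly over ``recruitment_window`` years; a woman
    entering with offset ``u`` is administratively censored at
    ``max_followup - u``, so follow-up ranges over
    ``[max_followup - recruitment_window, max_followup]``.
    """

    n_control: int = 101_299
    n_mms: int = 50_624
    n_uss: int = 50_623
    recruitment_window: float = 4.4
    max_followup: float = 13.6
    screening_duration: float = 8.0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_mms, self.n_uss) <= 0:
            raise ParameterError("arm sizes must be positive")
        if not 0 < self.screening_duration <= self.max_followup:
            raise ParameterError("need 0 < screening_duration <= max_followup")
        if self.recruitment_window < 0:
            raise ParameterError("recruitment_window must be >= 0")
        if self.recruitment_window >= self.max_followup:
            raise ParameterError("recruitment_window must be < max_followup")

    @property
    def min_followup(self) -> float:
        return self.max_followup - self.recruitment_window

    @property
    def n_years(self) -> int:
        """Number of yearly cost bins needed to cover any follow-up."""
        return int(math.ceil(self.max_followup))


@dataclass(frozen=True)
class HazardSpec:
    """Piecewise-constant ovarian-cancer death hazard per arm.

    The control arm has constant hazard ``baseline_oc_hazard``.  Screened
    arms multiply it by ``(1 - reduction_before_lead)`` on ``[0, lead_time)``
    and by ``(1 - reduction)`` thereafter; the pre-lead reductions are small
    and exist so that the overall and the late-window mortality reductions
    can both be matched (see module docstring).
    """

    baseline_oc_hazard: float
    lead_time: float = 7.0
    reduction_mms: float = 0.23
    reduction_uss: float = 0.21
    pre_lead_reduction_mms: float = 0.0
    pre_lead_reduction_uss: float = 0.0
    other_cause_hazard: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_oc_hazard < 0 or self.other_cause_hazard < 0:
            raise ParameterError("hazards must be >= 0")
        for r in (self.reduction_mms, self.reduction_uss,
                  self.pre_lead_reduction_mms, self.pre_lead_reduction_uss):
            if not 0 <= r < 1:
                raise ParameterError("reductions must lie in [0, 1)")
        if self.lead_time < 0:
            raise ParameterError("lead_time must be >= 0")

    def rates(self, arm: str) -> tuple[float, float]:
        """(pre-lead, post-lead) ovarian-cancer hazard for ``arm``."""
        lam = self.baseline_oc_hazard
        if arm == "control":
            return lam, lam
        if arm == "mms":
            return lam * (1 - self.pre_lead_reduction_mms), lam * (1 - self.reduction_mms)
        if arm == "uss":
            return lam * (1 - self.pre_lead_reduction_uss), lam * (1 - self.reduction_uss)
        raise ParameterError(f"unknown arm {arm!r}")

    def cumulative(self, arm: str, t: np.ndarray | float) -> np.ndarray | float:
        """Cumulative ovarian-cancer hazard H(t) for ``arm``."""
        r0, r1 = self.rates(arm)
        t = np.asarray(t, dtype=float)
        return r0 * np.minimum(t, self.lead_time) + r1 * np.maximum(t - self.lead_time, 0.0)


@dataclass(frozen=True)
class CostModel:
    """Unit costs and simple cost-accrual rules.

    Screen-year costs are charged in expectation: each screen year in the
    MMS arm costs the blood test plus phlebotomy plus the expected cost of
    second-line ultrasound among the ``referral_fraction`` of screens that
    trigger further assessment; a USS screen year costs the scan plus the
    expected repeat scan.  Treatment is a single stage-specific cost charged
    in the year of diagnosis.
    """

    test_cost: float = 20.0
    phlebotomy_cost: float = 3.0
    tvs_cost: float = 150.0
    referral_fraction: float = 0.03
    early_treatment_cost: float = 3422.0
    advanced_treatment_cost: float = 5666.0
    early_fraction_screened: float = 0.39
    early_fraction_control: float = 0.26
    diagnosis_lead_years: float = 1.0

    def __post_init__(self) -> None:
        for c in (self.test_cost, self.phlebotomy_cost, self.tvs_cost,
                  self.early_treatment_cost, self.advanced_treatment_cost,
                  self.diagnosis_lead_years):
            if c < 0:
                raise ParameterError("costs must be >= 0")
        for f in (self.referral_fraction, self.early_fraction_screened,
                  self.early_fraction_control):
            if not 0 <= f <= 1:
                raise ParameterError("fractions must lie in [0, 1]")

    def screen_year_cost(self, arm: str) -> float:
        """Expected cost of one screen year for a woman in ``arm``."""
        if arm == "control":
            return 0.0
        if arm == "mms":
            return self.test_cost + self.phlebotomy_cost + self.referral_fraction * self.tvs_cost
        if arm == "uss":
            return self.tvs_cost * (1 + self.referral_fraction)
        raise ParameterError(f"unknown arm {arm!r}")

    def early_fraction(self, arm: str) -> float:
        return self.early_fraction_control if arm == "control" else self.early_fraction_screened


@dataclass(frozen=True)
class PatientRecord:
    """One woman's trial history (convenience container for fixtures)."""

    id: int
    arm: str
    followup_time: float
    event: int
    yearly_costs: Sequence[float] = ()
    diagnosis_year: int | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.followup_time <= 0:
            raise ParameterError("followup_time must be > 0")
        if any(c < 0 for c in self.yearly_costs):
            raise ParameterError("costs must be >= 0")


# ---------------------------------------------------------------------------
# Calibration

def _mean_exp(a: float, lo: float, hi: float) -> float:
    """E[exp(-a C)] for C ~ Uniform(lo, hi)."""
    if hi == lo:
        return math.exp(-a * lo)
    if a == 0:
        return 1.0
    return (math.exp(-a * lo) - math.exp(-a * hi)) / (a * (hi - lo))


def true_event_probability(design: TrialDesign, hazard: HazardSpec, arm: str,
                           window: tuple[float, float] | None = None) -> float:
    """Exact probability of an observed in-trial ovarian-cancer death.

    ``window=(a, b)`` restricts to deaths with event time in ``(a, b]``;
    ``None`` means the whole follow-up.  Assumes no other-cause mortality
    (the within-trial default) and uniform entry.
    """
    lo, hi = design.min_followup, design.max_followup
    r0, r1 = hazard.rates(arm)
    L = hazard.lead_time
    a, b = window if window is not None else (0.0, hi)
    if a > lo:
        raise ParameterError("window start must not exceed the minimum follow-up")

    def surv_at(t: float) -> float:
        return math.exp(-(r0 * min(t, L) + r1 * max(t - L, 0.0)))

    # P(a < T <= min(C, b)) = S(a) - E[S(min(C, b))] for C ~ U(lo, hi)
    if b >= hi:
        e_tail = _mean_exp_piecewise(r0, r1, L, lo, hi)
    elif b <= lo:
        e_tail = surv_at(b)
    else:
        w = (b - lo) / (hi - lo)
        e_tail = w * _mean_exp_piecewise(r0, r1, L, lo, b) + (1 - w) * surv_at(b)
    return surv_at(a) - e_tail


def _mean_exp_piecewise(r0: float, r1: float, L: float, lo: float, hi: float) -> float:
    """E[exp(-H(C))] for C ~ U(lo, hi) under the change-point hazard."""
    if hi <= L:
        return _mean_exp(r0, lo, hi)
    if lo >= L:
        return math.exp(-(r0 - r1) * L) * _mean_exp(r1, lo, hi)
    w = (L - lo) / (hi - lo)
    below = _mean_exp(r0, lo, L)
    above = math.exp(-(r0 - r1) * L) * _mean_exp(r1, L, hi)
    return w * below + (1 - w) * above


def calibrate_hazard(
    design: TrialDesign | None = None,
    *,
    control_death_proportion: float = 0.0034,
    overall_reduction_mms: float = 0.15,
    overall_reduction_uss: float = 0.11,
    late_reduction_mms: float = 0.23,
    late_reduction_uss: float = 0.21,
    lead_time: float = 7.0,
) -> HazardSpec:
    """Solve hazard parameters from target arm-level trial outcomes.

    The baseline hazard is chosen so the expected observed death proportion
    in the control arm equals ``control_death_proportion`` under the
    design's censoring distribution; each screened arm's pre/post-lead
    reductions are then solved jointly so that the overall reduction and
    the reduction restricted to deaths after the lead time both match.
    """
    design = design or default_design()
    lo, hi = design.min_followup, design.max_followup

    lam = brentq(
        lambda l: (1 - _mean_exp(l, lo, hi)) - control_death_proportion,
        1e-9, 1.0,
    )

    p_ctrl = control_death_proportion
    q_ctrl = math.exp(-lam * lead_time) * (1 - _mean_exp(lam, lo - lead_time, hi - lead_time))

    def solve_arm(overall: float, late: float) -> tuple[float, float]:
        def eqs(x):
            r0, r1 = x
            s_lead = math.exp(-lam * (1 - r0) * lead_time)
            tail = _mean_exp(lam * (1 - r1), lo - lead_time, hi - lead_time)
            p = 1 - s_lead * tail
            q = s_lead * (1 - tail)
            return [p - (1 - overall) * p_ctrl, q - (1 - late) * q_ctrl]

        (r0, r1), _, ier, msg = fsolve(eqs, [overall / 2, late], full_output=True)
        if ier != 1:
            raise ParameterError(f"hazard calibration failed: {msg}")
        if not (0 <= r0 < 1 and 0 <= r1 < 1):
            raise ParameterError("calibrated reductions outside [0, 1)")
        return float(r0), float(r1)

    pre_mms, post_mms = solve_arm(overall_reduction_mms, late_reduction_mms)
    pre_uss, post_uss = solve_arm(overall_reduction_uss, late_reduction_uss)
    return HazardSpec(
        baseline_oc_hazard=float(lam),
        lead_time=lead_time,
        reduction_mms=post_mms,
        reduction_uss=post_uss,
        pre_lead_reduction_mms=pre_mms,
        pre_lead_reduction_uss=pre_uss,
    )


def default_design() -> TrialDesign:
    return TrialDesign()


def default_costs() -> CostModel:
    return CostModel()


def default_hazard(design: TrialDesign | None = None) -> HazardSpec:
    """Hazard spec calibrated to the trial's printed arm-level outcomes."""
    return calibrate_hazard(design)


# ---------------------------------------------------------------------------
# Generation

def _invert_piecewise(e: np.ndarray, r0: float, r1: float, lead: float) -> np.ndarray:
    """Event times with cumulative hazard H(t)=r0*min(t,L)+r1*max(t-L,0)."""
    t = np.full_like(e, np.inf)
    h_lead = r0 * lead
    if r0 > 0:
        early = e <= h_lead
        t[early] = e[early] / r0
    else:
        early = np.zeros_like(e, dtype=bool)
    late = ~early
    if r1 > 0:
        t[late] = lead + (e[late] - h_lead) / r1
    return t


def _generate_arm(arm: str, n: int, design: TrialDesign, hazard: HazardSpec,
                  costs: CostModel, arm_seed: np.random.SeedSequence,
                  id_offset: int) -> pd.DataFrame:
    entry_ss, event_ss, other_ss, stage_ss = arm_seed.spawn(4)
    rng_entry = np.random.default_rng(entry_ss)
    rng_event = np.random.default_rng(event_ss)
    rng_other = np.random.default_rng(other_ss)
    rng_stage = np.random.default_rng(stage_ss)

    offsets = rng_entry.uniform(0.0, design.recruitment_window, n)
    admin_censor = design.max_followup - offsets

    r0, r1 = hazard.rates(arm)
    t_oc = _invert_piecewise(rng_event.exponential(1.0, n), r0, r1, hazard.lead_time)
    if hazard.other_cause_hazard > 0:
        t_other = rng_other.exponential(1.0 / hazard.other_cause_hazard, n)
        censor = np.minimum(admin_censor, t_other)
    else:
        censor = admin_censor
    event = (t_oc <= censor).astype(np.int8)
    followup = np.minimum(t_oc, censor)

    n_years = design.n_years
    cost = np.zeros((n, n_years))

    diag_year = np.full(n, np.nan)
    stage = np.full(n, None, dtype=object)
    ev = event.astype(bool)
    if ev.any():
        diag_time = np.maximum(t_oc[ev] - costs.diagnosis_lead_years, 0.0)
        dy = np.floor(diag_time).astype(int)
        dy = np.minimum(dy, n_years - 1)
        diag_year[ev] = dy
        early = rng_stage.random(ev.sum()) < costs.early_fraction(arm)
        stage[ev] = np.where(early, "early", "advanced")
        treat = np.where(early, costs.early_treatment_cost, costs.advanced_treatment_cost)
        cost[np.flatnonzero(ev), dy] += treat

    screen_cost = costs.screen_year_cost(arm)
    if screen_cost > 0:
        years = np.arange(n_years)
        # a screen at the start of year y happens while on-screen, alive,
        # uncensored, and not past the year of diagnosis
        active = (years[None, :] < design.screening_duration) & (years[None, :] < followup[:, None])
        has_diag = ~np.isnan(diag_year)
        if has_diag.any():
            capped = years[None, :] <= np.where(np.isnan(diag_year), np.inf, diag_year)[:, None]
            active &= capped
        cost += screen_cost * active

    frame = pd.DataFrame({
        "id": np.arange(id_offset, id_offset + n),
        "arm": arm,
        "followup_time": followup,
        "event": event,
        "diagnosis_year": diag_year,
        "stage": stage,
    })
    for k in range(n_years):
        frame[f"cost_y{k}"] = cost[:, k]
    return frame


def generate_trial(design: TrialDesign, hazard: HazardSpec, costs: CostModel,
                   seed: int) -> pd.DataFrame:
    """Generate the full three-arm patient-level dataset.

    Returns a DataFrame with one row per woman and columns ``id, arm,
    followup_time, event, diagnosis_year, stage, cost_y0..``; costs in
    years beyond a woman's (ceiling of) follow-up are zero padding.  Each
    arm consumes an independent, deterministically derived random stream,
    so resizing one arm does not reshuffle the others.
    """
    master = np.random.SeedSequence(seed)
    arm_seeds = dict(zip(ARMS, master.spawn(len(ARMS))))
    sizes = {"control": design.n_control, "mms": design.n_mms, "uss": design.n_uss}
    frames, offset = [], 0
    for arm in ARMS:
        frames.append(_generate_arm(arm, sizes[arm], design, hazard, costs,
                                    arm_seeds[arm], offset))
        offset += sizes[arm]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Analytic oracle

def true_rmst(hazard: HazardSpec, arm: str, horizon: float,
              discount_rate: float = 0.0) -> float:
    """Exact discounted restricted mean ovarian-cancer survival.

    Integrates ``(1+d)^{-floor(t)} * exp(-H(t))`` from 0 to ``horizon`` in
    closed form, segment by segment over integer years and the hazard
    change-point — the same annual-step discounting convention used by the
    Kaplan–Meier restricted-mean estimator, so the two are directly
    comparable.  Other-cause mortality is treated as censoring and does not
    enter (the estimators target net ovarian-cancer survival).
    """
    if horizon <= 0:
        raise ParameterError("horizon must be > 0")
    if discount_rate < 0:
        raise ParameterError("discount_rate must be >= 0")
    r0, r1 = hazard.rates(arm)
    cuts = sorted({0.0, horizon, min(hazard.lead_time, horizon)}
                  | {float(k) for k in range(1, int(math.ceil(horizon)))})
    total = 0.0
    s_left = 1.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        rate = r0 if a < hazard.lead_time else r1
        w = (1 + discount_rate) ** (-math.floor(a + 1e-12))
        width = b - a
        if rate > 0:
            seg = s_left * (1 - math.exp(-rate * width)) / rate
        else:
            seg = s_left * width
        total += w * seg
        s_left *= math.exp(-rate * width)
    return total


# ---------------------------------------------------------------------------
# I/O

def records_to_frame(records: Iterable[PatientRecord], n_years: int | None = None) -> pd.DataFrame:
    """Build the canonical DataFrame from PatientRecord fixtures."""
    records = list(records)
    if not records:
        raise ParameterError("no records")
    if n_years is None:
        n_years = max(int(math.ceil(r.followup_time)) for r in records)
        n_years = max(n_years, max((len(r.yearly_costs) for r in records), default=0))
    rows = []
    for r in records:
        row = {
            "id": r.id, "arm": r.arm, "followup_time": r.followup_time,
            "event": r.event,
            "diagnosis_year": np.nan if r.diagnosis_year is None else float(r.diagnosis_year),
            "stage": r.stage,
        }
        for k in range(n_years):
            row[f"cost_y{k}"] = float(r.yearly_costs[k]) if k < len(r.yearly_costs) else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def cost_columns(records: pd.DataFrame) -> list[str]:
    cols = [c for c in records.columns if c.startswith("cost_y")]
    return sorted(cols, key=lambda c: int(c[6:]))


def records_to_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def records_from_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame["stage"] = frame["stage"].where(frame["stage"].notna(), None)
    return frame
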