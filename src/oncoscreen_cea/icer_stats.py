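"""Incremental cost-effectiveness ratios with Fieller confidence intervals.

The ICER is the ratio of the between-arm cost difference to the
between-arm effect difference.  Because a ratio of two correlated normal
quantities has no finite moments, its confidence interval is taken from
Fieller's construction: the set of candidate ratios R for which
``dC - R*dE`` is not significantly different from zero, i.e. the roots of

    (dE^2 - z^2 vE) R^2 - 2 (dC dE - z^2 vCE) R + (dC^2 - z^2 vC) = 0.

When the leading coefficient is non-positive the effect difference is not
significantly nonzero and the confidence set is unbounded; it is reported
as such, never truncated to a finite interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .censored_costs import lin_cost_estimate, cost_difference
from .survival_effects import (common_horizon, km_estimate, restricted_mean,
                               effect_difference)
from .synthetic_trial import (CostModel, HazardSpec, TrialDesign, cost_columns,
                              generate_trial)

__all__ = [
    "ICERResult",
    "compute_icer",
    "fieller_ci",
    "arm_cost_effect_bootstrap",
    "within_trial_icer",
    "univariate_sweep",
]


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_effect: float
    ratio: float | None
    ci_low: float | None
    ci_high: float | None
    unbounded: bool
    alpha: float
    classification: str  # tradeoff | dominant | dominated | undefined


def compute_icer(delta_cost: float, delta_effect: float,
                 alpha: float = 0.05) -> ICERResult:
    """Point ICER with dominance classification (no interval)."""
    if delta_effect == 0:
        cls, ratio = "undefined", None
    elif delta_cost < 0 and delta_effect > 0:
        cls, ratio = "dominant", delta_cost / delta_effect
    elif delta_cost > 0 and delta_effect < 0:
        cls, ratio = "dominated", delta_cost / delta_effect
    else:
        cls, ratio = "tradeoff", delta_cost / delta_effect
    return ICERResult(delta_cost=delta_cost, delta_effect=delta_effect,
                      ratio=ratio, ci_low=None, ci_high=None, unbounded=False,
                      alpha=alpha, classification=cls)


def fieller_ci(delta_cost: float, var_cost: float, delta_effect: float,
               var_effect: float, covariance: float = 0.0,
               alpha: float = 0.05) -> tuple[float | None, float | None, bool]:
    """Fieller interval for delta_cost / delta_effect.

    Returns ``(low, high, unbounded)``; ``unbounded=True`` means the
    confidence set is not a finite interval (effect not significantly
    nonzero at level ``alpha``) and the bounds are ``None``.
    """
    if var_cost < 0 or var_effect < 0:
        raise ValueError("variances must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    a = delta_effect ** 2 - z ** 2 * var_effect
    b = delta_cost * delta_effect - z ** 2 * covariance
    c = delta_cost ** 2 - z ** 2 * var_cost
    if a <= 0:
        return None, None, True
    disc = b ** 2 - a * c
    if disc < 0:
        # a > 0 with negative discriminant: empty interior, report unbounded
        return None, None, True
    root = math.sqrt(disc)
    return (b - root) / a, (b + root) / a, False


def icer_with_ci(delta_cost: float, var_cost: float, delta_effect: float,
                 var_effect: float, covariance: float = 0.0,
                 alpha: float = 0.05) -> ICERResult:
    res = compute_icer(delta_cost, delta_effect, alpha)
    lo, hi, unbounded = fieller_ci(delta_cost, var_cost, delta_effect,
                                   var_effect, covariance, alpha)
    return ICERResult(delta_cost=res.delta_cost, delta_effect=res.delta_effect,
                      ratio=res.ratio, ci_low=lo, ci_high=hi,
                      unbounded=unbounded, alpha=alpha,
                      classification=res.classification)


def arm_cost_effect_bootstrap(records: pd.DataFrame, arm: str, horizon: float,
                              discount_rate: float, n_bootstrap: int,
                              seed: int) -> dict[str, float]:
    """Joint patient-level bootstrap of (mean cost, restricted mean survival).

    One shared resample per replicate yields the variances *and* the
    within-arm covariance between the censoring-adjusted cost mean and the
    discounted restricted mean — the covariance Fieller needs.
    """
    sub = records[records["arm"] == arm]
    if len(sub) == 0:
        raise ValueError(f"no records in arm {arm!r}")
    cols = cost_columns(sub)
    t = sub["followup_time"].to_numpy(dtype=float)
    d = sub["event"].to_numpy(dtype=int)
    costs = sub[cols].to_numpy(dtype=float)

    from .censored_costs import _point_estimate  # shared kernel

    rng = np.random.default_rng(seed)
    n = len(t)
    cost_reps = np.empty(n_bootstrap)
    eff_reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        cost_reps[b], _ = _point_estimate(t[idx], d[idx], costs[idx], discount_rate)
        frame = pd.DataFrame({"followup_time": t[idx], "event": d[idx], "arm": arm})
        curve = km_estimate(frame, arm)
        hz = min(horizon, curve.max_time)
        eff_reps[b] = restricted_mean(curve, hz, discount_rate).estimate
    cov = np.cov(cost_reps, eff_reps, ddof=1)
    return {"var_cost": float(cov[0, 0]), "var_effect": float(cov[1, 1]),
            "covariance": float(cov[0, 1])}


def within_trial_icer(records: pd.DataFrame, arm: str, discount_rate: float,
                      horizon: float | None = None, alpha: float = 0.05,
                      n_bootstrap: int = 0, seed: int = 0) -> ICERResult:
    """Within-trial ICER of screened ``arm`` vs control.

    With ``n_bootstrap = 0``, variances come from the analytic restricted
    mean standard errors with zero cost variance and covariance (a fast
    analytic mode); otherwise all second moments come from the shared
    patient-level bootstrap.
    """
    if horizon is None:
        horizon = common_horizon(records)
    curves = {a: km_estimate(records, a) for a in ("control", arm)}
    eff = effect_difference(
        restricted_mean(curves[arm], horizon, discount_rate),
        restricted_mean(curves["control"], horizon, discount_rate),
    )
    cost = cost_difference(
        lin_cost_estimate(records, arm, discount_rate),
        lin_cost_estimate(records, "control", discount_rate),
    )
    if n_bootstrap > 0:
        ss = np.random.SeedSequence(seed).spawn(2)
        moments = [arm_cost_effect_bootstrap(records, a, horizon, discount_rate,
                                             n_bootstrap, int(s.generate_state(1)[0] % 2**31))
                   for a, s in zip((arm, "control"), ss)]
        var_cost = sum(m["var_cost"] for m in moments)
        var_eff = sum(m["var_effect"] for m in moments)
        cov = sum(m["covariance"] for m in moments)
    else:
        var_cost, var_eff, cov = 0.0, eff.variance, 0.0
    return icer_with_ci(cost.estimate, var_cost, eff.estimate, var_eff, cov, alpha)


def univariate_sweep(design: TrialDesign, hazard: HazardSpec, costs: CostModel,
                     seed: int, test_costs: tuple[float, ...] = (15, 20, 30, 40, 50),
                     discount_rate: float = 0.015, arm: str = "mms",
                     alpha: float = 0.05) -> pd.DataFrame:
    """Univariate sensitivity of the within-trial ICER to the screen test cost.

    Only the per-screen blood-test cost varies; the random streams are
    seeded identically, so event histories are byte-identical across sweep
    points and the ICER moves through costs alone.
    """
    if len(test_costs) == 0:
        raise ValueError("test_costs must be non-empty")
    if any(c < 0 for c in test_costs):
        raise ValueError("test costs must be >= 0")
    rows = []
    for tc in test_costs:
        records = generate_trial(design, hazard, dc_replace(costs, test_cost=float(tc)), seed)
        res = within_trial_icer(records, arm, discount_rate, alpha=alpha)
        rows.append({"test_cost": float(tc), "delta_cost": res.delta_cost,
                     "delta_effect": res.delta_effect, "icer": res.ratio,
                     "classification": res.classification})
    return pd.DataFrame(rows)
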