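"""Cohort statistics, group comparisons and the age-threshold strategy.

Turns per-run pathway outcomes into the model's reported quantities:

* cohort summaries with the casemix *cost homogeneity* coefficient
  ``mean / (mean + sd)`` — 1 for perfectly predictable costs, falling as
  cost dispersion grows;
* capability-style spec-limit rates (share of runs whose first failure /
  revision falls before a given year, share of runs the capped event
  sequences cannot cover);
* Welch's t-test for mean costs and Bonett's test for equality of two
  standard deviations;
* cost per successfully treated life-year as a ratio of sums;
* cost-by-duration and cost-by-surgery-count stratified tables, and the
  crossing point of two per-duration cost curves;
* the age-threshold treatment strategy (surgery-only for short remaining
  lifetimes, direct implant for long ones, one surgery followed by a
  conditional switch in between).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .engine import (
    _round,
    compute_top,
    event_year,
    simulate_group1,
    simulate_group2,
    simulate_group3,
    run_seeds,
)
from .sampling import ModelParameters, draw_run

__all__ = [
    "CohortSummary",
    "StrategyPolicy",
    "StrategyResult",
    "spec_limit_rate",
    "summarize_costs",
    "compare_groups",
    "bonett_sd_test",
    "cost_per_successful_year",
    "conditional_cost_table",
    "nhi_cost_table",
    "top_curve",
    "successful_years_curve",
    "crossing_year",
    "capability_rates",
    "simulate_strategy",
]


@dataclass(frozen=True)
class CohortSummary:
    """Summary of one cost vector: n, mean, sd, median, homogeneity."""

    n: int
    mean: float
    sd: float
    median: float
    homogeneity: float


def summarize_costs(costs) -> CohortSummary:
    """Mean, sample SD (n−1), median and homogeneity of a cost vector."""
    x = np.asarray(costs, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty cost vector")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    hom = mean / (mean + sd) if sd == sd else float("nan")
    return CohortSummary(n=int(x.size), mean=mean, sd=sd, median=float(np.median(x)), homogeneity=hom)


def spec_limit_rate(values, limit: float, side: str) -> float:
    """Share of values violating a one-sided spec limit.

    ``side='upper'`` counts values strictly above the limit, ``side='lower'``
    values strictly below it.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute a rate from an empty sample")
    if side == "upper":
        return float(np.mean(x > limit))
    if side == "lower":
        return float(np.mean(x < limit))
    raise ValueError("side must be 'lower' or 'upper'")


def bonett_sd_test(a, b) -> tuple[float, float]:
    """Bonett's (2006) test for equality of two standard deviations.

    Layard-type statistic on the log variance ratio with a pooled kurtosis
    estimate computed about trimmed means (trim proportion
    ``1/(2*sqrt(n-4))``).  Returns (z, two-sided p).  Accurate for the
    moderate-to-large samples this package produces; no small-sample
    constant correction is applied.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two observations")
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    if v1 == 0 or v2 == 0:
        raise ValueError("degenerate zero-variance sample")

    def _trimmed(x):
        n = x.size
        prop = 1.0 / (2.0 * math.sqrt(n - 4)) if n > 5 else 0.0
        return stats.trim_mean(x, prop)

    ta, tb = _trimmed(a), _trimmed(b)
    num = (n1 + n2) * (np.sum((a - ta) ** 4) + np.sum((b - tb) ** 4))
    den = (np.sum((a - np.mean(a)) ** 2) + np.sum((b - np.mean(b)) ** 2)) ** 2
    gamma = num / den  # pooled kurtosis
    se = math.sqrt(
        (gamma - (n1 - 3) / n1) / (n1 - 1) + (gamma - (n2 - 3) / n2) / (n2 - 1)
    )
    z = (math.log(v1) - math.log(v2)) / se
    p = 2.0 * (1.0 - ndtr(abs(z)))
    return z, p


def compare_groups(a, b) -> tuple[float, float]:
    """(location p-value, SD p-value) for two cost samples.

    Location: Welch's unequal-variance two-sample t-test.  Dispersion:
    Bonett's test for equality of the two standard deviations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    location_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    _, sd_p = bonett_sd_test(a, b)
    return location_p, sd_p


def cost_per_successful_year(costs, successful_years) -> float:
    """Total cohort cost divided by total successfully treated years.

    A ratio of sums, not a mean of per-run ratios.
    """
    c = np.asarray(costs, dtype=float)
    y = np.asarray(successful_years, dtype=float)
    if c.size != y.size:
        raise ValueError("costs and successful_years must have equal length")
    total_years = float(np.sum(y))
    if total_years <= 0:
        raise ValueError("total successfully treated years must be positive")
    return float(np.sum(c)) / total_years


def conditional_cost_table(outcomes, stratifier: str, levels) -> pd.DataFrame:
    """Cost summaries per exact stratifier level (e.g. top = 10/20/30).

    Levels with no runs are omitted (missing, not zero).
    """
    if not outcomes:
        raise ValueError("empty cohort")
    if not hasattr(outcomes[0], stratifier):
        raise ValueError(f"outcomes have no field {stratifier!r}")
    strat = np.array([getattr(o, stratifier) for o in outcomes])
    ltc = np.array([o.ltc for o in outcomes])
    rows = {}
    for level in levels:
        mask = strat == level
        if mask.any():
            rows[level] = vars(summarize_costs(ltc[mask]))
    return pd.DataFrame.from_dict(rows, orient="index")


def nhi_cost_table(g1_outcomes, g2_outcomes, levels=range(1, 6)) -> pd.DataFrame:
    """Lifetime cost by number of pre-implant surgeries.

    Level 0 is the direct-implant cohort; levels 1..5 are the group-2 runs
    with exactly that many surgeries (the capped sixth level is excluded).
    Each row beyond the first carries the Welch p-value against the
    one-surgery-less level.
    """
    table = conditional_cost_table(g2_outcomes, "nhi", levels)
    g1_row = vars(summarize_costs([o.ltc for o in g1_outcomes]))
    table = pd.concat([pd.DataFrame.from_dict({0: g1_row}, orient="index"), table])
    pvals = [float("nan")]
    prev = np.array([o.ltc for o in g1_outcomes])
    for level in table.index[1:]:
        cur = np.array([o.ltc for o in g2_outcomes if o.nhi == level])
        pvals.append(float(stats.ttest_ind(prev, cur, equal_var=False).pvalue))
        prev = cur
    table["p_vs_one_less"] = pvals
    return table


def top_curve(outcomes, per_successful_year: bool = False, min_n: int = 1) -> pd.Series:
    """Mean lifetime cost (or cost per successful year) by exact duration.

    Returns a Series indexed by the integer observation period; strata with
    fewer than ``min_n`` runs are omitted.
    """
    top = np.array([o.top for o in outcomes])
    ltc = np.array([o.ltc for o in outcomes])
    years = np.array([getattr(o, "successful_years", o.top) for o in outcomes])
    out = {}
    for t in np.unique(top):
        mask = top == t
        if mask.sum() < min_n:
            continue
        if per_successful_year:
            total = years[mask].sum()
            if total <= 0:
                continue
            out[int(t)] = float(ltc[mask].sum() / total)
        else:
            out[int(t)] = float(ltc[mask].mean())
    return pd.Series(out).sort_index()


def successful_years_curve(outcomes, min_n: int = 1) -> pd.Series:
    """Cost per successfully treated year, by rounded successful years.

    Unlike :func:`top_curve`, runs are stratified by the years of
    *successful* treatment they achieve (for pathways without care gaps the
    two stratifications coincide).  This is the axis on which a
    surgery-only pathway is compared with the implant pathway when runs the
    cap cannot cover are not credited with their uncovered years.
    """
    sy = np.array([getattr(o, "successful_years", o.top) for o in outcomes])
    ltc = np.array([o.ltc for o in outcomes])
    out = {}
    for t in np.unique(np.round(sy).astype(int)):
        mask = np.round(sy).astype(int) == t
        total = sy[mask].sum()
        if mask.sum() < min_n or total <= 0:
            continue
        out[int(t)] = float(ltc[mask].sum() / total)
    return pd.Series(out).sort_index()


def crossing_year(curve_a: pd.Series, curve_b: pd.Series) -> int | None:
    """Smallest grid point at which sign(a − b) changes; None if it never does.

    Both curves must be defined on a common integer grid; only shared grid
    points are compared, zeros are carried over (no interpolation below
    one-year resolution).
    """
    common = curve_a.index.intersection(curve_b.index).sort_values()
    diff = (curve_a.loc[common] - curve_b.loc[common]).to_numpy()
    signs = np.sign(diff)
    prev = 0.0
    for i, s in enumerate(signs):
        if s == 0:
            continue
        if prev != 0 and s != prev:
            return int(common[i])
        prev = s
    return None


def capability_rates(g1_outcomes) -> dict[str, float]:
    """Failure/revision/model-error rates of the direct-implant cohort.

    Failure and revision rates are the shares of runs whose rounded first
    event year lies strictly below the stated year; EP rates are the shares
    of runs whose capped event sequence leaves a positive uncovered rest.
    """
    fail = [o.first_failure_year for o in g1_outcomes]
    revs = [o.first_revision_year for o in g1_outcomes]
    return {
        "dr_lts_1": spec_limit_rate(fail, 1, "lower"),
        "dr_lts_10": spec_limit_rate(fail, 10, "lower"),
        "dr_lts_25": spec_limit_rate(fail, 25, "lower"),
        "dr_ttr_1": spec_limit_rate(revs, 1, "lower"),
        "dr_ttr_5": spec_limit_rate(revs, 5, "lower"),
        "dr_ttr_10": spec_limit_rate(revs, 10, "lower"),
        "ep_lts_rate": spec_limit_rate([o.ep_lts for o in g1_outcomes], 0, "upper"),
        "ep_ttr_rate": spec_limit_rate([o.ep_ttr for o in g1_outcomes], 0, "upper"),
    }


class StrategyPolicy:
    """Age-threshold decision rule between the three pathways.

    Surgery-only below ``g3_threshold`` remaining years, direct implant
    above ``g1_threshold``; in between, one hearing-improvement surgery and
    a switch to the implant at the second intervention iff more than
    ``switch_remaining_min`` years remain at that date.
    """

    def __init__(self, g3_threshold: float = 14, g1_threshold: float = 35,
                 switch_remaining_min: float = 13):
        if g3_threshold < 0 or switch_remaining_min < 0:
            raise ValueError("thresholds must be non-negative")
        if g3_threshold > g1_threshold:
            raise ValueError("g3_threshold cannot exceed g1_threshold")
        self.g3_threshold = g3_threshold
        self.g1_threshold = g1_threshold
        self.switch_remaining_min = switch_remaining_min

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"StrategyPolicy(g3_threshold={self.g3_threshold}, "
            f"g1_threshold={self.g1_threshold}, "
            f"switch_remaining_min={self.switch_remaining_min})"
        )


ARMS = ("g3_by_age_at_first", "g3_by_age_at_second", "g1_direct", "surgery_then_implant")


@dataclass(frozen=True)
class StrategyResult:
    """Cohort result of the age-threshold strategy."""

    n: int
    mean: float
    sd: float
    cost_per_successful_year: float
    arm_shares: dict
    costs: np.ndarray
    successful_years: np.ndarray
    arms: np.ndarray  # per-run arm label


def simulate_strategy(
    params: ModelParameters, n: int, seed: int, policy: StrategyPolicy | None = None
) -> StrategyResult:
    """Evaluate the age-threshold strategy on ``n`` runs.

    Uses the same per-run substreams as :func:`meicost.engine.run_cohort`,
    so a degenerate policy reproduces the corresponding pure cohort exactly
    under the same seed.
    """
    if policy is None:
        policy = StrategyPolicy()
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError("number of runs must be a positive integer")
    costs = np.empty(n)
    years = np.empty(n)
    arms = np.empty(n, dtype=object)
    for i, child in enumerate(run_seeds(n, seed)):
        rng = np.random.default_rng(child)
        draws = draw_run(params, rng)
        top, _ = compute_top(draws.afia, draws.afib, draws.afic, params.lex, params.mia)
        if top < policy.g3_threshold:
            o = simulate_group3(draws, params)
            arm = "g3_by_age_at_first"
        elif top > policy.g1_threshold:
            o = simulate_group1(draws, params)
            arm = "g1_direct"
        else:
            # the switch decision is taken at the event year of the second
            # intervention; if taken, the surgical phase covers the rounded
            # success duration of the first surgery (the same rounding that
            # turns THIt into THI in the standard group-2 model)
            first_success = max(draws.dsh[0], 0.0)
            if top - event_year(first_success) > policy.switch_remaining_min:
                o = simulate_group2(draws, params, thi_override=_round(first_success))
                arm = "surgery_then_implant"
            else:
                o = simulate_group3(draws, params)
                arm = "g3_by_age_at_second"
        costs[i] = o.ltc
        years[i] = getattr(o, "successful_years", o.top)
        arms[i] = arm
    shares = {a: float(np.mean(arms == a)) for a in ARMS}
    return StrategyResult(
        n=n,
        mean=float(costs.mean()),
        sd=float(costs.std(ddof=1)),
        cost_per_successful_year=cost_per_successful_year(costs, years),
        arm_shares=shares,
        costs=costs,
        successful_years=years,
        arms=arms,
    )
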