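"""Per-run deterministic model equations and cohort simulation.

Three treatment pathways are evaluated over a patient's remaining lifetime
(the total observation period TOP = life expectancy − age at first
intervention):

* group 1 — direct active middle-ear implant: initial implantation, up to
  two re-implantations, up to three revisions, up to twelve audio-processor
  upgrades, and annual check-ups;
* group 2 — hearing-improvement surgeries (up to six, incl. the initial one)
  for at most 25 years, then the implant pathway for the remaining years;
* group 3 — hearing-improvement surgeries only (up to fifteen, incl. the
  initial one).

All future costs are discounted to present value at the annual discount
rate; event times enter the discount exponent through a spreadsheet-style
``round(t - 0.5)`` year index.  Each capped event sequence carries a signed
"error" quantity (EP_*) measuring the years by which the cap fails to cover
the horizon; their positive share is the model-error rate of the pathway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, fields as dc_fields

import numpy as np
import pandas as pd

from .sampling import ModelParameters, RunDraws, draw_run

__all__ = [
    "Group1Outcome",
    "Group2Outcome",
    "Group3Outcome",
    "compute_top",
    "event_year",
    "present_value",
    "annual_checkup_cost",
    "upgrade_schedule",
    "simulate_group1",
    "simulate_group2",
    "simulate_group3",
    "run_cohort",
    "to_frame",
]

#: literal upper check of the TOP bound cascade.  The model's final clamp is
#: LEX - MIA (= 76 at the defaults) but the cascade's intermediate upper
#: check uses 77; kept verbatim.
TOP_UPPER_CHECK = 77.0


def _round(x: float) -> int:
    """Round half away from zero (spreadsheet convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def compute_top(afia: float, afib: float, afic: float, lex: float, mia: float) -> tuple[int, float]:
    """Total observation period from the age-at-first-intervention draws.

    The three i.i.d. age draws feed a bound-correction cascade: a candidate
    ``round(lex - age)`` that exceeds the upper check falls back to the next
    draw, a candidate below 1 likewise; the final value is floored at 1 and
    clamped at ``lex - mia``.  Returns ``(top, afi)`` with ``afi = lex - top``.
    """
    if lex <= mia:
        raise ValueError("life expectancy must exceed minimum implantation age")
    top_ub1 = _round(lex - afib) if _round(lex - afia) > (lex - mia) else _round(lex - afia)
    top_ub2 = _round(lex - afic) if top_ub1 > TOP_UPPER_CHECK else top_ub1
    top_lb1 = _round(lex - afib) if top_ub2 < 1 else top_ub2
    top_lb2 = _round(lex - afic) if top_lb1 < 1 else top_lb1
    top_lb3 = 1 if top_lb2 < 1 else top_lb2
    top = int(lex - mia) if top_lb3 > (lex - mia) else top_lb3
    return top, lex - top


def event_year(cumulative_time: float) -> int:
    """Discount/scheduling year of an event at ``cumulative_time`` years.

    ``round(t - 0.5)`` under round-half-away-from-zero, clamped at 0 so an
    event at exactly t = 0 is discounted at year 0.
    """
    if cumulative_time < 0:
        raise ValueError("cumulative event time must be non-negative")
    return max(0, _round(cumulative_time - 0.5))


def present_value(amount: float, year: int, dir_: float) -> float:
    """Discount ``amount`` arising in ``year`` to present value."""
    if year < 0:
        raise ValueError("events cannot precede the first intervention")
    if dir_ < 0:
        raise ValueError("discount rate must be non-negative")
    return amount / (1.0 + dir_) ** year


def annual_checkup_cost(foa: float, top: int, dir_: float) -> float:
    """Present value of annual check-up appointments in years 1..top-1.

    Closed-form annuity ``foa * ((1+d)^(top-1) - 1) / ((1+d)^(top-1) * d)``;
    the d -> 0 limit is ``foa * (top - 1)``.
    """
    if top < 1:
        raise ValueError("observation period must be at least one year")
    n = top - 1
    if dir_ == 0.0:
        return foa * n
    g = (1.0 + dir_) ** n
    return foa * (g - 1.0) / (g * dir_)


def upgrade_schedule(tap: int, horizon: int, offset: int = 0, cap: int = 12) -> list[int]:
    """Scheduled processor-upgrade years ``offset + k*tap``.

    An upgrade k (k = 1..cap) takes place iff ``horizon >= k*tap``.
    """
    if tap < 1:
        raise ValueError("upgrade interval must be at least one year")
    return [offset + k * tap for k in range(1, cap + 1) if horizon >= k * tap]


@dataclass(frozen=True)
class Group1Outcome:
    """One group-1 run: direct implant pathway over the full horizon."""

    top: int
    afi: float
    tap: int
    noi: int  # implantations incl. initial
    nor: int  # revisions
    nop: int  # processor upgrades
    ep_lts: float  # horizon years not covered by the capped implant sequence
    ep_ttr: float  # horizon years not covered by the capped revision sequence
    first_failure_year: int
    first_revision_year: int
    cfi: float  # cost first intervention
    cri: float  # cost re-implantations
    cre: float  # cost revisions
    apu: float  # cost processor upgrades
    tsc: float  # cost annual check-ups
    ltc: float  # lifetime cost


@dataclass(frozen=True)
class Group2Outcome:
    """One group-2 run: surgical phase (THI years) then implant phase (TSB)."""

    top: int
    thi: int
    tsb: int
    tap: int
    nhi: int  # hearing-improvement surgeries incl. initial
    noi: int
    nor: int
    nop: int
    ep_nhi: float  # surgical-phase years not covered by the capped surgeries
    ep_lts: float
    ep_ttr: float
    care_gap: float  # max(0, ep_nhi)
    successful_years: float  # top - care_gap
    cfi: float  # first surgery
    cfs: float  # further surgeries
    vsb: float  # implantation at end of surgical phase
    cri: float
    cre: float
    apu: float
    tsc: float
    ltc: float


@dataclass(frozen=True)
class Group3Outcome:
    """One group-3 run: hearing-improvement surgeries only."""

    top: int
    nhi: int
    ep_nhi: float
    care_gap: float
    successful_years: float
    cfi: float
    cfs: float
    tsc: float
    ltc: float


def _implant_phase(
    draws: RunDraws, params: ModelParameters, horizon: int, offset: int, tap: int
) -> tuple[int, int, int, float, float, float, float, float]:
    """Re-implantation / revision / upgrade block shared by groups 1 and 2.

    ``horizon`` is the implant-phase length (TOP for group 1, TSB for group
    2); ``offset`` shifts every discount exponent (THI for group 2).
    Returns (noi, nor, nop, ep_lts, ep_ttr, cri, cre, apu_cost).
    """
    d = params.discount_rate
    reimpl_cost = draws.isb + 2 * params.foa
    rev_cost = draws.rev + params.foa

    lts = [max(v, 0.0) for v in draws.lts]
    ttr = [max(v, 0.0) for v in draws.ttr]

    noi, cri, cum = 1, 0.0, 0.0
    for j in range(params.max_reimplantations):
        cum += lts[j]
        if cum < horizon:
            noi += 1
            cri += present_value(reimpl_cost, max(0, _round(offset + cum - 0.5)), d)

    nor, cre, cum = 0, 0.0, 0.0
    for j in range(params.max_revisions):
        cum += ttr[j]
        if cum < horizon:
            nor += 1
            cre += present_value(rev_cost, max(0, _round(offset + cum - 0.5)), d)

    years = upgrade_schedule(tap, horizon, offset, params.max_upgrades)
    apu_cost = sum(present_value(params.apu, y, d) for y in years)

    ep_lts = horizon - sum(lts)
    ep_ttr = horizon - sum(ttr)
    return noi, nor, len(years), ep_lts, ep_ttr, cri, cre, apu_cost


def simulate_group1(draws: RunDraws, params: ModelParameters) -> Group1Outcome:
    """Evaluate the direct-implant pathway for one run."""
    top, afi = compute_top(draws.afia, draws.afib, draws.afic, params.lex, params.mia)
    tap = _round(params.ttua + draws.ttub)
    noi, nor, nop, ep_lts, ep_ttr, cri, cre, apu = _implant_phase(draws, params, top, 0, tap)

    cfi = draws.isb + 3 * params.foa  # discounted at year 0
    tsc = annual_checkup_cost(params.foa, top, params.discount_rate)
    ltc = cfi + cri + cre + apu + tsc
    return Group1Outcome(
        top=top,
        afi=afi,
        tap=tap,
        noi=noi,
        nor=nor,
        nop=nop,
        ep_lts=ep_lts,
        ep_ttr=ep_ttr,
        first_failure_year=event_year(max(draws.lts[0], 0.0)),
        first_revision_year=event_year(max(draws.ttr[0], 0.0)),
        cfi=cfi,
        cri=cri,
        cre=cre,
        apu=apu,
        tsc=tsc,
        ltc=ltc,
    )


def _surgery_block(
    draws: RunDraws, params: ModelParameters, horizon: int, n_max: int
) -> tuple[int, float, float]:
    """Hearing-improvement surgery sequence against an integer ``horizon``.

    Returns (nhi, cfs, ep_nhi) for a cap of ``n_max`` surgeries including
    the initial one.  A further surgery j+1 is counted when the *unrounded*
    cumulative success time stays below the horizon; its cost is charged
    when the condition of the printed equations holds — unrounded for the
    first follow-up, rounded cumulative time for the later ones — at the
    event year of the cumulative time.
    """
    d = params.discount_rate
    dsh = draws.dsh
    nhi, cfs, cum = 1, 0.0, 0.0
    for j in range(1, n_max):
        cum += dsh[j - 1]
        if cum < horizon:
            nhi += 1
        charge = (cum < horizon) if j == 1 else (_round(cum) < horizon)
        if charge:
            cfs += present_value(draws.his[j] + params.foa, event_year(cum), d)
    ep_nhi = horizon - float(np.sum(dsh[:n_max]))
    return nhi, cfs, ep_nhi


def simulate_group2(
    draws: RunDraws, params: ModelParameters, thi_override: int | None = None
) -> Group2Outcome:
    """Evaluate the surgeries-then-implant pathway for one run.

    ``thi_override`` forces the length of the surgical phase (used by the
    treatment-strategy evaluation, where the implant is placed at the time
    of the second intervention); by default THI = min(round(THIt), TOP, cap).
    """
    top, _ = compute_top(draws.afia, draws.afib, draws.afic, params.lex, params.mia)
    cap = int(params.thi_cap)
    if thi_override is None:
        thilb = _round(draws.thit) if _round(draws.thit) < top else top
        thi = thilb if thilb < cap else cap
    else:
        if thi_override < 0:
            raise ValueError("surgical-phase length cannot be negative")
        thi = min(int(thi_override), top, cap)
    tsb = top - thi

    nhi, cfs, ep_nhi = _surgery_block(draws, params, thi, params.max_surgeries_g2)
    cfi = draws.his[0] + 2 * params.foa
    # the implant is charged at the end of the surgical phase unconditionally,
    # even when tsb == 0 (verbatim model behaviour)
    vsb = present_value(draws.isb + 2 * params.foa, thi, params.discount_rate)

    tap = _round(params.ttua + draws.ttub)
    noi, nor, nop, ep_lts, ep_ttr, cri, cre, apu = _implant_phase(draws, params, tsb, thi, tap)

    tsc = annual_checkup_cost(params.foa, top, params.discount_rate)
    ltc = cfi + cfs + vsb + cri + cre + apu + tsc
    care_gap = max(0.0, ep_nhi)
    return Group2Outcome(
        top=top,
        thi=thi,
        tsb=tsb,
        tap=tap,
        nhi=nhi,
        noi=noi,
        nor=nor,
        nop=nop,
        ep_nhi=ep_nhi,
        ep_lts=ep_lts,
        ep_ttr=ep_ttr,
        care_gap=care_gap,
        successful_years=top - care_gap,
        cfi=cfi,
        cfs=cfs,
        vsb=vsb,
        cri=cri,
        cre=cre,
        apu=apu,
        tsc=tsc,
        ltc=ltc,
    )


def simulate_group3(draws: RunDraws, params: ModelParameters) -> Group3Outcome:
    """Evaluate the surgeries-only pathway for one run."""
    top, _ = compute_top(draws.afia, draws.afib, draws.afic, params.lex, params.mia)
    nhi, cfs, ep_nhi = _surgery_block(draws, params, top, params.max_surgeries_g3)
    cfi = draws.his[0] + 2 * params.foa
    tsc = annual_checkup_cost(params.foa, top, params.discount_rate)
    ltc = cfi + cfs + tsc
    care_gap = max(0.0, ep_nhi)
    return Group3Outcome(
        top=top,
        nhi=nhi,
        ep_nhi=ep_nhi,
        care_gap=care_gap,
        successful_years=top - care_gap,
        cfi=cfi,
        cfs=cfs,
        tsc=tsc,
        ltc=ltc,
    )


_SIMULATORS = {"g1": simulate_group1, "g2": simulate_group2, "g3": simulate_group3}


def run_seeds(n: int, seed: int) -> list[np.random.SeedSequence]:
    """Deterministic per-run substreams from one root seed."""
    return np.random.SeedSequence(seed).spawn(n)


def run_cohort(params: ModelParameters, group: str, n: int, seed: int) -> list:
    """Simulate ``n`` independent runs of one treatment group.

    Each run gets its own RNG substream derived from the root seed, so the
    same (params, group, n, seed) always reproduces identical outcomes and
    the same run index sees the same draws in every group.
    """
    if group not in _SIMULATORS:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(_SIMULATORS)}")
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError("number of runs must be a positive integer")
    sim = _SIMULATORS[group]
    out = []
    for child in run_seeds(n, seed):
        rng = np.random.default_rng(child)
        out.append(sim(draw_run(params, rng), params))
    return out


def to_frame(outcomes: list) -> pd.DataFrame:
    """Per-run records as a DataFrame, one row per run, one column per field."""
    if not outcomes:
        raise ValueError("empty cohort")
    cols = [f.name for f in dc_fields(outcomes[0])]
    return pd.DataFrame([asdict(o) for o in outcomes], columns=cols)
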