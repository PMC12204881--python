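"""Literal scalar transcription of the model's printed output equations.

This module re-evaluates every output of the three pathway worksheets as a
direct, cell-by-cell translation of the published equation tables — nested
``if`` expressions, explicit bound-correction columns, spreadsheet rounding —
with no code shared with :mod:`meicost.engine`.  It exists solely as an
independent oracle: the production engine must agree with it to numerical
precision on random runs, which the ``validate`` command and the test suite
check.

The only deviation from a verbatim reading is that discount exponents are
clamped at zero (an event at exactly time 0 would otherwise produce the
exponent ``round(-0.5) = -1``); the engine applies the same convention.
"""

from __future__ import annotations

import math

from .sampling import ModelParameters, RunDraws

__all__ = ["g1_reference", "g2_reference", "g3_reference"]


def _r(x: float) -> int:
    """Spreadsheet ROUND to integer: half away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _ey(x: float) -> int:
    """Discount exponent round(x - 0.5), clamped at zero."""
    return max(0, _r(x - 0.5))


def _top_cascade(d: RunDraws, lex: float, mia: float) -> int:
    top_ub1 = _r(lex - d.afib) if _r(lex - d.afia) > (lex - mia) else _r(lex - d.afia)
    top_ub2 = _r(lex - d.afic) if top_ub1 > 77 else top_ub1
    top_lb1 = _r(lex - d.afib) if top_ub2 < 1 else top_ub2
    top_lb2 = _r(lex - d.afic) if top_lb1 < 1 else top_lb1
    top_lb3 = 1 if top_lb2 < 1 else top_lb2
    return (lex - mia) if top_lb3 > (lex - mia) else top_lb3


def g1_reference(d: RunDraws, p: ModelParameters) -> dict[str, float]:
    """All group-1 worksheet outputs for one run, evaluated literally."""
    LEX, MIA, DIR, FOA, APU = p.lex, p.mia, p.discount_rate, p.foa, p.apu
    ISB, REV = d.isb, d.rev
    TOP = _top_cascade(d, LEX, MIA)
    AFI = LEX - TOP

    LTS1lB = 0 if d.lts[0] < 0 else d.lts[0]
    LTS2lB = 0 if d.lts[1] < 0 else d.lts[1]
    LTS3lB = 0 if d.lts[2] < 0 else d.lts[2]
    EP_LTS_G1 = TOP - LTS1lB - LTS2lB - LTS3lB
    DR_LTS = _ey(LTS1lB)
    NOI_G1 = 1 + (0 if LTS1lB >= TOP else 1) + (0 if (LTS1lB + LTS2lB) >= TOP else 1)

    TTR1uB = 0 if d.ttr[0] < 0 else d.ttr[0]  # the uB columns equal the lB columns
    TTR2uB = 0 if d.ttr[1] < 0 else d.ttr[1]
    TTR3uB = 0 if d.ttr[2] < 0 else d.ttr[2]
    TTR4uB = 0 if d.ttr[3] < 0 else d.ttr[3]
    EP_TTR_G1 = TOP - TTR1uB - TTR2uB - TTR3uB - TTR4uB
    DR_TTR = _ey(TTR1uB)
    NOR_G1 = (
        (0 if TTR1uB >= TOP else 1)
        + (0 if (TTR1uB + TTR2uB) >= TOP else 1)
        + (0 if (TTR1uB + TTR2uB + TTR3uB) >= TOP else 1)
    )

    TAP = _r(p.ttua + d.ttub)
    NOP_G1 = sum(1 if TOP >= k * TAP else 0 for k in range(1, 13))

    G1_CFI = (ISB + 3 * FOA) / (1 + DIR) ** 0
    G1_CRI = (1 if LTS1lB < TOP else 0) * ((ISB + 2 * FOA) / (1 + DIR) ** _ey(LTS1lB)) + (
        1 if (LTS1lB + LTS2lB) < TOP else 0
    ) * ((ISB + 2 * FOA) / (1 + DIR) ** _ey(LTS1lB + LTS2lB))
    G1_CRE = (
        (1 if TTR1uB < TOP else 0) * ((REV + FOA) / (1 + DIR) ** _ey(TTR1uB))
        + (1 if (TTR1uB + TTR2uB) < TOP else 0)
        * ((REV + FOA) / (1 + DIR) ** _ey(TTR1uB + TTR2uB))
        + (1 if (TTR1uB + TTR2uB + TTR3uB) < TOP else 0)
        * ((REV + FOA) / (1 + DIR) ** _ey(TTR1uB + TTR2uB + TTR3uB))
    )
    G1_APU = sum(
        (1 if TOP >= k * TAP else 0) * (APU / (1 + DIR) ** (k * TAP)) for k in range(1, 13)
    )
    if DIR == 0:
        G1_TSC = FOA * (TOP - 1)
    else:
        G1_TSC = FOA * (((1 + DIR) ** (TOP - 1)) - 1) / (((1 + DIR) ** (TOP - 1)) * DIR)
    G1_LTC = G1_CFI + G1_CRI + G1_CRE + G1_APU + G1_TSC
    return {
        "TOP": TOP,
        "AFI": AFI,
        "EP_LTS_G1": EP_LTS_G1,
        "DR_LTS": DR_LTS,
        "NOI_G1": NOI_G1,
        "EP_TTR_G1": EP_TTR_G1,
        "DR_TTR": DR_TTR,
        "NOR_G1": NOR_G1,
        "TAP": TAP,
        "NOP_G1": NOP_G1,
        "G1_CFI": G1_CFI,
        "G1_CRI": G1_CRI,
        "G1_CRE": G1_CRE,
        "G1_APU": G1_APU,
        "G1_TSC": G1_TSC,
        "G1_LTC": G1_LTC,
    }


def g2_reference(d: RunDraws, p: ModelParameters) -> dict[str, float]:
    """All group-2 worksheet outputs for one run, evaluated literally."""
    LEX, MIA, DIR, FOA, APU = p.lex, p.mia, p.discount_rate, p.foa, p.apu
    ISB, REV = d.isb, d.rev
    TOP = _top_cascade(d, LEX, MIA)

    THIlB = _r(d.thit) if _r(d.thit) < TOP else TOP
    THI = THIlB if THIlB < 25 else 25
    TSB = TOP - THI

    DSH = list(d.dsh)
    HIS = list(d.his)
    c1 = DSH[0]
    c2 = c1 + DSH[1]
    c3 = c2 + DSH[2]
    c4 = c3 + DSH[3]
    c5 = c4 + DSH[4]
    NHI_G2 = (
        1
        + (1 if c1 < THI else 0)
        + (1 if c2 < THI else 0)
        + (1 if c3 < THI else 0)
        + (1 if c4 < THI else 0)
        + (1 if c5 < THI else 0)
    )
    EP_NHI_G2 = THI - DSH[0] - DSH[1] - DSH[2] - DSH[3] - DSH[4] - DSH[5]

    G2_CFI = (HIS[0] + 2 * FOA) / (1 + DIR) ** 0
    # the first follow-up surgery's condition uses the unrounded cumulative
    # time; the later ones round it first (verbatim)
    G2_CFS = (
        (1 if c1 < THI else 0) * ((HIS[1] + FOA) / (1 + DIR) ** _ey(c1))
        + (1 if _r(c2) < THI else 0) * ((HIS[2] + FOA) / (1 + DIR) ** _ey(c2))
        + (1 if _r(c3) < THI else 0) * ((HIS[3] + FOA) / (1 + DIR) ** _ey(c3))
        + (1 if _r(c4) < THI else 0) * ((HIS[4] + FOA) / (1 + DIR) ** _ey(c4))
        + (1 if _r(c5) < THI else 0) * ((HIS[5] + FOA) / (1 + DIR) ** _ey(c5))
    )
    G2_VSB = (ISB + 2 * FOA) / (1 + DIR) ** THI

    LTS1lB = 0 if d.lts[0] < 0 else d.lts[0]
    LTS2lB = 0 if d.lts[1] < 0 else d.lts[1]
    LTS3lB = 0 if d.lts[2] < 0 else d.lts[2]
    TTR1uB = 0 if d.ttr[0] < 0 else d.ttr[0]
    TTR2uB = 0 if d.ttr[1] < 0 else d.ttr[1]
    TTR3uB = 0 if d.ttr[2] < 0 else d.ttr[2]
    TTR4uB = 0 if d.ttr[3] < 0 else d.ttr[3]

    G2_CRI = (1 if LTS1lB < TSB else 0) * (
        (ISB + 2 * FOA) / (1 + DIR) ** max(0, _r(THI + LTS1lB - 0.5))
    ) + (1 if (LTS1lB + LTS2lB) < TSB else 0) * (
        (ISB + 2 * FOA) / (1 + DIR) ** max(0, _r(THI + LTS1lB + LTS2lB - 0.5))
    )
    NOI_G2 = 1 + (0 if LTS1lB >= TSB else 1) + (0 if (LTS1lB + LTS2lB) >= TSB else 1)
    G2_CRE = (
        (1 if TTR1uB < TSB else 0) * ((REV + FOA) / (1 + DIR) ** max(0, _r(THI + TTR1uB - 0.5)))
        + (1 if (TTR1uB + TTR2uB) < TSB else 0)
        * ((REV + FOA) / (1 + DIR) ** max(0, _r(THI + TTR1uB + TTR2uB - 0.5)))
        + (1 if (TTR1uB + TTR2uB + TTR3uB) < TSB else 0)
        * ((REV + FOA) / (1 + DIR) ** max(0, _r(THI + TTR1uB + TTR2uB + TTR3uB - 0.5)))
    )
    NOR_G2 = (
        (0 if TTR1uB >= TSB else 1)
        + (0 if (TTR1uB + TTR2uB) >= TSB else 1)
        + (0 if (TTR1uB + TTR2uB + TTR3uB) >= TSB else 1)
    )
    if DIR == 0:
        G2_TSC = FOA * (TOP - 1)
    else:
        G2_TSC = FOA * (((1 + DIR) ** (TOP - 1)) - 1) / (((1 + DIR) ** (TOP - 1)) * DIR)
    TAP = _r(p.ttua + d.ttub)
    G2_APU = sum(
        (1 if TSB >= k * TAP else 0) * (APU / (1 + DIR) ** (k * TAP + THI)) for k in range(1, 13)
    )
    NOP_G2 = sum(1 if TSB >= k * TAP else 0 for k in range(1, 13))
    G2_LTC = G2_CFI + G2_CFS + G2_VSB + G2_CRI + G2_CRE + G2_APU + G2_TSC
    EP_LTS_G2 = TSB - LTS1lB - LTS2lB - LTS3lB
    EP_TTR_G2 = TSB - TTR1uB - TTR2uB - TTR3uB - TTR4uB
    return {
        "TOP": TOP,
        "THI": THI,
        "TSB": TSB,
        "NHI_G2": NHI_G2,
        "EP_NHI_G2": EP_NHI_G2,
        "G2_CFI": G2_CFI,
        "G2_CFS": G2_CFS,
        "G2_VSB": G2_VSB,
        "G2_CRI": G2_CRI,
        "NOI_G2": NOI_G2,
        "G2_CRE": G2_CRE,
        "NOR_G2": NOR_G2,
        "G2_TSC": G2_TSC,
        "G2_APU": G2_APU,
        "NOP_G2": NOP_G2,
        "G2_LTC": G2_LTC,
        "EP_LTS_G2": EP_LTS_G2,
        "EP_TTR_G2": EP_TTR_G2,
    }


def g3_reference(d: RunDraws, p: ModelParameters) -> dict[str, float]:
    """All group-3 worksheet outputs for one run, evaluated literally."""
    LEX, MIA, DIR, FOA = p.lex, p.mia, p.discount_rate, p.foa
    TOP = _top_cascade(d, LEX, MIA)
    DSH = list(d.dsh)
    HIS = list(d.his)
    cum = [DSH[0]]
    for j in range(1, 15):
        cum.append(cum[-1] + DSH[j])

    G3_CFI = (HIS[0] + 2 * FOA) / (1 + DIR) ** 0
    G3_CFS = (1 if cum[0] < TOP else 0) * ((HIS[1] + FOA) / (1 + DIR) ** _ey(cum[0]))
    for j in range(1, 14):  # follow-up surgeries 3..15: rounded condition
        G3_CFS += (1 if _r(cum[j]) < TOP else 0) * (
            (HIS[j + 1] + FOA) / (1 + DIR) ** _ey(cum[j])
        )
    if DIR == 0:
        G3_TSC = FOA * (TOP - 1)
    else:
        G3_TSC = FOA * (((1 + DIR) ** (TOP - 1)) - 1) / (((1 + DIR) ** (TOP - 1)) * DIR)
    EP_NHI_G3 = TOP - sum(DSH[:15])
    G3_LTC = G3_CFI + G3_CFS + G3_TSC
    NHI_G3 = 1 + sum(1 if cum[j] < TOP else 0 for j in range(14))
    return {
        "TOP": TOP,
        "G3_CFI": G3_CFI,
        "G3_CFS": G3_CFS,
        "G3_TSC": G3_TSC,
        "EP_NHI_G3": EP_NHI_G3,
        "G3_LTC": G3_LTC,
        "NHI_G3": NHI_G3,
    }
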