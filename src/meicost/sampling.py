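"""Input distributions and per-run random draws for the lifetime-cost model.

This module is the synthetic-data generator of the whole pipeline: every
stochastic input of the simulation (patient age at first intervention,
implant/surgery costs, device lifetimes, revision intervals, surgery success
durations, ...) is drawn here from the published, pre-fitted distribution
families.  Five families occur:

``fixed``
    a degenerate point mass (flat rates, life expectancy, discount rate),
``weibull3``
    three-parameter Weibull, ``threshold + scale * W(shape)`` with ``W`` a
    standard Weibull variate,
``lognormal``
    ``exp(location + scale * Z)`` with ``Z`` standard normal,
``triangular``
    the usual (lower, mode, upper) triangle — note the device-lifetime and
    revision-interval triangles have a lower bound of -3 years and are *not*
    truncated at sampling time; negative draws are floored downstream by the
    model equations,
``exponential_shifted``
    ``shift + Exp(rate)``.

Sampling is inverse-CDF based: each variate is ``ppf(u)`` of one uniform from
a per-run :class:`numpy.random.Generator` substream, so a cohort is fully
reproducible from a single root seed regardless of vectorization order.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import gamma as _gamma
from scipy.special import ndtri

__all__ = [
    "DistributionSpec",
    "ModelParameters",
    "RunDraws",
    "sample_value",
    "draw_run",
    "theoretical_moments",
    "load_parameters",
    "default_parameters",
]

Family = Literal["fixed", "weibull3", "lognormal", "triangular", "exponential_shifted"]

_REQUIRED_PARAMS: dict[str, tuple[str, ...]] = {
    "fixed": ("value",),
    "weibull3": ("shape", "scale", "threshold"),
    "lognormal": ("location", "scale"),
    "triangular": ("lower", "mode", "upper"),
    "exponential_shifted": ("rate", "shift"),
}


class DistributionSpec(BaseModel):
    """One named input distribution: a family plus its parameters."""

    model_config = ConfigDict(frozen=True)

    family: Family
    params: dict[str, float]

    @model_validator(mode="after")
    def _check_params(self) -> "DistributionSpec":
        required = _REQUIRED_PARAMS[self.family]
        missing = set(required) - set(self.params)
        extra = set(self.params) - set(required)
        if missing or extra:
            raise ValueError(
                f"{self.family} distribution needs exactly {required}; "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        p = self.params
        if self.family == "weibull3":
            if p["shape"] <= 0 or p["scale"] <= 0:
                raise ValueError("weibull3 requires shape > 0 and scale > 0")
        elif self.family == "lognormal":
            if p["scale"] <= 0:
                raise ValueError("lognormal requires scale > 0")
        elif self.family == "triangular":
            if not (p["lower"] <= p["mode"] <= p["upper"]) or p["lower"] >= p["upper"]:
                raise ValueError("triangular requires lower <= mode <= upper, lower < upper")
        elif self.family == "exponential_shifted":
            if p["rate"] <= 0:
                raise ValueError("exponential_shifted requires rate > 0")
        return self

    # -- inverse CDF ------------------------------------------------------

    def ppf(self, q):
        """Quantile function, vectorized over ``q`` in [0, 1)."""
        q = np.asarray(q, dtype=float)
        p = self.params
        if self.family == "fixed":
            out = np.full_like(q, p["value"])
        elif self.family == "weibull3":
            out = p["threshold"] + p["scale"] * (-np.log1p(-q)) ** (1.0 / p["shape"])
        elif self.family == "lognormal":
            out = np.exp(p["location"] + p["scale"] * ndtri(q))
        elif self.family == "triangular":
            a, m, b = p["lower"], p["mode"], p["upper"]
            fc = (m - a) / (b - a)
            left = a + np.sqrt(np.clip(q, 0, 1) * (b - a) * (m - a))
            right = b - np.sqrt((1 - q) * (b - a) * (b - m))
            out = np.where(q < fc, left, right)
        else:  # exponential_shifted
            out = p["shift"] - np.log1p(-q) / p["rate"]
        return float(out) if out.ndim == 0 else out


def sample_value(spec: DistributionSpec, rng: np.random.Generator, size=None):
    """Draw one variate (or ``size`` variates) from ``spec``.

    The fixed family still consumes one uniform per variate so that the
    position of every other symbol in the stream does not depend on which
    inputs are degenerate.
    """
    return spec.ppf(rng.random(size))


def theoretical_moments(spec: DistributionSpec) -> tuple[float, float]:
    """Closed-form (mean, sd) of a distribution spec.

    Serves as the independent oracle for the sampler in validation checks.
    """
    p = spec.params
    if spec.family == "fixed":
        return p["value"], 0.0
    if spec.family == "weibull3":
        k, sc, thr = p["shape"], p["scale"], p["threshold"]
        g1 = _gamma(1 + 1 / k)
        g2 = _gamma(1 + 2 / k)
        return thr + sc * g1, sc * math.sqrt(g2 - g1**2)
    if spec.family == "lognormal":
        mu, sig = p["location"], p["scale"]
        mean = math.exp(mu + sig**2 / 2)
        var = (math.exp(sig**2) - 1) * math.exp(2 * mu + sig**2)
        return mean, math.sqrt(var)
    if spec.family == "triangular":
        a, m, b = p["lower"], p["mode"], p["upper"]
        mean = (a + m + b) / 3
        var = (a**2 + m**2 + b**2 - a * m - a * b - m * b) / 18
        return mean, math.sqrt(var)
    # exponential_shifted
    return p["shift"] + 1 / p["rate"], 1 / p["rate"]


class ModelParameters(BaseModel):
    """Complete input parameter set of the simulation model.

    Scalars are the fixed model inputs (life expectancy LEX, minimum
    implantation age MIA, discount rate, outpatient flat rate FOA, audio
    processor price APU, minimum upgrade interval TTUa); the
    :class:`DistributionSpec` fields are the stochastic inputs; the caps
    bound the number of events of each kind a run may accumulate.
    """

    model_config = ConfigDict(frozen=True)

    lex: float = Field(description="life expectancy, years")
    mia: float = Field(description="minimum implantation age, years")
    discount_rate: float = Field(ge=0, description="annual discount rate (DIR)")
    foa: float = Field(ge=0, description="flat-rate outpatient appointment, EUR")
    apu: float = Field(ge=0, description="audio processor price, EUR")
    ttua: float = Field(ge=0, description="minimum time to processor upgrade, years")

    afi: DistributionSpec  # age at first intervention (3 i.i.d. draws per run)
    isb: DistributionSpec  # implantation cost
    lts: DistributionSpec  # implant lifetime
    ttr: DistributionSpec  # time to revision
    rev: DistributionSpec  # revision cost
    ttub: DistributionSpec  # additional time to upgrade beyond ttua
    thit: DistributionSpec  # total time under surgical management (group 2)
    dsh: DistributionSpec  # duration of success of one hearing-improvement surgery
    his: DistributionSpec  # hearing-improvement surgery cost

    max_reimplantations: int = Field(gt=0)
    max_revisions: int = Field(gt=0)
    max_upgrades: int = Field(gt=0)
    max_surgeries_g2: int = Field(gt=0, description="incl. initial surgery")
    max_surgeries_g3: int = Field(gt=0, description="incl. initial surgery")
    thi_cap: float = Field(gt=0, description="max years under surgical management, group 2")

    independent_event_costs: bool = False  # stub: per-event cost draws not modelled

    @model_validator(mode="after")
    def _check(self) -> "ModelParameters":
        if self.lex <= self.mia:
            raise ValueError("life expectancy must exceed minimum implantation age")
        if self.max_surgeries_g2 > self.max_surgeries_g3:
            raise ValueError("group-2 surgery cap cannot exceed the group-3 cap")
        return self

    @property
    def parameter_hash(self) -> str:
        """Stable hash of the full parameter set, for logs and provenance."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunDraws:
    """The raw random draws of one simulation run, one value per symbol.

    ``isb`` and ``rev`` are single draws reused for every re-implantation /
    revision of the run (the model equations reuse those symbols); ``lts``,
    ``ttr``, ``dsh`` and ``his`` hold the per-event sequences.
    """

    afia: float
    afib: float
    afic: float
    isb: float
    rev: float
    lts: np.ndarray  # max_reimplantations + 1 values
    ttr: np.ndarray  # max_revisions + 1 values
    ttub: float
    thit: float
    dsh: np.ndarray  # max_surgeries_g3 values
    his: np.ndarray  # max_surgeries_g3 values


def draw_run(params: ModelParameters, rng: np.random.Generator) -> RunDraws:
    """Draw every stochastic symbol of one run, in a fixed documented order.

    Order: AFIa, AFIb, AFIc, ISB, REV, LTS1..n, TTR1..n, TTUb, THIt,
    DSH1..n, HIS1..n.  All draws are mutually independent.
    """
    if params.independent_event_costs:
        raise NotImplementedError(
            "per-event independent cost draws are a configuration stub; "
            "the model reuses one ISB and one REV draw per run"
        )
    return RunDraws(
        afia=sample_value(params.afi, rng),
        afib=sample_value(params.afi, rng),
        afic=sample_value(params.afi, rng),
        isb=sample_value(params.isb, rng),
        rev=sample_value(params.rev, rng),
        lts=sample_value(params.lts, rng, size=params.max_reimplantations + 1),
        ttr=sample_value(params.ttr, rng, size=params.max_revisions + 1),
        ttub=sample_value(params.ttub, rng),
        thit=sample_value(params.thit, rng),
        dsh=sample_value(params.dsh, rng, size=params.max_surgeries_g3),
        his=sample_value(params.his, rng, size=params.max_surgeries_g3),
    )


def load_parameters(path) -> ModelParameters:
    """Load and validate a YAML/JSON parameter file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return ModelParameters.model_validate(data)


def default_parameters() -> ModelParameters:
    """The packaged default parameter set (the published model inputs)."""
    text = resources.files("meicost").joinpath("data/default_params.yaml").read_text()
    return ModelParameters.model_validate(yaml.safe_load(text))
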