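"""Parametric sigmoidal growth models and their analytic inflection points.

Five classical families used to describe body weight of broiler chickens as a
function of age: logistic, Gompertz, Weibull, Hossfeld and von Bertalanffy.
Units are fixed package-wide: age in weeks, weight in grams; any conversion is
the caller's job.

Each family is a closed-form curve ``Y(t)`` rising from a hatch weight toward
an asymptotic mature weight ``A``, with an inflection point (IPT, IPW) where
the weekly gain is maximal:

=================  =============================  ==========================
family             Y(t)                           inflection (IPT, IPW)
=================  =============================  ==========================
logistic           A / (1 + b e^{-kt})            (ln b / k,  A/2)
gompertz           A exp(-b e^{-kt})              (ln b / k,  A/e)
weibull            A - b e^{-k t^lam}             ([(lam-1)/(k lam)]^{1/lam},
                                                   A - b e^{-(1-1/lam)})
hossfeld           A (1 + b1 t^{-b2})^{-1}        ([b1(b2-1)/(b2+1)]^{1/b2},
                                                   A (b2-1)/(2 b2))
von_bertalanffy    A (1 - b e^{-kt})^3            (ln(3b)/k,  8A/27)
=================  =============================  ==========================
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "ModelFamily",
    "FAMILY_ORDER",
    "ModelParameters",
    "InflectionPoint",
    "ParameterDomainError",
    "NoInflectionError",
    "evaluate",
    "inflection",
    "predict_curve",
]


class ParameterDomainError(ValueError):
    """A parameter lies outside the domain where the model is a growth curve."""


class NoInflectionError(ValueError):
    """The parameter values admit no inflection point (e.g. Weibull lam <= 1)."""


class ModelFamily(str, enum.Enum):
    """The five supported growth-curve families."""

    LOGISTIC = "logistic"
    GOMPERTZ = "gompertz"
    WEIBULL = "weibull"
    HOSSFELD = "hossfeld"
    VON_BERTALANFFY = "von_bertalanffy"

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self]

    @property
    def n_params(self) -> int:
        return len(_PARAM_NAMES[self])


_PARAM_NAMES: dict[ModelFamily, tuple[str, ...]] = {
    ModelFamily.LOGISTIC: ("A", "b", "k"),
    ModelFamily.GOMPERTZ: ("A", "b", "k"),
    ModelFamily.WEIBULL: ("A", "b", "k", "lam"),
    ModelFamily.HOSSFELD: ("A", "b1", "b2"),
    ModelFamily.VON_BERTALANFFY: ("A", "b", "k"),
}

#: Fixed reporting order used everywhere a "per family" table is produced.
FAMILY_ORDER: tuple[ModelFamily, ...] = (
    ModelFamily.LOGISTIC,
    ModelFamily.GOMPERTZ,
    ModelFamily.WEIBULL,
    ModelFamily.HOSSFELD,
    ModelFamily.VON_BERTALANFFY,
)


@dataclass(frozen=True)
class InflectionPoint:
    """Age (weeks) and weight (g) at which the growth rate is maximal."""

    ipt: float
    ipw: float


@dataclass(frozen=True)
class ModelParameters:
    """Named parameter vector for one growth-model family.

    Only the fields defined for the family may be set:

    * ``A`` — asymptotic (mature) weight, g; all families.
    * ``b`` — initial-size parameter; dimensionless except Weibull, where it
      is the weight deficit ``A - Y(0)`` in grams.
    * ``k`` — rate constant, per week.
    * ``lam`` — Weibull shape parameter (dimensionless).
    * ``b1``, ``b2`` — Hossfeld shape parameters (dimensionless; ``b1 > 1``).
    """

    family: ModelFamily
    A: float
    b: Optional[float] = None
    k: Optional[float] = None
    lam: Optional[float] = None
    b1: Optional[float] = None
    b2: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", ModelFamily(self.family))
        needed = set(self.family.param_names)
        for name in ("A", "b", "k", "lam", "b1", "b2"):
            value = getattr(self, name)
            if name in needed:
                if value is None:
                    raise ParameterDomainError(
                        f"{self.family.value} requires parameter {name!r}"
                    )
                if not math.isfinite(value):
                    raise ParameterDomainError(f"{name} must be finite, got {value}")
            elif value is not None:
                raise ParameterDomainError(
                    f"{self.family.value} does not define parameter {name!r}"
                )
        if self.A <= 0:
            raise ParameterDomainError(f"A must be positive, got {self.A}")
        for name in ("b", "k", "lam"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ParameterDomainError(f"{name} must be positive, got {value}")
        if self.family is ModelFamily.VON_BERTALANFFY and not self.b < 1:
            # b >= 1 would make the curve nonpositive at hatch.
            raise ParameterDomainError(
                f"von_bertalanffy requires 0 < b < 1, got b={self.b}"
            )
        if self.family is ModelFamily.HOSSFELD:
            if not self.b1 > 1:
                raise ParameterDomainError(f"hossfeld requires b1 > 1, got {self.b1}")
            if not self.b2 > 0:
                raise ParameterDomainError(f"hossfeld requires b2 > 0, got {self.b2}")

    # -- array/dict plumbing -------------------------------------------------

    def as_array(self) -> np.ndarray:
        """Parameter values as a vector in the family's canonical order."""
        return np.array([getattr(self, n) for n in self.family.param_names])

    @classmethod
    def from_array(cls, family: ModelFamily, values: Iterable[float]) -> "ModelParameters":
        family = ModelFamily(family)
        values = list(values)
        if len(values) != family.n_params:
            raise ParameterDomainError(
                f"{family.value} takes {family.n_params} parameters, got {len(values)}"
            )
        return cls(family=family, **dict(zip(family.param_names, map(float, values))))

    def to_dict(self) -> dict:
        """Flat JSON-ready mapping: family name plus named parameters."""
        out: dict = {"family": self.family.value}
        out.update({n: float(getattr(self, n)) for n in self.family.param_names})
        return out

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ModelParameters":
        family = ModelFamily(doc["family"])
        return cls(family=family, **{n: float(doc[n]) for n in family.param_names})


def evaluate(params: ModelParameters, age):
    """Predicted weight (g) at ``age`` (weeks, scalar or array, >= 0).

    The published equation typography is ambiguous in several places; the
    forms implemented here are the unique readings consistent with the
    model's own printed weekly predictions:

    * logistic is ``A / (1 + b e^{-kt})`` (division, not multiplication):
      at age 0 the printed prediction equals ``A / (1 + b)``;
    * weibull is ``A - b e^{-k t^lam}``: the printed age-0 prediction equals
      ``A - b``;
    * hossfeld is ``A (1 + b1 t^{-b2})^{-1}``;
    * von Bertalanffy uses ``e^{-kt}`` (a ``+kt`` exponent would decay away
      from ``A`` instead of growing toward it).
    """
    t = np.asarray(age, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative (weeks)")
    fam = params.family
    if fam is ModelFamily.LOGISTIC:
        out = params.A / (1.0 + params.b * np.exp(-params.k * t))
    elif fam is ModelFamily.GOMPERTZ:
        out = params.A * np.exp(-params.b * np.exp(-params.k * t))
    elif fam is ModelFamily.WEIBULL:
        out = params.A - params.b * np.exp(-params.k * t**params.lam)
    elif fam is ModelFamily.HOSSFELD:
        # t^(-b2) diverges at t = 0; the curve's limit there is 0, used by
        # continuity so week-0 records are representable.
        with np.errstate(divide="ignore"):
            out = np.where(
                t > 0, params.A / (1.0 + params.b1 * t ** -np.float64(params.b2)), 0.0
            )
    elif fam is ModelFamily.VON_BERTALANFFY:
        out = params.A * (1.0 - params.b * np.exp(-params.k * t)) ** 3
    else:  # pragma: no cover
        raise AssertionError(fam)
    return out if np.ndim(age) else float(out)


def inflection(params: ModelParameters) -> InflectionPoint:
    """Analytic inflection point of the growth curve.

    Raises
    ------
    NoInflectionError
        If the parameters admit no inflection: Weibull with ``lam <= 1``,
        Hossfeld with ``b2 <= 1``.
    """
    fam = params.family
    if fam is ModelFamily.LOGISTIC:
        return InflectionPoint(math.log(params.b) / params.k, params.A / 2.0)
    if fam is ModelFamily.GOMPERTZ:
        return InflectionPoint(math.log(params.b) / params.k, params.A / math.e)
    if fam is ModelFamily.WEIBULL:
        if params.lam <= 1:
            raise NoInflectionError(f"weibull needs lam > 1, got lam={params.lam}")
        ipt = ((params.lam - 1.0) / (params.k * params.lam)) ** (1.0 / params.lam)
        ipw = params.A - params.b * math.exp(-(1.0 - 1.0 / params.lam))
        return InflectionPoint(ipt, ipw)
    if fam is ModelFamily.HOSSFELD:
        if params.b2 <= 1:
            raise NoInflectionError(f"hossfeld needs b2 > 1, got b2={params.b2}")
        # The published inflection-time expression is typeset unreadably; the
        # reading below reproduces the printed value to 3 decimals and is the
        # age where the curve's second derivative vanishes.
        ipt = (params.b1 * (params.b2 - 1.0) / (params.b2 + 1.0)) ** (1.0 / params.b2)
        ipw = params.A * (params.b2 - 1.0) / (2.0 * params.b2)
        return InflectionPoint(ipt, ipw)
    if fam is ModelFamily.VON_BERTALANFFY:
        ipt = math.log(3.0 * params.b) / params.k
        return InflectionPoint(ipt, 8.0 * params.A / 27.0)
    raise AssertionError(fam)  # pragma: no cover


def predict_curve(params: ModelParameters, ages: Iterable[float]) -> np.ndarray:
    """Vectorized :func:`evaluate` over a sorted list of ages (weeks)."""
    ages = np.asarray(list(ages), dtype=float)
    if ages.size == 0:
        return ages
    return np.asarray(evaluate(params, ages), dtype=float)
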