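"""Nonlinear least-squares estimation of growth-curve parameters.

Fits any of the five families to long-format age-weight records by trust
region reflective least squares (:func:`scipy.optimize.least_squares`) with
deterministic, data-driven starting values and a seeded multi-start fallback:
Weibull and Hossfeld in particular have flat, strongly correlated likelihoods
on as few as seven weekly means, and a single start can stall on a ridge.

The loss is unweighted ordinary least squares on weights in grams; relative
(weight-proportional) residuals can be requested for heteroscedastic data but
are off by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .goodness_of_fit import GofStats, compute_criteria
from .growth_models import (
    FAMILY_ORDER,
    InflectionPoint,
    ModelFamily,
    ModelParameters,
    NoInflectionError,
    evaluate,
    inflection,
)

__all__ = [
    "GrowthRecord",
    "GrowthDataset",
    "FitConfig",
    "FitResult",
    "InsufficientDataError",
    "NonConvergenceError",
    "initial_values",
    "fit",
    "fit_all",
]


class InsufficientDataError(ValueError):
    """Too few (or degenerate) observations to identify the parameters."""


class NonConvergenceError(RuntimeError):
    """No optimizer start converged; ``best_attempt`` holds the least-bad one."""

    def __init__(self, message: str, best_attempt: Optional["FitResult"] = None):
        super().__init__(message)
        self.best_attempt = best_attempt


class GrowthRecord(NamedTuple):
    """One weighing: optional subject id, age in weeks, body weight in grams."""

    bird_id: Optional[str]
    age_weeks: float
    weight_g: float


@dataclass(frozen=True)
class GrowthDataset:
    """Long-format collection of weighings, the unit of fitting."""

    records: tuple
    label: str = ""

    def __post_init__(self) -> None:
        recs = tuple(
            r if isinstance(r, GrowthRecord) else GrowthRecord(*r) for r in self.records
        )
        for r in recs:
            if r.age_weeks < 0:
                raise ValueError(f"negative age in record {r}")
            if r.weight_g <= 0:
                raise ValueError(f"nonpositive weight in record {r}")
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.age_weeks for r in self.records], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight_g for r in self.records], dtype=float)

    @property
    def n_distinct_ages(self) -> int:
        return np.unique(self.ages).size

    @classmethod
    def from_arrays(
        cls,
        ages: Sequence[float],
        weights: Sequence[float],
        ids: Optional[Sequence] = None,
        label: str = "",
    ) -> "GrowthDataset":
        ids = [None] * len(list(ages)) if ids is None else list(ids)
        return cls(
            records=tuple(
                GrowthRecord(i, float(a), float(w)) for i, a, w in zip(ids, ages, weights)
            ),
            label=label,
        )

    @classmethod
    def from_csv(cls, path, label: Optional[str] = None) -> "GrowthDataset":
        """Read the package CSV dialect: header with ``age_weeks``, ``weight_g``
        and an optional leading ``id`` column; comma separated, '.' decimals."""
        try:
            df = pd.read_csv(path)
        except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
            raise ValueError(f"malformed CSV {path}: {exc}") from exc
        missing = {"age_weeks", "weight_g"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
        ids = df["id"].astype(str).tolist() if "id" in df.columns else None
        return cls.from_arrays(
            df["age_weeks"].to_numpy(float),
            df["weight_g"].to_numpy(float),
            ids=ids,
            label=str(path) if label is None else label,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "id": [r.bird_id for r in self.records],
                "age_weeks": self.ages,
                "weight_g": self.weights,
            }
        )
        if df["id"].isna().all():
            df = df.drop(columns="id")
        df.to_csv(path, index=False)

    def validate_for_fitting(self, family: ModelFamily) -> None:
        if self.n_distinct_ages < family.n_params + 1:
            raise InsufficientDataError(
                f"{family.value} needs at least {family.n_params + 1} distinct ages, "
                f"dataset has {self.n_distinct_ages}"
            )
        if np.ptp(self.weights) == 0.0:
            raise InsufficientDataError("all weights identical; no growth signal to fit")


@dataclass(frozen=True)
class FitConfig:
    """Optimizer options. ``ftol``/``gtol`` are scipy's relative-cost-change and
    gradient-norm stopping tolerances; ``n_starts`` counts the seeded random
    perturbations tried in addition to the deterministic start."""

    max_iter: int = 500
    ftol: float = 1e-10
    gtol: float = 1e-8
    n_starts: int = 8
    seed: int = 0
    perturb_factor: float = 3.0
    relative_residuals: bool = False


@dataclass(frozen=True)
class FitResult:
    """One family fitted to one dataset."""

    family: ModelFamily
    params: Optional[ModelParameters]
    predictions: Optional[np.ndarray]
    gof: Optional[GofStats]
    inflection: Optional[InflectionPoint]
    converged: bool
    n_starts_used: int
    gradient_norm: float = math.nan
    sse_initial: float = math.nan
    error: Optional[str] = None
    label: str = field(default="", compare=False)

    @property
    def ok(self) -> bool:
        return self.error is None

    def to_dict(self) -> dict:
        doc: dict = {"family": self.family.value, "label": self.label}
        if self.params is not None:
            doc["parameters"] = self.params.to_dict()
            doc["predictions"] = [float(p) for p in self.predictions]
        if self.gof is not None:
            doc["gof"] = self.gof.to_dict()
        doc["inflection"] = (
            None
            if self.inflection is None
            else {"ipt": self.inflection.ipt, "ipw": self.inflection.ipw}
        )
        doc["convergence"] = {
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "gradient_norm": self.gradient_norm,
            "sse_initial": self.sse_initial,
            "error": self.error,
        }
        return doc

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# -- initialization ---------------------------------------------------------


def _loglin_slope(t: np.ndarray, z: np.ndarray) -> Optional[float]:
    """Least-squares slope of z on t; None when degenerate."""
    good = np.isfinite(z)
    if good.sum() < 2 or np.ptp(t[good]) == 0:
        return None
    slope = np.polyfit(t[good], z[good], 1)[0]
    return float(slope) if math.isfinite(slope) else None


def initial_values(family: ModelFamily, data: GrowthDataset) -> ModelParameters:
    """Deterministic data-driven starting point.

    ``A0 = 1.2 x max(weight)``; the initial-size parameter comes from the
    earliest observation; rate constants come from the family's
    log-linearization evaluated on per-age mean weights; shape parameters
    start at fixed textbook values (``lam0 = 2``, ``b1_0 = 10``, ``b2_0 = 2``).
    """
    family = ModelFamily(family)
    data.validate_for_fitting(family)
    # Per-age means: robust to many birds per age, identical for means data.
    df = pd.DataFrame({"t": data.ages, "y": data.weights}).groupby("t")["y"].mean()
    t, y = df.index.to_numpy(), df.to_numpy()
    a0 = 1.2 * float(data.weights.max())
    y0 = float(y[0])
    frac = np.clip(y / a0, 1e-12, 1 - 1e-12)

    if family is ModelFamily.LOGISTIC:
        b0 = max(a0 / y0 - 1.0, 1e-6)
        slope = _loglin_slope(t, np.log(1.0 / frac - 1.0))
        k0 = -slope if slope is not None else 0.5
        return ModelParameters(family, A=a0, b=b0, k=float(np.clip(k0, 1e-5, 9.9)))
    if family is ModelFamily.GOMPERTZ:
        b0 = max(-math.log(y0 / a0), 1e-6)
        slope = _loglin_slope(t, np.log(-np.log(frac)))
        k0 = -slope if slope is not None else 0.3
        return ModelParameters(family, A=a0, b=b0, k=float(np.clip(k0, 1e-5, 9.9)))
    if family is ModelFamily.WEIBULL:
        b0 = max(a0 - y0, 1e-6)
        lam0 = 2.0
        pos = t > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            z = -np.log(np.clip((a0 - y) / b0, 1e-12, None))
        k0 = float(np.median(z[pos] / t[pos] ** lam0)) if pos.any() else 0.1
        return ModelParameters(
            family, A=a0, b=b0, k=float(np.clip(k0, 1e-5, 9.9)), lam=lam0
        )
    if family is ModelFamily.HOSSFELD:
        return ModelParameters(family, A=a0, b1=10.0, b2=2.0)
    if family is ModelFamily.VON_BERTALANFFY:
        b0 = float(np.clip(1.0 - (y0 / a0) ** (1.0 / 3.0), 1e-6, 1 - 1e-6))
        slope = _loglin_slope(t, np.log(1.0 - frac ** (1.0 / 3.0)))
        k0 = -slope if slope is not None else 0.3
        return ModelParameters(family, A=a0, b=b0, k=float(np.clip(k0, 1e-5, 9.9)))
    raise AssertionError(family)  # pragma: no cover


def _bounds(family: ModelFamily, max_w: float) -> tuple[np.ndarray, np.ndarray]:
    """Box constraints keeping every family's curve a growth curve with a
    defined inflection formula (lam > 1, b2 > 1)."""
    per_param = {
        "A": (max_w, 50.0 * max_w),
        "k": (1e-6, 10.0),
        "lam": (1.0 + 1e-3, 10.0),
        "b1": (1.0 + 1e-3, 1e6),
        "b2": (1.0 + 1e-3, 10.0),
    }
    b_range = {
        ModelFamily.LOGISTIC: (1e-6, 1e6),
        ModelFamily.GOMPERTZ: (1e-6, 1e3),
        ModelFamily.WEIBULL: (1e-6, 50.0 * max_w),
        ModelFamily.VON_BERTALANFFY: (1e-6, 1.0 - 1e-6),
    }
    lo, hi = [], []
    for name in family.param_names:
        lo_i, hi_i = b_range[family] if name == "b" else per_param[name]
        lo.append(lo_i)
        hi.append(hi_i)
    return np.array(lo), np.array(hi)


def fit(
    family: ModelFamily,
    data: GrowthDataset,
    config: Optional[FitConfig] = None,
    start: Optional[ModelParameters] = None,
) -> FitResult:
    """Fit one family by bounded multi-start least squares.

    Returns the lowest-SSE converged solution across the starting point plus
    ``config.n_starts`` seeded log-uniform perturbations of it (each
    coordinate multiplied by ``perturb_factor**u``, ``u ~ U(-1, 1)``). The
    start is :func:`initial_values` unless ``start`` overrides it. Raises
    :class:`NonConvergenceError` (carrying the best attempt) if no start
    converges.
    """
    family = ModelFamily(family)
    config = config or FitConfig()
    if start is None:
        start = initial_values(family, data)  # validates the dataset
    else:
        data.validate_for_fitting(family)
        if start.family is not family:
            raise ValueError(f"start is for {start.family.value}, fitting {family.value}")
    t, y = data.ages, data.weights
    lo, hi = _bounds(family, float(y.max()))

    def residuals(x: np.ndarray) -> np.ndarray:
        pred = evaluate(ModelParameters.from_array(family, x), t)
        res = pred - y
        return res / y if config.relative_residuals else res

    x0 = np.clip(start.as_array(), lo * (1 + 1e-12) + 1e-12, hi * (1 - 1e-12))
    sse_initial = float(np.sum(residuals(x0) ** 2))
    rng = np.random.default_rng(config.seed)
    starts = [x0]
    for _ in range(config.n_starts):
        u = rng.uniform(-1.0, 1.0, size=x0.size)
        starts.append(np.clip(x0 * config.perturb_factor**u, lo * (1 + 1e-9), hi * (1 - 1e-9)))

    best_converged = None  # (sse, solution)
    best_any = None
    n_used = 0
    for xs in starts:
        n_used += 1
        sol = least_squares(
            residuals,
            xs,
            bounds=(lo, hi),
            method="trf",
            ftol=config.ftol,
            gtol=config.gtol,
            xtol=1e-12,
            max_nfev=config.max_iter,
        )
        sse = 2.0 * sol.cost
        if best_any is None or sse < best_any[0]:
            best_any = (sse, sol)
        if sol.status > 0 and (best_converged is None or sse < best_converged[0]):
            best_converged = (sse, sol)
        # A machine-zero residual cannot be improved; stop early.
        if sol.status > 0 and sse <= 1e-16 * max(1.0, float(np.sum(y**2))):
            break

    sse_best, sol = best_converged if best_converged is not None else best_any
    params = ModelParameters.from_array(family, sol.x)
    preds = np.asarray(evaluate(params, t), dtype=float)
    gof = compute_criteria(y, preds, k=family.n_params)
    try:
        infl = inflection(params)
    except NoInflectionError:
        infl = None
    result = FitResult(
        family=family,
        params=params,
        predictions=preds,
        gof=gof,
        inflection=infl,
        converged=sol.status > 0,
        n_starts_used=n_used,
        gradient_norm=float(sol.optimality),
        sse_initial=sse_initial,
        label=data.label,
    )
    if sol.status <= 0:
        raise NonConvergenceError(
            f"no start converged for {family.value} ({sol.message})", best_attempt=result
        )
    return result


def fit_all(data: GrowthDataset, config: Optional[FitConfig] = None) -> list[FitResult]:
    """Fit all five families in fixed order; per-family failures are recorded
    in the returned results (``error`` set), not raised. Raises only when
    every family fails."""
    results: list[FitResult] = []
    for family in FAMILY_ORDER:
        try:
            results.append(fit(family, data, config))
        except NonConvergenceError as exc:
            base = exc.best_attempt
            results.append(
                FitResult(
                    family=family,
                    params=base.params if base else None,
                    predictions=base.predictions if base else None,
                    gof=base.gof if base else None,
                    inflection=base.inflection if base else None,
                    converged=False,
                    n_starts_used=base.n_starts_used if base else 0,
                    error=str(exc),
                    label=data.label,
                )
            )
        except (InsufficientDataError, ValueError) as exc:
            results.append(
                FitResult(
                    family=family,
                    params=None,
                    predictions=None,
                    gof=None,
                    inflection=None,
                    converged=False,
                    n_starts_used=0,
                    error=str(exc),
                    label=data.label,
                )
            )
    if all(r.error is not None for r in results):
        raise NonConvergenceError(
            "all five families failed: " + "; ".join(f"{r.family.value}: {r.error}" for r in results)
        )
    return results
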