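"""Single-predictor MARS: adaptive piecewise-linear (hinge) regression.

The model is an additive expansion in hinge basis functions of age ``x``:

    f(x) = beta_0 + sum_m beta_m * h_m(x),
    h_m(x) = max(0, x - t_m)  or  max(0, t_m - x),

built in two passes. The *forward* pass greedily adds, at each step, the
mirrored hinge pair (or a single hinge when its mirror is collinear on the
data) at the candidate knot that minimizes training RSS, refitting all
coefficients by exact linear least squares at every step. The *backward*
pass deletes terms one at a time (always the one whose removal hurts RSS
least) and keeps the member of the deletion sequence with the smallest
generalized cross-validation score

    GCV = (RSS / n) / (1 - M(lambda)/n)^2,

where the effective model size ``M(lambda)`` is the coefficient count plus a
per-knot penalty ``d`` (default 2, the usual additive-model convention)
times the number of distinct knots.

Only the single-predictor, additive, degree-1 case is implemented: growth
data here has age as the sole regressor.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .fitting import GrowthDataset, InsufficientDataError

__all__ = [
    "HingeDirection",
    "HingeTerm",
    "MarsModel",
    "MarsConfig",
    "hinge",
    "predict",
    "gcv",
    "effective_size",
    "fit_mars",
]


class HingeDirection(str, enum.Enum):
    ABOVE = "above"  # max(0, x - t)
    BELOW = "below"  # max(0, t - x)


def hinge(x, knot: float, direction: Union[HingeDirection, str]):
    """Hinge basis function: ``max(0, x - knot)`` (above) or ``max(0, knot - x)``
    (below); zero on one side of the knot, linear on the other."""
    direction = HingeDirection(direction)
    x = np.asarray(x, dtype=float)
    out = np.maximum(0.0, x - knot if direction is HingeDirection.ABOVE else knot - x)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class HingeTerm:
    knot: float
    direction: HingeDirection
    coefficient: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", HingeDirection(self.direction))

    def __call__(self, x):
        return self.coefficient * hinge(x, self.knot, self.direction)


@dataclass(frozen=True)
class MarsModel:
    """Fitted (or externally specified) hinge-spline model."""

    intercept: float
    terms: tuple
    gcv: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "terms",
            tuple(t if isinstance(t, HingeTerm) else HingeTerm(**t) for t in self.terms),
        )

    @property
    def n_basis(self) -> int:
        """Model size M: number of basis functions, intercept included."""
        return len(self.terms) + 1

    @property
    def knots(self) -> tuple[float, ...]:
        return tuple(sorted({t.knot for t in self.terms}))

    def predict(self, age):
        return predict(self, age)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "terms": [
                {"knot": t.knot, "direction": t.direction.value, "coefficient": t.coefficient}
                for t in self.terms
            ],
            "gcv": self.gcv,
        }

    @classmethod
    def from_dict(cls, doc) -> "MarsModel":
        return cls(
            intercept=float(doc["intercept"]),
            terms=tuple(doc["terms"]),
            gcv=doc.get("gcv"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MarsModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def predict(model: MarsModel, age):
    """Predicted weight (g) at ``age`` (weeks, scalar or array)."""
    x = np.asarray(age, dtype=float)
    out = np.full_like(x, model.intercept, dtype=float)
    for term in model.terms:
        out += term.coefficient * hinge(x, term.knot, term.direction)
    return out if np.ndim(age) else float(out)


def effective_size(n_coefficients: int, n_knots: int, penalty_per_knot: float) -> float:
    """Effective number of parameters M(lambda) charged by GCV."""
    return n_coefficients + penalty_per_knot * n_knots


def gcv(residual_sum_of_squares: float, n: int, effective_terms: float) -> float:
    """Generalized cross-validation score (RSS/n) / (1 - M(lambda)/n)^2."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if residual_sum_of_squares < 0:
        raise ValueError("RSS must be non-negative")
    if effective_terms >= n:
        raise ValueError(
            f"GCV undefined: effective model size {effective_terms} >= n = {n}"
        )
    return (residual_sum_of_squares / n) / (1.0 - effective_terms / n) ** 2


@dataclass(frozen=True)
class MarsConfig:
    """Fitting options.

    max_terms
        Cap on model size M (basis functions including the intercept).
    gcv_penalty_per_knot
        The GCV complexity charge d per distinct knot. With very few
        observations a model of j knots has M(lambda) = (1 + terms) + d*j,
        which can reach n and make GCV infinite; set d lower (down to 0) when
        fitting handfuls of points.
    minspan
        Minimum number of distinct predictor values between knots (1 = any
        unused distinct value is a candidate).
    prune
        Run the backward deletion pass (on by default).
    knot_strategy
        "observed": candidate knots are the distinct observed predictor
        values (deterministic default). "random": ``n_candidate_knots``
        uniform draws within the predictor range, seeded — the stochastic
        variant of classical MARS knot placement.
    """

    max_terms: int = 21
    gcv_penalty_per_knot: float = 2.0
    minspan: int = 1
    prune: bool = True
    knot_strategy: str = "observed"
    n_candidate_knots: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if self.gcv_penalty_per_knot < 0:
            raise ValueError("gcv_penalty_per_knot must be >= 0")
        if self.knot_strategy not in ("observed", "random"):
            raise ValueError(f"unknown knot_strategy {self.knot_strategy!r}")


# -- internal linear algebra -------------------------------------------------

_RANK_TOL = 1e-9


def _design(x: np.ndarray, terms: Sequence[tuple[float, HingeDirection]]) -> np.ndarray:
    cols = [np.ones_like(x)]
    cols += [hinge(x, knot, direction) for knot, direction in terms]
    return np.column_stack(cols)


def _ols(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact least-squares coefficients and RSS on basis matrix B."""
    beta, *_ = np.linalg.lstsq(B, y, rcond=None)
    rss = float(np.sum((y - B @ beta) ** 2))
    return beta, rss


def _adds_rank(B: np.ndarray, col: np.ndarray) -> bool:
    """True when ``col`` is not numerically collinear with the columns of B."""
    q, _ = np.linalg.qr(B)
    resid = col - q @ (q.T @ col)
    return float(np.linalg.norm(resid)) > _RANK_TOL * max(1.0, float(np.linalg.norm(col)))


def _candidate_knots(x: np.ndarray, config: MarsConfig) -> np.ndarray:
    distinct = np.unique(x)
    if config.knot_strategy == "random":
        rng = np.random.default_rng(config.seed)
        return np.sort(rng.uniform(distinct[0], distinct[-1], size=config.n_candidate_knots))
    return distinct


def fit_mars(data, config: Optional[MarsConfig] = None) -> MarsModel:
    """Fit a hinge-spline model to age-weight data.

    ``data`` is a :class:`~broilergrowth.fitting.GrowthDataset` or an
    ``(x, y)`` pair of equal-length arrays. Requires at least 3 distinct
    predictor values.
    """
    config = config or MarsConfig()
    if isinstance(data, GrowthDataset):
        x, y = data.ages, data.weights
    else:
        x, y = (np.asarray(v, dtype=float) for v in data)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = x.size
    distinct = np.unique(x)
    if distinct.size < 3:
        raise InsufficientDataError(
            f"MARS needs >= 3 distinct predictor values, got {distinct.size}"
        )

    candidates = _candidate_knots(x, config)
    rss_floor = 1e-12 * max(1.0, float(np.sum((y - y.mean()) ** 2)))

    # ---- forward pass ----
    terms: list[tuple[float, HingeDirection]] = []
    B = _design(x, terms)
    _, rss = _ols(B, y)
    while len(terms) + 1 < min(config.max_terms, n) and rss > rss_floor:
        used = {t[0] for t in terms}
        room = min(config.max_terms, n) - (len(terms) + 1)
        best = None  # (rss, knot, new_terms)
        for knot in candidates:
            # minspan: stay at least that many distinct-value positions away
            # from every knot already in the model.
            idx = int(np.searchsorted(distinct, knot))
            if any(
                abs(idx - int(np.searchsorted(distinct, u))) < config.minspan
                for u in used
            ):
                continue
            # Mirrored pair, keeping only sides that add rank; respect room.
            new: list[tuple[float, HingeDirection]] = []
            B_try = B
            for direction in (HingeDirection.ABOVE, HingeDirection.BELOW):
                if len(new) >= room:
                    break
                col = hinge(x, knot, direction)
                if _adds_rank(B_try, col):
                    new.append((float(knot), direction))
                    B_try = np.column_stack([B_try, col])
            if not new:
                continue
            _, rss_try = _ols(B_try, y)
            # Strict improvement ordering; ties broken by smaller knot (the
            # candidate scan is in ascending knot order, above before below).
            if best is None or rss_try < best[0] * (1 - 1e-12) - 1e-12:
                best = (rss_try, knot, new)
        if best is None or best[0] >= rss * (1 - 1e-12):
            break  # no candidate improves the fit
        rss, _, new = best
        terms.extend(new)
        B = _design(x, terms)

    beta, rss = _ols(B, y)

    def model_gcv(n_terms: int, knots: set, rss_val: float) -> float:
        m_eff = effective_size(n_terms + 1, len(knots), config.gcv_penalty_per_knot)
        if m_eff >= n:
            return math.inf
        return gcv(max(rss_val, 0.0), n, m_eff)

    # ---- backward pass ----
    if config.prune:
        seq = [(list(terms), beta, rss)]
        current = list(terms)
        while current:
            best_del = None  # (rss, index, beta)
            for i in range(len(current)):
                reduced = current[:i] + current[i + 1 :]
                beta_r, rss_r = _ols(_design(x, reduced), y)
                if best_del is None or rss_r < best_del[0]:
                    best_del = (rss_r, i, beta_r)
            rss_r, i, beta_r = best_del
            current = current[:i] + current[i + 1 :]
            seq.append((list(current), beta_r, rss_r))
        # Keep the sequence member with minimal GCV; on ties prefer the
        # smaller model (later in the deletion sequence).
        scored = [
            (model_gcv(len(t), {k for k, _ in t}, r), idx) for idx, (t, _, r) in enumerate(seq)
        ]
        best_gcv, best_idx = min(scored, key=lambda s: (s[0], -s[1]))
        terms, beta, rss = seq[best_idx]
        final_gcv = best_gcv
    else:
        final_gcv = model_gcv(len(terms), {k for k, _ in terms}, rss)

    return MarsModel(
        intercept=float(beta[0]),
        terms=tuple(
            HingeTerm(knot=k, direction=d, coefficient=float(c))
            for (k, d), c in zip(terms, beta[1:])
        ),
        gcv=None if math.isinf(final_gcv) else float(final_gcv),
    )
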