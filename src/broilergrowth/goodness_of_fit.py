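"""Fit-quality criteria (MSE, RMSE, R2, AIC, BIC) and cross-model ranking.

The criteria follow the least-squares conventions standard in growth-curve
comparison studies:

    MSE  = SSE / n                     RMSE = sqrt(MSE)
    R2   = 1 - SSE / SStot             adj R2 = 1 - (1 - R2)(n - 1)/(n - k - 1)
    AIC  = n ln(SSE / n) + 2 k         BIC  = n ln(SSE / n) + k ln(n)

where ``k`` counts only the curve parameters (no error-variance term), so the
exact identity ``BIC - AIC = k (ln n - 2)`` holds for every computed block.
``mse_df = SSE / (n - k)`` (the degrees-of-freedom variant some texts call the
mean square error) is reported alongside but is not used for ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["GofStats", "compute_criteria", "rank_models", "RANK_CRITERIA"]


@dataclass(frozen=True)
class GofStats:
    """Goodness-of-fit block for one model on one dataset."""

    n: int
    k: int
    sse: float
    mse: float
    rmse: float
    r2: float
    adj_r2: float
    aic: float
    bic: float
    mse_df: float = field(default=math.nan)
    #: True when SSE underflowed to exactly 0 and AIC/BIC are the -inf sentinel.
    perfect_fit: bool = field(default=False)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "k": self.k,
            "sse": self.sse,
            "mse": self.mse,
            "rmse": self.rmse,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "aic": self.aic,
            "bic": self.bic,
            "mse_df": self.mse_df,
            "perfect_fit": self.perfect_fit,
        }


def compute_criteria(observed: Sequence[float], predicted: Sequence[float], k: int) -> GofStats:
    """Compute the full criteria block for one observed/predicted pair.

    Parameters
    ----------
    observed, predicted
        Equal-length weight vectors (g).
    k
        Number of fitted curve parameters (>= 1).

    Raises
    ------
    ValueError
        On length mismatch, empty input, ``k < 1``, or a constant observed
        vector (R2 undefined).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"observed {y.shape} and predicted {yhat.shape} must be equal-length 1-d vectors")
    n = y.size
    if n == 0:
        raise ValueError("empty observation vector")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("observed vector is constant; R2 is undefined")
    sse = float(np.sum((y - yhat) ** 2))
    mse = sse / n
    r2 = 1.0 - sse / sstot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else math.nan
    if sse == 0.0:
        aic = bic = -math.inf
        perfect = True
    else:
        aic = n * math.log(sse / n) + 2.0 * k
        bic = n * math.log(sse / n) + k * math.log(n)
        perfect = False
    return GofStats(
        n=n,
        k=k,
        sse=sse,
        mse=mse,
        rmse=math.sqrt(mse),
        r2=r2,
        adj_r2=adj_r2,
        aic=aic,
        bic=bic,
        mse_df=sse / (n - k) if n > k else math.nan,
        perfect_fit=perfect,
    )


RANK_CRITERIA = ("aic", "bic", "mse", "rmse", "r2")


def rank_models(results: Sequence, criterion: str = "aic") -> list:
    """Order fit results from best to worst by one criterion.

    ``results`` may be any objects carrying a ``gof`` attribute (or being a
    :class:`GofStats` themselves). Ascending for aic/bic/mse/rmse, descending
    for r2; ties keep input order (stable sort).
    """
    if len(results) == 0:
        raise ValueError("rank_models needs at least one result")
    if criterion not in RANK_CRITERIA:
        raise ValueError(f"criterion must be one of {RANK_CRITERIA}, got {criterion!r}")

    def key(res):
        gof = getattr(res, "gof", res)
        value = getattr(gof, criterion)
        return -value if criterion == "r2" else value

    return sorted(results, key=key)
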