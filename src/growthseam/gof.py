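"""Goodness-of-fit statistics, overall and split by growth phase.

Because post-pouch morphometrics are far more variable than pouch-young
measurements, a pooled R² is dominated by the between-phase spread; the
statistics are therefore also computed separately for the records on each
side of the join age.

Conventions: RMSE uses divisor ``n`` (the biased standard deviation of the
residuals), recorded in every report as ``rmse_divisor`` so comparisons are
explicit.  Adjusted R² uses the standard ``(n-1)/(n-p-1)`` correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["GofSummary", "gof", "gof_by_phase"]


@dataclass(frozen=True)
class GofSummary:
    """Summary statistics for one set of (observed, predicted) pairs."""

    n: int
    p: int
    sst: float
    sse: float
    r2: Optional[float]
    r2_adjusted: Optional[float]
    rmse: float
    degenerate: bool = False  # constant observations: r2 undefined

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "p": self.p,
            "sst": self.sst,
            "sse": self.sse,
            "r2": self.r2,
            "r2_adjusted": self.r2_adjusted,
            "rmse": self.rmse,
            "rmse_divisor": "n",
            "degenerate": self.degenerate,
        }


def gof(observed, predicted, p: int) -> GofSummary:
    """Compute SST, SSE, R², adjusted R² and RMSE for one prediction set.

    ``p`` is the number of free model parameters used by the adjusted-R²
    correction.  Requires n > p + 1.  Constant observations (SST = 0) yield
    a summary flagged ``degenerate`` with undefined R².
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    n = obs.size
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    rmse = math.sqrt(sse / n)
    if sst == 0.0:
        return GofSummary(n=n, p=p, sst=sst, sse=sse, r2=None,
                          r2_adjusted=None, rmse=rmse, degenerate=True)
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return GofSummary(n=n, p=p, sst=sst, sse=sse, r2=r2, r2_adjusted=r2_adj, rmse=rmse)


def gof_by_phase(ages, observed, model, p: int,
                 min_side: int | None = None) -> tuple[Optional[GofSummary], Optional[GofSummary]]:
    """Per-phase statistics for an SJ2P model: records with age <= j form the
    pouch side (a record at exactly j counts as pouch), the rest post-pouch.

    A side with too few records (fewer than ``p + 2``, or ``min_side`` if
    given) is reported as ``None`` rather than fabricated.
    """
    ages = np.asarray(ages, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if ages.shape != obs.shape:
        raise ValueError("ages and observations must align")
    need = (p + 2) if min_side is None else min_side
    j = model.free.j
    pred = np.asarray(model.evaluate(ages), dtype=float)
    pouch_mask = ages <= j
    out = []
    for mask in (pouch_mask, ~pouch_mask):
        if int(mask.sum()) >= need:
            out.append(gof(obs[mask], pred[mask], p))
        else:
            out.append(None)
    return out[0], out[1]
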