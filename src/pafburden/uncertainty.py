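"""Monte-Carlo draw vectors and 95% uncertainty intervals (UIs).

Every stage of the burden pipeline that consumes stratified incidence
operates draw-wise: a quantity is carried as an ordered vector of
Monte-Carlo draws, the stage function is applied within each draw index
independently, and only at reporting time is the vector collapsed to a
point estimate (the draw mean) and a 95% UI (the 2.5th and 97.5th
percentiles, linear interpolation between closest ranks).

Draw index k is a coherent scenario across strata: summing cells within
a draw is valid, so aggregation always happens on draws, never on
summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

#: two-sided 95% normal quantile, fixed across the package
Z95 = 1.959964


@dataclass(frozen=True)
class DrawVector:
    """An ordered vector of nonnegative Monte-Carlo draws for one quantity."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("DrawVector requires a non-empty 1-D array of draws")
        if not np.all(np.isfinite(arr)):
            raise ValueError("draws must be finite")
        object.__setattr__(self, "values", arr)

    @property
    def n_draws(self) -> int:
        return int(self.values.size)

    def summary(self) -> tuple[float, float, float]:
        return summarize_ui(self)

    def __add__(self, other: "DrawVector") -> "DrawVector":
        if self.n_draws != other.n_draws:
            raise ValueError(
                f"misaligned draw counts: {self.n_draws} vs {other.n_draws}"
            )
        return DrawVector(self.values + other.values)

    def __mul__(self, scalar: float) -> "DrawVector":
        return DrawVector(self.values * float(scalar))

    __rmul__ = __mul__


def summarize_ui(draws) -> tuple[float, float, float]:
    """Collapse draws to ``(point, ui_low, ui_high)``.

    The point estimate is the draw mean; the UI bounds are the 2.5th and
    97.5th percentiles computed by linear interpolation between closest
    ranks.  A single draw degenerates to a point with a warning.
    """
    values = draws.values if isinstance(draws, DrawVector) else np.asarray(draws, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty draw vector")
    if values.size == 1:
        warnings.warn("single draw: UI collapses to the point estimate", stacklevel=2)
        v = float(values[0])
        return v, v, v
    low, high = np.percentile(values, [2.5, 97.5], method="linear")
    return float(values.mean()), float(low), float(high)


def propagate(op: Callable, *inputs) -> DrawVector:
    """Apply a stage operation within each draw index independently.

    ``inputs`` may mix DrawVectors (or 1-D arrays) and scalars.  All draw
    inputs must share the draw count; scalars are broadcast to every
    draw.  ``op`` must act element-wise on its arguments, so vectorized
    evaluation over the draw axis is identical to a per-index loop.
    """
    arrays = []
    n_draws = None
    for x in inputs:
        if isinstance(x, DrawVector):
            arr = x.values
        elif isinstance(x, np.ndarray) and x.ndim == 1:
            arr = x
        else:
            arrays.append(float(x))
            continue
        if n_draws is None:
            n_draws = arr.size
        elif arr.size != n_draws:
            raise ValueError(f"misaligned draw counts: {arr.size} vs {n_draws}")
        arrays.append(arr)
    if n_draws is None:
        raise ValueError("propagate needs at least one draw-vector input")
    out = np.asarray(op(*arrays), dtype=float)
    if out.shape != (n_draws,):
        raise ValueError("stage operation did not preserve the draw axis")
    return DrawVector(out)


def sample_parameter_draws(pooled, n_draws: int, seed) -> DrawVector:
    """Draw parameter uncertainty for a pooled RR or a pooled prevalence.

    Relative risks are sampled normally on the log scale around the
    pooled log-RR; prevalences are sampled normally on the logit scale
    (delta-method SE) and mapped back, which keeps draws inside (0, 1).
    SE = 0 yields constant draws.  Off by default in the pipeline, where
    UIs carry incidence-draw uncertainty only.
    """
    from pafburden.meta import PooledEffect
    from pafburden.prevalence import RegionPrevalence

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if isinstance(pooled, PooledEffect):
        draws = np.exp(rng.normal(pooled.log_rr, pooled.se, size=n_draws))
    elif isinstance(pooled, RegionPrevalence):
        if pooled.se == 0 or pooled.pe in (0.0, 1.0):
            draws = np.full(n_draws, pooled.pe)
        else:
            se_logit = pooled.se / (pooled.pe * (1.0 - pooled.pe))
            draws = expit(rng.normal(logit(pooled.pe), se_logit, size=n_draws))
    else:
        raise TypeError(f"cannot sample draws for {type(pooled).__name__}")
    return DrawVector(draws)
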