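"""Inverse-variance meta-analysis of disease effect estimates.

Per-disease odds ratios, relative risks, and hazard ratios from
epidemiological studies are pooled on the log scale.  The pooling model
is chosen by the heterogeneity rule used throughout comparative risk
assessment: a fixed-effect inverse-variance pool when I-squared < 50%,
otherwise a DerSimonian-Laird random-effects pool.  OR, RR, and HR are
treated as interchangeable ratio measures on the log scale; no
rare-disease conversion is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pafburden.uncertainty import Z95

_EFFECT_TYPES = frozenset({"OR", "RR", "HR"})
#: I-squared threshold (percent) above which random effects is used
I2_THRESHOLD = 50.0


@dataclass(frozen=True)
class StudyEffect:
    """One study's effect estimate for one disease, on the log scale."""

    disease: str
    study_id: str
    log_effect: float
    se: float
    effect_type: str = "RR"
    n: int | None = None

    def __post_init__(self) -> None:
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"study {self.study_id}: se must be positive, got {self.se}")
        if not math.isfinite(self.log_effect):
            raise ValueError(f"study {self.study_id}: non-finite log effect")
        if self.effect_type not in _EFFECT_TYPES:
            raise ValueError(f"effect_type must be one of {sorted(_EFFECT_TYPES)}")


@dataclass(frozen=True)
class PooledEffect:
    """A pooled ratio effect with heterogeneity statistics.

    ``ci95`` is on the ratio scale.  ``i2`` is the percentage of total
    variability due to between-study heterogeneity,
    ``max(0, 100 * (Q - (k - 1)) / Q)``; ``tau2`` is the
    DerSimonian-Laird between-study variance (0 for the fixed model).
    """

    disease: str
    model: str
    log_rr: float
    se: float
    ci95: tuple[float, float]
    q: float
    i2: float
    tau2: float
    k: int

    @property
    def rr(self) -> float:
        return math.exp(self.log_rr)

    def __post_init__(self) -> None:
        if self.model not in ("fixed", "random"):
            raise ValueError("model must be 'fixed' or 'random'")
        low, high = self.ci95
        if not (low <= self.rr <= high):
            raise ValueError("CI does not bracket the pooled estimate")


def ci_to_se(ci_low: float, ci_high: float) -> float:
    """SE of a log ratio from its reported 95% CI on the ratio scale."""
    if not (0 < ci_low <= ci_high):
        raise ValueError("require 0 < ci_low <= ci_high")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)


def _validated(effects: Sequence[StudyEffect]) -> tuple[np.ndarray, np.ndarray, str]:
    effects = list(effects)
    if not effects:
        raise ValueError("cannot pool an empty list of studies")
    diseases = {e.disease for e in effects}
    if len(diseases) > 1:
        raise ValueError(f"mixed diseases in one pool: {sorted(diseases)}")
    y = np.array([e.log_effect for e in effects])
    se = np.array([e.se for e in effects])
    return y, se, effects[0].disease


def _heterogeneity(y: np.ndarray, se: np.ndarray) -> tuple[float, float]:
    """Cochran's Q and I-squared (%) under fixed inverse-variance weights."""
    w = 1.0 / se**2
    est = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - est) ** 2))
    k = y.size
    i2 = max(0.0, 100.0 * (q - (k - 1)) / q) if q > 0 else 0.0
    return q, i2


def pool_fixed(effects: Sequence[StudyEffect]) -> PooledEffect:
    """Fixed-effect inverse-variance pool: weights 1/se_i^2."""
    y, se, disease = _validated(effects)
    w = 1.0 / se**2
    log_rr = float(np.sum(w * y) / np.sum(w))
    se_pool = float(np.sqrt(1.0 / np.sum(w)))
    q, i2 = _heterogeneity(y, se)
    ci = (math.exp(log_rr - Z95 * se_pool), math.exp(log_rr + Z95 * se_pool))
    return PooledEffect(disease, "fixed", log_rr, se_pool, ci, q, i2, 0.0, int(y.size))


def pool_random(effects: Sequence[StudyEffect]) -> PooledEffect:
    """DerSimonian-Laird random-effects pool.

    tau^2 = max(0, (Q - (k - 1)) / (sum(w) - sum(w^2)/sum(w))) with fixed
    weights w = 1/se^2; the pooled estimate then uses weights
    1/(se^2 + tau^2).  Requires k >= 2 (tau^2 is undefined for one study).
    """
    y, se, disease = _validated(effects)
    k = y.size
    if k < 2:
        raise ValueError("random-effects pooling needs at least 2 studies")
    w = 1.0 / se**2
    q, i2 = _heterogeneity(y, se)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    log_rr = float(np.sum(w_star * y) / np.sum(w_star))
    se_pool = float(np.sqrt(1.0 / np.sum(w_star)))
    ci = (math.exp(log_rr - Z95 * se_pool), math.exp(log_rr + Z95 * se_pool))
    return PooledEffect(disease, "random", log_rr, se_pool, ci, q, i2, tau2, int(k))


def pool_auto(effects: Sequence[StudyEffect]) -> PooledEffect:
    """Pool with the model chosen by the I-squared rule.

    Fixed effect when I-squared < 50% (strict), random effects otherwise.
    A single study is pooled as fixed by convention (tau^2 undefined).
    """
    fixed = pool_fixed(effects)
    if fixed.k == 1 or fixed.i2 < I2_THRESHOLD:
        return fixed
    return pool_random(effects)


def read_study_table(path) -> list[StudyEffect]:
    """Read a study effect CSV.

    Columns: disease, study_id, effect_type, effect, ci_low, ci_high, n.
    The SE of each log effect is recovered from the reported 95% CI.
    """
    df = pd.read_csv(path)
    required = {"disease", "study_id", "effect_type", "effect", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    effects = []
    for row in df.itertuples(index=False):
        n = int(row.n) if "n" in df.columns and pd.notna(row.n) else None
        effects.append(
            StudyEffect(
                disease=str(row.disease),
                study_id=str(row.study_id),
                log_effect=math.log(float(row.effect)),
                se=ci_to_se(float(row.ci_low), float(row.ci_high)),
                effect_type=str(row.effect_type),
                n=n,
            )
        )
    return effects


def pooled_to_frame(pooled: Iterable[PooledEffect]) -> pd.DataFrame:
    """Tabulate pooled effects (ratio scale) for CSV output."""
    rows = [
        {
            "disease": p.disease,
            "model": p.model,
            "rr": p.rr,
            "ci_low": p.ci95[0],
            "ci_high": p.ci95[1],
            "log_rr": p.log_rr,
            "se": p.se,
            "q": p.q,
            "i2": p.i2,
            "tau2": p.tau2,
            "k": p.k,
        }
        for p in pooled
    ]
    return pd.DataFrame(rows)
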