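"""Exposure-prevalence pooling: within-country, geographical, risk-based.

Survey estimates of early-maturation prevalence (menarche before age 12,
13 for Asian populations; voice break earlier than the population mean
— definitions carried as upstream survey metadata) are pooled in three
tiers:

1. within a country, by inverse-variance meta-analysis over surveys
   (binomial SE per survey);
2. across a region, by a weighted average with weights equal to survey
   sample size times the country's disease case count;
3. for regions with no surveys, by an ordinary least-squares regression
   of pooled prevalence on disease incidence across known regions,
   predicting at the target region's incidence (truncated to [0, 1]).

Prevalence is treated as time-invariant over the exposure window; a
configurable lag (default 20 years) tags which historical prevalence
feeds which outcome year and is metadata only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: years between exposure-prevalence window and outcome year (metadata)
DEFAULT_EXPOSURE_LAG_YEARS = 20


@dataclass(frozen=True)
class PrevalenceRecord:
    """One survey's (or one country's pooled) prevalence estimate."""

    country: str
    region: str
    sex: str
    survey_id: str
    prevalence: float
    n: int
    period: str = "1960s-2000s"

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0,1], got {self.prevalence}")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")

    @property
    def se(self) -> float:
        return binomial_se(self.prevalence, self.n)


@dataclass(frozen=True)
class RegionPrevalence:
    """Pooled exposure prevalence Pe for one region and sex."""

    region: str
    sex: str
    pe: float
    method: str
    se: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pe <= 1.0:
            raise ValueError(f"pe must be in [0,1], got {self.pe}")
        if self.method not in ("geographical", "risk_based"):
            raise ValueError("method must be 'geographical' or 'risk_based'")
        if self.se < 0:
            raise ValueError("se must be nonnegative")


def binomial_se(p: float, n: int) -> float:
    """Binomial SE sqrt(p(1-p)/n), with a +2/+4 shift at the boundary.

    Surveys reporting prevalence of exactly 0 or 1 have an undefined
    Wald SE; an Agresti-Coull-style shift (add 2 successes and 4 trials)
    keeps the weight finite without excluding the survey.
    """
    if p in (0.0, 1.0):
        p = (p * n + 2.0) / (n + 4.0)
    return math.sqrt(p * (1.0 - p) / n)


def pool_within_country(records: Sequence[PrevalenceRecord]) -> PrevalenceRecord:
    """Inverse-variance pool of all surveys in one (country, sex)."""
    records = list(records)
    if not records:
        raise ValueError("no surveys to pool")
    keys = {(r.country, r.sex) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple (country, sex) strata: {sorted(keys)}")
    if len(records) == 1:
        return records[0]
    p = np.array([r.prevalence for r in records])
    w = np.array([1.0 / r.se**2 for r in records])
    pooled = float(np.sum(w * p) / np.sum(w))
    first = records[0]
    return PrevalenceRecord(
        country=first.country,
        region=first.region,
        sex=first.sex,
        survey_id="pooled",
        prevalence=pooled,
        n=sum(r.n for r in records),
        period=first.period,
    )


def pool_geographical(
    countries: Sequence[PrevalenceRecord],
    case_counts: Mapping[str, float],
) -> RegionPrevalence:
    """Region-level weighted average of country prevalences.

    The weight of country c is its survey sample size times its disease
    case count: pe = sum(n_c * cases_c * p_c) / sum(n_c * cases_c).
    The output is a convex combination of the country prevalences.
    """
    countries = list(countries)
    if not countries:
        raise ValueError("no country records to pool")
    regions = {r.region for r in countries}
    sexes = {r.sex for r in countries}
    if len(regions) > 1 or len(sexes) > 1:
        raise ValueError("geographical pooling requires one (region, sex) stratum")
    weights = []
    for rec in countries:
        if rec.country not in case_counts:
            raise KeyError(f"no case count for country '{rec.country}'")
        weights.append(rec.n * float(case_counts[rec.country]))
    w = np.asarray(weights, dtype=float)
    if np.sum(w) <= 0:
        raise ValueError("nonpositive total weight in geographical pooling")
    p = np.array([r.prevalence for r in countries])
    se = np.array([r.se for r in countries])
    pe = float(np.sum(w * p) / np.sum(w))
    pooled_se = float(np.sqrt(np.sum((w * se) ** 2)) / np.sum(w))
    return RegionPrevalence(countries[0].region, countries[0].sex, pe, "geographical", pooled_se)


def pool_risk_based(
    known: Sequence[RegionPrevalence],
    incidence_by_region: Mapping[str, float],
    target_region: str,
) -> RegionPrevalence:
    """Impute a survey-free region's prevalence from disease incidence.

    An OLS line of pooled prevalence on incidence rate is fitted across
    the known regions and evaluated at the target region's incidence.
    Predictions outside [0, 1] are truncated with a logged warning.
    """
    known = list(known)
    if len(known) < 2:
        raise ValueError("risk-based pooling needs >= 2 known regions")
    sexes = {r.sex for r in known}
    if len(sexes) > 1:
        raise ValueError("risk-based pooling requires a single sex stratum")
    missing = [r.region for r in known if r.region not in incidence_by_region]
    if target_region not in incidence_by_region:
        missing.append(target_region)
    if missing:
        raise KeyError(f"no incidence for region(s): {missing}")
    x = np.array([float(incidence_by_region[r.region]) for r in known])
    y = np.array([r.pe for r in known])
    if np.ptp(x) == 0:
        raise ValueError("identical incidence across known regions: singular design")
    slope, intercept = np.polyfit(x, y, 1)
    x0 = float(incidence_by_region[target_region])
    pred = float(intercept + slope * x0)
    # prediction SE: residual spread plus leverage at x0
    k = len(known)
    if k > 2:
        resid = y - (intercept + slope * x)
        s2 = float(np.sum(resid**2) / (k - 2))
        sxx = float(np.sum((x - x.mean()) ** 2))
        se = math.sqrt(s2 * (1.0 / k + (x0 - x.mean()) ** 2 / sxx))
    else:
        se = 0.0
    if pred < 0.0 or pred > 1.0:
        clipped = min(max(pred, 0.0), 1.0)
        logger.warning(
            "risk-based prediction %.4f for region '%s' truncated to %.1f",
            pred, target_region, clipped,
        )
        pred = clipped
    return RegionPrevalence(target_region, known[0].sex, pred, "risk_based", se)


def records_from_frame(df) -> list[PrevalenceRecord]:
    """Build records from a survey table (country, region, sex, survey_id, prevalence, n, period)."""
    return [
        PrevalenceRecord(
            country=str(r.country),
            region=str(r.region),
            sex=str(r.sex),
            survey_id=str(r.survey_id),
            prevalence=float(r.prevalence),
            n=int(r.n),
            period=str(getattr(r, "period", "1960s-2000s")),
        )
        for r in df.itertuples(index=False)
    ]
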