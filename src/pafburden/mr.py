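"""Two-sample Mendelian randomization and the causal gate.

Genetic variants associated with puberty timing serve as instruments:
the variant-exposure association (years of puberty-timing delay per
allele) comes from one GWAS sample and the variant-outcome association
(log-odds of disease per allele) from another.  The ratio of the two is
a per-variant causal estimate; inverse-variance weighting (IVW) of
those ratios is the primary estimator, with MR-Egger and the weighted
median as sensitivity analyses.

Effects are expressed as an odds ratio per 1-year *increase* (delay) in
puberty timing, so OR < 1 means earlier maturation raises disease risk.
A disease passes the causal gate when its forward IVW estimate is
significant at p < 0.05 with OR < 1; the reverse direction is reported
but does not veto.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from pafburden.uncertainty import Z95

logger = logging.getLogger(__name__)

#: genome-wide significance threshold for instrument selection
GWAS_P_THRESHOLD = 5e-8

_REQUIRED_COLS = (
    "variant_id",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
)


@dataclass(frozen=True)
class InstrumentSet:
    """GWAS summary statistics for one disease's instruments.

    ``data`` columns: variant_id, beta_exposure, se_exposure,
    beta_outcome, se_outcome, and optionally p_exposure.  Variants are
    assumed mutually independent (no LD).
    """

    disease: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(_REQUIRED_COLS) - set(df.columns)
        if missing:
            raise ValueError(f"instrument table missing columns: {sorted(missing)}")
        if len(df) < 1:
            raise ValueError("instrument set needs at least one variant")
        if df["variant_id"].duplicated().any():
            raise ValueError("variant_ids must be unique")
        if (df["se_exposure"] <= 0).any() or (df["se_outcome"] <= 0).any():
            raise ValueError("all SEs must be positive")

    @property
    def n_variants(self) -> int:
        return len(self.data)

    def filter_significant(self, threshold: float = GWAS_P_THRESHOLD) -> "InstrumentSet":
        """Keep variants whose exposure association passes ``threshold``."""
        if "p_exposure" not in self.data.columns:
            raise ValueError("no p_exposure column to filter on")
        kept = self.data[self.data["p_exposure"] < threshold].reset_index(drop=True)
        if kept.empty:
            raise ValueError(f"{self.disease}: no instruments pass p < {threshold:g}")
        return InstrumentSet(self.disease, kept)


@dataclass(frozen=True)
class MrResult:
    """A causal estimate for one disease and direction.

    ``or_per_year`` is the odds ratio per 1-year increase in puberty
    timing; ``causal_gate`` marks a forward estimate that is significant
    with OR < 1 (early maturation harmful).
    """

    disease: str
    direction: str
    method: str
    or_per_year: float
    ci95: tuple[float, float]
    p: float
    q: float = 0.0
    causal_gate: bool = False
    intercept: float | None = None
    intercept_p: float | None = None
    n_variants: int = 1

    @property
    def log_or(self) -> float:
        return math.log(self.or_per_year)


def _result(disease, direction, method, slope, se, q=0.0, n_variants=1, **extra) -> MrResult:
    p = 2.0 * stats.norm.sf(abs(slope) / se) if se > 0 else (0.0 if slope != 0 else 1.0)
    gate = direction == "forward" and p < 0.05 and slope < 0
    return MrResult(
        disease=disease,
        direction=direction,
        method=method,
        or_per_year=math.exp(slope),
        ci95=(math.exp(slope - Z95 * se), math.exp(slope + Z95 * se)),
        p=float(p),
        q=float(q),
        causal_gate=gate,
        n_variants=n_variants,
        **extra,
    )


def wald_ratio(variant, disease: str = "", direction: str = "forward") -> MrResult:
    """Single-variant ratio estimate with first-order delta-method SE.

    ``variant`` is any mapping with beta_exposure, se_exposure,
    beta_outcome, se_outcome.  The slope is beta_outcome/beta_exposure
    and its SE is se_outcome/|beta_exposure|.
    """
    be = float(variant["beta_exposure"])
    bo = float(variant["beta_outcome"])
    so = float(variant["se_outcome"])
    if be == 0:
        raise ValueError("beta_exposure is zero: Wald ratio undefined (weak instrument)")
    slope = bo / be
    se = so / abs(be)
    return _result(disease, direction, "wald", slope, se, n_variants=1)


def ivw(instruments: InstrumentSet, direction: str = "forward") -> MrResult:
    """Inverse-variance-weighted estimate over the per-variant ratios.

    Equivalent to a zero-intercept regression of beta_outcome on
    beta_exposure with weights 1/se_outcome^2: the ratio weights are
    w_j = beta_exposure_j^2 / se_outcome_j^2.  Cochran's Q over the
    ratios quantifies instrument heterogeneity.  With a single variant
    the estimate degenerates to the Wald ratio.
    """
    df = instruments.data
    if len(df) < 2:
        logger.warning("%s: fewer than 2 instruments, falling back to Wald ratio", instruments.disease)
        return wald_ratio(df.iloc[0], instruments.disease, direction)
    be = df["beta_exposure"].to_numpy(float)
    bo = df["beta_outcome"].to_numpy(float)
    so = df["se_outcome"].to_numpy(float)
    if np.any(be == 0):
        raise ValueError("zero beta_exposure among instruments")
    r = bo / be
    w = be**2 / so**2
    slope = float(np.sum(w * r) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (r - slope) ** 2))
    return _result(instruments.disease, direction, "ivw", slope, se, q=q, n_variants=len(df))


def egger(instruments: InstrumentSet, direction: str = "forward") -> MrResult:
    """MR-Egger: weighted regression with a free intercept.

    The slope is the pleiotropy-adjusted causal estimate; a nonzero
    intercept indicates directional pleiotropy.  Needs >= 3 variants.
    """
    df = instruments.data
    if len(df) < 3:
        raise ValueError("MR-Egger needs at least 3 variants")
    import statsmodels.api as sm

    be = df["beta_exposure"].to_numpy(float)
    bo = df["beta_outcome"].to_numpy(float)
    w = 1.0 / df["se_outcome"].to_numpy(float) ** 2
    # orient so all exposure effects are positive (standard Egger convention)
    sign = np.sign(be)
    be, bo = be * sign, bo * sign
    fit = sm.WLS(bo, sm.add_constant(be), weights=w).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    # multiplicative random-effects scaling, never below 1
    scale = max(float(fit.scale), 1.0)
    ncov = np.asarray(fit.normalized_cov_params)
    se_slope = float(np.sqrt(scale * ncov[1, 1]))
    se_int = float(np.sqrt(scale * ncov[0, 0]))
    int_p = 2.0 * stats.norm.sf(abs(intercept) / se_int) if se_int > 0 else 1.0
    return _result(
        instruments.disease,
        direction,
        "egger",
        slope,
        se_slope,
        n_variants=len(be),
        intercept=intercept,
        intercept_p=float(int_p),
    )


def weighted_median(instruments: InstrumentSet, direction: str = "forward",
                    n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Weighted median of the Wald ratios (50% breakdown).

    Consistent when at least half the weight comes from valid
    instruments.  With equal weights this is the ordinary median.  The
    SE comes from a parametric bootstrap of the summary statistics.
    """
    df = instruments.data
    be = df["beta_exposure"].to_numpy(float)
    bo = df["beta_outcome"].to_numpy(float)
    so = df["se_outcome"].to_numpy(float)
    se_e = df["se_exposure"].to_numpy(float)
    w = be**2 / so**2
    slope = _weighted_median_value(bo / be, w)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        be_b = rng.normal(be, se_e)
        bo_b = rng.normal(bo, so)
        ok = be_b != 0
        boot[b] = _weighted_median_value(bo_b[ok] / be_b[ok], w[ok])
    se = float(boot.std(ddof=1))
    return _result(instruments.disease, direction, "weighted_median", slope, se,
                   n_variants=len(be))


def _weighted_median_value(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, r))


def sensitivity_estimates(instruments: InstrumentSet, direction: str = "forward",
                          seed: int = 0) -> list[MrResult]:
    """IVW plus the sensitivity pair (MR-Egger, weighted median).

    Methods whose variant-count requirement is not met are omitted with
    a logged notice; sensitivity estimates are advisory and never drive
    the causal gate.
    """
    out = [ivw(instruments, direction)]
    if instruments.n_variants >= 3:
        out.append(egger(instruments, direction))
    else:
        logger.warning("%s: < 3 variants, MR-Egger omitted", instruments.disease)
    if instruments.n_variants >= 2:
        out.append(weighted_median(instruments, direction, seed=seed))
    else:
        logger.warning("%s: < 2 variants, weighted median omitted", instruments.disease)
    return out


def per_year_earlier(result: MrResult) -> MrResult:
    """Flip the convention from per-year-delay to per-year-earlier."""
    low, high = result.ci95
    return replace(
        result,
        or_per_year=1.0 / result.or_per_year,
        ci95=(1.0 / high, 1.0 / low),
    )


def gate_diseases(results: list[MrResult]) -> set[str]:
    """Diseases whose forward IVW estimate is causal and harmful.

    Gated in: forward p < 0.05 and OR per year of delay < 1 (delay
    protective, hence early maturation harmful).  Reverse-direction
    results are logged but never veto.
    """
    gated: set[str] = set()
    for res in results:
        if res.direction == "reverse":
            if res.p < 0.05:
                logger.info("%s: significant reverse-direction signal (p=%.3g), not a veto",
                            res.disease, res.p)
            continue
        if res.method != "ivw" and res.method != "wald":
            continue
        if res.causal_gate:
            gated.add(res.disease)
        else:
            logger.info("%s: gated out (OR=%.3f, p=%.3g)", res.disease, res.or_per_year, res.p)
    return gated


def read_gwas_table(path, disease: str = "") -> InstrumentSet:
    """Read a GWAS summary CSV: variant_id, beta_exp, se_exp, p_exp, beta_out, se_out."""
    df = pd.read_csv(path)
    renames = {
        "beta_exp": "beta_exposure",
        "se_exp": "se_exposure",
        "p_exp": "p_exposure",
        "beta_out": "beta_outcome",
        "se_out": "se_outcome",
    }
    df = df.rename(columns={k: v for k, v in renames.items() if k in df.columns})
    return InstrumentSet(disease, df)
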