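"""Levin-formula PAFs, attributable cases, and age-standardized rates.

The population attributable fraction combines exposure prevalence Pe
with the pooled relative risk RRx through Levin's formula,

    PAF = Pe*(RRx - 1) / (Pe*(RRx - 1) + 1),

and attributable cases are incidence times PAF, applied draw-wise so
uncertainty propagates through every aggregation.  Age-standardized
incidence rates (ASIR, cases per 100,000 person-years) use the WHO
World Standard population renormalized over adult ages (>= 20 years).

Incidence and burden tables are pandas DataFrames with identifier
columns (region, country, sex, age_group, disease, development), a
``population`` person-years column, and wide draw columns
``draw_0 .. draw_{N-1}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PER_100K = 100_000.0

#: WHO World Standard population weights (percent) by 5-year age band
WHO_WORLD_STANDARD = {
    "0-4": 8.86, "5-9": 8.69, "10-14": 8.60, "15-19": 8.47,
    "20-24": 8.22, "25-29": 7.93, "30-34": 7.61, "35-39": 7.15,
    "40-44": 6.59, "45-49": 6.04, "50-54": 5.37, "55-59": 4.55,
    "60-64": 3.72, "65-69": 2.96, "70-74": 2.21, "75-79": 1.52,
    "80-84": 0.91, "85+": 0.63,
}

#: adult 5-year bands, ordered (GBD-style: 20-80 in fives, then 85+)
ADULT_AGE_BANDS = (
    "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84", "85+",
)

#: collapse of 5-year bands into the reporting bands
COARSE_AGE_MAP = {
    **{b: "20-49" for b in ADULT_AGE_BANDS[:6]},
    **{b: "50-69" for b in ADULT_AGE_BANDS[6:10]},
    **{b: "70+" for b in ADULT_AGE_BANDS[10:]},
}

#: diseases confined to one sex
SEX_SPECIFIC_DISEASES = {"testicular_cancer": "male", "uterine_cancer": "female"}


@dataclass(frozen=True)
class StandardPopulation:
    """A set of age-band weights summing to one."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"standard-population weights sum to {total}, not 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")

    @classmethod
    def who_world(cls, min_age: int = 20) -> "StandardPopulation":
        """WHO World Standard weights renormalized over bands at or above ``min_age``."""
        kept = {
            band: w
            for band, w in WHO_WORLD_STANDARD.items()
            if int(band.split("-")[0].rstrip("+")) >= min_age
        }
        total = sum(kept.values())
        return cls({band: w / total for band, w in kept.items()})

    @property
    def age_bands(self) -> tuple[str, ...]:
        return tuple(self.weights)


def draw_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("draw_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def group_sum(df: pd.DataFrame, by: Sequence[str], value_cols: Sequence[str]) -> pd.DataFrame:
    """Sum ``value_cols`` within groups of ``by``, keeping columns wide.

    Wide draw tables make column-at-a-time groupby assembly quadratic in
    pandas, so the sum is done as one scatter-add on the value matrix.
    """
    by = list(by)
    value_cols = list(value_cols)
    if len(by) == 1:
        codes, uniques = pd.factorize(df[by[0]], sort=True)
        key_frame = pd.DataFrame({by[0]: uniques})
    else:
        keys = pd.MultiIndex.from_frame(df[by])
        codes, uniques = pd.factorize(keys, sort=True)
        key_frame = pd.MultiIndex.from_tuples(uniques, names=by).to_frame(index=False)
    mat = df[value_cols].to_numpy(dtype=float)
    out = np.zeros((len(key_frame), mat.shape[1]))
    np.add.at(out, codes, mat)
    return pd.concat([key_frame, pd.DataFrame(out, columns=value_cols)], axis=1)


def levin_paf(pe: float, rr: float) -> float:
    """Levin's attributable fraction Pe*(RR-1)/(Pe*(RR-1)+1).

    Strictly increasing in both arguments for RR > 1.  RR < 1
    (protective exposure) is refused: the attributable-fraction
    framework here admits harmful exposures only, and protective strata
    are excluded upstream.
    """
    if not 0.0 <= pe <= 1.0:
        raise ValueError(f"pe must be in [0,1], got {pe}")
    if rr <= 0:
        raise ValueError(f"rr must be positive, got {rr}")
    if rr < 1.0:
        raise ValueError(f"rr={rr} < 1: protective exposure, PAF refused")
    excess = pe * (rr - 1.0)
    return excess / (excess + 1.0)


def make_paf_table(
    pe_by_region_sex: Sequence,
    rr_by_disease: Mapping[str, float],
    diseases: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cross region/sex prevalences with per-disease RRs into PAF entries.

    ``pe_by_region_sex`` is a sequence of RegionPrevalence.  Strata with
    RR < 1 are excluded with a warning rather than given negative PAFs.
    Sex-specific diseases only produce entries for the applicable sex.
    """
    rows = []
    for disease, rr in rr_by_disease.items():
        if diseases is not None and disease not in diseases:
            continue
        if rr < 1.0:
            logger.warning("%s: pooled RR %.3f < 1, stratum excluded from PAF", disease, rr)
            continue
        only_sex = SEX_SPECIFIC_DISEASES.get(disease)
        for rp in pe_by_region_sex:
            if only_sex is not None and rp.sex != only_sex:
                continue
            rows.append(
                {
                    "disease": disease,
                    "sex": rp.sex,
                    "region": rp.region,
                    "pe": rp.pe,
                    "rr": rr,
                    "paf": levin_paf(rp.pe, rr),
                }
            )
    return pd.DataFrame(rows)


def attributable_cases(
    incidence: pd.DataFrame,
    pafs: pd.DataFrame,
    gated: set[str] | None = None,
) -> pd.DataFrame:
    """Multiply incidence draws by matching PAFs, draw-wise.

    ``pafs`` must carry one row per (disease, sex, region) present in
    the (gate-filtered) incidence table; a missing entry is an error
    naming the stratum.  Rows for a sex-specific disease in the
    inapplicable sex are dropped.
    """
    df = incidence.copy()
    if gated is not None:
        df = df[df["disease"].isin(gated)]
    for disease, sex in SEX_SPECIFIC_DISEASES.items():
        df = df[~((df["disease"] == disease) & (df["sex"] != sex))]
    df = df.reset_index(drop=True)
    merged = df.merge(
        pafs[["disease", "sex", "region", "paf"]],
        on=["disease", "sex", "region"],
        how="left",
        validate="many_to_one",
    )
    if merged["paf"].isna().any():
        bad = merged.loc[merged["paf"].isna(), ["disease", "sex", "region"]].drop_duplicates()
        strata = [tuple(r) for r in bad.itertuples(index=False)]
        raise KeyError(f"no PAF entry for strata: {strata}")
    cols = draw_columns(merged)
    merged[cols] = merged[cols].to_numpy() * merged["paf"].to_numpy()[:, None]
    return merged.copy()  # consolidate blocks after the wide assignment


def aggregate(burden: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Draw-wise sums of cases (and person-years) over strata.

    ``by`` may include ``age_band`` to collapse 5-year age groups into
    the coarse reporting bands 20-49 / 50-69 / 70+, or ``world`` for a
    grand total.  Draw counts must agree across rows.
    """
    df = burden.copy()
    cols = draw_columns(df)
    if not cols:
        raise ValueError("no draw columns to aggregate")
    if df[cols].isna().any().any():
        raise ValueError("inconsistent draw counts across cells")
    by = list(by)
    if "age_band" in by and "age_band" not in df.columns:
        df["age_band"] = df["age_group"].map(COARSE_AGE_MAP)
        if df["age_band"].isna().any():
            unknown = sorted(df.loc[df["age_band"].isna(), "age_group"].unique())
            raise ValueError(f"age groups without a coarse band: {unknown}")
    if "world" in by:
        df["world"] = "world"
    keep = cols + (["population"] if "population" in df.columns else [])
    return group_sum(df, by, keep)


def asir(
    cells: pd.DataFrame,
    std: StandardPopulation,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Direct age standardization, per draw.

    Within each group defined by ``by``, rates cases/population in each
    age band are weighted by the standard population and scaled to
    cases per 100,000 person-years:
    ASIR = sum_a w_a * (cases_a / pop_a) * 100,000.
    Every group must cover all bands of the standard; gaps are an error.
    """
    df = cells.copy()
    cols = draw_columns(df)
    if "population" not in df.columns:
        raise ValueError("ASIR needs a population column")
    by = list(by)
    group_keys = by if by else [()]
    if not by:
        df["_all"] = 0
        by = ["_all"]
    out_rows = []
    for key, grp in df.groupby(by, sort=True, observed=True):
        agg = group_sum(grp, ["age_group"], cols + ["population"]).set_index("age_group")
        missing = [b for b in std.age_bands if b not in agg.index]
        if missing:
            raise ValueError(f"group {key}: missing age bands {missing}")
        agg = agg.loc[list(std.age_bands)]
        w = np.array([std.weights[b] for b in std.age_bands])
        rates = agg[cols].to_numpy() / agg["population"].to_numpy()[:, None]
        asir_draws = PER_100K * (w[:, None] * rates).sum(axis=0)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(dict(zip(cols, asir_draws)))
        out_rows.append(row)
    out = pd.DataFrame(out_rows)
    return out.drop(columns=["_all"], errors="ignore")
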