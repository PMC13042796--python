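"""Synthetic input tables with known ground truth.

Stands in for the four real data sources of the burden pipeline — an
effect-estimate literature, GWAS summary statistics, prevalence
surveys, and a stratified incidence export with posterior draws — so
every downstream stage is testable without any download.  The
generator's job is statistical shape, not realism: magnitudes are
plausible for an early-maturation exposure (prevalence 5-25%, relative
risks 1.05-1.6, per-year-delay causal ORs of 0.81-0.95) but make no
attempt to imitate real GBD levels, allele frequencies, or LD.

Ground truth is carried on the config; the recovery of true relative
risks, causal slopes, and prevalences by the pipeline is the package's
main correctness check.  A single global seed is threaded to all
generators, with per-table substreams derived deterministically from
it, so an identical config reproduces byte-identical tables.

Incidence draws are log-normal around each cell's estimate (median-
centered), which keeps counts positive; draw index k is a coherent
scenario across cells, so draw-wise sums are valid before percentiles.
One region is generated survey-free by default to exercise the
risk-based prevalence-pooling path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from pafburden.attribution import ADULT_AGE_BANDS, SEX_SPECIFIC_DISEASES
from pafburden.mr import InstrumentSet
from pafburden.uncertainty import Z95

WORLD_BANK_REGIONS = (
    "east_asia_and_pacific",
    "europe_and_central_asia",
    "latin_america_and_caribbean",
    "middle_east_and_north_africa",
    "north_america",
    "south_asia",
    "sub_saharan_africa",
)

#: regions whose synthetic countries are classed as more developed
MORE_DEVELOPED_REGIONS = frozenset({"north_america", "europe_and_central_asia"})

DEFAULT_DISEASES = (
    "asthma",
    "type2_diabetes",
    "ischemic_heart_disease",
    "stroke",
    "testicular_cancer",
    "uterine_cancer",
    "depression",
)

DEFAULT_TRUE_RR = {
    "asthma": 1.35,
    "type2_diabetes": 1.06,
    "ischemic_heart_disease": 1.10,
    "stroke": 1.12,
    "testicular_cancer": 1.30,
    "uterine_cancer": 1.55,
    "depression": 1.25,
}

#: log-OR per 1-year delay in puberty timing (negative: delay protective)
DEFAULT_TRUE_MR_SLOPE = {
    "asthma": -0.055,
    "type2_diabetes": -0.207,
    "ischemic_heart_disease": -0.069,
    "stroke": -0.119,
    "testicular_cancer": -0.176,
    "uterine_cancer": -0.172,
    "depression": -0.054,
}

#: (incidence per 100,000 person-years in the 20-24 band, growth per band)
DISEASE_RATE_MODEL = {
    "asthma": (180.0, 0.93),
    "type2_diabetes": (90.0, 1.12),
    "ischemic_heart_disease": (25.0, 1.32),
    "stroke": (12.0, 1.33),
    "testicular_cancer": (9.0, 0.82),
    "uterine_cancer": (4.0, 1.20),
    "depression": (4200.0, 0.90),
}

#: multiplicative female rate factor (male factor is 2 - value)
FEMALE_RATE_FACTOR = {"asthma": 1.15, "depression": 1.45}

SEXES = ("female", "male")

# substream indices off the global seed
_SUB_TRUTH, _SUB_STUDIES, _SUB_INSTRUMENTS, _SUB_SURVEYS, _SUB_INCIDENCE = range(5)


def _band_start(band: str) -> int:
    return int(band.split("-")[0].rstrip("+"))


@dataclass
class SimConfig:
    """Ground-truth parameters and sizes for the synthetic world."""

    seed: int = 0
    n_regions: int = 7
    n_countries_per_region: int = 3
    diseases: tuple[str, ...] = DEFAULT_DISEASES
    true_rr: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_RR))
    true_prevalence: dict | None = None
    true_mr_slope: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_MR_SLOPE))
    true_reverse_slope: float = 0.0
    n_instruments: int = 30
    n_studies_per_disease: int = 10
    heterogeneity_tau: float = 0.1
    study_se_range: tuple[float, float] = (0.05, 0.25)
    exposure_beta_mean: float = 0.1
    exposure_beta_sd: float = 0.03
    exposure_se: float = 0.005
    outcome_se: float = 0.005
    n_draws: int = 1000
    draw_sigma: float = 0.1
    draw_sigma_shared: float = 0.08
    n_surveys_per_country: int = 2
    survey_n: int = 5000
    survey_free_regions: tuple[str, ...] = ("sub_saharan_africa",)
    prevalence_range: tuple[float, float] = (0.05, 0.25)
    male_prevalence_scale: float = 0.75
    age_groups: tuple[str, ...] = ADULT_AGE_BANDS
    population: dict | None = None

    def __post_init__(self) -> None:
        self.diseases = tuple(self.diseases)
        self.age_groups = tuple(self.age_groups)
        self.survey_free_regions = tuple(self.survey_free_regions)
        self.study_se_range = tuple(self.study_se_range)
        self.prevalence_range = tuple(self.prevalence_range)
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a nonnegative 31-bit integer")
        if not 1 <= self.n_regions <= len(WORLD_BANK_REGIONS):
            raise ValueError(f"n_regions must be in 1..{len(WORLD_BANK_REGIONS)}")
        if self.n_countries_per_region < 1 or self.n_instruments < 1 or self.n_studies_per_disease < 1:
            raise ValueError("counts must be >= 1")
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")
        if self.heterogeneity_tau < 0 or self.draw_sigma < 0 or self.draw_sigma_shared < 0:
            raise ValueError("spread parameters must be nonnegative")
        for d in self.diseases:
            if d not in self.true_rr:
                raise ValueError(f"no true_rr for disease '{d}'")
            if self.true_rr[d] <= 0:
                raise ValueError(f"true_rr for '{d}' must be positive")
            if d not in self.true_mr_slope:
                raise ValueError(f"no true_mr_slope for disease '{d}'")
        lo, hi = self.prevalence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("prevalence_range must lie in [0,1]")
        if not 0.0 < self.male_prevalence_scale <= 1.0:
            raise ValueError("male_prevalence_scale must be in (0,1]")
        if self.true_prevalence is not None:
            for key, p in self.true_prevalence.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"true_prevalence[{key}] outside [0,1]")
        starts = [_band_start(b) for b in self.age_groups]
        if starts != sorted(set(starts)):
            raise ValueError("age bands must be ordered and non-overlapping")
        if self.survey_n < 1:
            raise ValueError("survey_n must be >= 1")
        if self.population is not None and any(v <= 0 for v in self.population.values()):
            raise ValueError("populations must be positive")

    # ---- derived structure -------------------------------------------------

    @property
    def regions(self) -> tuple[str, ...]:
        return WORLD_BANK_REGIONS[: self.n_regions]

    def countries(self, region: str) -> tuple[str, ...]:
        return tuple(f"{region}_c{i + 1}" for i in range(self.n_countries_per_region))

    def development(self, region: str) -> str:
        return "more_developed" if region in MORE_DEVELOPED_REGIONS else "less_developed"

    def _rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])

    def resolved_true_prevalence(self) -> dict[tuple[str, str], float]:
        """True Pe per (country, sex); drawn once from the seed if not given.

        Male prevalence is scaled down by ``male_prevalence_scale``,
        reflecting the historically higher prevalence of early
        maturation among females.
        """
        if self.true_prevalence is not None:
            return dict(self.true_prevalence)
        rng = self._rng(_SUB_TRUTH)
        lo, hi = self.prevalence_range
        out = {}
        for region in self.regions:
            for country in self.countries(region):
                for sex in SEXES:
                    p = float(rng.uniform(lo, hi))
                    if sex == "male":
                        p *= self.male_prevalence_scale
                    out[(country, sex)] = p
        return out

    def stratum_population(self, region: str, country: str, sex: str, age_group: str) -> float:
        if self.population is not None:
            return float(self.population[(region, country, sex, age_group)])
        i = self.age_groups.index(age_group)
        return 2_000_000.0 * (1.0 - 0.045 * i)

    # ---- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["true_prevalence"] is not None:
            d["true_prevalence"] = {f"{c}|{s}": p for (c, s), p in d["true_prevalence"].items()}
        if d["population"] is not None:
            d["population"] = {"|".join(k): v for k, v in d["population"].items()}
        for key in ("diseases", "age_groups", "survey_free_regions", "study_se_range", "prevalence_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("true_prevalence") is not None:
            d["true_prevalence"] = {
                tuple(k.split("|")): v for k, v in d["true_prevalence"].items()
            }
        if d.get("population") is not None:
            d["population"] = {tuple(k.split("|")): v for k, v in d["population"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---- generators ------------------------------------------------------------


def simulate_study_effects(cfg: SimConfig) -> pd.DataFrame:
    """Epidemiological effect table: per disease, study log-effects around
    log(true_rr) with between-study spread ``heterogeneity_tau`` and
    per-study sampling SEs drawn from ``study_se_range``.  CIs are exact
    functions of the SE, so they round-trip through table readers."""
    rng = cfg._rng(_SUB_STUDIES)
    lo, hi = cfg.study_se_range
    rows = []
    types = ("RR", "OR", "HR")
    for disease in cfg.diseases:
        mu = np.log(cfg.true_rr[disease])
        for i in range(cfg.n_studies_per_disease):
            theta = mu + cfg.heterogeneity_tau * rng.standard_normal()
            se = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            y = theta + se * rng.standard_normal() if se > 0 else theta
            se_rec = max(se, 1e-12)
            rows.append(
                {
                    "disease": disease,
                    "study_id": f"{disease}_s{i + 1}",
                    "effect_type": types[i % 3],
                    "effect": np.exp(y),
                    "ci_low": np.exp(y - Z95 * se_rec),
                    "ci_high": np.exp(y + Z95 * se_rec),
                    "log_effect": y,
                    "se": se_rec,
                    "n": int(rng.integers(500, 50_000)),
                }
            )
    return pd.DataFrame(rows)


def simulate_instruments(cfg: SimConfig, disease: str, direction: str = "forward") -> InstrumentSet:
    """GWAS summary statistics for one disease's instruments.

    True per-allele exposure effects gamma_j are drawn once; observed
    exposure betas add noise ``exposure_se`` and outcome betas are
    slope * gamma_j plus noise ``outcome_se``.  Variants are mutually
    independent (no LD).  The reverse direction uses
    ``true_reverse_slope`` (0 by default: no reverse causation).
    """
    if disease not in cfg.diseases:
        raise ValueError(f"unknown disease '{disease}'")
    d_idx = cfg.diseases.index(disease)
    rng = cfg._rng(_SUB_INSTRUMENTS, d_idx, 0 if direction == "forward" else 1)
    slope = cfg.true_mr_slope[disease] if direction == "forward" else cfg.true_reverse_slope
    gamma = rng.normal(cfg.exposure_beta_mean, cfg.exposure_beta_sd, size=cfg.n_instruments)
    se_e = max(cfg.exposure_se, 1e-12)
    se_o = max(cfg.outcome_se, 1e-12)
    beta_exp = gamma + cfg.exposure_se * rng.standard_normal(cfg.n_instruments)
    beta_out = slope * gamma + cfg.outcome_se * rng.standard_normal(cfg.n_instruments)
    p_exp = 2.0 * stats.norm.sf(np.abs(beta_exp) / se_e)
    data = pd.DataFrame(
        {
            "variant_id": [f"rs{d_idx + 1:02d}{j + 1:04d}" for j in range(cfg.n_instruments)],
            "beta_exposure": beta_exp,
            "se_exposure": se_e,
            "p_exposure": p_exp,
            "beta_outcome": beta_out,
            "se_outcome": se_o,
        }
    )
    return InstrumentSet(disease, data)


def simulate_prevalence_surveys(cfg: SimConfig) -> pd.DataFrame:
    """Survey table: binomial-sampled prevalence per (country, sex).

    Regions listed in ``survey_free_regions`` get no surveys, so the
    pipeline must impute them by risk-based pooling.
    """
    rng = cfg._rng(_SUB_SURVEYS)
    truth = cfg.resolved_true_prevalence()
    rows = []
    for region in cfg.regions:
        if region in cfg.survey_free_regions:
            continue
        for country in cfg.countries(region):
            for sex in SEXES:
                p = truth[(country, sex)]
                for k in range(cfg.n_surveys_per_country):
                    x = int(rng.binomial(cfg.survey_n, p))
                    rows.append(
                        {
                            "country": country,
                            "region": region,
                            "sex": sex,
                            "survey_id": f"{country}_{sex}_s{k + 1}",
                            "prevalence": x / cfg.survey_n,
                            "n": cfg.survey_n,
                            "period": "1960s-2000s",
                        }
                    )
    return pd.DataFrame(rows)


def true_mean_cases(cfg: SimConfig) -> pd.DataFrame:
    """Noise-free incidence strata with the ground-truth mean case count.

    Rates follow a per-disease geometric age gradient with a mild sex
    factor; sex-specific diseases appear only in the applicable sex.
    """
    rows = []
    for region in cfg.regions:
        for country in cfg.countries(region):
            for sex in SEXES:
                for a_idx, age in enumerate(cfg.age_groups):
                    pop = cfg.stratum_population(region, country, sex, age)
                    for disease in cfg.diseases:
                        only = SEX_SPECIFIC_DISEASES.get(disease)
                        if only is not None and sex != only:
                            continue
                        base, growth = DISEASE_RATE_MODEL.get(disease, (50.0, 1.0))
                        f = FEMALE_RATE_FACTOR.get(disease, 1.0)
                        sex_factor = f if sex == "female" else 2.0 - f
                        rate = base * growth**a_idx * sex_factor / 100_000.0
                        rows.append(
                            {
                                "region": region,
                                "country": country,
                                "sex": sex,
                                "age_group": age,
                                "disease": disease,
                                "development": cfg.development(region),
                                "population": pop,
                                "true_cases": rate * pop,
                            }
                        )
    return pd.DataFrame(rows)


def simulate_incidence(cfg: SimConfig) -> pd.DataFrame:
    """Stratified incidence with ``n_draws`` log-normal Monte-Carlo draws.

    Each cell's point estimate ``val`` is log-normal around the true
    mean, and its draws are log-normal around ``val`` (median-centered),
    mirroring posterior draws around a modeled estimate.  The log-scale
    noise has two components: a cell-level term with SD ``draw_sigma``,
    independent across strata, and a per-disease term with SD
    ``draw_sigma_shared`` that is common to every stratum of a disease
    within a draw — shared modeling uncertainty, without which
    aggregate-level UIs would collapse as independent cell noise
    averages out.  Draw index k is aligned across cells, so a draw-wise
    sum is a coherent world.
    """
    rng = cfg._rng(_SUB_INCIDENCE)
    df = true_mean_cases(cfg)
    n = len(df)
    sigma = cfg.draw_sigma
    sigma_s = cfg.draw_sigma_shared
    d_idx = df["disease"].map({d: i for i, d in enumerate(cfg.diseases)}).to_numpy()
    true = df.pop("true_cases").to_numpy()
    shared0 = rng.standard_normal(len(cfg.diseases))
    shared_k = rng.standard_normal((len(cfg.diseases), cfg.n_draws))
    val = true * np.exp(sigma * rng.standard_normal(n) + sigma_s * shared0[d_idx])
    draws = val[:, None] * np.exp(
        sigma * rng.standard_normal((n, cfg.n_draws)) + sigma_s * shared_k[d_idx, :]
    )
    df["val"] = val
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=1)
    df["lower"], df["upper"] = lo, hi
    draw_df = pd.DataFrame(draws, columns=[f"draw_{k}" for k in range(cfg.n_draws)])
    return pd.concat([df.reset_index(drop=True), draw_df], axis=1)


# ---- file output -----------------------------------------------------------


def write_gbd_csv(incidence: pd.DataFrame, path) -> None:
    """Write incidence in the GBD results-tool export dialect (plus
    region/development/population/draw columns needed by the pipeline)."""
    from pafburden.attribution import draw_columns

    out = pd.DataFrame(
        {
            "measure_name": "Incidence",
            "location_name": incidence["country"],
            "sex_name": incidence["sex"].str.capitalize(),
            "age_name": incidence["age_group"],
            "cause_name": incidence["disease"],
            "metric_name": "Number",
            "year": 2021,
            "val": incidence["val"],
            "upper": incidence["upper"],
            "lower": incidence["lower"],
            "region": incidence["region"],
            "development": incidence["development"],
            "population": incidence["population"],
        }
    )
    out = pd.concat([out, incidence[draw_columns(incidence)]], axis=1)
    out.to_csv(path, index=False)


def read_gbd_csv(path) -> pd.DataFrame:
    """Read the GBD-dialect incidence CSV back into pipeline form."""
    df = pd.read_csv(path)
    rename = {
        "location_name": "country",
        "sex_name": "sex",
        "age_name": "age_group",
        "cause_name": "disease",
    }
    df = df.rename(columns=rename)
    df["sex"] = df["sex"].str.lower()
    drop = [c for c in ("measure_name", "metric_name", "year") if c in df.columns]
    return df.drop(columns=drop)


def write_tables(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Generate and write all four input tables plus the config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    studies = simulate_study_effects(cfg)
    paths["studies"] = outdir / "studies.csv"
    studies.to_csv(paths["studies"], index=False)

    gwas_frames = []
    for disease in cfg.diseases:
        for direction in ("forward", "reverse"):
            inst = simulate_instruments(cfg, disease, direction)
            frame = inst.data.copy()
            frame.insert(0, "disease", disease)
            frame.insert(1, "direction", direction)
            gwas_frames.append(frame)
    paths["instruments"] = outdir / "instruments.csv"
    pd.concat(gwas_frames, ignore_index=True).to_csv(paths["instruments"], index=False)

    paths["surveys"] = outdir / "surveys.csv"
    simulate_prevalence_surveys(cfg).to_csv(paths["surveys"], index=False)

    paths["incidence"] = outdir / "incidence.csv"
    write_gbd_csv(simulate_incidence(cfg), paths["incidence"])

    paths["config"] = outdir / "sim.yaml"
    cfg.to_yaml(paths["config"])
    return paths
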