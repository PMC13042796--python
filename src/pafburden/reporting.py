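"""Assemble burden tables and drive the end-to-end pipeline.

Outputs mirror a comparative-risk-assessment report: attributable
cases (in thousands) by sex and disease, by development status and
coarse age band, and by geographic region with overall PAFs and
age-standardized rates.  All internal math is unrounded and draw-wise;
rounding to one decimal happens only when tables are written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pafburden import attribution, meta, mr, prevalence, synthetic
from pafburden.attribution import StandardPopulation, draw_columns
from pafburden.uncertainty import summarize_ui

logger = logging.getLogger(__name__)

THOUSANDS = 1_000.0


@dataclass
class BurdenReport:
    """Report tables plus the metadata needed to trace every number."""

    tables: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        """Write one CSV per table (rounded to one decimal) and a JSON
        run summary; regeneration from the same report is byte-identical."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            out = table.copy()
            num = out.select_dtypes(include=[np.number]).columns
            out[num] = out[num].round(1)
            out.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "run_summary.json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True, default=str) + "\n"
        )


def _summarize_rows(df: pd.DataFrame, value: str, scale: float = 1.0) -> pd.DataFrame:
    """Collapse wide draw columns into point/lo/hi columns named after ``value``."""
    cols = draw_columns(df)
    out = df.drop(columns=cols).copy()
    triples = [summarize_ui(row) for row in df[cols].to_numpy() / scale]
    out[value] = [t[0] for t in triples]
    out[f"{value}_lo"] = [t[1] for t in triples]
    out[f"{value}_hi"] = [t[2] for t in triples]
    return out


def population_table(incidence: pd.DataFrame) -> pd.DataFrame:
    """Person-years per (region, country, development, sex, age band)."""
    keys = ["region", "country", "development", "sex", "age_group"]
    return incidence[keys + ["population"]].drop_duplicates(subset=keys).reset_index(drop=True)


def _asir_rows(
    burden: pd.DataFrame,
    pop: pd.DataFrame,
    std: StandardPopulation,
    by: Sequence[str],
) -> pd.DataFrame:
    """ASIR draws for each group in ``by``.

    Case draws are summed per (group, age band).  The person-years
    denominator comes from the population table filtered only on the
    group keys it knows about (region, country, sex, development) — so
    a disease-level ASIR is rated against the whole population, and a
    sex-specific one against that sex.
    """
    by = list(by)
    cols = draw_columns(burden)
    cases = attribution.group_sum(burden, by + ["age_group"], cols)
    pop_keys = [k for k in by if k in ("region", "country", "sex", "development")]
    rows = []
    for key, grp in cases.groupby(by, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        sel = pop
        for k, v in zip(by, key):
            if k in pop_keys:
                sel = sel[sel[k] == v]
        denom = sel.groupby("age_group", observed=True)["population"].sum()
        cells = grp.merge(denom.rename("population"), on="age_group", how="left")
        if cells["population"].isna().any():
            raise ValueError(f"group {key}: no population for some age bands")
        res = attribution.asir(cells, std)
        for k, v in zip(by, key):
            res[k] = v
        rows.append(res)
    return pd.concat(rows, ignore_index=True)[by + draw_columns(burden)]


def _paf_percent(
    burden: pd.DataFrame, incidence: pd.DataFrame, keys: Sequence[str]
) -> pd.DataFrame:
    """Overall PAF (%) per group: attributable over total incident cases
    of the gated diseases, on point estimates (draw means)."""
    keys = list(keys)
    cols = draw_columns(burden)
    attr = attribution.group_sum(burden, keys, cols).set_index(keys).mean(axis=1)
    inc = incidence[incidence["disease"].isin(burden["disease"].unique())]
    tot = attribution.group_sum(inc, keys, draw_columns(inc)).set_index(keys).mean(axis=1)
    out = (100.0 * attr / tot).rename("paf_percent").reset_index()
    return out


def make_tables(
    burden: pd.DataFrame,
    incidence: pd.DataFrame,
    pafs: pd.DataFrame,
    std: StandardPopulation | None = None,
) -> BurdenReport:
    """Build the three report tables plus the overall PAF-by-sex summary.

    ``burden`` carries attributable-case draws per stratum; ``incidence``
    the matching total-incidence draws (for PAF denominators) and the
    population column; ``pafs`` the (disease, sex, region) Levin entries.
    """
    std = std or StandardPopulation.who_world()
    pop = population_table(incidence)
    cols = draw_columns(burden)

    # --- table 1: sex x disease, cases (thousands) and ASIR ---------------
    pieces = []
    for label, sub in (("total", burden), ("female", burden[burden["sex"] == "female"]),
                       ("male", burden[burden["sex"] == "male"])):
        if sub.empty:
            continue
        for disease_level in (True, False):
            if disease_level:
                grp_cases = attribution.group_sum(sub, ["disease"], cols)
                grp_cases["sex_group"] = label
                sub2 = sub.copy()
                if label != "total":
                    asir_by = ["disease", "sex"]
                else:
                    asir_by = ["disease"]
                rates = _asir_rows(sub2, pop, std, asir_by)
                rates = attribution.group_sum(rates, ["disease"], cols)
            else:
                grp_cases = sub[cols].sum().to_frame().T
                grp_cases.insert(0, "disease", "total_causes")
                grp_cases["sex_group"] = label
                sub2 = sub.copy()
                sub2["world"] = "world"
                asir_by = ["world"] if label == "total" else ["sex"]
                rates = _asir_rows(sub2, pop, std, asir_by)[cols]
                rates.insert(0, "disease", "total_causes")
            cases_summ = _summarize_rows(grp_cases, "cases_thousands", scale=THOUSANDS)
            asir_summ = _summarize_rows(rates, "asir")
            merged = cases_summ.merge(asir_summ, on="disease")
            pieces.append(merged)
    table1 = pd.concat(pieces, ignore_index=True)[
        ["disease", "sex_group", "cases_thousands", "cases_thousands_lo",
         "cases_thousands_hi", "asir", "asir_lo", "asir_hi"]
    ]

    # --- table 2: disease x development status and coarse age band --------
    dev = attribution.aggregate(burden, ["disease", "development"])
    dev = _summarize_rows(dev.drop(columns=["population"], errors="ignore"),
                          "cases_thousands", scale=THOUSANDS)
    dev = dev.rename(columns={"development": "group"})
    dev["group_type"] = "development"
    age = attribution.aggregate(burden, ["disease", "age_band"])
    age = _summarize_rows(age.drop(columns=["population"], errors="ignore"),
                          "cases_thousands", scale=THOUSANDS)
    age = age.rename(columns={"age_band": "group"})
    age["group_type"] = "age_band"
    table2 = pd.concat([dev, age], ignore_index=True)[
        ["disease", "group_type", "group", "cases_thousands",
         "cases_thousands_lo", "cases_thousands_hi"]
    ]

    # --- table 3: geography (regions, development classes, world) --------
    rows3 = []
    groupings = [("region", "region"), ("development", "development")]
    for group_type, key in groupings:
        agg = attribution.aggregate(burden, [key]).drop(columns=["population"], errors="ignore")
        cases = _summarize_rows(agg, "cases_thousands", scale=THOUSANDS)
        rates = _summarize_rows(_asir_rows(burden, pop, std, [key]), "asir")
        paf = _paf_percent(burden, incidence, [key])
        merged = cases.merge(rates, on=key).merge(paf, on=key)
        merged = merged.rename(columns={key: "area"})
        merged["group_type"] = group_type
        rows3.append(merged)
    world = burden.copy()
    world["world"] = "world"
    agg = attribution.aggregate(world, ["world"]).drop(columns=["population"], errors="ignore")
    cases = _summarize_rows(agg, "cases_thousands", scale=THOUSANDS)
    rates = _summarize_rows(_asir_rows(world, pop, std, ["world"]), "asir")
    inc_world = incidence.copy()
    inc_world["world"] = "world"
    paf = _paf_percent(world, inc_world, ["world"])
    merged = cases.merge(rates, on="world").merge(paf, on="world").rename(columns={"world": "area"})
    merged["group_type"] = "world"
    rows3.append(merged)
    table3 = pd.concat(rows3, ignore_index=True)[
        ["area", "group_type", "cases_thousands", "cases_thousands_lo",
         "cases_thousands_hi", "asir", "asir_lo", "asir_hi", "paf_percent"]
    ]

    paf_sex = _paf_percent(burden, incidence, ["sex"])

    return BurdenReport(
        tables={
            "table1_sex_disease": table1,
            "table2_development_age": table2,
            "table3_regions": table3,
            "paf_by_sex": paf_sex,
            "paf_entries": pafs.copy(),
        }
    )


# ---- pipeline --------------------------------------------------------------


def pool_relative_risks(studies: pd.DataFrame) -> dict[str, meta.PooledEffect]:
    """Pool each disease's study effects with the I-squared model rule."""
    pooled = {}
    for disease, grp in studies.groupby("disease", observed=True):
        effects = [
            meta.StudyEffect(
                disease=disease,
                study_id=str(r.study_id),
                log_effect=float(r.log_effect) if "log_effect" in grp.columns
                else float(np.log(r.effect)),
                se=float(r.se) if "se" in grp.columns
                else meta.ci_to_se(float(r.ci_low), float(r.ci_high)),
                effect_type=str(r.effect_type),
            )
            for r in grp.itertuples(index=False)
        ]
        pooled[disease] = meta.pool_auto(effects)
    return pooled


def run_mr_gate(cfg: synthetic.SimConfig) -> tuple[list[mr.MrResult], set[str]]:
    """Bidirectional IVW per disease; gate on the forward direction."""
    results = []
    for disease in cfg.diseases:
        for direction in ("forward", "reverse"):
            inst = synthetic.simulate_instruments(cfg, disease, direction)
            results.append(mr.ivw(inst, direction))
    return results, mr.gate_diseases(results)


def pool_all_prevalence(
    surveys: pd.DataFrame,
    incidence: pd.DataFrame,
    regions: Sequence[str],
) -> tuple[list[prevalence.RegionPrevalence], dict]:
    """Three-tier prevalence pooling over the whole world.

    Within-country inverse-variance pooling, then geographical pooling
    with sample-size-times-case-count weights (all-cause case counts),
    then risk-based regression imputation for regions without surveys
    (predictor: the region's all-cause incidence rate).
    """
    case_counts = incidence.groupby("country", observed=True)["val"].sum().to_dict()
    pop = population_table(incidence)
    region_rate = (
        incidence.groupby("region", observed=True)["val"].sum()
        / pop.groupby("region", observed=True)["population"].sum()
    ).to_dict()

    records = prevalence.records_from_frame(surveys)
    by_country: dict[tuple[str, str], list] = {}
    for rec in records:
        by_country.setdefault((rec.country, rec.sex), []).append(rec)
    country_pooled = [prevalence.pool_within_country(v) for v in by_country.values()]

    surveyed_regions = sorted({r.region for r in country_pooled})
    out: list[prevalence.RegionPrevalence] = []
    methods: dict[str, str] = {}
    for sex in synthetic.SEXES:
        known = []
        for region in surveyed_regions:
            recs = [r for r in country_pooled if r.region == region and r.sex == sex]
            if recs:
                known.append(prevalence.pool_geographical(recs, case_counts))
                methods[f"{region}/{sex}"] = "geographical"
        out.extend(known)
        for region in regions:
            if region in surveyed_regions:
                continue
            imputed = prevalence.pool_risk_based(known, region_rate, region)
            out.append(imputed)
            methods[f"{region}/{sex}"] = "risk_based"
            logger.info("region %s (%s): prevalence imputed by risk-based pooling", region, sex)
    return out, methods


def run_pipeline(cfg: synthetic.SimConfig, outdir=None) -> BurdenReport:
    """Execute simulate -> pool-rr -> mr-gate -> pool-prevalence -> paf ->
    burden -> report on one synthetic world, logging every gate and
    pooling-model decision."""
    logger.info("simulating input tables (seed=%d, n_draws=%d)", cfg.seed, cfg.n_draws)
    studies = synthetic.simulate_study_effects(cfg)
    incidence = synthetic.simulate_incidence(cfg)
    surveys = synthetic.simulate_prevalence_surveys(cfg)

    pooled = pool_relative_risks(studies)
    for disease, p in pooled.items():
        logger.info("%s: pooled RR %.3f (%s model, I2=%.1f%%)", disease, p.rr, p.model, p.i2)

    mr_results, gated = run_mr_gate(cfg)
    logger.info("causal gate passed by: %s", sorted(gated))

    pe_list, pe_methods = pool_all_prevalence(surveys, incidence, cfg.regions)

    rr_by_disease = {d: pooled[d].rr for d in sorted(gated)}
    pafs = attribution.make_paf_table(pe_list, rr_by_disease)
    # a gated disease whose pooled RR fell below 1 has no PAF entries:
    # it leaves the burden calculation entirely (protective strata refused)
    burdened = gated & set(pafs["disease"].unique() if len(pafs) else [])
    burden = attribution.attributable_cases(incidence, pafs, gated=burdened)

    report = make_tables(burden, incidence, pafs)
    cfg_yaml = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    report.metadata = {
        "seed": cfg.seed,
        "n_draws": cfg.n_draws,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "gate": {r.disease: bool(r.causal_gate) for r in mr_results if r.direction == "forward"},
        "mr_or_per_year": {
            r.disease: r.or_per_year for r in mr_results if r.direction == "forward"
        },
        "pooling_model": {d: p.model for d, p in pooled.items()},
        "pooled_rr": {d: p.rr for d, p in pooled.items()},
        "prevalence_method": pe_methods,
        "diseases_gated": sorted(gated),
        "diseases_burdened": sorted(burdened),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta.pooled_to_frame(pooled.values()).to_csv(outdir / "pooled_rr.csv", index=False)
        pd.DataFrame(
            [
                {
                    "disease": r.disease,
                    "direction": r.direction,
                    "method": r.method,
                    "or_per_year": r.or_per_year,
                    "ci_low": r.ci95[0],
                    "ci_high": r.ci95[1],
                    "p": r.p,
                    "gated": r.causal_gate,
                }
                for r in mr_results
            ]
        ).to_csv(outdir / "mr_results.csv", index=False)
        pd.DataFrame([vars(r) for r in pe_list]).to_csv(outdir / "pe.csv", index=False)
        pafs.to_csv(outdir / "paf.csv", index=False)
        (outdir / "gated.txt").write_text("\n".join(sorted(gated)) + "\n")
        report.write(outdir)
    return report
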