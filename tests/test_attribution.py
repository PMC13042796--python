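"""Levin PAFs, attributable cases, aggregation, and ASIR."""

import numpy as np
import pandas as pd
import pytest

from pafburden.attribution import (
    ADULT_AGE_BANDS,
    StandardPopulation,
    aggregate,
    asir,
    attributable_cases,
    draw_columns,
    levin_paf,
    make_paf_table,
)
from pafburden.prevalence import RegionPrevalence


def make_cells(rows, draws):
    """Build an incidence frame from (ids, draw-list) pairs."""
    frame = pd.DataFrame(rows)
    draw_df = pd.DataFrame(np.asarray(draws, dtype=float),
                           columns=[f"draw_{k}" for k in range(len(draws[0]))])
    return pd.concat([frame, draw_df], axis=1)


class TestLevin:
    def test_zero_prevalence_zero_paf(self):
        assert levin_paf(0.0, 2.5) == 0.0

    def test_unit_rr_zero_paf(self):
        assert levin_paf(0.4, 1.0) == 0.0

    def test_direct_arithmetic(self):
        assert levin_paf(0.2, 2.0) == pytest.approx(0.2 / 1.2, abs=1e-15)

    def test_protective_rr_refused(self):
        with pytest.raises(ValueError, match="protective"):
            levin_paf(0.2, 0.8)

    def test_strict_monotonicity_on_grid(self):
        pes = np.linspace(0.01, 0.99, 50)
        rrs = np.linspace(1.01, 5.0, 50)
        grid = np.array([[levin_paf(pe, rr) for rr in rrs] for pe in pes])
        assert (np.diff(grid, axis=0) > 0).all()  # increasing in pe
        assert (np.diff(grid, axis=1) > 0).all()  # increasing in rr


class TestPafTable:
    def pe_rows(self):
        return [RegionPrevalence("r1", "female", 0.2, "geographical"),
                RegionPrevalence("r1", "male", 0.1, "geographical")]

    def test_entries_apply_levin(self):
        table = make_paf_table(self.pe_rows(), {"stroke": 1.5})
        row = table[(table.sex == "female")].iloc[0]
        assert row.paf == pytest.approx(levin_paf(0.2, 1.5))

    def test_sex_specific_disease_single_sex(self):
        table = make_paf_table(self.pe_rows(), {"uterine_cancer": 1.5})
        assert set(table.sex) == {"female"}

    def test_protective_rr_excluded_with_warning(self, caplog):
        table = make_paf_table(self.pe_rows(), {"stroke": 0.9, "asthma": 1.2})
        assert set(table.disease) == {"asthma"}


class TestAttributableCases:
    def incidence(self):
        return make_cells(
            [
                {"disease": "stroke", "sex": "female", "region": "r1",
                 "age_group": "20-24", "population": 1000.0},
                {"disease": "stroke", "sex": "male", "region": "r1",
                 "age_group": "20-24", "population": 1000.0},
            ],
            [[10.0, 20.0, 30.0], [8.0, 16.0, 24.0]],
        )

    def test_zero_paf_zeroes_all_draws(self):
        pafs = pd.DataFrame(
            {"disease": ["stroke"] * 2, "sex": ["female", "male"],
             "region": ["r1"] * 2, "paf": [0.0, 0.0]}
        )
        out = attributable_cases(self.incidence(), pafs)
        assert (out[draw_columns(out)].to_numpy() == 0).all()

    def test_hand_multiplication_oracle(self):
        pafs = pd.DataFrame(
            {"disease": ["stroke"] * 2, "sex": ["female", "male"],
             "region": ["r1"] * 2, "paf": [0.1, 0.25]}
        )
        out = attributable_cases(self.incidence(), pafs)
        got = out.sort_values("sex")[draw_columns(out)].to_numpy()
        expected = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_missing_paf_names_stratum(self):
        pafs = pd.DataFrame(
            {"disease": ["stroke"], "sex": ["female"], "region": ["r1"], "paf": [0.1]}
        )
        with pytest.raises(KeyError, match="male"):
            attributable_cases(self.incidence(), pafs)

    def test_attributable_never_exceeds_total(self):
        pafs = pd.DataFrame(
            {"disease": ["stroke"] * 2, "sex": ["female", "male"],
             "region": ["r1"] * 2, "paf": [0.9, 0.5]}
        )
        inc = self.incidence()
        out = attributable_cases(inc, pafs)
        assert (out[draw_columns(out)].to_numpy() <= inc[draw_columns(inc)].to_numpy()).all()


class TestAggregate:
    def burden(self):
        rows, draws = [], []
        for region in ("r1", "r2"):
            for sex in ("female", "male"):
                for age in ADULT_AGE_BANDS:
                    rows.append({"disease": "stroke", "sex": sex, "region": region,
                                 "age_group": age, "population": 1000.0})
                    draws.append(np.random.default_rng(len(rows)).uniform(1, 9, 4))
        return make_cells(rows, draws)

    def test_single_cell_identity(self):
        df = self.burden().iloc[:1]
        out = aggregate(df, ["disease"])
        np.testing.assert_allclose(out[draw_columns(out)].to_numpy()[0],
                                   df[draw_columns(df)].to_numpy()[0])

    def test_grouping_order_invariance(self):
        df = self.burden()
        direct = aggregate(df, ["disease"])[draw_columns(df)].to_numpy()
        staged = aggregate(aggregate(df, ["disease", "region"]), ["disease"])
        np.testing.assert_allclose(staged[draw_columns(df)].to_numpy(), direct, rtol=1e-14)
        staged2 = aggregate(aggregate(df, ["disease", "sex", "age_group"]), ["disease"])
        np.testing.assert_allclose(staged2[draw_columns(df)].to_numpy(), direct, rtol=1e-14)

    def test_age_band_collapse(self):
        out = aggregate(self.burden(), ["age_band"])
        assert sorted(out["age_band"]) == ["20-49", "50-69", "70+"]

    def test_world_total(self):
        df = self.burden()
        out = aggregate(df, ["world"])
        np.testing.assert_allclose(out[draw_columns(df)].to_numpy()[0],
                                   df[draw_columns(df)].to_numpy().sum(axis=0))

    def test_nan_draws_rejected(self):
        df = self.burden()
        df.loc[0, "draw_0"] = np.nan
        with pytest.raises(ValueError, match="draw counts"):
            aggregate(df, ["disease"])


class TestAsir:
    def test_uniform_rates_invariant_to_weights(self):
        std = StandardPopulation.who_world()
        rate = 0.002
        rows, draws = [], []
        for age in std.age_bands:
            pop = 1000.0 + 100 * len(rows)
            rows.append({"age_group": age, "population": pop})
            draws.append([rate * pop] * 3)
        out = asir(make_cells(rows, draws), std)
        np.testing.assert_allclose(out[draw_columns(out)].to_numpy(), rate * 1e5)

    def test_two_band_toy(self):
        std = StandardPopulation({"20-24": 0.25, "25-29": 0.75})
        cells = make_cells(
            [{"age_group": "20-24", "population": 1000.0},
             {"age_group": "25-29", "population": 1000.0}],
            [[1.0], [3.0]],
        )
        out = asir(cells, std)
        assert out["draw_0"].iloc[0] == pytest.approx(
            1e5 * (0.25 * 0.001 + 0.75 * 0.003)
        )

    def test_matches_direct_standardization_oracle(self, rng):
        """Equality with an independently coded direct-standardization routine."""
        bands = list(ADULT_AGE_BANDS)
        raw = rng.uniform(0.5, 2.0, len(bands))
        std = StandardPopulation(dict(zip(bands, raw / raw.sum())))
        for _ in range(20):
            pops = rng.uniform(1e3, 1e6, len(bands))
            draws = rng.uniform(0, 500, (len(bands), 5))
            cells = make_cells(
                [{"age_group": b, "population": p} for b, p in zip(bands, pops)],
                draws,
            )
            # oracle: explicit loop over bands and draws
            expected = np.zeros(5)
            for k in range(5):
                total = 0.0
                for i, b in enumerate(bands):
                    total += std.weights[b] * draws[i, k] / pops[i]
                expected[k] = total * 1e5
            got = asir(cells, std)[draw_columns(cells)].to_numpy()[0]
            np.testing.assert_allclose(got, expected, atol=1e-10, rtol=1e-12)

    def test_split_band_invariance(self):
        # splitting a band evenly with equal rates leaves ASIR unchanged
        std = StandardPopulation({"20-24": 0.4, "25-29": 0.6})
        whole = make_cells(
            [{"age_group": "20-24", "population": 2000.0},
             {"age_group": "25-29", "population": 1000.0}],
            [[4.0], [3.0]],
        )
        split = make_cells(
            [{"age_group": "20-24", "population": 1000.0},
             {"age_group": "20-24", "population": 1000.0},
             {"age_group": "25-29", "population": 1000.0}],
            [[2.0], [2.0], [3.0]],
        )
        assert asir(whole, std)["draw_0"].iloc[0] == pytest.approx(
            asir(split, std)["draw_0"].iloc[0]
        )

    def test_missing_band_is_an_error(self):
        std = StandardPopulation({"20-24": 0.5, "25-29": 0.5})
        cells = make_cells([{"age_group": "20-24", "population": 1000.0}], [[1.0]])
        with pytest.raises(ValueError, match="25-29"):
            asir(cells, std)


def test_who_standard_renormalization():
    std = StandardPopulation.who_world()
    assert set(std.age_bands) == set(ADULT_AGE_BANDS)
    assert sum(std.weights.values()) == pytest.approx(1.0)
    # older bands carry less weight than younger ones
    assert std.weights["20-24"] > std.weights["85+"]
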