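"""Wald ratio, IVW, sensitivity estimators, and the causal gate."""

import math

import numpy as np
import pandas as pd
import pytest

from pafburden.mr import (
    InstrumentSet,
    MrResult,
    egger,
    gate_diseases,
    ivw,
    per_year_earlier,
    sensitivity_estimates,
    wald_ratio,
    weighted_median,
)


def make_instruments(beta_exp, beta_out, se_out=0.05, se_exp=0.01, disease="stroke"):
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    return InstrumentSet(
        disease,
        pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(len(beta_exp))],
                "beta_exposure": beta_exp,
                "se_exposure": np.full(len(beta_exp), se_exp),
                "beta_outcome": beta_out,
                "se_outcome": np.full(len(beta_exp), se_out),
            }
        ),
    )


class TestWaldRatio:
    def test_null_outcome_gives_unit_or(self):
        res = wald_ratio({"beta_exposure": 0.5, "se_exposure": 0.01,
                          "beta_outcome": 0.0, "se_outcome": 0.05})
        assert res.or_per_year == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        res = wald_ratio({"beta_exposure": 1.0, "se_exposure": 0.01,
                          "beta_outcome": -0.2, "se_outcome": 0.05})
        assert res.log_or == pytest.approx(-0.2)
        assert res.or_per_year == pytest.approx(math.exp(-0.2), abs=1e-6)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError, match="beta_exposure"):
            wald_ratio({"beta_exposure": 0.0, "se_exposure": 0.01,
                        "beta_outcome": 0.1, "se_outcome": 0.05})

    def test_delta_se_matches_monte_carlo(self, rng):
        """First-order delta SE of the ratio vs direct simulation at small noise."""
        be, so = 0.8, 0.02
        slope = -0.3
        sims = (slope * be + so * rng.standard_normal(200_000)) / be
        res = wald_ratio({"beta_exposure": be, "se_exposure": 1e-9,
                          "beta_outcome": slope * be, "se_outcome": so})
        delta_se = (math.log(res.ci95[1]) - math.log(res.ci95[0])) / (2 * 1.959964)
        assert delta_se == pytest.approx(sims.std(), rel=0.10)


class TestIvw:
    def test_noiseless_common_slope_recovered_exactly(self):
        be = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        res = ivw(make_instruments(be, -0.25 * be))
        assert res.log_or == pytest.approx(-0.25, abs=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-20)

    def test_matches_weighted_least_squares_oracle(self, rng):
        """Zero-intercept WLS normal equations, solved independently."""
        be = rng.uniform(0.05, 0.4, 5)
        bo = -0.2 * be + rng.normal(0, 0.05, 5)
        so = rng.uniform(0.02, 0.1, 5)
        inst = make_instruments(be, bo)
        inst.data["se_outcome"] = so
        w = 1.0 / so**2
        slope_oracle = np.sum(w * be * bo) / np.sum(w * be**2)
        se_oracle = math.sqrt(1.0 / np.sum(w * be**2))
        res = ivw(inst)
        assert res.log_or == pytest.approx(slope_oracle, abs=1e-12)
        obs_se = (math.log(res.ci95[1]) - math.log(res.ci95[0])) / (2 * 1.959964)
        assert obs_se == pytest.approx(se_oracle, abs=1e-9)

    def test_single_variant_degenerates_to_wald(self):
        inst = make_instruments([0.3], [-0.06])
        assert ivw(inst).log_or == pytest.approx(wald_ratio(inst.data.iloc[0]).log_or)

    @pytest.mark.parametrize("c", [0.5, 2.0, -1.0])
    def test_equivariance_under_exposure_rescaling(self, c):
        be = np.array([0.1, 0.2, 0.3])
        bo = np.array([-0.02, -0.05, -0.055])
        base = ivw(make_instruments(be, bo))
        scaled = ivw(make_instruments(c * be, bo))
        assert scaled.log_or == pytest.approx(base.log_or / c, abs=1e-12)


class TestSensitivity:
    def test_egger_equals_ivw_without_pleiotropy(self):
        be = np.array([0.1, 0.18, 0.26, 0.34, 0.4])
        inst = make_instruments(be, -0.3 * be)
        res_egger = egger(inst)
        assert res_egger.log_or == pytest.approx(-0.3, abs=1e-10)
        assert res_egger.intercept == pytest.approx(0.0, abs=1e-12)

    def test_weighted_median_equal_weights_is_median(self):
        be = np.full(5, 0.2)
        ratios = np.array([-0.5, -0.1, -0.2, -0.3, -0.4])
        res = weighted_median(make_instruments(be, ratios * be), n_boot=10)
        assert res.log_or == pytest.approx(np.median(ratios), abs=1e-12)

    def test_weighted_median_resists_directional_pleiotropy(self):
        """With half the variants pleiotropic, the weighted median stays
        closer to the truth than IVW in most replicates."""
        truth = -0.2
        wins = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            be = rng.uniform(0.1, 0.3, 20)
            bo = truth * be + rng.normal(0, 0.02, 20)
            bo[:10] += rng.uniform(0.05, 0.15, 10)  # directional pleiotropy
            inst = make_instruments(be, bo, se_out=0.02)
            wm = weighted_median(inst, n_boot=5, seed=rep).log_or
            iv = ivw(inst).log_or
            wins += abs(wm - truth) < abs(iv - truth)
        assert wins / n_rep >= 0.70

    def test_method_omitted_when_too_few_variants(self):
        inst = make_instruments([0.2, 0.3], [-0.04, -0.06])
        methods = {r.method for r in sensitivity_estimates(inst)}
        assert methods == {"ivw", "weighted_median"}  # Egger needs 3 variants


class TestGate:
    def _result(self, disease, or_, p, direction="forward", method="ivw"):
        gate = direction == "forward" and p < 0.05 and or_ < 1
        return MrResult(disease, direction, method, or_, (or_ * 0.9, or_ * 1.1), p,
                        causal_gate=gate)

    def test_harmful_significant_gated_in(self):
        assert gate_diseases([self._result("stroke", 0.90, 0.001)]) == {"stroke"}

    def test_protective_direction_gated_out(self):
        # delay increases risk => early maturation protective: no PAF
        assert gate_diseases([self._result("stroke", 1.10, 0.001)]) == set()

    def test_nonsignificant_gated_out(self):
        assert gate_diseases([self._result("stroke", 0.90, 0.20)]) == set()

    def test_reverse_direction_does_not_veto(self):
        results = [
            self._result("stroke", 0.90, 0.001),
            self._result("stroke", 0.85, 0.001, direction="reverse"),
        ]
        assert gate_diseases(results) == {"stroke"}


def test_per_year_earlier_flips_convention():
    res = MrResult("stroke", "forward", "ivw", 0.8, (0.7, 0.9), 0.01)
    flipped = per_year_earlier(res)
    assert flipped.or_per_year == pytest.approx(1.25)
    assert flipped.ci95 == (pytest.approx(1 / 0.9), pytest.approx(1 / 0.7))


def test_instrument_validation():
    with pytest.raises(ValueError, match="unique"):
        InstrumentSet("x", pd.DataFrame({
            "variant_id": ["rs1", "rs1"],
            "beta_exposure": [0.1, 0.2],
            "se_exposure": [0.01, 0.01],
            "beta_outcome": [0.0, 0.0],
            "se_outcome": [0.05, 0.05],
        }))


def test_filter_significant_keeps_strong_instruments():
    inst = make_instruments([0.2, 0.3], [-0.04, -0.06])
    inst.data["p_exposure"] = [1e-10, 1e-3]
    kept = inst.filter_significant()
    assert kept.data["variant_id"].tolist() == ["rs0"]
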