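"""Cancer-risk computation, disaggregation, and decay scenarios."""

import dataclasses

import numpy as np
import pytest

from iaqrisk.concentration import fit_lognormal_mom
from iaqrisk.exposure import ExposureDraws, simulate_personal_exposure
from iaqrisk.guidelines import ToxicityFactor, get_toxicity_factor
from iaqrisk.risk import (
    DecayScenario,
    RiskDraws,
    cancer_risk,
    decay_scenario,
    disaggregate,
    summarize_risk,
)
from iaqrisk.synthetic import TimeUseModel


def _draws(e_home, e_office, compound="formaldehyde"):
    e_home = np.asarray(e_home, dtype=float)
    e_office = np.asarray(e_office, dtype=float)
    return ExposureDraws(compound, e_home, e_office, e_home.size, None)


IRIS_HCHO = get_toxicity_factor("formaldehyde", "U.S. EPA IRIS")


class TestCancerRisk:
    def test_constant_exposure_per_million(self):
        # 85 µg/m³ × 1.3e-5 per (µg/m³) × 1e6 = 1105 per million
        risks = cancer_risk(_draws([85.0], [0.0]), IRIS_HCHO)
        assert risks.risk_total[0] == pytest.approx(1105.0)

    def test_raw_probability_scale(self):
        risks = cancer_risk(_draws([85.0], [0.0]), IRIS_HCHO, per_million=False)
        assert risks.risk_total[0] == pytest.approx(1.105e-3)

    def test_zero_exposure_zero_risk(self):
        risks = cancer_risk(_draws([0.0, 0.0], [0.0, 0.0]), IRIS_HCHO)
        assert np.all(risks.risk_total == 0.0)

    def test_compound_mismatch_rejected(self):
        with pytest.raises(ValueError, match="benzene"):
            cancer_risk(_draws([1.0], [1.0], compound="benzene"), IRIS_HCHO)

    def test_linearity_doubling_exposure_doubles_statistics(self, rng):
        e = rng.lognormal(3, 0.5, 100)
        base = summarize_risk(cancer_risk(_draws(e, e / 2), IRIS_HCHO))
        doubled = summarize_risk(cancer_risk(_draws(2 * e, e), IRIS_HCHO))
        for attr in ("mean", "sd", "median", "p95"):
            assert getattr(doubled, attr) == pytest.approx(2 * getattr(base, attr))

    def test_iur_swap_rescales_exactly(self, rng):
        e = rng.lognormal(3, 0.5, 200)
        draws = _draws(e, e / 3)
        iris = summarize_risk(cancer_risk(draws, IRIS_HCHO))
        oehha = summarize_risk(cancer_risk(draws, get_toxicity_factor("formaldehyde", "OEHHA")))
        assert oehha.median / iris.median == pytest.approx(6.0 / 13.0, rel=1e-12)
        assert oehha.mean / iris.mean == pytest.approx(6.0 / 13.0, rel=1e-12)


class TestDisaggregate:
    def test_equal_components(self):
        shares = disaggregate(cancer_risk(_draws([2.0, 4.0], [2.0, 4.0]), IRIS_HCHO))
        assert shares == {"home_share": pytest.approx(0.5), "office_share": pytest.approx(0.5)}

    def test_shares_sum_to_one(self, rng):
        draws = _draws(rng.lognormal(3, 0.6, 500), rng.lognormal(2, 0.6, 500))
        shares = disaggregate(cancer_risk(draws, IRIS_HCHO))
        assert shares["home_share"] + shares["office_share"] == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            disaggregate(cancer_risk(_draws([0.0, 0.0], [0.0, 0.0]), IRIS_HCHO))


class TestDecayScenario:
    def test_published_formaldehyde_arithmetic(self):
        # median 1,160 per million at 35% retained concentration -> 406
        summary = summarize_risk(cancer_risk(_draws([1160 / 13.0] * 3, [0.0] * 3), IRIS_HCHO))
        decayed = decay_scenario(summary, DecayScenario("formaldehyde", 0.35))
        assert decayed.median == pytest.approx(406.0, rel=1e-6)

    def test_published_benzene_arithmetic(self):
        summary = summarize_risk(
            cancer_risk(
                _draws([107 / 7.8] * 3, [0.0] * 3, compound="benzene"),
                get_toxicity_factor("benzene", "U.S. EPA IRIS"),
            )
        )
        decayed = decay_scenario(summary, DecayScenario("benzene", 0.25))
        assert decayed.median == pytest.approx(26.75, rel=1e-6)

    def test_identity_at_full_retention(self):
        summary = summarize_risk(cancer_risk(_draws([5.0, 6.0], [1.0, 2.0]), IRIS_HCHO))
        assert decay_scenario(summary, DecayScenario("formaldehyde", 1.0)) == summary

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            DecayScenario("formaldehyde", fraction)

    def test_commutes_with_cancer_risk(self):
        exposure = simulate_personal_exposure(
            fit_lognormal_mom(131.0, 90.0),
            fit_lognormal_mom(85.0, 56.0),
            TimeUseModel(),
            n_trials=2000,
            seed=13,
            compound="formaldehyde",
        )
        scenario = DecayScenario("formaldehyde", 0.35)
        # risk first, then decay
        a = decay_scenario(cancer_risk(exposure, IRIS_HCHO), scenario)
        # decay exposures first, then risk
        decayed_exposure = ExposureDraws(
            exposure.compound,
            exposure.e_home * 0.35,
            exposure.e_office * 0.35,
            exposure.n_trials,
            None,
        )
        b = cancer_risk(decayed_exposure, IRIS_HCHO)
        assert np.allclose(a.risk_total, b.risk_total, rtol=1e-12)


class TestSummarizeRisk:
    def test_constant_risk(self):
        s = summarize_risk(cancer_risk(_draws([10.0] * 5, [0.0] * 5), IRIS_HCHO))
        assert s.mean == s.median == s.p95 == pytest.approx(130.0)
        assert s.sd == 0.0
        assert s.home_share == pytest.approx(1.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            summarize_risk(cancer_risk(_draws([1.0], [1.0]), IRIS_HCHO))
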