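"""Synthetic references and cohorts: construction, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import growthref as gr
from growthref.simulate import make_base_reference, write_cohort


class TestReferencePair:
    def test_zero_shift_is_identity(self):
        base = make_base_reference("height", "male")
        _, spec = gr.make_reference_pair(base, delta=0.0, sd_ratio=1.0)
        np.testing.assert_allclose(spec.M, base.M)
        np.testing.assert_allclose(spec.S, base.S)

    def test_shifted_median_hand_value(self):
        # L=1, M=100, S=0.04, delta=-2 -> 100*(1 + 0.04*(-2)) = 92
        base = gr.LMSReference(measure="height", sex="male",
                               ages=[1.0, 2.0], L=[1.0, 1.0],
                               M=[100.0, 100.0], S=[0.04, 0.04])
        _, spec = gr.make_reference_pair(base, delta=-2.0)
        np.testing.assert_allclose(spec.M, 92.0)

    def test_specialized_median_scores_delta_on_standard(self):
        """A child at specialized-z 0 sits at standard-z delta exactly."""
        base = make_base_reference("weight", "female")
        _, spec = gr.make_reference_pair(base, delta=-1.0)
        for age in (0.5, 4.0, 11.7):
            L, M, S = base.interpolate(age)
            m_spec = spec.interpolate(age)[1]
            assert gr.lms_z(m_spec, L, M, S) == pytest.approx(-1.0, abs=1e-9)

    def test_domain_violation_names_the_age(self):
        base = gr.LMSReference(measure="weight", sex="male",
                               ages=[1.0, 2.0], L=[2.0, 2.0],
                               M=[10.0, 10.0], S=[0.3, 0.3])
        with pytest.raises(ValueError, match="age 1"):
            gr.make_reference_pair(base, delta=-2.0)  # 1+2*0.3*(-2) < 0


class TestSimulationConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n": 0}, {"male_fraction": 1.5}, {"rho": 1.0},
        {"birth_weight_sd_g": 0}, {"age_min": 5, "age_max": 4},
        {"truth": "other"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            gr.SimulationConfig(**kwargs)


class TestSimulateCohort:
    def test_single_child_deterministic(self, chart_pair, tmp_path):
        std, spec = chart_pair
        config = gr.SimulationConfig(n=1, seed=5)
        c1, t1 = gr.simulate_cohort(config, std, spec)
        c2, t2 = gr.simulate_cohort(config, std, spec)
        assert len(c1) == 1
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(c1, p1)
        write_cohort(c2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_marginals_recovered_within_3se(self, simulated):
        config, cohort, truth = simulated
        n = config.n
        se_frac = np.sqrt(0.54 * 0.46 / n)
        assert abs((cohort["sex"] == "male").mean() - 0.54) < 3 * se_frac
        for col, z in (("z_weight", truth["z_weight"]),
                       ("z_height", truth["z_height"])):
            assert abs(z.mean()) < 3 / np.sqrt(n)
            assert abs(z.std() - 1) < 3 / np.sqrt(2 * n)
        bw = cohort["birth_weight_g"]
        assert abs(bw.mean() - 2898) < 3 * 513 / np.sqrt(n)
        # gestation is truncated to [22, 43] wk; the oracle is the
        # truncated-normal mean, evaluated independently via scipy
        a, b = (22 - 37.7) / 2.17, (43 - 37.7) / 2.17
        gest_mean = sps.truncnorm.mean(a, b, loc=37.7, scale=2.17)
        assert abs(cohort["gestational_age_wk"].mean() - gest_mean) \
            < 3 * 2.17 / np.sqrt(n)
        assert abs(cohort["l_thyroxine"].mean() - 0.64) < 3 * np.sqrt(0.64 * 0.36 / n)
        assert abs(cohort["breastfed"].mean() - 0.78) < 3 * np.sqrt(0.78 * 0.22 / n)

    def test_latent_correlation_recovered(self, simulated):
        config, _, truth = simulated
        r = np.corrcoef(truth["z_weight"], truth["z_height"])[0, 1]
        assert r == pytest.approx(0.7, abs=0.06)

    def test_derived_bmi_z_approximately_standard(self, chart_pair):
        """BMI is derived from weight and height, so against the coherent
        delta-method BMI reference of the truth chart its z is only
        approximately N(0,1).  (The specialized chart's BMI offset is an
        independent scenario parameter, so coherence holds for the
        standard-chart truth.)"""
        std, spec = chart_pair
        config = gr.SimulationConfig(n=1500, seed=6, truth="standard")
        _, truth = gr.simulate_cohort(config, std, spec)
        assert abs(truth["z_bmi"].mean()) < 0.1
        assert abs(truth["z_bmi"].std() - 1) < 0.1

    def test_truth_chart_classification_near_3pct_under(self, chart_pair):
        std, spec = chart_pair
        config = gr.SimulationConfig(n=10_000, seed=77)
        cohort, _ = gr.simulate_cohort(config, std, spec)
        out = gr.standardize_cohort(cohort, std, spec)
        table = gr.band_table(out, reference_labels=("standard", "specialized"))
        for measure in ("weight", "height"):
            under = table.percentages[(measure, "specialized")]["under"]
            assert under == pytest.approx(3.01, abs=0.5)

    def test_chart_discordance_sign_in_50_replicates(self):
        """With a -1 SDS specialized-chart shift, the under-3rd share is
        higher on the standard chart in every seeded replicate."""
        std, spec = gr.make_chart_pair({"weight": -1.0, "height": -1.0,
                                        "bmi": -1.0})
        for rep in range(50):
            config = gr.SimulationConfig(
                n=1000, seed=20_000 + rep,
                delta={"weight": -1.0, "height": -1.0, "bmi": -1.0})
            cohort, _ = gr.simulate_cohort(config, std, spec)
            out = gr.standardize_cohort(cohort, std, spec)
            table = gr.band_table(out,
                                  reference_labels=("standard", "specialized"))
            for measure in ("weight", "height"):
                assert (table.percentages[(measure, "standard")]["under"]
                        > table.percentages[(measure, "specialized")]["under"])

    def test_shifted_under_share_matches_closed_form(self):
        """delta=-1 on the height chart: standard-z = z*(1+S*delta) + delta,
        so P(under) = Phi((-1.88 - delta)/(1 + S*delta)); checked to 3
        Monte-Carlo standard errors."""
        delta = -1.0
        std, spec = gr.make_chart_pair({"weight": delta, "height": delta,
                                        "bmi": delta})
        config = gr.SimulationConfig(
            n=10_000, seed=99,
            delta={"weight": delta, "height": delta, "bmi": delta})
        cohort, _ = gr.simulate_cohort(config, std, spec)
        out = gr.standardize_cohort(cohort, std, spec)
        table = gr.band_table(out, reference_labels=("standard", "specialized"))
        S_height = 0.04
        expected = sps.norm.cdf((-1.88 - delta) / (1 + S_height * delta))
        se = np.sqrt(expected * (1 - expected) / config.n)
        observed = table.percentages[("height", "standard")]["under"] / 100
        assert abs(observed - expected) < 3 * se
        # the naive approximation Phi(-0.88) is close but not exact
        assert expected == pytest.approx(sps.norm.cdf(-0.88), abs=0.012)
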