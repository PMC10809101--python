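import numpy as np
import pandas as pd
import pytest

from lungtraj import risk
from lungtraj.synthetic import CohortConfig, generate_cohort

from conftest import make_truth


def outcome_cohort(log_hr, log_rate, n=800, seed=0, zero_prob=0.2,
                   base_hazard=0.05, sigma=0.5):
    K = len(log_hr)
    truth = make_truth(
        -1.5 * np.arange(K), sigma=sigma, log_hr=log_hr, log_rate=log_rate,
        zero_prob=zero_prob,
    )
    cc = CohortConfig(n_subjects=n, base_hazard=base_hazard)
    _, _, outcomes, labels = generate_cohort(cc, truth, seed=seed)
    return outcomes, labels


class TestCoxMortality:
    def test_reference_row_is_unit_hazard(self):
        outcomes, labels = outcome_cohort([0.0, np.log(2.0)],
                                          np.log([0.3, 0.9]), seed=1)
        out = risk.cox_mortality(outcomes, labels, reference=0)
        ref = out[out["reference"]]
        assert ref["trajectory"].iloc[0] == 0
        assert ref["hr"].iloc[0] == 1.0

    def test_recovers_known_hazard_ratio(self):
        outcomes, labels = outcome_cohort([0.0, np.log(2.0)],
                                          np.log([0.3, 0.9]), n=1000, seed=2)
        out = risk.cox_mortality(outcomes, labels, reference=0)
        row = out[out["trajectory"] == 1].iloc[0]
        assert row["ci_lo"] <= 2.0 <= row["ci_hi"]
        assert np.isfinite(out.attrs["ph_p"])

    def test_full_model_includes_extra_covariates(self):
        outcomes, labels = outcome_cohort([0.0, np.log(2.0)],
                                          np.log([0.3, 0.9]), seed=3)
        reduced = risk.cox_mortality(outcomes, labels, "reduced", reference=0)
        full = risk.cox_mortality(outcomes, labels, "full", reference=0)
        assert full.attrs["model_form"] == "full"
        assert reduced.attrs["model_form"] == "reduced"

    def test_subject_reordering_invariance(self):
        outcomes, labels = outcome_cohort([0.0, np.log(2.0)],
                                          np.log([0.3, 0.9]), seed=4)
        out1 = risk.cox_mortality(outcomes, labels, reference=0)
        perm = np.random.default_rng(0).permutation(len(outcomes))
        out2 = risk.cox_mortality(outcomes.iloc[perm], labels[perm],
                                  reference=0)
        np.testing.assert_allclose(
            out1["hr"].to_numpy(), out2["hr"].to_numpy(), rtol=1e-8
        )

    def test_no_events_rejected(self):
        outcomes, labels = outcome_cohort([0.0, 0.0], np.log([0.3, 0.3]),
                                          n=50, seed=5)
        outcomes = outcomes.assign(death=0)
        with pytest.raises(ValueError, match="events"):
            risk.cox_mortality(outcomes, labels, reference=0)

    def test_eventless_trajectory_flagged_non_estimable(self):
        outcomes, labels = outcome_cohort([0.0, 0.0], np.log([0.3, 0.3]),
                                          n=300, seed=6)
        outcomes = outcomes.copy()
        outcomes.loc[labels == 1, "death"] = 0
        out = risk.cox_mortality(outcomes, labels, reference=0)
        row = out[out["trajectory"] == 1].iloc[0]
        assert not row["estimable"]


class TestZinbExacerbations:
    def test_offset_invariance(self):
        outcomes, labels = outcome_cohort([0.0, 0.7], np.log([0.3, 1.0]),
                                          seed=7)
        out1 = risk.zinb_exacerbations(outcomes, labels, reference=0)
        doubled = outcomes.assign(obs_years=outcomes["obs_years"] * 2.0)
        out2 = risk.zinb_exacerbations(doubled, labels, reference=0)
        np.testing.assert_allclose(out1["irr"].to_numpy(),
                                   out2["irr"].to_numpy(), rtol=1e-4)

    def test_recovers_known_rate_ratio(self):
        outcomes, labels = outcome_cohort(
            [0.0, 0.0], np.log([0.4, 1.2]), n=1500, seed=8
        )
        out = risk.zinb_exacerbations(outcomes, labels, reference=0)
        row = out[out["trajectory"] == 1].iloc[0]
        assert row["ci_lo"] <= 3.0 <= row["ci_hi"]
        assert out.attrs["dispersion"] > 0

    def test_no_structural_zeros_matches_plain_nb(self):
        outcomes, labels = outcome_cohort(
            [0.0, 0.0], np.log([0.4, 1.2]), n=1500, seed=9, zero_prob=0.0
        )
        out = risk.zinb_exacerbations(outcomes, labels, reference=0)
        assert out.attrs["zero_inflation"] == pytest.approx(0.0, abs=0.05)
        # nested-model check against a plain negative binomial fit
        import statsmodels.api as sm

        X = sm.add_constant(pd.DataFrame({
            "traj_1": (labels == 1).astype(float),
            "entry_age": outcomes["entry_age"],
            "current_smoker": outcomes["current_smoker"].astype(float),
            "packyears": outcomes["packyears"],
            "female": (outcomes["sex"] == "female").astype(float),
            "race_aa": (outcomes["race"] == "AA").astype(float),
        }))
        nb = sm.NegativeBinomial(
            outcomes["exacerbations"].to_numpy(float), X,
            exposure=outcomes["obs_years"].to_numpy(float),
        ).fit(disp=0, maxiter=500)
        irr_nb = float(np.exp(nb.params["traj_1"]))
        assert out[out["trajectory"] == 1]["irr"].iloc[0] == pytest.approx(
            irr_nb, rel=0.02
        )

    def test_all_zero_counts_rejected(self):
        outcomes, labels = outcome_cohort([0.0, 0.0], np.log([0.3, 0.3]),
                                          n=50, seed=10)
        outcomes = outcomes.assign(exacerbations=0)
        with pytest.raises(ValueError, match="zero"):
            risk.zinb_exacerbations(outcomes, labels, reference=0)


class TestScaleByReferenceSd:
    def test_reference_group_scaled_to_unit_sd(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0.04, 0.004, 200)
        labels = np.repeat([0, 1], 100)
        scaled, s = risk.scale_by_reference_sd(values, labels, reference=0)
        assert np.std(scaled[labels == 0], ddof=1) == pytest.approx(1.0)
        assert s == pytest.approx(np.std(values[:100], ddof=1))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0.04, 0.004, 100)
        labels = np.zeros(100)
        s1, _ = risk.scale_by_reference_sd(values, labels, 0)
        s2, _ = risk.scale_by_reference_sd(values * 7.0, labels, 0)
        np.testing.assert_allclose(s1, s2, rtol=1e-12)

    def test_manual_published_constant(self):
        values = np.array([0.040, 0.036, 0.044])
        scaled, s = risk.scale_by_reference_sd(values, np.zeros(3), 0,
                                               scale=0.0039)
        assert s == 0.0039
        np.testing.assert_allclose(scaled, values / 0.0039)

    def test_zero_reference_sd_rejected(self):
        with pytest.raises(ValueError):
            risk.scale_by_reference_sd(np.ones(5), np.zeros(5), 0)


class TestMultinomialStepwise:
    def test_binary_case_matches_odds_ratio_oracle(self):
        rng = np.random.default_rng(2)
        n = 600
        x = rng.integers(0, 2, n)
        p = np.where(x == 1, 0.6, 0.3)
        y = (rng.random(n) < p).astype(int)
        preds = pd.DataFrame({"flag": x.astype(float)})
        table, path = risk.multinomial_stepwise(
            y, preds, reference=0, alpha_enter=0.05, decrease_cols=()
        )
        a = np.sum((y == 1) & (x == 1))
        b = np.sum((y == 0) & (x == 1))
        c = np.sum((y == 1) & (x == 0))
        d = np.sum((y == 0) & (x == 0))
        oracle_or = (a * d) / (b * c)
        assert table["rrr"].iloc[0] == pytest.approx(oracle_or, rel=1e-4)
        assert path[0]["entered"] == "flag"

    def test_informative_predictor_enters_noise_stays_out(self):
        rng = np.random.default_rng(3)
        n = 600
        labels = rng.integers(0, 3, n)
        al = rng.normal(-0.8 * labels, 1.0)
        noise = rng.normal(size=n)
        preds = pd.DataFrame({"al_scaled": al, "noise": noise})
        table, path = risk.multinomial_stepwise(labels, preds, reference=0)
        assert table.attrs["selected"] == ["al_scaled"]
        # negative coefficient => RRR per unit decrease > 1
        assert (table[table["predictor"] == "al_scaled"]["rrr"] > 1).all()

    def test_reference_category_must_exist(self):
        with pytest.raises(ValueError):
            risk.multinomial_stepwise(
                np.array([1, 2, 1, 2]), pd.DataFrame({"x": np.arange(4.0)}),
                reference=0,
            )
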