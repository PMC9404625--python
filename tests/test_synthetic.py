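"""Cohort generation, record simulation, missingness, imputation and splitting."""

import numpy as np
import pandas as pd
import pytest

from pipuq import clinical, poppk, synthetic
from pipuq.poppk import TypicalValues
from pipuq.synthetic import NoiseModel


class TestGenerateCohort:
    def test_covariate_medians_match_targets(self):
        cohort = synthetic.generate_cohort(1000, seed=1, site="GUH")
        weights = np.array([p.weight for p in cohort])
        clcrs = np.array([p.clcr for p in cohort])
        assert np.median(weights) == pytest.approx(75.0, abs=3.0)
        assert np.median(clcrs) == pytest.approx(107.5, abs=10.0)

    def test_deterministic_per_seed(self):
        a = synthetic.generate_cohort(20, seed=5)
        b = synthetic.generate_cohort(20, seed=5)
        assert [p.clcr for p in a] == [p.clcr for p in b]
        c = synthetic.generate_cohort(20, seed=6)
        assert [p.clcr for p in a] != [p.clcr for p in c]

    def test_physiologic_ranges(self, guh_cohort):
        for p in guh_cohort:
            assert 30 <= p.weight <= 250
            assert 1 <= p.clcr <= 300
            assert 18 <= p.age <= 100

    def test_errors(self):
        with pytest.raises(ValueError):
            synthetic.generate_cohort(0, seed=1)
        with pytest.raises(ValueError):
            synthetic.generate_cohort(5, seed=1, site="MAYO")


class TestSimulateRecords:
    def test_zero_noise_matches_a_priori_predictor(self, guh_cohort):
        """Generator and predictor share the PK model: zero-noise error is 0."""
        records = synthetic.simulate_records(
            guh_cohort[:30], noise=NoiseModel.zero(), seed=2
        )
        tv = TypicalValues()
        pred = np.array(
            [
                poppk.a_priori_predict(tv, r.clcr, r.weight, r.dose_per_hour)
                for r in records.itertuples()
            ]
        )
        np.testing.assert_allclose(records.observed_concentration, pred, rtol=1e-12)

    def test_ode_method_consistent_with_steady_state(self, guh_cohort):
        ss = synthetic.simulate_records(guh_cohort[:4], noise=NoiseModel.zero(), seed=2)
        ode = synthetic.simulate_records(
            guh_cohort[:4], noise=NoiseModel.zero(), seed=2, method="ode"
        )
        # day-3 samples have essentially converged
        day3 = ss.sample_time_h == 72.0
        np.testing.assert_allclose(
            ode.loc[day3, "true_concentration"],
            ss.loc[day3, "true_concentration"],
            rtol=1e-3,
        )

    def test_record_linking(self, guh_records):
        first = guh_records.groupby("patient_id").first()
        assert (first.previous_concentration == 0).all()
        assert (first.hours_to_previous == 0).all()
        later = guh_records.groupby("patient_id").nth(slice(1, None))
        if len(later):
            assert (later.hours_to_previous == 24.0).all()
            assert (later.previous_concentration > 0).all()

    def test_observed_floor_and_noise(self, guh_records):
        assert (guh_records.observed_concentration >= 0.1).all()
        # residual noise present: observed deviates from true
        assert (guh_records.observed_concentration != guh_records.true_concentration).any()

    def test_iiv_disperses_concentrations(self, guh_cohort):
        with_iiv = synthetic.simulate_records(guh_cohort[:40], seed=3)
        no_iiv = synthetic.simulate_records(
            guh_cohort[:40],
            noise=NoiseModel(iiv_cv={"cl": 0.0, "v": 0.0, "vp": 0.0, "q": 0.0},
                             residual_proportional_cv=0.0, residual_additive_sd=0.0),
            seed=3,
        )
        assert with_iiv.true_concentration.std() > no_iiv.true_concentration.std()


class TestMissingness:
    def test_zero_rate_is_identity(self, guh_records):
        out = synthetic.inject_missingness(guh_records, rates={"albumin": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out, guh_records)

    def test_full_rate_blanks_feature(self, guh_records):
        out = synthetic.inject_missingness(guh_records, rates={"albumin": 1.0}, seed=1)
        assert out.albumin.isna().all()

    def test_default_rates_binomial(self):
        """At the published per-feature rates, a 752-record table loses ~39
        urine-creatinine values."""
        cohort = synthetic.generate_cohort(300, seed=4)
        records = synthetic.simulate_records(cohort, n_days=4, seed=4)
        records = records.iloc[:752]
        out = synthetic.inject_missingness(records, seed=4)
        n_missing = int(out.urine_creatinine.isna().sum())
        # binomial(752, 39/752): mean 39, sd ~6.1
        assert 15 <= n_missing <= 63

    def test_unknown_feature_errors(self, guh_records):
        with pytest.raises(KeyError):
            synthetic.inject_missingness(guh_records, rates={"nope": 0.5})


class TestImpute:
    def test_no_missing_is_identity(self, guh_records):
        out = synthetic.impute(guh_records)
        assert out.attrs["n_dropped"] == 0
        assert len(out) == len(guh_records)

    def test_sentinel_strategy(self, guh_records):
        gaps = synthetic.inject_missingness(
            guh_records, rates={"temperature": 0.5, "urine_creatinine": 0.5}, seed=2
        )
        out = synthetic.impute(gaps, strategy="sentinel")
        assert (out.temperature == -999.0).any()
        assert not out.temperature.isna().any()

    def test_mean_strategy(self, guh_records):
        gaps = synthetic.inject_missingness(guh_records, rates={"temperature": 0.5}, seed=2)
        observed_mean = gaps.temperature.mean()
        out = synthetic.impute(gaps, strategy="mean")
        filled = out.loc[
            gaps.sort_values(["patient_id", "sample_time_h"]).temperature.isna().to_numpy(),
            "temperature",
        ]
        assert np.allclose(filled, observed_mean)

    def test_clcr_from_weighted_formula(self, guh_records):
        gaps = guh_records.copy()
        idx = gaps.index[0]
        gaps.loc[idx, "clcr"] = np.nan
        out = synthetic.impute(gaps)
        row = guh_records.loc[idx]
        cg = clinical.estimate_gfr("cockcroft_gault", row.age, row.weight, row.sex, row.race, row.scr)
        mdrd = clinical.estimate_gfr("mdrd", row.age, row.weight, row.sex, row.race, row.scr)
        got = out.loc[
            (out.patient_id == row.patient_id) & (out.sample_time_h == row.sample_time_h), "clcr"
        ].iloc[0]
        assert got == pytest.approx(clinical.weighted_clcr(cg, mdrd))

    def test_low_missing_previous_next_fill(self, guh_records):
        multi = guh_records.groupby("patient_id").filter(lambda g: len(g) >= 2)
        pid = multi.patient_id.iloc[0]
        gaps = guh_records.copy()
        target = gaps[(gaps.patient_id == pid)].index[0]
        gaps.loc[target, "albumin"] = np.nan
        out = synthetic.impute(gaps)
        got = out[(out.patient_id == pid)].albumin.iloc[0]
        assert got == pytest.approx(guh_records[guh_records.patient_id == pid].albumin.iloc[1])


class TestSplitPatients:
    def test_sizes_and_disjointness(self, guh_records):
        train, apri, apost = synthetic.split_patients(guh_records, seed=1)
        counts = guh_records.groupby("patient_id").size()
        eligible = (counts >= 2).sum()
        n_test = apri.patient_id.nunique()
        assert n_test == int(np.ceil(0.25 * eligible))
        assert set(train.patient_id) & set(apri.patient_id) == set()
        assert len(train) + len(apri) == len(guh_records)

    def test_a_priori_zeroes_previous(self, guh_records):
        _, apri, apost = synthetic.split_patients(guh_records, seed=1)
        assert (apri.previous_concentration == 0).all()
        assert (apost.previous_concentration > 0).all()
        assert len(apost) <= len(apri)
        # a posteriori drops exactly one (the first) record per test patient
        assert len(apost) == len(apri) - apri.patient_id.nunique()

    def test_disjoint_for_any_seed(self, guh_records):
        for seed in range(5):
            train, apri, _ = synthetic.split_patients(guh_records, seed=seed)
            assert set(train.patient_id) & set(apri.patient_id) == set()

    def test_too_few_eligible(self, guh_records):
        singles = guh_records.groupby("patient_id").head(1)
        with pytest.raises(ValueError):
            synthetic.split_patients(singles, min_records=2, seed=0)


class TestHeteroRegressionData:
    def test_sigma_range_and_determinism(self):
        df = synthetic.heteroscedastic_regression_data(n=2000, seed=3)
        assert df.true_sigma.min() >= 5.0
        assert df.true_sigma.max() <= 20.0
        assert df.true_sigma.max() / df.true_sigma.min() > 3.5
        df2 = synthetic.heteroscedastic_regression_data(n=2000, seed=3)
        pd.testing.assert_frame_equal(df, df2)
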