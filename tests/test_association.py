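"""Per-feature logistic models, BH correction, endpoint, Cox, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from omicfuse import (
    CohortSpec,
    EndpointRules,
    OmicsBlock,
    bh_adjust,
    cox_ph,
    derive_time_to_insulin,
    generate_cohort,
    generate_survival_directly,
    logistic_per_feature,
    overlap_enrichment,
)


def _block_from_array(X, ids=None):
    X = np.asarray(X, dtype=float)
    ids = ids or [f"P{i}" for i in range(X.shape[0])]
    cols = [f"f{j}" for j in range(X.shape[1])]
    return OmicsBlock(data=pd.DataFrame(X, index=ids, columns=cols))


class TestLogisticPerFeature:
    def test_contingency_table_matches_closed_form_log_odds(self):
        # binary feature with 2x2 counts (30,10 / 10,30): log OR = log 9
        y = np.array([1] * 40 + [2] * 40)
        x = np.array([0.0] * 30 + [1.0] * 10 + [1.0] * 30 + [0.0] * 10)
        rows = logistic_per_feature(_block_from_array(x[:, None]), y, clinical=None)
        assert np.isclose(rows[0].coefficient, np.log(9), atol=1e-6)

    def test_perfect_separation_is_flagged(self):
        y = np.array([1] * 20 + [2] * 20)
        x = (y == 2).astype(float)
        rows = logistic_per_feature(_block_from_array(x[:, None]), y, clinical=None)
        assert rows[0].separation
        assert np.isnan(rows[0].p_value)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            logistic_per_feature(
                _block_from_array(np.zeros((6, 1))), np.array([1, 2, 3, 1, 2, 3])
            )

    def test_type_one_error_at_nominal_level(self):
        """Null features against random labels reject at ~5%."""
        r = np.random.default_rng(31)
        n, m = 200, 400
        X = r.normal(size=(n, m))
        y = np.repeat([1, 2], n // 2)
        clinical = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "age": r.normal(60, 8, n),
                "sex": r.integers(0, 2, n),
                "bmi": r.normal(30, 4, n),
            }
        )
        rows = logistic_per_feature(
            _block_from_array(X, ids=list(clinical["patient_id"])), y, clinical
        )
        rate = np.mean([row.p_value < 0.05 for row in rows])
        band = 1.96 * np.sqrt(0.05 * 0.95 / m)
        assert abs(rate - 0.05) <= band + 0.01


class TestBHAdjust:
    def test_textbook_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_missing_values_preserved(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        assert np.all(~np.isnan(q[[0, 2]]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    def test_matches_reference_stepup_and_is_monotone(self, ps):
        q = bh_adjust(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-12)


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "visit_time",
            "hba1c",
            "n_noninsulin_drugs",
            "insulin_flag",
            "insulin_stop_time",
        ],
    )


class TestEndpointDerivation:
    def test_short_insulin_use_does_not_qualify(self):
        # insulin from 2.0 to 2.3 years: below the six-month threshold
        rec = _records(
            [
                ("A", 0.0, 50, 0, 0, np.nan),
                ("A", 2.0, 55, 0, 1, 2.3),
                ("A", 3.0, 52, 0, 0, np.nan),
                ("A", 5.0, 53, 0, 0, np.nan),
            ]
        )
        out = derive_time_to_insulin(rec)
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "time"] == pytest.approx(5.0)

    def test_sustained_insulin_sets_event_at_start(self):
        rec = _records(
            [
                ("A", 0.0, 50, 0, 0, np.nan),
                ("A", 2.0, 55, 0, 1, np.nan),
                ("A", 3.0, 52, 0, 1, np.nan),
            ]
        )
        out = derive_time_to_insulin(rec)
        assert out.loc[0, "event"] == 1
        assert out.loc[0, "time"] == pytest.approx(2.0)

    def test_two_qualifying_hba1c_visits_set_event_at_second(self):
        rec = _records(
            [
                ("A", 0.0, 50, 0, 0, np.nan),
                ("A", 1.0, 75, 2, 0, np.nan),
                ("A", 1.4, 80, 2, 0, np.nan),
                ("A", 2.0, 60, 2, 0, np.nan),
            ]
        )
        out = derive_time_to_insulin(rec)
        assert out.loc[0, "event"] == 1
        assert out.loc[0, "time"] == pytest.approx(1.4)

    def test_drug_condition_failure_censors(self):
        rec = _records(
            [
                ("A", 1.0, 75, 1, 0, np.nan),  # only one non-insulin drug
                ("A", 1.5, 80, 2, 0, np.nan),
            ]
        )
        out = derive_time_to_insulin(rec)
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "time"] == pytest.approx(1.5)

    def test_idempotent_and_duplicate_insensitive(self):
        rec = _records(
            [
                ("A", 1.0, 75, 2, 0, np.nan),
                ("A", 1.4, 80, 2, 0, np.nan),
            ]
        )
        doubled = pd.concat([rec, rec], ignore_index=True)
        pd.testing.assert_frame_equal(
            derive_time_to_insulin(rec), derive_time_to_insulin(doubled)
        )

    def test_no_visits_errors(self):
        with pytest.raises(ValueError):
            derive_time_to_insulin(_records([]).iloc[0:0])
        rec = _records([("A", 1.0, 50, 0, 0, np.nan)])
        with pytest.raises(ValueError, match="columns"):
            derive_time_to_insulin(rec.drop(columns=["hba1c"]))

    def test_threshold_is_strict(self):
        rec = _records(
            [
                ("A", 1.0, 69.0, 2, 0, np.nan),  # not > 69
                ("A", 1.5, 69.0, 2, 0, np.nan),
            ]
        )
        assert derive_time_to_insulin(rec).loc[0, "event"] == 0


class TestCoxPH:
    def _simulate(self, n, hr, seed, rate=0.15, censor=8.0):
        spec = CohortSpec(
            n_patients=n, block_sizes=(5,), n_informative=(0,),
            true_hazard_ratio=hr, baseline_rate=rate, censor_time=censor, seed=seed,
        )
        _, clinical = generate_cohort(spec)
        surv = generate_survival_directly(spec, clinical, np.random.default_rng(seed))
        return clinical, surv

    def test_closed_form_rate_ratio_without_censoring(self):
        clinical, _ = self._simulate(2000, 0.5, seed=41)
        g = clinical["true_subgroup"].to_numpy()
        r = np.random.default_rng(41)
        rate = np.where(g == 2, 0.05, 0.1)
        time = r.exponential(1 / rate)
        event = np.ones_like(time, dtype=int)
        res = cox_ph(time, event, g)
        # with exponential data and no censoring the MLE is the event-rate ratio
        rate_ratio = (event[g == 2].sum() / time[g == 2].sum()) / (
            event[g == 1].sum() / time[g == 1].sum()
        )
        assert np.isclose(res.hazard_ratio, rate_ratio, rtol=0.05)
        assert res.ci_low <= res.hazard_ratio <= res.ci_high

    def test_permuted_labels_center_on_unity(self):
        clinical, surv = self._simulate(300, 0.56, seed=43)
        r = np.random.default_rng(43)
        hrs = []
        g = clinical["true_subgroup"].to_numpy()
        for _ in range(50):
            hrs.append(
                cox_ph(surv["time"], surv["event"], r.permutation(g), clinical).hazard_ratio
            )
        assert 0.8 <= np.mean(hrs) <= 1.25

    def test_time_rescaling_invariance(self):
        clinical, surv = self._simulate(400, 0.56, seed=47)
        g = clinical["true_subgroup"].to_numpy()
        res_years = cox_ph(surv["time"], surv["event"], g, clinical)
        res_days = cox_ph(surv["time"] * 365.25, surv["event"], g, clinical)
        assert np.isclose(res_years.hazard_ratio, res_days.hazard_ratio, rtol=1e-6)

    def test_efron_and_breslow_agree_on_continuous_times(self):
        clinical, surv = self._simulate(300, 0.5, seed=53)
        g = clinical["true_subgroup"].to_numpy()
        e = cox_ph(surv["time"], surv["event"], g, clinical, ties="efron")
        b = cox_ph(surv["time"], surv["event"], g, clinical, ties="breslow")
        assert np.isclose(e.hazard_ratio, b.hazard_ratio, rtol=0.02)

    def test_zero_events_errors(self):
        with pytest.raises(ValueError, match="events"):
            cox_ph([1.0, 2.0], [0, 0], [1, 2])

    def test_monotone_likelihood_flagged(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 0])
        group = np.array([1, 1, 2, 2])  # all events in group 1
        res = cox_ph(time, event, group)
        assert not res.converged


class TestOverlapEnrichment:
    def test_exact_small_example(self):
        # N=10, |a|=5, |b|=4, intersect=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        a = [1] * 5 + [2] * 5
        b = [1, 1, 1, 1, 2, 2, 2, 2, 2, 2]
        table = overlap_enrichment(a, b)
        row = table[(table.cluster_a == 1) & (table.cluster_b == 1)].iloc[0]
        assert row.intersect == 4
        assert np.isclose(row.p_value, 5 / 210)

    def test_empty_intersection_has_p_one(self):
        a = [1] * 4 + [2] * 6
        b = [2] * 4 + [1] * 6
        table = overlap_enrichment(a, b)
        row = table[(table.cluster_a == 1) & (table.cluster_b == 1)].iloc[0]
        assert row.intersect == 0
        assert row.p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Hypergeometric tail equals brute-force enumeration of draws."""
        N, na, nb = 10, 4, 5
        a = np.array([1] * na + [2] * (N - na))
        universe = list(range(N))
        r = np.random.default_rng(3)
        b_members = set(r.choice(N, size=nb, replace=False).tolist())
        b = np.array([1 if i in b_members else 2 for i in range(N)])
        obs = int(((a == 1) & (b == 1)).sum())
        count = sum(
            1
            for comb in itertools.combinations(universe, nb)
            if len(set(comb) & set(range(na))) >= obs
        )
        from math import comb as C

        expected = count / C(N, nb)
        table = overlap_enrichment(a, b)
        row = table[(table.cluster_a == 1) & (table.cluster_b == 1)].iloc[0]
        assert np.isclose(row.p_value, expected, atol=1e-12)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            overlap_enrichment([1, 2], [1, 2, 1])
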