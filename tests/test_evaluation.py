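"""AUC folds, transferability, driver comparison, thresholds and group smooths."""

import numpy as np
import pandas as pd
import pytest

from habtrack.evaluation import (
    auc,
    cross_site_transfer,
    driver_comparison,
    group_smoother_test,
    leave_one_individual_out,
    threshold_and_map,
    weekly_auc,
    youden_threshold,
)
from habtrack.model import SplineBinomialGAM
from habtrack.synthetic import make_use_availability


def brute_force_auc(scores, labels):
    """Concordant-pair count, ties half-weighted."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_hand_counted_worked_example(self):
        assert auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0]) == 1.0

    def test_random_labels_near_half(self, rng):
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_with_ties(self, rng):
        scores = rng.integers(0, 5, 60) / 4.0  # heavy ties
        labels = rng.integers(0, 2, 60)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


@pytest.fixture(scope="module")
def habitat_records():
    return make_use_availability(
        n_individuals=8, records_per_individual=250, weights={"sst": 1.5}, seed=77
    )


@pytest.fixture(scope="module")
def habitat_model(habitat_records):
    return SplineBinomialGAM(covariates=["sst"]).fit(
        habitat_records, habitat_records["response"].to_numpy()
    )


class TestWeeklyAuc:
    def test_folds_partition_records(self, habitat_model, habitat_records):
        tbl = weekly_auc(habitat_model, habitat_records)
        assert (tbl["n_presence"] + tbl["n_absence"]).sum() == len(habitat_records)
        assert set(tbl["week"]) == set(habitat_records["week"].unique())

    def test_habitat_driven_data_scores_high(self, habitat_model, habitat_records):
        tbl = weekly_auc(habitat_model, habitat_records)
        assert tbl["auc"].median() > 0.8

    def test_intercept_only_near_half(self, habitat_records):
        m = SplineBinomialGAM(covariates=[]).fit(
            habitat_records, habitat_records["response"].to_numpy()
        )
        tbl = weekly_auc(m, habitat_records)
        assert abs(tbl["auc"].median() - 0.5) < 0.05

    def test_single_week_single_fold(self, habitat_model, habitat_records):
        one = habitat_records.assign(week=7)
        tbl = weekly_auc(habitat_model, one)
        assert len(tbl) == 1


class TestLeaveOneIndividualOut:
    def test_one_fold_per_individual(self, habitat_records):
        tbl = leave_one_individual_out(habitat_records, ["sst"])
        assert len(tbl) == habitat_records["individual_id"].nunique()
        assert tbl["auc"].median() > 0.75

    def test_inverted_individual_scores_lowest(self):
        df = make_use_availability(
            n_individuals=6, records_per_individual=300, weights={"sst": 1.5}, seed=31
        )
        flip = df["individual_id"] == "ind000"
        df.loc[flip, "response"] = 1 - df.loc[flip, "response"]  # inverted preference
        tbl = leave_one_individual_out(df, ["sst"]).set_index("individual_id")
        assert tbl["auc"].idxmin() == "ind000"
        assert tbl.loc["ind000", "auc"] < 0.5

    def test_requires_three_individuals(self, habitat_records):
        two = habitat_records[habitat_records["individual_id"].isin(["ind000", "ind001"])]
        with pytest.raises(ValueError):
            leave_one_individual_out(two, ["sst"])


class TestCrossSiteTransfer:
    def test_self_transfer_equals_training_auc(self, habitat_model, habitat_records):
        a = cross_site_transfer(habitat_model, habitat_records)
        direct = auc(
            habitat_model.decision_function(habitat_records),
            habitat_records["response"].to_numpy(),
        )
        assert a == pytest.approx(direct)

    def test_shared_truth_transfers_well_opposite_fails(self):
        site_a = make_use_availability(10, 200, weights={"sst": 1.5}, seed=50)
        site_b_same = make_use_availability(10, 200, weights={"sst": 1.5}, seed=51)
        site_b_opp = make_use_availability(10, 200, weights={"sst": -1.5}, seed=52)
        m = SplineBinomialGAM(covariates=["sst"]).fit(site_a, site_a["response"].to_numpy())
        within = cross_site_transfer(m, site_a)
        same = cross_site_transfer(m, site_b_same)
        opposite = cross_site_transfer(m, site_b_opp)
        assert same == pytest.approx(within, abs=0.05)
        assert opposite < 0.6

    def test_missing_covariate_rejected(self, habitat_model):
        with pytest.raises(ValueError, match="missing covariates"):
            cross_site_transfer(habitat_model, pd.DataFrame({"response": [0, 1]}))


class TestDriverComparison:
    def test_identical_specs_give_zero_differences(self, habitat_records):
        res = driver_comparison(habitat_records, ["sst"], ["sst"], ["sst"])
        assert np.allclose(res.tests["median_difference"], 0.0)

    def test_habitat_truth_ranks_habitat_model_first(self):
        df = make_use_availability(
            10, 300, weights={"sst": 1.5},
            covariates=["sst", "chl", "dist_own", "dist_closest"], seed=60,
        )
        res = driver_comparison(
            df,
            ["sst", "chl", "dist_own", "dist_closest"],
            ["sst", "chl"],
            ["dist_own", "dist_closest"],
        )
        row = res.tests.set_index("pair").loc["habitat-distance"]
        assert row["median_difference"] > 0.1
        assert not res.descriptive_only

    def test_few_weeks_descriptive_only(self):
        df = make_use_availability(6, 100, weights={"sst": 1.0}, weeks=3, seed=61)
        res = driver_comparison(df, ["sst"], ["sst"], ["sst"])
        assert res.descriptive_only


class TestYoudenThreshold:
    def test_enumerated_worked_example(self):
        thr, j = youden_threshold([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0])
        assert 0.4 < thr <= 0.8
        assert j == 1.0

    def test_no_point_beats_returned_j(self, rng):
        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.3, 200) > 0.5).astype(int)
        thr, j = youden_threshold(scores, labels)
        for cand in np.unique(scores):
            pred = scores >= cand
            tpr = (pred & (labels == 1)).sum() / (labels == 1).sum()
            fpr = (pred & (labels == 0)).sum() / (labels == 0).sum()
            assert tpr - fpr <= j + 1e-12

    def test_tie_broken_toward_higher_threshold(self):
        # two thresholds achieve J=1; the higher one must be returned
        thr, j = youden_threshold([0.9, 0.7, 0.3, 0.1], [1, 1, 0, 0])
        assert thr >= 0.7


class TestThresholdAndMap:
    def test_probability_map_bounds_and_threshold_monotonicity(
        self, env_small, colonies
    ):
        df = make_use_availability(6, 200, weights={"sst": 1.0}, seed=70)
        m = SplineBinomialGAM(covariates=["sst", "depth"]).fit(df, df["response"].to_numpy())
        pm = threshold_and_map(m, env_small, "summer", df, colonies, "marion")
        finite = pm.probability[np.isfinite(pm.probability)]
        assert np.all((finite >= 0) & (finite <= 1))
        assert pm.suitability is not None
        # suitable-cell count is monotone non-increasing in the threshold
        counts = [
            np.nansum(pm.probability >= t) for t in np.linspace(0.05, 0.95, 10)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_degenerate_roc_gives_probability_only(self, env_small, colonies):
        df = make_use_availability(6, 50, weights={"sst": 1.0}, seed=71)
        df["response"] = 1
        m = SplineBinomialGAM(covariates=["sst"]).fit(
            make_use_availability(6, 50, weights={"sst": 1.0}, seed=72),
            make_use_availability(6, 50, weights={"sst": 1.0}, seed=72)["response"].to_numpy(),
        )
        with pytest.warns(UserWarning, match="degenerate ROC"):
            pm = threshold_and_map(m, env_small, "summer", df, colonies, "marion")
        assert pm.suitability is None and pm.threshold is None


class TestGroupSmootherTest:
    def test_opposite_preferences_detected(self):
        df = make_use_availability(
            n_individuals=12, records_per_individual=250,
            group_factor="sex", group_weights=({"chl": 1.5}, {"chl": -1.5}),
            covariates=["chl"], seed=80,
        )
        res = group_smoother_test(df, "sex", ["chl"])
        assert res.preferred == "group-specific"
        assert res.median_difference > 0

    def test_identical_preferences_not_significant(self):
        df = make_use_availability(
            n_individuals=12, records_per_individual=250,
            group_factor="sex", group_weights=({"chl": 1.2}, {"chl": 1.2}),
            covariates=["chl"], seed=81,
        )
        res = group_smoother_test(df, "sex", ["chl"])
        assert res.preferred == "shared"

    def test_small_groups_inapplicable(self):
        df = make_use_availability(
            n_individuals=4, records_per_individual=50,
            group_factor="sex", covariates=["chl"], seed=82,
        )
        df = df[df["sex"].eq("female") | df["individual_id"].eq("ind001")]
        with pytest.raises(ValueError):
            group_smoother_test(df, "sex", ["chl"])
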