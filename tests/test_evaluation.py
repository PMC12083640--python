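"""Metrics, stratified bootstrap, confirmation rates, subgroups, agreement."""

import random

import numpy as np
import pandas as pd
import pytest

from compac import (
    ConfusionCounts,
    SubgroupSpec,
    bootstrap_metrics,
    characterize_cohort,
    confirmation_rate,
    confirmation_rate_from_counts,
    confusion,
    interannotator_agreement,
    parse_rule,
    point_metrics,
    subgroup_eval,
    table2_fixture,
)
from compac.evaluation import ALL_ENCOUNTERS, WITHIN_GROUP, round_half_up
from compac.rule_engine import COMPAC_TEXT

from conftest import make_cohort


def labels_map(**kwargs):
    return {k: ("asthma" if v else "not_asthma") for k, v in kwargs.items()}


class TestConfusion:
    def test_basic_counts(self):
        c = confusion({"A"}, labels_map(A=True, B=False))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 1)

    def test_false_positive(self):
        c = confusion({"A", "B"}, labels_map(A=True, B=False))
        assert c.fp == 1

    def test_all_missed(self):
        c = confusion(set(), labels_map(A=True, B=True, C=True))
        assert (c.tp, c.fn) == (0, 3)

    def test_empty_labels_fatal(self):
        with pytest.raises(ValueError):
            confusion({"A"}, {})

    def test_disagreeing_reviewers_excluded_and_tallied(self):
        labels = pd.DataFrame(
            [("A", "R1", "asthma"), ("A", "R2", "asthma"),
             ("B", "R1", "asthma"), ("B", "R2", "not_asthma")],
            columns=["patient_id", "reviewer_id", "label"],
        )
        c = confusion({"A"}, labels)
        assert (c.tp, c.n, c.n_excluded) == (1, 1, 1)


class TestPointMetrics:
    def test_stratum_ppv_three_dp(self):
        m = point_metrics(ConfusionCounts(tp=30, fp=2, fn=0, tn=0))
        assert round_half_up(m["ppv"], 3) == 0.938

    def test_hand_arithmetic(self):
        m = point_metrics(ConfusionCounts(tp=1, fp=0, fn=1, tn=0))
        assert m["sensitivity"] == 0.5
        assert m["ppv"] == 1.0
        assert m["f1"] == pytest.approx(2 / 3)

    def test_degenerate_ratios_are_none(self):
        m = point_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert m["sensitivity"] is None
        assert m["specificity"] == 1.0
        assert m["f1"] is None


def independent_bootstrap_means(identified, label_map, n_pos, n_neg, iters, seed):
    """Second, independently coded resampler: pure-python loops over
    ``random.Random`` draws (different RNG family from the implementation)."""
    pos = sorted(p for p in label_map if p in identified)
    neg = sorted(p for p in label_map if p not in identified)
    rng = random.Random(seed)
    sums = {"sensitivity": [], "ppv": [], "specificity": [], "f1": []}
    for _ in range(iters):
        tp = sum(label_map[rng.choice(pos)] == "asthma" for _ in range(n_pos))
        fn = sum(label_map[rng.choice(neg)] == "asthma" for _ in range(n_neg))
        fp, tn = n_pos - tp, n_neg - fn
        if tp + fn:
            sums["sensitivity"].append(tp / (tp + fn))
        sums["ppv"].append(tp / (tp + fp))
        if tn + fp:
            sums["specificity"].append(tn / (tn + fp))
        if tp + fn and (tp / (tp + fn) + tp / (tp + fp)) > 0:
            s, p = tp / (tp + fn), tp / (tp + fp)
            sums["f1"].append(2 * s * p / (s + p))
    return {k: sum(v) / len(v) for k, v in sums.items()}


class TestBootstrap:
    def perfect_fixture(self):
        identified = {f"C{i}" for i in range(10)}
        label_map = {f"C{i}": "asthma" for i in range(10)}
        label_map.update({f"N{i}": "not_asthma" for i in range(10)})
        return identified, label_map

    def test_perfect_separation_gives_unit_metrics(self):
        identified, label_map = self.perfect_fixture()
        res = bootstrap_metrics(identified, None, label_map, iters=500, seed=1)
        for name in ("sensitivity", "ppv", "f1", "specificity"):
            m = res.metrics[name]
            assert (m.point, m.boot_mean, m.ci_low, m.ci_high) == (1.0, 1.0, 1.0, 1.0)

    def test_same_seed_is_bit_identical(self):
        identified, label_map = self.perfect_fixture()
        label_map["C3"] = "not_asthma"
        label_map["N5"] = "asthma"
        a = bootstrap_metrics(identified, None, label_map, iters=400, seed=9)
        b = bootstrap_metrics(identified, None, label_map, iters=400, seed=9)
        assert a.metrics == b.metrics

    def test_label_noise_independent_of_stratum_gives_half_sensitivity(self):
        # equal strata with equal asthma rates: E[sens] = p/(p+p) = 0.5
        rng = np.random.default_rng(5)
        identified = {f"P{i}" for i in range(100)}
        label_map = {
            f"P{i}": ("asthma" if rng.random() < 0.5 else "not_asthma") for i in range(200)
        }
        res = bootstrap_metrics(identified, None, label_map, iters=4000, seed=2)
        assert res.metrics["sensitivity"].boot_mean == pytest.approx(0.5, abs=0.03)

    def test_ci_brackets_mean_for_every_metric(self, small_synth):
        _, cohort, _, counts = small_synth
        res = bootstrap_metrics(
            parse_rule(COMPAC_TEXT), counts, cohort.labels, iters=1000, seed=4
        )
        for m in res.metrics.values():
            if m.boot_mean is not None:
                assert m.ci_low <= m.boot_mean <= m.ci_high

    def test_ppv_depends_only_on_identified_stratum(self):
        identified = {f"P{i}" for i in range(40)}
        rng = np.random.default_rng(8)
        label_map = {
            f"P{i}": ("asthma" if rng.random() < 0.6 else "not_asthma") for i in range(80)
        }
        res1 = bootstrap_metrics(identified, None, label_map, iters=800, seed=3)
        # permute labels within the negative stratum only
        neg = sorted(p for p in label_map if p not in identified)
        shuffled = list(np.random.default_rng(99).permutation([label_map[p] for p in neg]))
        label_map2 = dict(label_map)
        label_map2.update(dict(zip(neg, shuffled)))
        res2 = bootstrap_metrics(identified, None, label_map2, iters=800, seed=3)
        assert res1.metrics["ppv"] == res2.metrics["ppv"]

    def test_empty_stratum_is_fatal_naming_stratum(self):
        label_map = labels_map(A=True, B=False)
        with pytest.raises(ValueError, match="stratum"):
            bootstrap_metrics(set(), None, label_map, iters=10, seed=0)

    def test_matches_independent_resampler(self):
        rng = np.random.default_rng(12)
        identified = {f"P{i}" for i in range(60)}
        label_map = {}
        for i in range(120):
            p_asthma = 0.8 if i < 60 else 0.25
            label_map[f"P{i}"] = "asthma" if rng.random() < p_asthma else "not_asthma"
        res = bootstrap_metrics(identified, None, label_map, iters=10_000, seed=21)
        indep = independent_bootstrap_means(identified, label_map, 20, 20, 10_000, 22)
        for name in ("sensitivity", "ppv", "specificity", "f1"):
            assert res.metrics[name].boot_mean == pytest.approx(indep[name], abs=0.005)

    def test_mean_stable_between_1k_and_10k_iterations(self):
        rng = np.random.default_rng(30)
        identified = {f"P{i}" for i in range(50)}
        label_map = {
            f"P{i}": ("asthma" if rng.random() < (0.8 if i < 50 else 0.2) else "not_asthma")
            for i in range(100)
        }
        big = bootstrap_metrics(identified, None, label_map, iters=10_000, seed=7)
        small = bootstrap_metrics(identified, None, label_map, iters=1_000, seed=7)
        for name in ("sensitivity", "ppv", "specificity", "f1"):
            assert abs(big.metrics[name].boot_mean - small.metrics[name].boot_mean) < 0.02


class TestConfirmationRate:
    # (row index, printed rate) for the published strata
    PRINTED = [
        (0, 25.0), (1, 20.0), (2, 5.3), (3, 93.8), (4, 16.7), (5, 95.7), (6, 94.4),
        (7, 66.7), (8, 68.4), (9, 52.6), (10, 42.9), (11, 100.0), (12, 70.0),
    ]

    @pytest.mark.parametrize("idx, printed", PRINTED)
    def test_published_rates_recomputed_exactly(self, idx, printed):
        row = table2_fixture()[idx]
        assert confirmation_rate_from_counts(row.confirmed, row.reviewed) == printed

    def test_rate_from_patient_sets(self):
        labels = labels_map(A=True, B=True, C=False)
        pattern = table2_fixture()[0].pattern
        assert confirmation_rate(pattern, labels, {"A", "B", "C"}) == pytest.approx(66.7)

    def test_zero_confirmed(self):
        assert confirmation_rate_from_counts(0, 1) == 0.0

    def test_no_reviewed_in_stratum_fatal(self):
        with pytest.raises(ValueError):
            confirmation_rate_from_counts(0, 0)


class TestSubgroups:
    def test_age_bin_boundaries(self):
        from compac.evaluation import age_bin_label

        spec = SubgroupSpec(dimension="age_group")
        assert age_bin_label(5.9, spec) == "2-5"
        assert age_bin_label(6.0, spec) == "6-12"
        assert age_bin_label(13.0, spec) == "13-18"
        assert age_bin_label(18.0, spec) is None

    def test_sex_confusions_sum_to_whole(self, small_synth):
        _, cohort, _, counts = small_synth
        rule = parse_rule(COMPAC_TEXT)
        spec = SubgroupSpec(dimension="sex")
        results = subgroup_eval(rule, cohort, cohort.labels, spec, iters=200, seed=6)
        total = ConfusionCounts(0, 0, 0, 0)
        for res in results.values():
            if res is not None:
                total = total + res.confusion
        whole = bootstrap_metrics(rule, counts, cohort.labels, iters=10, seed=0).confusion
        assert (total.tp, total.fp, total.fn, total.tn) == (
            whole.tp, whole.fp, whole.fn, whole.tn,
        )

    def test_within_group_identifies_subset_of_all_encounters(self, small_synth):
        _, cohort, _, _ = small_synth
        from compac import apply_phenotype, apply_age_window, build_feature_events
        from compac import count_features, restrict_to_age_range

        rule = parse_rule(COMPAC_TEXT)
        events = apply_age_window(build_feature_events(cohort))
        ids = cohort.patients["patient_id"].astype(str)
        full = set(apply_phenotype(rule, count_features(events, patient_ids=ids)))
        for lo, hi in ((2.0, 6.0), (6.0, 13.0), (13.0, 18.0)):
            bin_counts = count_features(
                restrict_to_age_range(events, lo, hi), patient_ids=ids
            )
            assert set(apply_phenotype(rule, bin_counts)) <= full

    def test_subgroup_without_labeled_members_is_none(self):
        cohort = make_cohort(
            patients=[("P1", "2010-01-01", "Male", "NHW"), ("P2", "2011-01-01", "Female", "NHB")],
            encounters=[("E1", "P1", "2015-01-01"), ("E2", "P2", "2015-01-01")],
            diagnoses=[("E1", "ICD10CM", "J45.901"), ("E2", "ICD10CM", "J45.901")],
            notes=[("N1", "E1", "asthma"), ("N2", "E2", "asthma")],
            labels=[("P1", "R1", "asthma")],  # no labeled Female
        )
        results = subgroup_eval(
            parse_rule("dx>=1"), cohort, cohort.labels,
            SubgroupSpec(dimension="sex"), iters=10, seed=0,
        )
        assert results["Female"] is None
        assert results["Male"] is not None

    def test_window_modes_differ_when_signal_is_age_local(self):
        # all asthma activity at ages 6-12; rule needs dx>=2
        cohort = make_cohort(
            patients=[("P1", "2000-01-01", "Male", "NHW")],
            encounters=[("E1", "P1", "2007-01-01"), ("E2", "P1", "2013-06-01")],
            diagnoses=[("E1", "ICD10CM", "J45.901"), ("E2", "ICD10CM", "J45.901")],
            labels=[("P1", "R1", "asthma")],
        )
        # first event at age 7 -> bin 6-12; second dx is at age 13.4
        rule = parse_rule("dx>=2")
        res_all = subgroup_eval(
            rule, cohort, cohort.labels,
            SubgroupSpec(dimension="age_group", window_mode=ALL_ENCOUNTERS),
            iters=10, seed=0,
        )
        res_within = subgroup_eval(
            rule, cohort, cohort.labels,
            SubgroupSpec(dimension="age_group", window_mode=WITHIN_GROUP),
            iters=10, seed=0,
        )
        assert res_all["6-12"].confusion.tp == 1      # both dx visits count
        assert res_within["6-12"].confusion.tp == 0   # only the in-bin dx visit


class TestCharacterize:
    def test_empty_identified_set(self, small_synth):
        _, cohort, _, counts = small_synth
        table = characterize_cohort(cohort, set(), counts_table=counts)
        assert (table["n"] == 0).all()

    def test_percentages_bounded(self, small_synth):
        _, cohort, truth, counts = small_synth
        identified = {p for p, s in truth.items() if s}
        table = characterize_cohort(cohort, identified, counts_table=counts)
        for dim in ("sex", "race_ethnicity", "age"):
            sub = table[table["dimension"] == dim]
            assert sub["pct"].sum() <= 100.0 + 0.5

    def test_planted_sex_split_recovered(self, small_synth):
        _, cohort, _, counts = small_synth
        everyone = set(cohort.patients["patient_id"].astype(str))
        table = characterize_cohort(cohort, everyone, counts_table=counts)
        male = table[(table["dimension"] == "sex") & (table["category"] == "Male")]["pct"].iloc[0]
        # planted 52.6% male; binomial 99% interval at n=400 is about +/- 6.5
        assert abs(male - 52.6) < 6.5

    def test_top_prescriptions_exclude_nothing_but_are_patient_level(self, small_synth):
        _, cohort, truth, counts = small_synth
        identified = {p for p, s in truth.items() if s}
        table = characterize_cohort(cohort, identified, counts_table=counts)
        meds = table[table["dimension"] == "prescription"]
        assert len(meds) <= 5
        assert (meds["n"] <= len(identified)).all()


class TestInterannotatorAgreement:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "reviewer_id", "label"])

    def test_full_agreement(self):
        labels = self.frame(
            [("A", "R1", "asthma"), ("A", "R2", "asthma"),
             ("B", "R1", "not_asthma"), ("B", "R2", "not_asthma")]
        )
        assert interannotator_agreement(labels) == 1.0

    def test_six_of_seven(self):
        rows = []
        for i in range(6):
            rows += [(f"P{i}", "R1", "asthma"), (f"P{i}", "R2", "asthma")]
        rows += [("P6", "R1", "asthma"), ("P6", "R2", "not_asthma")]
        assert round_half_up(interannotator_agreement(self.frame(rows)), 3) == 0.857

    def test_single_annotated_excluded_from_denominator(self):
        labels = self.frame(
            [("A", "R1", "asthma"), ("A", "R2", "asthma"), ("B", "R1", "asthma")]
        )
        assert interannotator_agreement(labels) == 1.0

    def test_no_double_annotation_fatal(self):
        with pytest.raises(ValueError):
            interannotator_agreement(self.frame([("A", "R1", "asthma")]))
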