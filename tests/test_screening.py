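"""Univariate screening, exhaustive model search and the CV separation check."""

import math

import numpy as np
import pytest

import ctratio as cr
from ctratio.errors import ConfigError, ValidationError


def report_signature(report):
    return [(m.covariates, m.performance.accuracy, m.performance.auc)
            for m in report.top_models]


class TestComparisons:
    def test_four_study_contrasts(self):
        assert set(cr.COMPARISONS) == {"NTP_vs_others", "ALL_vs_others",
                                       "AML_vs_others", "ALL_vs_AML"}

    def test_all_vs_aml_excludes_ntp(self, cohort):
        mask, y = cr.COMPARISONS["ALL_vs_AML"].labels(cohort.groups)
        assert mask.sum() == 66            # 22 ALL + 44 AML
        assert y.sum() == 22               # positive class is ALL

    def test_rest_comparisons_use_everyone(self, cohort):
        for name in ("NTP_vs_others", "ALL_vs_others", "AML_vs_others"):
            mask, y = cr.COMPARISONS[name].labels(cohort.groups)
            assert mask.sum() == 114
            assert y.sum() == {"NTP_vs_others": 48, "ALL_vs_others": 22,
                               "AML_vs_others": 44}[name]

    def test_overlapping_sides_rejected(self):
        with pytest.raises(ConfigError):
            cr.ComparisonSpec("bad", frozenset({"ALL"}), frozenset({"ALL"}))


class TestModelCounts:
    def test_full_space_closed_form(self):
        assert cr.count_models(406, (2, 3)) == 11_153_835

    @pytest.mark.parametrize("v,sizes", [(5, (2, 3)), (8, (1, 2)), (12, (3,)),
                                         (6, (2,)), (9, (1, 2, 3))])
    def test_closed_form_matches_sharder(self, v, sizes):
        assert cr.count_models(v, sizes) == sum(
            1 for _ in cr.iter_subsets(v, sizes))
        assert cr.count_models(v, sizes) == sum(
            math.comb(v, k) for k in sizes)

    def test_shards_partition_the_space(self):
        serial = list(cr.iter_subsets(7, (2, 3)))
        shards = [list(cr.iter_subsets(7, (2, 3), n_shards=3, shard_index=s))
                  for s in range(3)]
        merged = sorted(sum(shards, []))
        assert merged == sorted(serial)
        assert sum(len(s) for s in shards) == len(serial)


class TestUnivariateScreen:
    def test_planted_variable_ranks_first(self, panel):
        cfg = cr.SyntheticConfig(effects=(("miR-150", "ALL", 2.0),
                                          ("miR-150", "AML", 2.0)))
        matrix = cr.generate_cohort(cfg, seed=7)
        results = cr.univariate_screen(matrix, cr.COMPARISONS["NTP_vs_others"],
                                       panel)
        top = results[0]
        assert "miR-150" in top.covariates[0].split(":")
        assert top.significant
        assert results == sorted(results,
                                 key=lambda r: (r.p_adjusted, r.covariates))

    def test_row_count_and_adjustment(self, cohort, panel):
        results = cr.univariate_screen(cohort, cr.COMPARISONS["ALL_vs_AML"],
                                       panel)
        assert len(results) == 406
        for r in results[:10]:
            assert r.p_adjusted == pytest.approx(r.p_raw * 1624)

    def test_filter_keeps_significant_and_nf3(self, cohort, panel):
        results = cr.univariate_screen(cohort, cr.COMPARISONS["NTP_vs_others"],
                                       panel)
        kept = cr.filter_report_rows(results)
        names = {r.covariates[0] for r in kept}
        # every :nf3 variable appears regardless of significance
        assert sum(1 for n in names if "nf3" in n.split(":")) == 28
        assert all(r.significant or "nf3" in r.covariates[0].split(":")
                   for r in kept)

    def test_degenerate_side_rejected(self, panel):
        cfg = cr.SyntheticConfig(group_sizes={"NTP": 5, "ALL": 1, "AML": 5})
        matrix = cr.generate_cohort(cfg, seed=0)
        with pytest.raises(ValidationError):
            cr.univariate_screen(matrix, cr.COMPARISONS["ALL_vs_others"], panel)


@pytest.fixture(scope="module")
def small_search_setup():
    panel = cr.MarkerPanel()
    cfg = cr.SyntheticConfig(effects=(("miR-150", "ALL", 2.0),
                                      ("miR-150", "AML", 2.0),
                                      ("miR-223", "ALL", -1.5),
                                      ("miR-223", "AML", -1.5)))
    matrix = cr.generate_cohort(cfg, seed=3)
    variables = [cr.RatioVariable.from_name(n) for n in
                 ("miR-150:nf3", "miR-223:nf3", "miR-21:nf3", "miR-24:nf3",
                  "miR-100:miR-124", "miR-126:miR-128", "let7a:miR-96",
                  "miR-9:miR-92a")]
    return panel, matrix, variables


class TestExhaustiveSearch:
    def test_subset_of_five_gives_twenty_models(self, small_search_setup):
        panel, matrix, variables = small_search_setup
        rep = cr.exhaustive_search(matrix, cr.COMPARISONS["NTP_vs_others"],
                                   panel, variable_subset=variables[:5],
                                   top_n=3, log_every=0)
        assert rep.total_models_evaluated == 20

    def test_two_variables_sizes_two(self, small_search_setup):
        panel, matrix, variables = small_search_setup
        rep = cr.exhaustive_search(matrix, cr.COMPARISONS["NTP_vs_others"],
                                   panel, sizes=(2,),
                                   variable_subset=variables[:2],
                                   top_n=1, log_every=0)
        assert rep.total_models_evaluated == 1
        assert set(rep.top_models[0].covariates) == {v.name for v in variables[:2]}

    def test_informative_pair_wins(self, small_search_setup):
        panel, matrix, variables = small_search_setup
        rep = cr.exhaustive_search(matrix, cr.COMPARISONS["NTP_vs_others"],
                                   panel, sizes=(2,),
                                   variable_subset=variables,
                                   top_n=1, log_every=0)
        assert {"miR-150:nf3", "miR-223:nf3"} <= set(rep.top_models[0].covariates)

    def test_sharded_equals_serial(self, small_search_setup):
        panel, matrix, variables = small_search_setup
        comp = cr.COMPARISONS["NTP_vs_others"]
        serial = cr.exhaustive_search(matrix, comp, panel,
                                      variable_subset=variables, top_n=4,
                                      log_every=0)
        shards = [cr.exhaustive_search(matrix, comp, panel,
                                       variable_subset=variables, top_n=4,
                                       n_shards=4, shard_index=s, log_every=0)
                  for s in range(4)]
        merged = cr.merge_search_reports(shards)
        assert report_signature(serial) == report_signature(merged)
        assert serial.total_models_evaluated == merged.total_models_evaluated

    def test_ranking_is_deterministic_and_sorted(self, small_search_setup):
        panel, matrix, variables = small_search_setup
        rep = cr.exhaustive_search(matrix, cr.COMPARISONS["NTP_vs_others"],
                                   panel, variable_subset=variables, top_n=5,
                                   log_every=0)
        keys = [m.key for m in rep.top_models]
        assert keys == sorted(keys)

    def test_max_models_caps_evaluation(self, small_search_setup):
        panel, matrix, variables = small_search_setup
        rep = cr.exhaustive_search(matrix, cr.COMPARISONS["NTP_vs_others"],
                                   panel, variable_subset=variables,
                                   top_n=2, max_models=10, log_every=0)
        assert rep.total_models_evaluated == 10

    def test_bad_arguments(self, small_search_setup):
        panel, matrix, variables = small_search_setup
        with pytest.raises(ConfigError):
            cr.exhaustive_search(matrix, cr.COMPARISONS["NTP_vs_others"],
                                 panel, variable_subset=[], top_n=1)
        with pytest.raises(ConfigError):
            cr.exhaustive_search(matrix, cr.COMPARISONS["NTP_vs_others"],
                                 panel, variable_subset=variables, top_n=0)


class TestCvPredictionTest:
    def test_constant_predictions_p_one(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        res = cr.cv_prediction_test(np.full(6, 0.5), y)
        assert res.p_raw == 1.0

    def test_perfect_separation_below_display_floor(self):
        y = np.concatenate([np.ones(48), np.zeros(66)])
        probs = np.concatenate([np.linspace(0.8, 1.0, 48),
                                np.linspace(0.0, 0.2, 66)])
        res = cr.cv_prediction_test(probs, y)
        assert res.p_raw == pytest.approx(2 / math.comb(114, 48), rel=1e-9)
        assert res.p_raw < 2.2e-16

    def test_null_p_roughly_uniform(self, rng):
        from scipy.stats import kstest
        ps = []
        for _ in range(200):
            y = np.concatenate([np.ones(10), np.zeros(12)])
            probs = rng.random(22)
            ps.append(cr.cv_prediction_test(probs, y).p_raw)
        # exact p-values are discrete and conservative; KS against uniform
        # should not reject wildly
        assert kstest(ps, "uniform").pvalue > 1e-3
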