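import numpy as np
import pandas as pd
import pytest

import frontload as fl
from frontload.classify import Bookkeeping, flip_contrast
from frontload.de import response_contrast
from frontload.exceptions import ContrastSpecError, UndefinedRatioError


class TestGenotypeSpecificResponse:
    def test_identical_deg_sets_give_empty(self, fixture_quartet):
        q = fixture_quartet
        # focal contrast carrying the same DEG calls as the other genotype
        focal_like = fl.ContrastResult(q["response_HI"].spec, q["response_LO"].table)
        assert len(fl.genotype_specific_response(q["response_LO"], focal_like)) == 0

    def test_hand_set_difference(self, fixture_matrix):
        q = fl.de_quartet(fixture_matrix)
        specific = fl.genotype_specific_response(q["response_LO"], q["response_HI"])
        assert set(specific.index) == {
            "g_front", "g_relup", "g_failratio", "g_failde", "g_notexpr",
        }
        assert specific["g_front"] == "up"
        assert specific["g_relup"] == "down"

    def test_rejects_non_response_contrast(self, fixture_matrix):
        q = fl.de_quartet(fixture_matrix)
        with pytest.raises(ContrastSpecError):
            fl.genotype_specific_response(q["between_N1"], q["response_HI"])

    def test_planted_frontloaded_land_in_other_specific_set(self, default_run):
        _, truth, res = default_run
        specific = fl.genotype_specific_response(
            res.contrasts["response_LO"], res.contrasts["response_HI"])
        planted = set(truth.loc[truth["archetype"] == "frontloaded_in_HI", "gene_id"])
        hit = planted & set(specific.index)
        assert len(hit) / len(planted) >= 0.9
        assert (specific.loc[sorted(hit)] == "up").all()


class TestFilters:
    def test_expression_filter_drops_silent_focal_gene(self, fixture_matrix):
        cfg = fl.ClassifierConfig()
        kept, removed = fl.expression_filter(
            ["g_front", "g_notexpr"], fixture_matrix, "HI", cfg)
        assert kept == ["g_front"] and removed == 1

    def test_zero_floor_is_identity(self, fixture_matrix):
        cfg = fl.ClassifierConfig(expression_floor=0.0)
        genes = ["g_front", "g_notexpr", "g_relup"]
        kept, removed = fl.expression_filter(genes, fixture_matrix, "HI", cfg)
        assert kept == genes and removed == 0

    def test_trend_filter_keeps_sign_consistent_genes(self, fixture_quartet):
        genes = pd.Series({"g_front": "up", "g_relup": "down"})
        kept, removed = fl.trend_filter(
            genes, fixture_quartet["between_N1"], fixture_quartet["between_N0"])
        assert list(kept.index) == ["g_front", "g_relup"] and removed == 0

    def test_trend_filter_drops_sign_contradiction(self, fixture_quartet):
        b1 = fixture_quartet["between_N1"]
        t = b1.table.copy()
        t.loc["g_front", "log2fc"] = -t.loc["g_front", "log2fc"]  # contradict means
        tampered = fl.ContrastResult(b1.spec, t, b1.alpha, b1.fc_min)
        genes = pd.Series({"g_front": "up", "g_relup": "down"})
        kept, removed = fl.trend_filter(genes, tampered, fixture_quartet["between_N0"])
        assert list(kept.index) == ["g_relup"] and removed == 1

    def test_trend_filter_drops_undefined_ratio_gene(self, fixture_quartet):
        b1, b0 = fixture_quartet["between_N1"], fixture_quartet["between_N0"]
        t1, t0 = b1.table.copy(), b0.table.copy()
        for t in (t1, t0):  # other genotype silent in both treatments
            t.loc["g_front", ["mean_den", "log2fc"]] = [0.0, 1.0]
            t.loc["g_front", "mean_num"] = 2.0
        genes = pd.Series({"g_front": "up"})
        kept, removed = fl.trend_filter(
            genes,
            fl.ContrastResult(b1.spec, t1, b1.alpha, b1.fc_min),
            fl.ContrastResult(b0.spec, t0, b0.alpha, b0.fc_min),
        )
        assert len(kept) == 0 and removed == 1


class TestClassify:
    def test_hand_fixture_full_ledger(self, fixture_matrix, fixture_quartet):
        res = fl.classify(fixture_matrix, fixture_quartet, focal="HI")
        labels = res.table["label"]
        assert labels["g_front"] == "frontloaded"
        assert labels["g_relup"] == "relatively_upregulated"
        assert labels["g_failratio"] == "candidate_unclassified"
        assert labels["g_failde"] == "not_candidate"
        assert labels["g_notexpr"] == "excluded_not_expressed"
        assert "g_shared" not in res.table.index
        bk = res.bookkeeping
        assert bk == Bookkeeping(
            n_specific=5, n_not_expressed=1, n_trend_inconsistent=0,
            n_classifiable=4, n_up=2, n_down=2,
            n_candidate_front=1, n_candidate_relup=2, n_front=1, n_relup=1,
        )
        # ratio sanity on the frontloaded gene: >2 under N1, <0.5 under N0
        assert res.table.loc["g_front", "r_n1"] > 2
        assert res.table.loc["g_front", "r_n0"] < 0.5

    def test_all_null_simulation_labels_nothing(self):
        model, _ = fl.FrontloadModel.from_simulation(fl.null_config(400, seed=8))
        res = model.fit()
        for g in ("HI", "LO"):
            bk = res.classifications[g].bookkeeping
            assert bk.n_front == 0 and bk.n_relup == 0

    def test_labeled_sets_disjoint_and_within_specific(self, default_run):
        _, _, res = default_run
        for g in ("HI", "LO"):
            c = res.classifications[g]
            front = set(c.frontloaded)
            relup = set(c.relatively_upregulated)
            assert not front & relup
            assert front | relup <= set(c.table.index)

    def test_genotype_swap_exchanges_results(self, default_run):
        model, _, res = default_run
        sheet = model.counts.samples.table.copy()
        sheet["genotype"] = sheet["genotype"].map({"HI": "LO", "LO": "HI"})
        swapped = fl.FrontloadModel(
            fl.CountMatrix(model.counts.counts, fl.SampleSheet(sheet)))
        res_sw = swapped.fit()
        for a, b in (("HI", "LO"), ("LO", "HI")):
            orig, sw = res.classifications[a], res_sw.classifications[b]
            assert orig.bookkeeping == sw.bookkeeping
            pd.testing.assert_frame_equal(
                orig.table.sort_index(), sw.table.sort_index())

    def test_threshold_monotonicity(self, fixture_matrix, fixture_quartet, default_run):
        model, _, _ = default_run
        loose = fl.classify(model.counts, fl.de_quartet(model.counts), "HI",
                            fl.ClassifierConfig(ratio_high=2.0, ratio_low=0.5))
        tight = fl.classify(model.counts, fl.de_quartet(model.counts), "HI",
                            fl.ClassifierConfig(ratio_high=4.0, ratio_low=0.25))
        assert set(tight.frontloaded) <= set(loose.frontloaded)

    def test_global_rescaling_invariance(self, fixture_matrix, fixture_quartet):
        res1 = fl.classify(fixture_matrix, fixture_quartet, "HI")
        m2 = fl.CountMatrix(fixture_matrix.counts * 2, fixture_matrix.samples)
        res2 = fl.classify(m2, fl.de_quartet(m2), "HI")
        assert res1.table["label"].equals(res2.table["label"])

    def test_malformed_quartet_is_spec_error(self, fixture_matrix, fixture_quartet):
        broken = {k: v for k, v in fixture_quartet.items() if k != "between_N0"}
        with pytest.raises(ContrastSpecError, match="between_N0"):
            fl.classify(fixture_matrix, broken, "HI")

    def test_flip_contrast_is_involutive(self, fixture_quartet):
        b = fixture_quartet["between_N1"]
        bb = flip_contrast(flip_contrast(b))
        pd.testing.assert_frame_equal(b.table, bb.table)
        assert bb.spec.numerator == b.spec.numerator


class TestBookkeepingAndSummary:
    def test_published_funnel_arithmetic(self):
        # two DEG funnels: specific -> minus not-expressed -> minus trend ->
        # classifiable split into up/down
        bk_w = Bookkeeping(4789, 25, 39, 4725, 2584, 2141, 203, 72, 103, 43)
        assert bk_w.n_classifiable == 4789 - 25 - 39 == 4725
        bk_y = Bookkeeping(4658, 63, 61, 4534, 1905, 2629, 95, 93, 45, 50)
        assert bk_y.n_classifiable == 4658 - 63 - 61 == 4534

    def test_inconsistent_bookkeeping_rejected(self):
        with pytest.raises(ValueError):
            Bookkeeping(10, 1, 1, 9, 5, 4, 2, 2, 1, 1)

    def test_summary_ratio_cases(self, fixture_matrix, fixture_quartet):
        res_hi = fl.classify(fixture_matrix, fixture_quartet, "HI")

        def fake(n_front):
            bk = Bookkeeping(n_front, 0, 0, n_front, n_front, 0, n_front, 0, n_front, 0)
            return fl.ClassificationResult("LO", res_hi.table.iloc[:0], bk,
                                           fl.ClassifierConfig())

        assert fl.summary_ratio(fake(103), fake(45)) == pytest.approx(2.2889, abs=1e-4)
        assert fl.summary_ratio(fake(7), fake(7)) == 1.0
        assert fl.summary_ratio(fake(10), fake(4)) == 2.5
        with pytest.raises(UndefinedRatioError):
            fl.summary_ratio(fake(1), fake(0))

    def test_parameter_recovery_on_default_benchmark(self, default_run):
        _, truth, res = default_run
        metrics = fl.evaluate_classification(res.classifications, truth)
        assert (metrics["sensitivity"] >= 0.8).all()
        assert (metrics["precision"] >= 0.8).all()
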