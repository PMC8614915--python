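import numpy as np
import pandas as pd
import pytest

import frontload as fl
from frontload.de import between_contrast, response_contrast
from frontload.exceptions import ContrastSpecError, DomainError, SchemaError
from frontload.simulate import ArchetypeSpec, Archetype, SimulationConfig, design_sheet, simulate


def brute_force_bh(p):
    """Direct enumeration of the step-up rule, independent of the implementation."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, min(1.0, m * p[i] / rank))
        adj[i] = running_min
    return adj


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.005, 0.1], [0.01, 0.1]),
        ],
    )
    def test_hand_cases(self, p, expected):
        assert fl.bh_adjust(p) == pytest.approx(expected)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 21))
            assert fl.bh_adjust(p) == pytest.approx(brute_force_bh(p))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(size=50))
        adj = fl.bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= p).all() and (adj <= 1).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            fl.bh_adjust([0.5, 1.5])


class TestSizeFactors:
    def test_identical_columns_give_ones(self):
        sheet = design_sheet(2)
        m = fl.CountMatrix(
            pd.DataFrame({s: [10, 20, 30] for s in sheet.sample_ids},
                         index=["a", "b", "c"]), sheet)
        assert fl.size_factors(m).to_numpy() == pytest.approx(np.ones(8))

    def test_doubled_column_scales_factor(self):
        sheet = design_sheet(2)
        base = np.array([10, 20, 30])
        data = {s: base for s in sheet.sample_ids[:-1]}
        data[sheet.sample_ids[-1]] = base * 2
        m = fl.CountMatrix(pd.DataFrame(data, index=["a", "b", "c"]), sheet)
        sf = fl.size_factors(m)
        assert sf.iloc[-1] / sf.iloc[0] == pytest.approx(2.0)

    def test_fallback_proportional_to_column_sums(self, caplog):
        sheet = design_sheet(2)
        # every gene has a zero somewhere -> median-of-ratios undefined
        data = np.eye(8, dtype=int) * np.array([4, 9, 4, 9, 4, 9, 4, 9])
        m = fl.CountMatrix(
            pd.DataFrame(data, index=[f"g{i}" for i in range(8)],
                         columns=sheet.sample_ids), sheet)
        with caplog.at_level("WARNING"):
            sf = fl.size_factors(m)
        assert "falling back" in caplog.text
        assert sf.to_numpy() == pytest.approx(
            np.array([4, 9, 4, 9, 4, 9, 4, 9]) / 6.5)


class TestDeTest:
    def test_identical_groups_yield_no_degs(self, fixture_matrix):
        res = fl.de_test(fixture_matrix, between_contrast("N1"))
        # HI_N1 and LO_N1 anchors are identical by construction
        anchors = [g for g in fixture_matrix.gene_ids if g.startswith("anchor")]
        sub = res.table.loc[anchors]
        assert (sub["log2fc"].abs() < 0.01).all()
        assert not sub["is_deg"].any()

    def test_antisymmetry_under_swap(self, fixture_matrix):
        fwd = fl.de_test(fixture_matrix, between_contrast("N0"))
        spec = between_contrast("N0")
        rev = fl.de_test(
            fixture_matrix,
            fl.ContrastSpec("rev", spec.denominator, spec.numerator),
        )
        assert rev.table["log2fc"].to_numpy() == pytest.approx(
            -fwd.table["log2fc"].to_numpy())
        assert rev.table["p"].to_numpy() == pytest.approx(fwd.table["p"].to_numpy())

    def test_planted_response_is_detected_upward(self):
        cfg = SimulationConfig(
            archetypes=(
                ArchetypeSpec(Archetype.FRONTLOADED_IN_HI, 20),
                ArchetypeSpec(Archetype.NULL, 200),
            ),
            seed=4,
        )
        m, truth = simulate(cfg)
        res = fl.de_test(m, response_contrast("LO"))
        planted = truth.loc[truth["archetype"] == "frontloaded_in_HI", "gene_id"]
        sub = res.table.loc[planted]
        assert (sub["direction"] == "up").mean() >= 0.9

    def test_invariant_to_replicate_permutation(self, fixture_matrix):
        res1 = fl.de_test(fixture_matrix, response_contrast("LO"))
        sheet = fixture_matrix.samples.table.copy()
        # swap replicate order inside the LO/N0 group
        ids = list(sheet["sample_id"])
        i, j = ids.index("N0_LO_r1"), ids.index("N0_LO_r3")
        sheet.iloc[[i, j]] = sheet.iloc[[j, i]].to_numpy()
        m2 = fl.CountMatrix(fixture_matrix.counts, fl.SampleSheet(sheet))
        res2 = fl.de_test(m2, response_contrast("LO"))
        assert res2.table["p"].to_numpy() == pytest.approx(res1.table["p"].to_numpy())
        assert res2.table["log2fc"].to_numpy() == pytest.approx(
            res1.table["log2fc"].to_numpy())

    def test_missing_group_is_spec_error(self, fixture_matrix):
        sheet = fixture_matrix.samples.table
        half = fl.SampleSheet(sheet[sheet["genotype"] == "HI"])
        m = fl.CountMatrix(fixture_matrix.counts[half.sample_ids], half)
        with pytest.raises(ContrastSpecError):
            fl.de_test(m, between_contrast("N1"))

    def test_welch_engine_available(self, fixture_matrix):
        res = fl.de_test(fixture_matrix, response_contrast("LO"), engine="welch")
        assert res.table.loc["g_relup", "direction"] == "down"
        with pytest.raises(ValueError):
            fl.de_test(fixture_matrix, response_contrast("LO"), engine="bogus")

    def test_null_simulation_controls_fdr(self):
        hits = total = 0
        for seed in range(10):
            m, _ = simulate(fl.null_config(500, seed=seed))
            res = fl.de_test(m, response_contrast("HI"))
            hits += int((res.table["padj"] < 0.05).sum())
            total += len(res.table)
        assert hits / total <= 0.05


class TestContrastTableIO:
    def _write(self, path, padj=True):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2fc": [1.0, -2.0, 0.2],
                "p": [0.001, 0.02, 0.5],
            }
        )
        if padj:
            df["padj"] = [0.04, 0.2, 0.6]
        df.to_csv(path, sep="\t", index=False)

    def test_file_padj_is_honored(self, tmp_path):
        self._write(tmp_path / "de.tsv", padj=True)
        res = fl.read_contrast_table(tmp_path / "de.tsv")
        # b has small p but padj 0.2 in the file -> not a DEG
        assert bool(res.table.loc["a", "is_deg"]) is True
        assert bool(res.table.loc["b", "is_deg"]) is False

    def test_missing_padj_is_recomputed(self, tmp_path):
        self._write(tmp_path / "de.tsv", padj=False)
        res = fl.read_contrast_table(tmp_path / "de.tsv")
        assert res.table["padj"].to_numpy() == pytest.approx(
            fl.bh_adjust([0.001, 0.02, 0.5]))

    def test_fold_change_threshold_is_inclusive(self, tmp_path):
        self._write(tmp_path / "de.tsv", padj=True)
        res = fl.read_contrast_table(tmp_path / "de.tsv", fc_min=1.0)
        assert bool(res.table.loc["a", "is_deg"]) is True  # log2fc exactly 1.0
        strict = fl.read_contrast_table(tmp_path / "de.tsv", fc_min=1.0, fc_strict=True)
        assert bool(strict.table.loc["a", "is_deg"]) is False

    def test_missing_column_is_schema_error(self, tmp_path):
        pd.DataFrame({"gene_id": ["a"], "p": [0.1]}).to_csv(
            tmp_path / "de.tsv", sep="\t", index=False)
        with pytest.raises(SchemaError, match="log2fc"):
            fl.read_contrast_table(tmp_path / "de.tsv")
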