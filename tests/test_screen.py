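"""Read-pair counting, normalization, filters, hit calling and QC metrics."""

import numpy as np
import pandas as pd
import pytest

from lncscreen.screen import (
    ArrayIndex,
    ScreenError,
    analyze_screen,
    array_depletion_pvalues,
    blacklist_arrays,
    call_hits,
    casrx_activity,
    classify_localization,
    compute_array_lfc,
    control_auc,
    count_read_pairs,
    empirical_fdr,
    filter_arrays,
    gene_unified_lfc,
    insertion_normalized_coverage,
    lorenz_representation,
    normalize_counts,
)
from lncscreen.seq import revcomp
from lncscreen.simulate import (
    VECTOR_PREFIX,
    SimulationConfig,
    simulate_library,
    simulate_screen_fastq,
)

_FLIP = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _flip(seq, positions):
    chars = list(seq)
    for p in positions:
        chars[p] = _FLIP[chars[p]]
    return "".join(chars)


def _write_fastq(path, reads):
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


@pytest.fixture
def small_library():
    cfg = SimulationConfig(seed=21)
    lib = simulate_library(
        cfg, n_lnc_genes=5, arrays_per_gene=2, n_ae_genes=1, n_ne_genes=1,
        n_nt_arrays=2,
    )
    return lib


@pytest.fixture
def small_index(small_library):
    return ArrayIndex(
        {a: (r["seq30_1"], r["seq30_2"]) for a, r in small_library.iterrows()}
    )


class TestCounting:
    def _pair_for(self, lib, aid, mm1=(), mm2=()):
        row = lib.loc[aid]
        r1 = _flip(revcomp(row["seq30_2"]), mm1)
        r2 = _flip(VECTOR_PREFIX + row["seq30_1"][:27], mm2)
        return r1, r2

    def test_error_free_pair_counts_once(self, tmp_path, small_library, small_index):
        aid = small_library.index[0]
        r1, r2 = self._pair_for(small_library, aid)
        _write_fastq(tmp_path / "r1.fq", [r1])
        _write_fastq(tmp_path / "r2.fq", [r2])
        counts, report = count_read_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq", small_index)
        assert counts[aid] == 1 and counts.sum() == 1 and report["counted"] == 1

    def test_two_mismatches_tolerated_three_rejected(
        self, tmp_path, small_library, small_index
    ):
        aid = small_library.index[0]
        ok1, ok2 = self._pair_for(small_library, aid, mm2=(30, 40))  # 2 subs in spacer portion
        bad1, bad2 = self._pair_for(small_library, aid, mm2=(30, 40, 50))
        _write_fastq(tmp_path / "r1.fq", [ok1, bad1])
        _write_fastq(tmp_path / "r2.fq", [ok2, bad2])
        counts, report = count_read_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq", small_index)
        assert counts[aid] == 1 and report["unmatched"] == 1

    def test_discordant_mates_are_not_counted(self, tmp_path, small_library, small_index):
        a, b = small_library.index[0], small_library.index[5]
        r1a, _ = self._pair_for(small_library, a)
        _, r2b = self._pair_for(small_library, b)
        _write_fastq(tmp_path / "r1.fq", [r1a])
        _write_fastq(tmp_path / "r2.fq", [r2b])
        counts, report = count_read_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq", small_index)
        assert counts.sum() == 0 and report["discordant"] == 1

    def test_unpaired_files_rejected(self, tmp_path, small_library, small_index):
        r1, r2 = self._pair_for(small_library, small_library.index[0])
        _write_fastq(tmp_path / "r1.fq", [r1, r1])
        _write_fastq(tmp_path / "r2.fq", [r2])
        with pytest.raises(ScreenError, match="read count"):
            count_read_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq", small_index)

    def test_duplicate_keys_reported_and_ambiguous(self, tmp_path):
        lib = {
            "a1": ("A" * 30, "C" * 30),
            "a2": ("A" * 30, "G" * 30),  # shares the position-1 key with a1
        }
        index = ArrayIndex(lib)
        assert index.collisions == ["A" * 27]
        _write_fastq(tmp_path / "r1.fq", [revcomp("C" * 30)])
        _write_fastq(tmp_path / "r2.fq", [VECTOR_PREFIX + "A" * 27])
        counts, report = count_read_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq", index)
        assert counts.sum() == 0 and report["ambiguous"] == 1

    def test_simulated_fastq_roundtrip_exact(self, tmp_path, small_library, small_index):
        cfg = SimulationConfig(seed=3, read_error_rate=0.0)
        rng = np.random.default_rng(4)
        truth = pd.Series(
            rng.integers(0, 20, len(small_library)), index=small_library.index
        )
        simulate_screen_fastq(truth, small_library, tmp_path / "r1.fq", tmp_path / "r2.fq", cfg)
        counts, _ = count_read_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq", small_index)
        assert counts.sort_index().equals(truth.sort_index().astype(np.int64))


class TestNormalization:
    def test_cpm_columns_sum_to_a_million(self):
        m = pd.DataFrame({"a": [10, 30], "b": [5, 5]}, index=["x", "y"])
        cpm, sf = normalize_counts(m, "cpm")
        assert sf is None
        assert cpm.sum(axis=0).tolist() == pytest.approx([1e6, 1e6])

    def test_cpm_all_zero_column_rejected(self):
        m = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ScreenError, match="all-zero"):
            normalize_counts(m, "cpm")

    def test_identical_columns_unit_size_factors(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        _, sf = normalize_counts(m, "median_of_ratios")
        assert sf.tolist() == pytest.approx([1.0, 1.0])

    def test_median_of_ratios_hand_example(self):
        # rows: geometric means sqrt(4*1)=2, sqrt(8*2)=4, sqrt(6*6)=6
        # ratios col a: 2, 2, 1 -> median 2; col b: 0.5, 0.5, 1 -> median 0.5
        m = pd.DataFrame({"a": [4, 8, 6], "b": [1, 2, 6]}, index=["x", "y", "z"])
        normed, sf = normalize_counts(m, "median_of_ratios")
        assert sf.tolist() == pytest.approx([2.0, 0.5])
        assert normed.loc["x"].tolist() == pytest.approx([2.0, 2.0])

    def test_rows_with_zeros_excluded_from_median(self):
        m = pd.DataFrame({"a": [4, 8, 0], "b": [1, 2, 100]})
        _, sf = normalize_counts(m, "median_of_ratios")
        assert sf.tolist() == pytest.approx([2.0, 0.5])


class TestLfc:
    def test_equal_sample_and_baseline_is_zero(self):
        m = pd.DataFrame({"plasmid": [100.0], "s": [100.0]})
        lfc = compute_array_lfc(m, "plasmid")
        assert lfc["s"].iloc[0] == pytest.approx(0.0)

    def test_fourfold_enrichment_is_about_two(self):
        m = pd.DataFrame({"plasmid": [1000.0], "s": [4000.0]})
        assert compute_array_lfc(m, "plasmid")["s"].iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_double_zero_with_pseudocount_is_zero(self):
        m = pd.DataFrame({"plasmid": [0.0], "s": [0.0]})
        assert compute_array_lfc(m, "plasmid")["s"].iloc[0] == 0.0

    def test_missing_baseline_rejected(self):
        with pytest.raises(ScreenError, match="baseline"):
            compute_array_lfc(pd.DataFrame({"s": [1.0]}), "plasmid")


class TestFilters:
    def test_plasmid_count_threshold_is_strict(self):
        idx = [f"a{i}" for i in range(4)]
        counts = pd.DataFrame({"plasmid": [29, 30, 100, 100]}, index=idx)
        lfc = pd.DataFrame({"s": [0.0, 0.0, 0.0, 0.0]}, index=idx)
        keep, report = filter_arrays(lfc, counts, "plasmid", ["s"], [])
        assert list(keep) == ["a1", "a2", "a3"]
        assert report["low_plasmid"] == ["a0"]

    def test_noise_rule_needs_two_controls_and_one_screen(self):
        rng = np.random.default_rng(0)
        idx = [f"a{i}" for i in range(200)]
        base = rng.normal(0, 0.1, 200)
        lfc = pd.DataFrame(
            {"s1": base.copy(), "c1": base.copy(), "c2": base.copy()}, index=idx
        )
        # a0 extreme everywhere -> noisy; a1 extreme only in controls -> kept
        lfc.loc["a0", ["s1", "c1", "c2"]] = [5.0, 5.0, -5.0]
        lfc.loc["a1", ["c1", "c2"]] = [4.0, 4.0]
        counts = pd.DataFrame({"plasmid": 100}, index=idx)
        keep, report = filter_arrays(lfc, counts, "plasmid", ["s1"], ["c1", "c2"])
        assert report["noisy"] == ["a0"] and "a1" in keep

    def test_without_controls_only_plasmid_rule_applies(self):
        idx = ["a0", "a1"]
        lfc = pd.DataFrame({"s1": [9.0, 0.0]}, index=idx)
        counts = pd.DataFrame({"plasmid": [100, 100]}, index=idx)
        keep, report = filter_arrays(lfc, counts, "plasmid", ["s1"], [])
        assert list(keep) == idx and report["noisy"] == []


class TestHitCalling:
    def test_fdr_threshold_is_strict(self):
        genes = pd.DataFrame({"fdr": [0.20, 0.30]}, index=["hit", "miss"])
        assert call_hits(genes, 0.25) == ["hit"]

    def test_blacklist_requires_match_and_reproducible_significance(self):
        p = pd.DataFrame(
            {"s1": [0.04, 0.04, 0.5], "s2": [0.03, 0.5, 0.01]},
            index=["bad", "once", "clean"],
        )
        out = blacklist_arrays(p, {"bad": True, "once": True, "clean": False})
        assert out == ["bad"]

    def test_empty_results_empty_hits(self):
        assert call_hits(pd.DataFrame({"fdr": []}), 0.25) == []

    @pytest.mark.parametrize("fp,total,expected", [(3, 100, 0.03), (0, 50, 0.0), (5, 5, 1.0), (0, 0, 0.0)])
    def test_empirical_fdr(self, fp, total, expected):
        assert empirical_fdr(fp, total) == pytest.approx(expected)

    def test_unified_lfc_two_most_significant(self):
        assert gene_unified_lfc([0.001, 0.01, 0.5], [-2, -1, 0]) == pytest.approx(-1.5)
        assert gene_unified_lfc([0.3, 0.2], [1.0, -1.0]) == pytest.approx(0.0)
        # tie on p: more negative LFCs win
        assert gene_unified_lfc([0.01, 0.01, 0.01], [-3, -1, 0]) == pytest.approx(-2.0)

    def test_array_pvalues_are_normalized_ranks(self):
        lfc = pd.DataFrame({"s": [-2.0, 0.0, 1.0, -1.0]}, index=list("abcd"))
        p = array_depletion_pvalues(lfc)
        assert p["s"].tolist() == pytest.approx([0.25, 0.75, 1.0, 0.5])


class TestQcMetrics:
    def test_auc_separated_identical_and_hand_case(self):
        assert control_auc([-3, -2], [0, 1]) == pytest.approx(1.0)
        assert control_auc([-3, -2], [-2.5, 0]) == pytest.approx(0.75)
        assert control_auc([0.0, 1.0], [0.0, 1.0]) == pytest.approx(0.5)

    def test_auc_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(-1, 1, 30), rng.normal(0, 1, 40)
        assert control_auc(a, b) + control_auc(b, a) == pytest.approx(1.0)

    def test_lorenz_uniform_skewed_single(self):
        assert lorenz_representation([5] * 10) == pytest.approx(90.0)
        # cumulative 70, 80, 90: three of four arrays reach 90% of reads
        assert lorenz_representation([70, 10, 10, 10]) == pytest.approx(75.0)
        assert lorenz_representation([42]) == pytest.approx(100.0)

    def test_localization_threshold_inclusive_on_nuclear_side(self):
        label, lfc = classify_localization(10.0, 10.0)
        assert label == "nuclear-enriched" and lfc == pytest.approx(0.0)
        label, lfc = classify_localization(3.5, 0.5)
        assert label == "cytoplasm-enriched" and lfc == pytest.approx(2.0)
        label, _ = classify_localization(2 ** 0.75 * 8 - 0.5, 7.5)  # LFC exactly 0.75
        assert label == "nuclear-enriched"

    def test_casrx_activity(self):
        assert casrx_activity(100, 1000) == pytest.approx(0.90)
        assert casrx_activity(1000, 1000) == 0.0
        assert casrx_activity(0, 500) == 1.0
        with pytest.warns(UserWarning, match="clipping"):
            assert casrx_activity(2000, 1000) == 0.0

    def test_insertion_coverage_strictly_above_two(self):
        out = insertion_normalized_coverage([50, 0, 20], 1000)
        assert out["normalized_coverage"].tolist() == pytest.approx([5.0, 0.0, 2.0])
        assert out["reliable"].tolist() == [True, False, False]

    def test_artifact_flag_overrides_coverage(self):
        out = insertion_normalized_coverage([50], 1000, artifact_flags=[True])
        assert not out["reliable"].iloc[0]


class TestAnalyzePipeline:
    def test_hit_set_shrinks_with_threshold_and_is_reproducible(self):
        cfg = SimulationConfig(seed=31)
        lib = simulate_library(cfg, n_lnc_genes=60, arrays_per_gene=3,
                               n_ae_genes=5, n_ne_genes=5, n_nt_arrays=10)
        from lncscreen.simulate import simulate_screen_counts

        counts, roles, _ = simulate_screen_counts(cfg, lib)
        kwargs = dict(
            sample_roles=roles,
            array_genes=dict(lib["gene_id"]),
            array_roles=dict(lib["role"]),
            n_permutations=5000,
            rng_seed=2,
        )
        res1 = analyze_screen(counts, **kwargs)
        res2 = analyze_screen(counts, **kwargs)
        pd.testing.assert_frame_equal(res1.gene_table, res2.gene_table)
        strict = call_hits(res1.gene_table, 0.05)
        assert set(strict) <= set(res1.hits)

    def test_blacklisted_arrays_removed_before_aggregation(self):
        cfg = SimulationConfig(seed=33)
        # no AE genes here so the spiked gene's arrays occupy the very top
        # depletion ranks (p < 0.05 in both screen replicates)
        lib = simulate_library(cfg, n_lnc_genes=40, arrays_per_gene=3,
                               n_ae_genes=0, n_ne_genes=8, n_nt_arrays=8)
        from lncscreen.simulate import simulate_screen_counts

        counts, roles, truth = simulate_screen_counts(cfg, lib)
        # mark every array of one depleted gene as essential-matching; only
        # those also depleting (p < 0.05) in both replicates are blacklisted
        gene = truth.depleted_genes[0]
        flags = {a: bool(lib.loc[a, "gene_id"] == gene) for a in lib.index}
        cpm, _ = normalize_counts(counts, "cpm")
        lfc = compute_array_lfc(cpm, "plasmid")
        pv = array_depletion_pvalues(lfc[["screen_rep1", "screen_rep2"]])
        expected = [
            a
            for a in lib.index
            if flags[a] and (pv.loc[a] < 0.05).sum() >= 2
        ]
        assert expected  # the construction must exercise the rule
        res = analyze_screen(
            counts, roles, dict(lib["gene_id"]), dict(lib["role"]),
            essential_match=flags, n_permutations=5000, rng_seed=2,
        )
        assert res.blacklisted_arrays == expected
        assert res.gene_table.loc[gene, "n_arrays"] == 3 - len(expected)
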