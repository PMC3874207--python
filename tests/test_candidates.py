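"""Candidate selection: summit extension, replicate consensus, expression filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trmkit._util import TRMWarning
from trmkit.candidates import (
    CandidateSet,
    EnrichmentRecord,
    ExpressionMatrix,
    MotifMatch,
    compute_cpm,
    consensus_enriched_motifs,
    expressed_genes,
    extend_summits,
    filter_motif_matches,
    parse_enrichment_runs,
    select_candidates,
    write_bed,
)
from trmkit.motif_library import MotifGeneMap, OrthologMap


class TestExtendSummits:
    def test_default_flank_gives_400bp_regions(self):
        (r,) = extend_summits([("chr1", 1000)])
        assert (r.chrom, r.start, r.end) == ("chr1", 800, 1200)
        assert r.width == 400

    def test_clipped_at_chromosome_start(self):
        (r,) = extend_summits([("chr1", 50)], flank=200)
        assert (r.start, r.end) == (0, 250)

    def test_nonpositive_flank_is_error(self):
        with pytest.raises(ValueError):
            extend_summits([("chr1", 100)], flank=0)

    def test_negative_position_is_error(self):
        with pytest.raises(ValueError, match="negative"):
            extend_summits([("chr1", -5)])

    def test_bed_roundtrip(self, tmp_path):
        regions = extend_summits([("chr1", 1000), ("chr2", 300)])
        path = tmp_path / "regions.bed"
        write_bed(regions, path)
        df = pd.read_csv(path, sep="\t", header=None)
        assert df.shape == (2, 4)
        assert list(df.iloc[0, :3]) == ["chr1", 800, 1200]


def _write_run(path, rows):
    with open(path, "w") as fh:
        fh.write("motif_id\tq_value\n")
        for m, q in rows:
            fh.write(f"{m}\t{q}\n")


class TestParseEnrichmentRuns:
    def test_run_ids_follow_file_order(self, tmp_path):
        f1, f2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        _write_run(f1, [("m1", 0.01), ("m2", 0.2), ("m3", 0.03)])
        _write_run(f2, [("m1", 0.02), ("m2", 0.01), ("m3", 0.5)])
        records = parse_enrichment_runs([f1, f2])
        assert len(records) == 6
        assert {r.run_id for r in records} == {1, 2}

    def test_unparsable_q_dropped_with_warning(self, tmp_path):
        f = tmp_path / "r.tsv"
        _write_run(f, [("m1", 0.01), ("m2", "NA")])
        with pytest.warns(TRMWarning, match="unparsable"):
            records = parse_enrichment_runs([f])
        assert [r.motif_id for r in records] == ["m1"]

    def test_missing_q_column_is_error_naming_file(self, tmp_path):
        f = tmp_path / "noq.tsv"
        f.write_text("motif_id\tscore\nm1\t5\n")
        with pytest.raises(ValueError, match="noq.tsv"):
            parse_enrichment_runs([f])


def _records(motif, good_runs, n_runs, q_good=0.01, q_bad=0.5):
    return [
        EnrichmentRecord(run_id=r, motif_id=motif,
                         q_value=q_good if r in good_runs else q_bad)
        for r in range(1, n_runs + 1)
    ]


class TestConsensus:
    def test_eight_of_ten_kept(self):
        recs = _records("m", set(range(1, 9)), 10)
        assert consensus_enriched_motifs(recs, n_runs=10) == {"m"}

    def test_seven_of_ten_dropped(self):
        recs = _records("m", set(range(1, 8)), 10)
        assert consensus_enriched_motifs(recs, n_runs=10) == set()

    def test_q_exactly_at_threshold_dropped(self):
        recs = [EnrichmentRecord(run_id=r, motif_id="m", q_value=0.05)
                for r in range(1, 11)]
        assert consensus_enriched_motifs(recs, n_runs=10) == set()

    def test_run_id_beyond_n_runs_is_error(self):
        with pytest.raises(ValueError, match="run_id"):
            consensus_enriched_motifs(_records("m", {1, 2, 3}, 3), n_runs=2)

    def test_duplicated_records_do_not_change_result(self):
        recs = _records("m", set(range(1, 9)), 10)
        assert consensus_enriched_motifs(recs + recs, n_runs=10) == {"m"}

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        q=st.lists(st.floats(0, 1, allow_nan=False), min_size=5, max_size=5),
        q_hi=st.floats(0.01, 0.5),
        frac_lo=st.floats(0.2, 0.8),
    )
    def test_monotone_in_thresholds(self, q, q_hi, frac_lo):
        """Raising q_thresh or lowering min_frac never removes a kept motif."""
        recs = [EnrichmentRecord(run_id=i + 1, motif_id="m", q_value=qi)
                for i, qi in enumerate(q)]
        base = consensus_enriched_motifs(recs, 5, q_thresh=0.05, min_frac=0.8)
        looser_q = consensus_enriched_motifs(recs, 5, q_thresh=0.05 + q_hi, min_frac=0.8)
        looser_f = consensus_enriched_motifs(recs, 5, q_thresh=0.05, min_frac=frac_lo)
        assert base <= looser_q
        assert base <= looser_f


class TestFilterMotifMatches:
    def test_strict_threshold(self):
        matches = [MotifMatch("d1", "m1", 0.01), MotifMatch("d1", "m2", 0.05)]
        assert filter_motif_matches(matches) == {"d1": {"m1"}}

    def test_all_matches_fail_gives_empty_entry_and_warning(self):
        with pytest.warns(TRMWarning, match="d1"):
            out = filter_motif_matches([MotifMatch("d1", "m1", 0.9)])
        assert out == {"d1": set()}


class TestCpm:
    def test_single_gene_whole_library(self):
        expr = ExpressionMatrix(pd.DataFrame({"s1": [7.0]}, index=["g"]), "raw_counts")
        cpm = compute_cpm(expr)
        assert cpm.scale == "cpm"
        assert cpm.values.loc["g", "s1"] == pytest.approx(1e6)

    def test_hand_arithmetic(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [2.0, 8.0]}, index=["g1", "g2"]), "raw_counts"
        )
        cpm = compute_cpm(expr)
        assert cpm.values["s1"].tolist() == pytest.approx([2e5, 8e5])

    def test_zero_library_size_is_error_naming_sample(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0], "bad": [0.0]}, index=["g"]), "raw_counts"
        )
        with pytest.raises(ValueError, match="bad"):
            compute_cpm(expr)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.integers(0, 100, size=(20, 3)).astype(float),
                          index=[f"g{i}" for i in range(20)],
                          columns=["a", "b", "c"])
        cpm = compute_cpm(ExpressionMatrix(df, "raw_counts"))
        np.testing.assert_allclose(cpm.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_preserves_within_sample_rank_order(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.integers(0, 50, size=(15, 2)).astype(float),
                          index=[f"g{i}" for i in range(15)], columns=["a", "b"])
        cpm = compute_cpm(ExpressionMatrix(df, "raw_counts"))
        for col in df:
            assert (df[col].rank() == cpm.values[col].rank()).all()


class TestExpressedGenes:
    def test_cpm_above_one_in_all_samples(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [1.2, 1.2, 1.0], "s2": [3.0, 0.5, 1.0]},
                         index=["hi", "mixed", "at_cutoff"]),
            "cpm",
        )
        assert expressed_genes(expr, 1.0) == {"hi"}
        assert expressed_genes(expr, 1.0, mode="any") == {"hi", "mixed"}

    def test_value_exactly_at_cutoff_not_expressed(self):
        expr = ExpressionMatrix(pd.DataFrame({"s": [5.5]}, index=["g"]), "log2_intensity")
        assert expressed_genes(expr, 5.5) == set()

    def test_all_mode_subset_of_any_mode(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(5, 3, size=(30, 4)),
                          index=[f"g{i}" for i in range(30)])
        expr = ExpressionMatrix(df, "log2_intensity")
        assert expressed_genes(expr, 5.0) <= expressed_genes(expr, 5.0, mode="any")


class TestSelectCandidates:
    @pytest.fixture
    def maps(self):
        gm = MotifGeneMap(pairs={"m1": {("g1", "mouse"), ("g2", "mouse")}})
        return gm, OrthologMap()

    def test_hand_traced_pipeline(self, maps):
        gm, ortho = maps
        out = select_candidates({"d1"}, {"d1": {"m1"}}, gm, ortho,
                                expressed={"g1"}, target_species="mouse")
        assert out.genes == {"g1"}
        assert out.provenance == {"g1": {"m1"}}

    def test_nothing_expressed_gives_empty_set(self, maps):
        gm, ortho = maps
        out = select_candidates({"d1"}, {"d1": {"m1"}}, gm, ortho,
                                expressed=set(), target_species="mouse")
        assert out.genes == set() and out.provenance == {}

    def test_unmatched_consensus_motif_warned(self, maps):
        gm, ortho = maps
        with pytest.warns(TRMWarning, match="d_unknown"):
            out = select_candidates({"d1", "d_unknown"}, {"d1": {"m1"}}, gm, ortho,
                                    expressed={"g1", "g2"}, target_species="mouse")
        assert out.genes == {"g1", "g2"}

    def test_provenance_keys_must_be_subset_of_genes(self):
        with pytest.raises(ValueError):
            CandidateSet(genes={"a"}, provenance={"b": {"m"}})
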