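"""PWM library: parsing, merging, ontology resolution and gene mapping."""

import numpy as np
import pytest

from trmkit._util import TRMWarning
from trmkit.motif_library import (
    MotifGeneMap,
    OrthologMap,
    PWMCollection,
    PWMParseError,
    PWMatrix,
    annotate_tf_class,
    db_summary,
    load_pwm_set,
    map_motifs_to_genes,
    merge_pwm_sources,
    parse_tfclass_obo,
)

JASPAR_TWO_MOTIFS = """\
>MA0001.1 AGL3
A  [ 0  3 79 40 ]
C  [94 75  4  3 ]
G  [ 1  0  3  4 ]
T  [ 2 19 11 50 ]
>MA0002.1 RUNX1
A  10 12 3 5
C  2 2 1 1
G  3 1 11 9
T  0 0 0 0
"""


@pytest.fixture
def jaspar_file(tmp_path):
    p = tmp_path / "motifs.pfm"
    p.write_text(JASPAR_TWO_MOTIFS)
    return p


class TestLoadPwmSet:
    def test_jaspar_file_with_two_motifs(self, jaspar_file):
        coll = load_pwm_set([jaspar_file], source="jaspar", species="human")
        assert len(coll) == 2
        assert coll.per_source_counts == {"jaspar": 2}
        assert coll["MA0001.1"].length == 4
        assert coll["MA0002.1"].matrix[0, 1] == 12

    def test_agrees_with_biopython_jaspar_parser(self, tmp_path):
        Bio_motifs = pytest.importorskip("Bio.motifs")
        p = tmp_path / "uniform.pfm"
        p.write_text(
            ">MA0001.1 AGL3\n"
            "A  [ 0  3 79 40 ]\nC  [94 75  4  3 ]\n"
            "G  [ 1  0  3  4 ]\nT  [ 2 19 11 50 ]\n"
            ">MA0002.1 RUNX1\n"
            "A  [10 12  3  5 ]\nC  [ 2  2  1  1 ]\n"
            "G  [ 3  1 11  9 ]\nT  [ 0  0  0  0 ]\n"
        )
        coll = load_pwm_set([p], source="jaspar", species="human")
        with open(p) as fh:
            ref = Bio_motifs.parse(fh, "jaspar")
        for motif in ref:
            ours = coll[motif.matrix_id].matrix
            theirs = np.array([motif.counts[b] for b in "ACGT"])
            np.testing.assert_allclose(ours, theirs)

    def test_three_row_matrix_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.pfm"
        p.write_text(">M1\n1 2\n3 4\n5 6\n")
        with pytest.raises(PWMParseError, match="M1"):
            load_pwm_set([p], source="jaspar", species="human")

    def test_negative_entry_is_parse_error(self, tmp_path):
        p = tmp_path / "neg.pfm"
        p.write_text(">M1\n1 2\n3 -4\n5 6\n7 8\n")
        with pytest.raises(PWMParseError, match="negative"):
            load_pwm_set([p], source="jaspar", species="human")

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "ragged.pfm"
        p.write_text(">M1\n1 2 3\n1 2\n1 2 3\n1 2 3\n")
        with pytest.raises(PWMParseError, match="ragged"):
            load_pwm_set([p], source="jaspar", species="human")

    def test_duplicate_id_within_call_is_error(self, tmp_path):
        p = tmp_path / "dup.pfm"
        p.write_text(">M1\n1\n1\n1\n1\n>M1\n2\n2\n2\n2\n")
        with pytest.raises(PWMParseError, match="duplicate"):
            load_pwm_set([p], source="jaspar", species="human")

    def test_generic_tsv_format(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "motif_id\tbase\tp1\tp2\n"
            "M9\tA\t1\t2\nM9\tC\t3\t4\nM9\tG\t5\t6\nM9\tT\t7\t8\n"
        )
        coll = load_pwm_set([p], source="custom", species="mouse")
        np.testing.assert_allclose(coll["M9"].matrix, [[1, 2], [3, 4], [5, 6], [7, 8]])


def _coll(ids, source):
    c = PWMCollection()
    for i in ids:
        c.matrices[i] = PWMatrix(i, source, np.ones((4, 2)), "human")
    return c


class TestMergeSources:
    def test_disjoint_union_size(self):
        merged = merge_pwm_sources(
            [_coll(["a", "b", "c"], "jaspar"), _coll(["d", "e"], "uniprobe"),
             _coll(["f", "g", "h", "i"], "htselex")]
        )
        assert len(merged) == 9
        assert merged.per_source_counts == {"jaspar": 3, "uniprobe": 2, "htselex": 4}

    def test_cross_source_collision_keeps_both_with_suffix(self):
        merged = merge_pwm_sources([_coll(["m", "x"], "jaspar"), _coll(["m"], "uniprobe")])
        assert set(merged.matrices) == {"m@jaspar", "m@uniprobe", "x"}
        assert len(merged) == 3

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError, match="no collections"):
            merge_pwm_sources([])

    def test_merge_associative_up_to_key_order(self):
        a, b, c = _coll(["a"], "jaspar"), _coll(["b"], "uniprobe"), _coll(["a", "c"], "htselex")
        left = merge_pwm_sources([merge_pwm_sources([a, b]), c])
        right = merge_pwm_sources([a, merge_pwm_sources([b, c])])
        assert set(left.matrices) == set(right.matrices)


SYNTHETIC_OBO = """\
format-version: 1.2
ontology: tfclass-test

[Term]
id: TF:1
name: Basic domains
subset: superclass

[Term]
id: TF:2
name: Zinc fingers
subset: superclass

[Term]
id: TF:1.1
name: bZIP
subset: class
is_a: TF:1

[Term]
id: TF:1.2
name: bHLH
subset: class
is_a: TF:1

[Term]
id: TF:2.1
name: C2H2
subset: class
is_a: TF:2

[Term]
id: TF:1.1.1
name: Jun-related
subset: family
is_a: TF:1.1

[Term]
id: TF:1.2.1
name: Tal-related
subset: family
is_a: TF:1.2

[Term]
id: TF:2.1.1
name: Kruppel-related
subset: family
is_a: TF:2.1

[Term]
id: TF:1.1.1.g1
name: JUN
subset: gene
is_a: TF:1.1.1

[Term]
id: TF:1.2.1.g1
name: TAL1
subset: gene
is_a: TF:1.2.1

[Term]
id: TF:2.1.1.g1
name: KLF4
subset: gene
is_a: TF:2.1.1

[Term]
id: TF:2.1.1.g2
name: SP1
subset: gene
is_a: TF:2.1.1
"""


class TestParseTfclassObo:
    def test_synthetic_hierarchy_resolved(self, tmp_path):
        p = tmp_path / "tfclass.obo"
        p.write_text(SYNTHETIC_OBO)
        ann = parse_tfclass_obo(p)
        assert len(ann) == 4
        assert ann.hierarchy["JUN"] == ("Basic domains", "bZIP", "Jun-related", None)
        assert ann.hierarchy["TAL1"] == ("Basic domains", "bHLH", "Tal-related", None)
        assert ann.hierarchy["KLF4"] == ("Zinc fingers", "C2H2", "Kruppel-related", None)
        assert ann.hierarchy["SP1"] == ("Zinc fingers", "C2H2", "Kruppel-related", None)

    def test_factor_species_entries_removed(self, tmp_path):
        doc = SYNTHETIC_OBO + (
            "\n[Term]\nid: TF:2.1.1.g2.1\nname: SP1-isoform1\n"
            "subset: factor_species\nis_a: TF:2.1.1.g2\n"
        )
        p = tmp_path / "tfclass.obo"
        p.write_text(doc)
        ann = parse_tfclass_obo(p)
        assert "SP1-isoform1" not in ann.hierarchy
        assert "SP1" in ann.hierarchy

    def test_empty_obo_gives_empty_annotation(self, tmp_path):
        p = tmp_path / "empty.obo"
        p.write_text("format-version: 1.2\nontology: empty\n")
        assert len(parse_tfclass_obo(p)) == 0

    def test_cyclic_is_a_is_error(self, tmp_path):
        doc = (
            "format-version: 1.2\nontology: cyc\n\n"
            "[Term]\nid: TF:a\nname: A\nsubset: class\nis_a: TF:b\n\n"
            "[Term]\nid: TF:b\nname: B\nsubset: class\nis_a: TF:a\n"
        )
        p = tmp_path / "cyc.obo"
        p.write_text(doc)
        with pytest.raises(ValueError, match="cyclic"):
            parse_tfclass_obo(p)

    def test_orphan_term_skipped_with_warning(self, tmp_path):
        doc = SYNTHETIC_OBO + "\n[Term]\nid: TF:9.9.9.g9\nname: ORPHAN\nsubset: gene\n"
        p = tmp_path / "orphan.obo"
        p.write_text(doc)
        with pytest.warns(TRMWarning, match="orphan"):
            ann = parse_tfclass_obo(p)
        assert "ORPHAN" not in ann.hierarchy


@pytest.fixture
def gene_map():
    return MotifGeneMap(pairs={
        "m1": {("g1", "mouse"), ("g2", "mouse")},
        "m2": {("h1", "human")},
        "m3": set(),
    })


@pytest.fixture
def ortho():
    return OrthologMap(pairs={("h1", "human"): {("m_1", "mouse")}})


class TestMapMotifsToGenes:
    def test_same_species_direct_lookup(self, gene_map, ortho):
        assert map_motifs_to_genes({"m1"}, gene_map, ortho, "mouse") == {"g1", "g2"}

    def test_foreign_gene_via_ortholog(self, gene_map, ortho):
        assert map_motifs_to_genes({"m2"}, gene_map, ortho, "mouse") == {"m_1"}

    def test_unmapped_motif_warns_not_errors(self, gene_map, ortho):
        with pytest.warns(TRMWarning, match="m3"):
            assert map_motifs_to_genes({"m3"}, gene_map, ortho, "mouse") == set()

    def test_empty_motif_set_is_error(self, gene_map, ortho):
        with pytest.raises(ValueError):
            map_motifs_to_genes(set(), gene_map, ortho, "mouse")

    def test_union_bound_on_distinct_genes(self, gene_map, ortho):
        out = map_motifs_to_genes({"m1", "m2"}, gene_map, ortho, "mouse")
        per_motif = sum(len(gene_map.genes_for(m)) for m in ("m1", "m2"))
        assert len(out) <= per_motif


class TestAnnotateTfClass:
    def test_via_ortholog(self, ortho):
        from trmkit.motif_library import TFClassAnnotation

        ann = TFClassAnnotation(hierarchy={"m_1": ("Helix-turn-helix", "Homeodomain", "HOX", None)})
        ortho2 = OrthologMap(pairs={("Pou5f1", "mouse"): {("m_1", "human")}})
        table = annotate_tf_class({"Pou5f1"}, ann, ortho2, species="mouse", ann_species="human")
        assert table["Pou5f1"][1] == "Homeodomain"

    def test_unclassified_without_entry_or_ortholog(self):
        from trmkit.motif_library import TFClassAnnotation

        table = annotate_tf_class({"gX"}, TFClassAnnotation(), OrthologMap())
        assert table["gX"] == "unclassified"

    def test_empty_gene_set(self):
        from trmkit.motif_library import TFClassAnnotation

        assert annotate_tf_class(set(), TFClassAnnotation(), OrthologMap()) == {}


class TestDbSummary:
    def test_counts(self):
        coll = merge_pwm_sources([_coll(["a", "b"], "jaspar"), _coll(["c", "d", "e"], "uniprobe")])
        gm = MotifGeneMap(pairs={
            "a": {("g1", "m")}, "b": {("g2", "m")},
            "c": {("g3", "m")}, "d": {("g4", "m")}, "e": set(),
        })
        s = db_summary(coll, gm)
        assert s["total_motifs"] == 5
        assert s["distinct_genes"] == 4
        assert s["per_source"] == {"jaspar": 2, "uniprobe": 3}

    def test_empty_collection_gives_zeros(self):
        s = db_summary(PWMCollection(), MotifGeneMap())
        assert s["total_motifs"] == 0 and s["distinct_genes"] == 0

    def test_shared_gene_counted_once(self):
        coll = _coll(["a", "b"], "jaspar")
        gm = MotifGeneMap(pairs={"a": {("g1", "m")}, "b": {("g1", "m")}})
        assert db_summary(coll, gm)["distinct_genes"] == 1
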