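"""Record model and file I/O round trips."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ureidoscan.records import (
    STANDARD_AA,
    BgcGene,
    BgcRecord,
    LabelTable,
    ProteinRecord,
    clean_sequence,
    newick_string,
    read_bgc_record,
    read_fasta,
    read_newick,
    write_fasta,
    write_newick,
)


class TestProteinRecord:
    def test_basic_invariants(self):
        rec = ProteinRecord("a", "MKTEHH")
        assert len(rec) == 6

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"id": "", "sequence": "MKT"},
            {"id": "a", "sequence": ""},
            {"id": "a", "sequence": "MK7"},
            {"id": "a", "sequence": "mkt"},  # lowercase rejected post-ingestion
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ProteinRecord(**kwargs)

    def test_ambiguity_codes_become_x_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert clean_sequence("mkBz") == "MKXX"
        assert "mapped to X" in caplog.text

    def test_illegal_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            clean_sequence("MK*T")


class TestFasta:
    def test_single_record_wrapped_lines_joined(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">a\nMKT\nEHH\n")
        recs = read_fasta(p)
        assert [(r.id, r.sequence) for r in recs] == [("a", "MKTEHH")]

    def test_duplicate_id_error_names_id(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nACDE\n>a\nACDE\n")
        with pytest.raises(ValueError, match="'a'"):
            read_fasta(p)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_round_trip_is_byte_identical(self, tmp_path):
        recs = [
            ProteinRecord("a", "M" * 130, description="a long one"),
            ProteinRecord("b", "ACDEFGHIKLMNPQRSTVWYX"),
        ]
        p1, p2 = tmp_path / "x.fasta", tmp_path / "y.fasta"
        write_fasta(recs, p1)
        write_fasta(read_fasta(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    @settings(max_examples=50, derandomize=True)
    @given(
        seqs=st.lists(
            st.text(alphabet=STANDARD_AA + "X", min_size=1, max_size=130),
            min_size=1,
            max_size=6,
        )
    )
    def test_round_trip_preserves_sequences(self, tmp_path_factory, seqs):
        tmp = tmp_path_factory.mktemp("fasta")
        recs = [ProteinRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        p = tmp / "r.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [r.sequence for r in back] == seqs
        assert [r.id for r in back] == [r.id for r in recs]


class TestBgcRecords:
    def _write(self, tmp_path, payload):
        import json

        p = tmp_path / "bgc.json"
        p.write_text(json.dumps(payload))
        return p

    def test_minimal_record_parses(self, tmp_path):
        p = self._write(
            tmp_path,
            {
                "bgc_id": "BGC1",
                "genes": [
                    {
                        "gene_id": "snaE",
                        "protein": {"id": "snaE", "sequence": "MKTEHH"},
                        "family_annotations": ["PF04738"],
                    }
                ],
            },
        )
        rec = read_bgc_record(p)
        assert rec.bgc_id == "BGC1"
        assert len(rec.genes) == 1
        assert rec.genes[0].family_annotations == ("PF04738",)

    def test_missing_genes_key_is_named(self, tmp_path):
        p = self._write(tmp_path, {"bgc_id": "BGC1"})
        with pytest.raises(ValueError, match="'genes'"):
            read_bgc_record(p)

    def test_family_annotations_normalized_to_uppercase(self, tmp_path):
        p = self._write(
            tmp_path,
            {
                "bgc_id": "B",
                "genes": [
                    {
                        "gene_id": "g",
                        "protein": {"id": "g", "sequence": "MK"},
                        "family_annotations": ["pf14028"],
                    }
                ],
            },
        )
        assert read_bgc_record(p).genes[0].family_annotations == ("PF14028",)

    def test_duplicate_gene_ids_rejected(self):
        g = BgcGene("g", ProteinRecord("g", "MK"))
        with pytest.raises(ValueError, match="duplicate"):
            BgcRecord("B", (g, g))


class TestLabelTable:
    def test_reads_and_restricts_labels(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text("domain_id\tfunction_label\nd1\turea\nd2\tamide\nd3\tother\n")
        t = LabelTable.from_tsv(p)
        assert t["d1"] == "urea" and len(t) == 3

    def test_unknown_label_rejected(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text("domain_id\tfunction_label\nd1\tureido\n")
        with pytest.raises(ValueError, match="ureido"):
            LabelTable.from_tsv(p)

    def test_duplicate_domain_id_rejected(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text("domain_id\tfunction_label\nd1\turea\nd1\turea\n")
        with pytest.raises(ValueError, match="duplicate"):
            LabelTable.from_tsv(p)


class TestNewick:
    def test_three_leaf_star_format(self):
        from skbio import TreeNode

        tips = [TreeNode(name=n) for n in "abc"]
        for tip, length in zip(tips, (1.0, 2.0, 3.0)):
            tip.length = length
        root = TreeNode(children=tips)
        assert newick_string(root) == "(a:1.0,b:2.0,c:3.0);"

    def test_round_trip_topology_and_lengths(self, tmp_path):
        from ureidoscan.phylo import bipartitions

        text = "((a:0.123456789,b:2.0):0.5,(c:3.0,d:0.000000001):0.25,e:1.0);"
        tree = read_newick(text)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(str(p))
        assert bipartitions(back) == bipartitions(tree)
        d0, d1 = tree.tip_tip_distances(), back.tip_tip_distances()
        for i in "abcde":
            for j in "abcde":
                assert abs(d0[i, j] - d1[i, j]) < 1e-9

    def test_unlabeled_leaf_is_an_error(self):
        from skbio import TreeNode

        root = TreeNode(children=[TreeNode(name="a"), TreeNode()])
        with pytest.raises(ValueError, match="unlabeled"):
            newick_string(root)

    def test_empty_tree_is_an_error(self):
        from skbio import TreeNode

        with pytest.raises(ValueError, match="empty"):
            newick_string(TreeNode())
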