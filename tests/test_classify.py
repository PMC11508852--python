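"""SINTAX database parsing, k-mer bootstrap classification, SH aggregation."""

import numpy as np
import pytest

from nanoits import (
    Classification,
    ClassifyParams,
    ReferenceDB,
    RefRecord,
    ZOtu,
    add_reference,
    aggregate_sh,
    apply_confidence_filter,
    classification_rate,
    classify_zotus,
    load_sintax_db,
    sintax_classify,
    write_sintax_db,
)
from nanoits.classify import RANKS


class TestSintaxIO:
    HEADER_DB = (
        ">UDB05341741;tax=d:Fungi,p:Rozellomycota,s:SH0910702.10FU;\n"
        "ACGTACGTACGTACGTACGT\n"
        ">X2;tax=d:Fungi,p:Ascomycota,c:Leotiomycetes,o:Helotiales,"
        "f:Helotiaceae,g:Hymenoscyphus,s:SH0000002.10FU;\n"
        "TTTTACGTACGTACGTAAAA\n"
    )

    def test_rank_parsing_with_missing_intermediates(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(self.HEADER_DB)
        db = load_sintax_db(p)
        assert db.records[0].lineage == {
            "d": "Fungi", "p": "Rozellomycota", "s": "SH0910702.10FU"
        }
        assert db.records[1].lineage["g"] == "Hymenoscyphus"

    def test_round_trip_is_identity(self, tmp_path, mock_db):
        p1 = tmp_path / "a.fasta"
        p2 = tmp_path / "b.fasta"
        write_sintax_db(mock_db, p1)
        db2 = load_sintax_db(p1)
        write_sintax_db(db2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_tax_annotation_raises(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">acc_without_tax\nACGT\n")
        with pytest.raises(ValueError, match="acc_without_tax"):
            load_sintax_db(p)

    def test_empty_tax_string_raises(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">acc;tax=;\nACGT\n")
        with pytest.raises(ValueError):
            load_sintax_db(p)


class TestAddReference:
    def test_added_dummy_sh_is_queryable(self, divergent_db):
        db = ReferenceDB(list(divergent_db.records))
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 400))
        add_reference(
            db, seq, {"d": "Fungi", "g": "Laccaria", "s": "SH0000099.10FU"}
        )
        params = ClassifyParams(seed=1)
        cls = sintax_classify(seq, db, params)
        assert cls.species == "SH0000099.10FU"
        assert cls.species_confidence == pytest.approx(1.0)

    def test_duplicate_code_rejected(self, divergent_db):
        db = ReferenceDB(list(divergent_db.records))
        existing = db.records[0].lineage["s"]
        with pytest.raises(ValueError):
            add_reference(db, "ACGT" * 50, {"d": "Fungi", "s": existing})

    def test_malformed_code_rejected(self, divergent_db):
        db = ReferenceDB(list(divergent_db.records))
        with pytest.raises(ValueError):
            add_reference(db, "ACGT" * 50, {"d": "Fungi", "s": "SH1.10FU"})


def _two_taxon_db(rng):
    a = "".join(rng.choice(list("ACGT"), 300))
    b = "".join(rng.choice(list("ACGT"), 300))
    return ReferenceDB([
        RefRecord("A", a, {"d": "Fungi", "f": "Fam1", "g": "GenA", "s": "SH0000001.10FU"}),
        RefRecord("B", b, {"d": "Fungi", "f": "Fam1", "g": "GenB", "s": "SH0000002.10FU"}),
    ])


class TestSintaxClassify:
    def test_exact_reference_query_full_confidence(self):
        db = _two_taxon_db(np.random.default_rng(2))
        cls = sintax_classify(db.records[0].seq, db, ClassifyParams(seed=3))
        assert cls.species == "SH0000001.10FU"
        assert cls.species_confidence == 1.0
        assert cls.top_hit == "A"

    def test_even_chimera_splits_genus_but_keeps_family(self):
        rng = np.random.default_rng(4)
        db = _two_taxon_db(rng)
        a, b = db.records[0].seq, db.records[1].seq
        chim = a[:150] + b[150:]
        cls = sintax_classify(chim, db, ClassifyParams(seed=5, n_boot=400))
        assert cls.confidence("f") == pytest.approx(1.0, abs=0.01)
        assert 0.35 <= cls.confidence("g") <= 0.65

    def test_foreign_query_is_unclassifiable(self):
        rng = np.random.default_rng(6)
        db = _two_taxon_db(rng)
        # homopolymer query shares no 8-mers with the random references
        cls = sintax_classify("A" * 200, db, ClassifyParams(seed=7))
        assert cls.unclassifiable
        assert cls.species_confidence == 0.0

    def test_query_shorter_than_k_raises(self):
        db = _two_taxon_db(np.random.default_rng(8))
        with pytest.raises(ValueError):
            sintax_classify("ACGT", db, ClassifyParams())

    def test_confidence_monotone_across_ranks(self, mock_db):
        rng = np.random.default_rng(9)
        params = ClassifyParams(seed=10)
        for _ in range(10):
            rec = mock_db.records[rng.integers(len(mock_db))]
            seq = list(rec.seq)
            for i in rng.choice(len(seq), size=30, replace=False):
                seq[i] = rng.choice(list("ACGT"))
            cls = sintax_classify("".join(seq), mock_db, params)
            confs = [cls.confidence(r) for r in RANKS]
            assert all(c0 >= c1 - 1e-12 for c0, c1 in zip(confs, confs[1:]))

    def test_fixed_seed_is_deterministic(self, mock_db):
        q = mock_db.records[3].seq[:400]
        a = sintax_classify(q, mock_db, ClassifyParams(seed=11))
        b = sintax_classify(q, mock_db, ClassifyParams(seed=11))
        assert a.ranks == b.ranks and a.top_hit == b.top_hit

    def test_self_classification_of_every_reference(self, mock_db):
        params = ClassifyParams(seed=12)
        for rec in mock_db.records:
            cls = sintax_classify(rec.seq, mock_db, params)
            assert cls.species == rec.lineage["s"]
            assert cls.species_confidence >= 0.95


class TestConfidenceFilter:
    @pytest.mark.parametrize(
        "size,conf,kept",
        [(1, 0.94, False), (1, 0.95, True), (3, 0.80, True), (3, 0.79, False),
         (2, 0.80, True)],
    )
    def test_dual_threshold_boundaries(self, size, conf, kept):
        z = ZOtu("ACGT", size, {"s1": size}, "z")
        cls = Classification({"s": ("SH0000001.10FU", conf)}, "A")
        assert apply_confidence_filter(z, cls, ClassifyParams()) is kept

    def test_missing_species_never_kept(self):
        z = ZOtu("ACGT", 5, {"s1": 5}, "z")
        cls = Classification({"s": (None, 0.0)}, None)
        assert not apply_confidence_filter(z, cls, ClassifyParams())


class TestAggregateSh:
    def _cls(self, sh):
        return Classification({"s": (sh, 1.0)}, "A")

    def test_conspecific_sizes_sum(self):
        zotus = [
            ZOtu("AAAA", 5, {"s1": 5}, "z1"),
            ZOtu("AAAT", 7, {"s2": 7}, "z2"),
        ]
        cls = {"z1": self._cls("SH0000001.10FU"), "z2": self._cls("SH0000001.10FU")}
        table = aggregate_sh(zotus, cls)
        assert table.n_units() == 1
        assert table.total() == 12
        assert table.df.loc["SH0000001.10FU", "s1"] == 5
        assert table.df.loc["SH0000001.10FU", "s2"] == 7

    def test_empty_input_gives_empty_table(self):
        table = aggregate_sh([], {})
        assert table.n_units() == 0

    def test_missing_sh_raises(self):
        zotus = [ZOtu("AAAA", 1, {"s1": 1}, "z1")]
        with pytest.raises(ValueError):
            aggregate_sh(zotus, {"z1": Classification({"s": (None, 0.0)}, None)})


class TestClassificationRate:
    def test_error_free_databased_reads_fully_classified(self, mock_db, clean_reads):
        from nanoits import dereplicate

        z = dereplicate(clean_reads)
        rate = classification_rate(z, mock_db, ClassifyParams(seed=13))
        assert rate == pytest.approx(1.0, abs=0.02)

    def test_undatabased_taxon_unclassified(self, mock_db):
        rng = np.random.default_rng(14)
        foreign = "".join(rng.choice(list("ACGT"), 600))
        z = [ZOtu(foreign, 10, {"s1": 10}, "z1")]
        rate = classification_rate(z, mock_db, ClassifyParams(seed=15))
        assert rate == 0.0

    def test_empty_input_raises(self, mock_db):
        with pytest.raises(ValueError):
            classification_rate([], mock_db, ClassifyParams())
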