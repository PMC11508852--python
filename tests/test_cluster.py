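"""Dereplication, identity, greedy clustering, chimeras, LULU curation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import affine_identity, chimera_breakpoint_scan
from nanoits import (
    ClusterParams,
    MatchList,
    QualityRead,
    UnitTable,
    ZOtu,
    build_match_list,
    dereplicate,
    detect_chimeras,
    greedy_cluster,
    lulu_curate,
    pairwise_identity,
    zotu_table,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def _read(seq, sample="s1", rid="r"):
    return QualityRead(rid, seq, [30] * len(seq), sample)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestDereplicate:
    def test_grouping_and_per_sample_counts(self):
        reads = [_read("AAA", "s1")] * 3 + [_read("AAT", "s2")]
        z = dereplicate(reads)
        assert [(x.seq, x.size) for x in z] == [("AAA", 3), ("AAT", 1)]
        assert z[0].per_sample == {"s1": 3}
        assert z[1].per_sample == {"s2": 1}
        assert z[0].label == "zOTU_1"

    def test_all_identical_single_zotu(self):
        z = dereplicate([_read("ACGT")] * 5)
        assert len(z) == 1 and z[0].size == 5

    def test_distinct_reads_all_singletons(self):
        rng = np.random.default_rng(0)
        seqs = {_rand_seq(rng, 30) for _ in range(20)}
        z = dereplicate([_read(s) for s in seqs])
        assert len(z) == len(seqs)
        assert all(x.size == 1 for x in z)

    def test_size_conservation(self, noisy_reads_q20):
        reads, _ = noisy_reads_q20
        z = dereplicate(reads)
        assert sum(x.size for x in z) == len(reads)


class TestPairwiseIdentity:
    def test_identical(self):
        s = "ACGT" * 25
        assert pairwise_identity(s, s) == 1.0

    def test_single_substitution(self):
        rng = np.random.default_rng(1)
        a = _rand_seq(rng, 100)
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        assert pairwise_identity(a, b) == pytest.approx(0.99)

    def test_internal_two_bp_deletion(self):
        rng = np.random.default_rng(2)
        a = _rand_seq(rng, 100)
        b = a[:40] + a[42:]
        assert pairwise_identity(a, b) == pytest.approx(0.98)
        assert affine_identity(a, b) == pytest.approx(0.98)

    @given(st.integers(0, 500))
    def test_symmetric_and_matches_affine_oracle_on_close_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = _rand_seq(rng, 120)
        b = list(a)
        for i in rng.choice(120, size=3, replace=False):
            b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
        b = "".join(b)
        pid = pairwise_identity(a, b)
        assert pid == pytest.approx(pairwise_identity(b, a))
        assert pid == pytest.approx(affine_identity(a, b), abs=0.01)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestGreedyCluster:
    def test_threshold_splits_near_and_far(self):
        rng = np.random.default_rng(3)
        a = _rand_seq(rng, 100)
        b = a[:10] + ("G" if a[10] != "G" else "T") + a[11:]  # 1 sub -> 0.99
        c = list(a)
        for i in [5, 25, 45, 65, 85]:
            c[i] = "A" if c[i] != "A" else "C"  # 5 subs -> 0.95
        c = "".join(c)
        zotus = [
            ZOtu(a, 10, {"s1": 10}, "zOTU_1"),
            ZOtu(b, 2, {"s1": 2}, "zOTU_2"),
            ZOtu(c, 1, {"s1": 1}, "zOTU_3"),
        ]
        res = greedy_cluster(zotus, ClusterParams(0.98))
        sizes = sorted(res.table.unit_sizes().tolist(), reverse=True)
        assert sizes == [12, 1]

    def test_identity_one_equals_dereplication(self, clean_reads):
        z = dereplicate(clean_reads)
        res = greedy_cluster(z, ClusterParams(1.0))
        assert res.table.n_units() == len(z)

    def test_membership_contract(self, noisy_reads_q20):
        # every member within radius of its centroid; centroids mutually apart
        reads, _ = noisy_reads_q20
        z = dereplicate(reads[:200])
        t = 0.98
        res = greedy_cluster(z, ClusterParams(t))
        for zotu in z:
            label = res.assignments[zotu.label]
            assert pairwise_identity(zotu.seq, res.centroids[label]) >= t

    def test_read_conservation(self, noisy_reads_q20):
        reads, _ = noisy_reads_q20
        z = dereplicate(reads)
        res = greedy_cluster(z, ClusterParams(0.98))
        assert res.table.total() == len(reads)

    def test_sub_radius_reference_pair_merges(self, mock_db, mock_spec, primers):
        # the two references at 1.5% divergence must collapse into one OTU
        from conftest import trim_all
        from nanoits import ErrorModel, simulate_reads

        reads, _ = simulate_reads(
            mock_db, mock_spec, 400, [40], model=ErrorModel(qual_spread=0),
            seed=21, inject_errors=False,
        )
        z = dereplicate(trim_all(reads, primers))
        res = greedy_cluster(z, ClusterParams(0.98))
        assert res.table.n_units() == len(mock_db) - 1


class TestDetectChimeras:
    @pytest.fixture()
    def parents(self, mock_db):
        return mock_db.records[0].seq, mock_db.records[5].seq

    def test_even_crossover_flagged_and_oracle_agrees(self, parents):
        a, b = parents
        chim = a[: len(a) // 2] + b[len(b) // 2 :]
        zotus = [
            ZOtu(a, 10, {"s1": 10}, "zOTU_1"),
            ZOtu(b, 10, {"s1": 10}, "zOTU_2"),
            ZOtu(chim, 1, {"s1": 1}, "zOTU_3"),
        ]
        flags = detect_chimeras(zotus)
        assert flags == {"zOTU_1": False, "zOTU_2": False, "zOTU_3": True}
        assert chimera_breakpoint_scan(chim, a, b)

    def test_copy_of_abundant_parent_not_flagged(self, parents):
        a, b = parents
        zotus = [
            ZOtu(a, 10, {"s1": 10}, "zOTU_1"),
            ZOtu(b, 10, {"s1": 10}, "zOTU_2"),
            ZOtu(a[:-1] + ("A" if a[-1] != "A" else "C"), 1, {"s1": 1}, "zOTU_3"),
        ]
        flags = detect_chimeras(zotus)
        assert not flags["zOTU_3"]
        assert not chimera_breakpoint_scan(zotus[2].seq, a, b)

    def test_most_abundant_never_flagged(self, parents):
        a, b = parents
        chim = a[: len(a) // 2] + b[len(b) // 2 :]
        zotus = [
            ZOtu(chim, 20, {"s1": 20}, "zOTU_1"),
            ZOtu(a, 10, {"s1": 10}, "zOTU_2"),
            ZOtu(b, 10, {"s1": 10}, "zOTU_3"),
        ]
        assert not detect_chimeras(zotus)["zOTU_1"]

    def test_simulated_chimeras_detected(self, mock_db, mock_spec, primers):
        from conftest import trim_all
        from nanoits import simulate_reads

        reads, truth = simulate_reads(
            mock_db, mock_spec, 300, [30], chimera_rate=0.05, seed=31,
            inject_errors=False,
        )
        z = dereplicate(trim_all(reads, primers))
        flags = detect_chimeras(z)
        truth_map = truth.by_read()
        chim_seqs = set()
        by_acc = {r.accession: r.seq for r in mock_db.records}
        for r, t in zip(reads, truth.records):
            if t.is_chimera:
                chim_seqs.add(t.read_id)
        n_true = len(chim_seqs)
        assert n_true >= 5
        flagged_sizes = sum(x.size for x in z if flags[x.label])
        # every simulated chimera is a singleton zOTU with two abundant parents
        assert flagged_sizes >= 0.8 * n_true


class TestMatchListAndLulu:
    def _table(self, rows, samples):
        df = pd.DataFrame(rows, index=None)
        df.columns = samples
        return df

    def test_identical_centroids_reciprocal_full_match(self):
        ml = build_match_list({"A": "ACGT" * 30, "B": "ACGT" * 30})
        assert sorted(ml.rows) == [("A", "B", 100.0), ("B", "A", 100.0)]

    def test_distant_pair_empty(self):
        rng = np.random.default_rng(7)
        ml = build_match_list({"A": _rand_seq(rng, 200), "B": _rand_seq(rng, 200)})
        assert ml.rows == []

    def test_three_centroids_one_close_pair(self):
        rng = np.random.default_rng(8)
        a = _rand_seq(rng, 200)
        b = list(a)
        for i in rng.choice(200, 10, replace=False):  # 5% divergence
            b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
        ml = build_match_list({"A": a, "B": "".join(b), "C": _rand_seq(rng, 200)})
        assert len(ml.rows) == 2
        assert {(q, t) for q, t, _ in ml.rows} == {("A", "B"), ("B", "A")}

    def test_no_self_matches_enforced(self):
        with pytest.raises(ValueError):
            MatchList([("A", "A", 100.0)])

    def _lulu_setup(self):
        table = UnitTable(
            pd.DataFrame(
                {"s1": [100, 10], "s2": [50, 5]}, index=["parent", "daughter"]
            ),
            "OTU",
        )
        matches = MatchList(
            [("daughter", "parent", 95.0), ("parent", "daughter", 95.0)]
        )
        return table, matches

    def test_daughter_merges_and_counts_conserved(self):
        table, matches = self._lulu_setup()
        col_sums = table.df.sum(axis=0)
        curated, log = lulu_curate(table, matches)
        assert log == [("daughter", "parent")]
        assert curated.n_units() == 1
        assert (curated.df.sum(axis=0) == col_sums).all()

    def test_daughter_without_cooccurrence_kept(self):
        table = UnitTable(
            pd.DataFrame(
                {"s1": [100, 0], "s2": [0, 5]}, index=["parent", "daughter"]
            ),
            "OTU",
        )
        matches = MatchList([("daughter", "parent", 95.0)])
        curated, log = lulu_curate(table, matches)
        assert log == [] and curated.n_units() == 2

    def test_empty_match_list_is_identity(self):
        table, _ = self._lulu_setup()
        curated, log = lulu_curate(table, MatchList([]))
        assert curated.df.equals(table.df) and log == []

    def test_low_ratio_blocks_merge(self):
        table = UnitTable(
            pd.DataFrame({"s1": [6, 5], "s2": [6, 5]}, index=["parent", "daughter"]),
            "OTU",
        )
        matches = MatchList([("daughter", "parent", 95.0)])
        curated, _ = lulu_curate(table, matches, min_ratio=2.0)
        assert curated.n_units() == 2


class TestUnitTable:
    def test_drops_all_zero_rows_and_validates(self):
        df = pd.DataFrame({"s1": [3, 0], "s2": [1, 0]}, index=["u1", "u2"])
        t = UnitTable(df, "OTU")
        assert t.units == ["u1"]
        with pytest.raises(ValueError):
            UnitTable(pd.DataFrame({"s1": [-1]}, index=["u"]), "OTU")
        with pytest.raises(ValueError):
            UnitTable(df, "bogus")

    def test_tsv_round_trip(self, tmp_path):
        t = UnitTable(
            pd.DataFrame({"s1": [3, 2], "s2": [1, 7]}, index=["u1", "u2"]), "SH"
        )
        p = tmp_path / "t.tsv"
        t.to_tsv(p)
        back = UnitTable.from_tsv(p, "SH")
        assert back.df.equals(t.df)

    def test_zotu_table_counts(self):
        z = dereplicate(
            [_read("AAAA", "s1"), _read("AAAA", "s2"), _read("TTTT", "s1")]
        )
        t = zotu_table(z)
        assert t.total() == 3
        assert t.kind == "zOTU"
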