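"""SHM computation, CDR3 distances and clone clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from bmpcrep import cdr3_distance, cluster_clones, compute_shm, strip_allele
from bmpcrep.clonotyping import dedupe_heavy_chains

from conftest import make_airr


class TestComputeShm:
    @pytest.mark.parametrize("seq,germ,expected", [
        ("ATGC", "ATGC", 0.0),
        ("A" * 99 + "C", "A" * 100, 1.0),          # 1 mismatch / 100
        ("ATGG", "ATNC", 100.0 / 3),               # N excluded: 1/3
        ("AT-C", "ATGC", 0.0),                     # gap excluded both ways
    ])
    def test_worked_examples(self, seq, germ, expected):
        assert compute_shm(seq, germ) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compute_shm("ATG", "ATGC")

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            compute_shm("NNNN", "ATGC")

    def test_matches_direct_mismatch_count(self, rng):
        """SHM equals a direct hamming count over unambiguous positions."""
        for _ in range(50):
            n = int(rng.integers(10, 120))
            germ = "".join(rng.choice(list("ACGT"), n))
            seq = list(germ)
            k = int(rng.integers(0, n // 2))
            pos = rng.choice(n, size=k, replace=False)
            for p in pos:
                seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
            assert compute_shm("".join(seq), germ) == pytest.approx(100 * k / n)


class TestCdr3Distance:
    def test_identity(self):
        assert cdr3_distance("CARDYW", "CARDYW") == 0.0

    def test_single_mismatch(self):
        assert cdr3_distance("CARDYW", "CARDFW") == pytest.approx(1 / 6)

    def test_length_mismatch_incomparable(self):
        assert cdr3_distance("CARDYW", "CARDYYW") is None

    def test_empty_incomparable(self):
        assert cdr3_distance("", "") is None


def test_strip_allele():
    assert strip_allele("IGHV3-23*01") == "IGHV3-23"
    assert strip_allele("IGHV1-2*02,IGHV1-2*04") == "IGHV1-2"
    assert strip_allele("IGHJ4") == "IGHJ4"


class TestClusterClones:
    def test_within_cutoff_joined(self):
        recs = make_airr([("c1", "V1*01", "J1*01", "CARDYWAAAA"),
                          ("c2", "V1*01", "J1*01", "CARDFWAAAA")])
        clones = cluster_clones(recs, cutoff=0.85)
        assert clones["c1"] == clones["c2"]  # distance 0.1 <= 0.15

    def test_identical_cdr3_different_v_gene_split(self):
        recs = make_airr([("c1", "V1*01", "J1*01", "CARDYW"),
                          ("c2", "V2*01", "J1*01", "CARDYW")])
        clones = cluster_clones(recs)
        assert clones["c1"] != clones["c2"]

    def test_allele_difference_does_not_split(self):
        recs = make_airr([("c1", "V1*01", "J1*01", "CARDYW"),
                          ("c2", "V1*03", "J1*02", "CARDYW")])
        clones = cluster_clones(recs)
        assert clones["c1"] == clones["c2"]

    def test_single_linkage_chain(self):
        # A-B and B-C within threshold, A-C beyond: one clone of three
        recs = make_airr([("a", "V1*01", "J1*01", "AAAAAAAAAA"),
                          ("b", "V1*01", "J1*01", "CAAAAAAAAA"),
                          ("c", "V1*01", "J1*01", "CDAAAAAAAA")])
        clones = cluster_clones(recs)
        assert len(set(clones)) == 1

    def test_zero_cutoff_is_exact_grouping(self, rng):
        cdr3s = ["".join(rng.choice(list("ACDEF"), 8)) for _ in range(30)]
        recs = make_airr([(f"c{i}", "V1*01", "J1*01", s)
                          for i, s in enumerate(cdr3s)])
        clones = cluster_clones(recs, cutoff=0.0, semantics="distance")
        groups = {}
        for i, s in enumerate(cdr3s):
            groups.setdefault(s, set()).add(clones[f"c{i}"])
        assert all(len(v) == 1 for v in groups.values())
        assert len(set(clones)) == len(set(cdr3s))

    def test_order_permutation_invariant(self, rng):
        rows = [(f"c{i:02d}", "V1*01", "J1*01",
                 "".join(rng.choice(list("ACD"), 6))) for i in range(25)]
        recs = make_airr(rows)
        shuffled = recs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = cluster_clones(recs).sort_index()
        b = cluster_clones(shuffled).sort_index()
        pd.testing.assert_series_equal(a, b)

    def test_matches_bruteforce_oracle(self, rng):
        """Single-linkage clustering equals all-pairs transitive closure."""
        for trial in range(30):
            n = int(rng.integers(2, 40))
            length = int(rng.integers(4, 9))
            alphabet = list("ACDE")
            rows = [(f"c{i:02d}", "V1*01", "J1*01",
                     "".join(rng.choice(alphabet, length))) for i in range(n)]
            recs = make_airr(rows)
            clones = cluster_clones(recs, cutoff=0.85)
            # oracle: adjacency + reachability by repeated squaring
            cdr3s = [r[3] for r in rows]
            adj = np.eye(n, dtype=bool)
            for i, j in itertools.combinations(range(n), 2):
                d = sum(a != b for a, b in zip(cdr3s[i], cdr3s[j])) / length
                if d <= 0.15 + 1e-12:
                    adj[i, j] = adj[j, i] = True
            reach = adj.copy()
            for _ in range(n):
                new = reach @ reach
                if (new == reach).all():
                    break
                reach = new
            for i, j in itertools.combinations(range(n), 2):
                same = clones[f"c{i:02d}"] == clones[f"c{j:02d}"]
                assert same == bool(reach[i, j])

    def test_ids_ordered_by_smallest_barcode(self):
        recs = make_airr([("z9", "V1*01", "J1*01", "AAAA"),
                          ("a1", "V2*01", "J1*01", "CCCC")])
        clones = cluster_clones(recs)
        assert clones["a1"] == "clone_000001"
        assert clones["z9"] == "clone_000002"


class TestDistanceProperties:
    aa = hst.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25)
    nt = hst.text(alphabet="ACGT", min_size=1, max_size=120)

    @given(a=aa, b=aa)
    @settings(deadline=None, derandomize=True)
    def test_cdr3_distance_is_a_metric_on_equal_lengths(self, a, b):
        d = cdr3_distance(a, b)
        if len(a) != len(b):
            assert d is None
        else:
            assert 0.0 <= d <= 1.0
            assert d == cdr3_distance(b, a)
            assert (d == 0.0) == (a == b)

    @given(s=nt)
    @settings(deadline=None, derandomize=True)
    def test_shm_zero_on_self_and_symmetric(self, s):
        assert compute_shm(s, s) == 0.0

    @given(a=nt, b=nt)
    @settings(deadline=None, derandomize=True)
    def test_shm_symmetric_for_unambiguous_sequences(self, a, b):
        if len(a) == len(b):
            assert compute_shm(a, b) == compute_shm(b, a)


def test_dedupe_keeps_best_evidence():
    recs = make_airr([
        {"cell_id": "c1", "sequence": "ATGC", "c_call": None},
        {"cell_id": "c1", "sequence": "ATGCATGC", "c_call": "IGHG1"},
        {"cell_id": "c2", "sequence": "ATGC", "c_call": "IGHM"},
    ])
    out = dedupe_heavy_chains(recs)
    assert len(out) == 2
    assert out.loc[out["cell_id"] == "c1", "c_call"].iloc[0] == "IGHG1"
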