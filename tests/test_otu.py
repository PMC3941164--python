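"""Furthest-neighbor clustering, OTU tables, and nearest-reference labels."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from methanodiv.datasets import clone_counts
from methanodiv.errors import ClusteringError
from methanodiv.io import Alignment, AlignmentRecord, DistanceMatrix
from methanodiv.otu import (
    cluster_furthest_neighbor,
    nearest_reference,
    otu_table,
    similarity_cutoff,
)

from conftest import random_distance_matrix


def _dm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"s{i}" for i in range(len(values)))
    return DistanceMatrix(tuple(labels), values)


def _partition(assignment):
    out = {}
    for sid, k in assignment.otu_of.items():
        out.setdefault(k, set()).add(sid)
    return set(frozenset(s) for s in out.values())


class TestClustering:
    def test_all_zero_gives_one_otu(self):
        asg = cluster_furthest_neighbor(_dm(np.zeros((4, 4))), 0.02)
        assert asg.n_otus == 1

    def test_all_beyond_cutoff_gives_singletons(self, rng):
        v = random_distance_matrix(6, rng, low=0.3, high=0.9)
        asg = cluster_furthest_neighbor(_dm(v), 0.02)
        assert asg.n_otus == 6

    def test_planted_blocks_recovered_and_minimal(self):
        """Three planted blocks are the unique minimal feasible partition."""
        n = 6
        blocks = [(0, 1), (2, 3), (4, 5)]
        v = np.full((n, n), 0.20)
        for b in blocks:
            for i in b:
                for j in b:
                    v[i, j] = 0.0 if i == j else 0.01
        dm = _dm(v)
        asg = cluster_furthest_neighbor(dm, 0.02)
        assert asg.n_otus == 3
        assert _partition(asg) == {
            frozenset({"s0", "s1"}), frozenset({"s2", "s3"}), frozenset({"s4", "s5"})
        }
        # brute force: no partition with < 3 blocks keeps all diameters <= cutoff
        labels = list(dm.labels)

        def partitions(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for part in partitions(rest):
                for k in range(len(part)):
                    yield part[:k] + [part[k] + [first]] + part[k + 1:]
                yield [[first]] + part

        feasible_sizes = []
        for part in partitions(labels):
            ok = all(
                dm.get(a, b) <= 0.02
                for block in part
                for a, b in itertools.combinations(block, 2)
            )
            if ok:
                feasible_sizes.append(len(part))
        assert min(feasible_sizes) == 3

    def test_diameter_invariant_random(self, rng):
        for _ in range(10):
            v = random_distance_matrix(12, rng)
            dm = _dm(v)
            cutoff = float(rng.uniform(0.1, 0.9))
            asg = cluster_furthest_neighbor(dm, cutoff)
            for members in asg.members().values():
                for a, b in itertools.combinations(members, 2):
                    assert dm.get(a, b) <= cutoff

    def test_otu_count_monotone_in_cutoff(self, rng):
        v = random_distance_matrix(10, rng)
        dm = _dm(v)
        counts = [
            cluster_furthest_neighbor(dm, c).n_otus
            for c in np.linspace(0, 1, 11)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_cutoff_extremes(self, rng):
        # duplicates at distance 0, everything else distinct
        v = random_distance_matrix(5, rng, low=0.1, high=0.9)
        v[0, 1] = v[1, 0] = 0.0
        dm = _dm(v)
        asg0 = cluster_furthest_neighbor(dm, 0.0)
        assert asg0.n_otus == 4
        assert {"s0", "s1"} in [set(m) for m in asg0.members().values()]
        assert cluster_furthest_neighbor(dm, v.max()).n_otus == 1

    def test_scipy_complete_linkage_oracle(self, rng):
        """Cluster counts match scipy's complete linkage on tie-free matrices."""
        for _ in range(10):
            n = int(rng.integers(5, 15))
            v = random_distance_matrix(n, rng)
            cutoff = float(rng.uniform(0.2, 0.8))
            ours = cluster_furthest_neighbor(_dm(v), cutoff).n_otus
            z = linkage(squareform(v), method="complete")
            theirs = len(set(fcluster(z, t=cutoff, criterion="distance")))
            assert ours == theirs

    def test_empty_and_nan(self):
        assert cluster_furthest_neighbor(_dm(np.zeros((0, 0)), ()), 0.1).otu_of == {}
        dm = _dm(np.zeros((3, 3)))
        dm.values[0, 1] = dm.values[1, 0] = np.nan  # corrupt after validation
        with pytest.raises(ClusteringError):
            cluster_furthest_neighbor(dm, 0.1)

    def test_merge_trace_nondecreasing(self, rng):
        v = random_distance_matrix(10, rng)
        asg = cluster_furthest_neighbor(_dm(v), 1.0)
        dists = [d for d, _, _ in asg.merge_trace]
        assert dists == sorted(dists)


class TestSimilarityCutoff:
    def test_criteria_map(self):
        assert similarity_cutoff(98) == pytest.approx(0.02)
        assert similarity_cutoff(95) == pytest.approx(0.05)


class TestOTUTable:
    def _aln(self, n_horse, n_pony):
        recs = [
            AlignmentRecord(f"horse_c{i}", "horse", "ACGT") for i in range(n_horse)
        ] + [AlignmentRecord(f"pony_c{i}", "pony", "ACGT") for i in range(n_pony)]
        return Alignment(tuple(recs), "dna")

    def test_single_otu_counts(self):
        aln = self._aln(50, 50)
        dm = _dm(np.zeros((100, 100)), tuple(aln.ids))
        asg = cluster_furthest_neighbor(dm, 0.02)
        table = otu_table(asg, aln)
        assert table.rows == ((1, (50, 50)),)

    def test_published_mcra_table_shape(self):
        table = clone_counts("mcra")
        df = table.to_frame()
        assert df.loc["OTU1", "total"] == 62
        assert df.loc["OTU1", "horse"] == 29 and df.loc["OTU1", "pony"] == 33
        assert df["horse"].sum() == 50 and df["pony"].sum() == 50
        # rows ordered by descending total
        totals = list(df["total"])
        assert totals == sorted(totals, reverse=True)

    def test_generator_round_trip_counts(self):
        from methanodiv.distances import distance_matrix
        from methanodiv.synthetic import CommunitySpec, generate_library

        counts = (29, 10, 6, 1, 1, 1, 1, 1)
        spec = CommunitySpec(
            abundance_model="explicit", explicit_counts=counts,
            sequence_length=300, seed=3,
        )
        lib = generate_library(spec, 50, "horse", seed=3)
        asg = cluster_furthest_neighbor(distance_matrix(lib.alignment), 0.02)
        table = otu_table(asg, lib.alignment)
        assert sorted(c[0] for _, c in table.rows) == sorted(counts)


class TestNearestReference:
    def _refs(self):
        return Alignment(
            (
                AlignmentRecord("ref_A", "ref", "A" * 100),
                AlignmentRecord("ref_B", "ref", "C" * 7 + "A" * 93),
            ),
            "dna",
        )

    def test_identical_query(self):
        q = Alignment((AlignmentRecord("q_1", "q", "A" * 100),), "dna")
        (qid, ref, sim), = nearest_reference(q, self._refs())
        assert (qid, ref, sim) == ("q_1", "ref_A", 100.0)

    def test_seven_percent_distance(self):
        q = Alignment((AlignmentRecord("q_1", "q", "C" * 7 + "A" * 93),), "dna")
        out = nearest_reference(q, self._refs())
        assert out[0][1] == "ref_B"
        assert out[0][2] == pytest.approx(100.0)
        q2 = Alignment((AlignmentRecord("q_2", "q", "G" * 7 + "A" * 93),), "dna")
        out2 = nearest_reference(q2, self._refs())
        assert out2[0][2] == pytest.approx(93.0)

    def test_tie_broken_by_input_order(self):
        q = Alignment((AlignmentRecord("q_1", "q", "T" * 100),), "dna")
        out = nearest_reference(q, self._refs())
        assert out[0][1] == "ref_A"  # both distances 1.0; first ref wins

    def test_argmin_oracle(self, rng):
        from methanodiv.distances import cross_distance_values

        chars = np.array(list("ACGT"))
        qs = Alignment(
            tuple(
                AlignmentRecord(f"q_{i}", "q", "".join(rng.choice(chars, 50)))
                for i in range(6)
            ),
            "dna",
        )
        refs = Alignment(
            tuple(
                AlignmentRecord(f"r_{i}", "r", "".join(rng.choice(chars, 50)))
                for i in range(5)
            ),
            "dna",
        )
        xd = cross_distance_values(qs, refs)
        for i, (qid, ref, sim) in enumerate(nearest_reference(qs, refs)):
            assert xd[i, refs.ids.index(ref)] == xd[i].min()
            assert sim == pytest.approx((1 - xd[i].min()) * 100)
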