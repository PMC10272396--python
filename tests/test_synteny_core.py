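"""Synteny scores and clusters, checked against exhaustive enumeration."""

import itertools

import numpy as np
import pytest

from ghsynteny.synteny_core import (
    clustered_fraction,
    find_clusters,
    synteny_scores,
)
from conftest import build_genome


# ---------------------------------------------------------------------------
# Independent oracles: scan distances by definition / connected components
# ---------------------------------------------------------------------------


def brute_ssc(positions, n, circular):
    """SSc by definition: smallest d such that a class gene sits d PEGs away."""
    pos = set(positions)
    out = []
    for p in positions:
        found = None
        for d in range(1, n):
            if circular:
                around = {(p - 1 - d) % n + 1, (p - 1 + d) % n + 1}
            else:
                around = {q for q in (p - d, p + d) if 1 <= q <= n}
            if any(q in pos and q != p for q in around):
                found = d
                break
        out.append(found)
    return out


def brute_clusters(positions, n, circular, threshold):
    """Partition by linking successive class genes whose gap <= threshold."""
    ordered = sorted(positions)
    m = len(ordered)
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(m - 1):
        if ordered[i + 1] - ordered[i] <= threshold:
            union(i, i + 1)
    if circular and m > 1 and (n - ordered[-1] + ordered[0]) <= threshold:
        union(m - 1, 0)
    groups = {}
    for i, p in enumerate(ordered):
        groups.setdefault(find(i), set()).add(p)
    return frozenset(frozenset(g) for g in groups.values())


def cluster_partition(clusters):
    return frozenset(frozenset(g.ordinal for g in c.genes) for c in clusters)


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------


class TestSyntenyScores:
    def test_circular_three_genes(self):
        genome = build_genome(10, gh=[2, 3, 7])
        profile = synteny_scores(genome)
        assert profile.ssc == (1, 1, 4)

    def test_topology_changes_end_distances(self):
        linear = build_genome(10, gh=[1, 10], topology="linear")
        circular = build_genome(10, gh=[1, 10], topology="circular")
        assert synteny_scores(linear).ssc == (9, 9)
        assert synteny_scores(circular).ssc == (1, 1)

    def test_single_gene_is_undefined(self):
        genome = build_genome(10, gh=[4])
        assert synteny_scores(genome).ssc == (None,)

    def test_empty_class_gives_empty_profile(self):
        genome = build_genome(10)
        profile = synteny_scores(genome)
        assert profile.n_genes == 0 and len(profile.ssc) == 0

    def test_histogram_parts_sum_to_total(self):
        genome = build_genome(60, gh=[1, 2, 10, 40, 55])
        profile = synteny_scores(genome)
        assert (
            int(profile.n_ssc.sum()) + profile.n_beyond + profile.n_undefined
            == profile.n_genes
        )
        assert np.all(profile.f_ssc >= 0) and np.all(profile.f_ssc <= 1)

    def test_scores_never_cross_replicons(self):
        from ghsynteny.annotation_io import (
            DomainHit,
            GeneRecord,
            Replicon,
            annotate,
        )

        replicons = []
        for rid, n in (("c1", 6), ("c2", 6)):
            genes = tuple(
                GeneRecord("G", rid, o, "+", f"{rid}_g{o}") for o in range(1, n + 1)
            )
            replicons.append(Replicon(rid, "linear", genes))
        hits = [
            DomainHit("c1_g6", "PF00128", 60.0),
            DomainHit("c2_g1", "PF00128", 60.0),
        ]
        genome = annotate(replicons, hits)
        # adjacent across the boundary, yet both undefined within replicons
        assert synteny_scores(genome).ssc == (None, None)


class TestFindClusters:
    def test_threshold_three_splits_wrap(self):
        genome = build_genome(10, gh=[2, 3, 7])
        parts = cluster_partition(find_clusters(genome, 3))
        assert parts == frozenset({frozenset({2, 3}), frozenset({7})})

    def test_threshold_five_wrap_chains_all(self):
        genome = build_genome(10, gh=[2, 3, 7])
        parts = cluster_partition(find_clusters(genome, 5))
        assert parts == frozenset({frozenset({2, 3, 7})})

    def test_no_genes_no_clusters(self):
        assert find_clusters(build_genome(10), 5) == []

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            find_clusters(build_genome(10, gh=[1]), 0)

    def test_cluster_gaps_and_span(self):
        genome = build_genome(20, gh=[4, 6, 9])
        (cluster,) = find_clusters(genome, 5)
        assert cluster.gaps == (2, 3)
        assert cluster.span == 6
        assert cluster.size == 3

    def test_wrapped_cluster_lists_members_in_chain_order(self):
        genome = build_genome(12, gh=[11, 12, 1, 2])
        (cluster,) = find_clusters(genome, 2)
        assert [g.ordinal for g in cluster.genes] == [11, 12, 1, 2]
        assert cluster.gaps == (1, 1, 1)


class TestClusteredFraction:
    def test_examples(self):
        genome = build_genome(10, gh=[2, 3, 7])
        assert clustered_fraction(genome, 5) == pytest.approx(1.0)
        assert clustered_fraction(genome, 1) == pytest.approx(2 / 3)

    def test_single_gene_counts_as_unclustered(self):
        assert clustered_fraction(build_genome(10, gh=[4]), 5) == 0.0

    def test_no_gh_genes_is_error(self):
        with pytest.raises(ValueError, match="no GH genes"):
            clustered_fraction(build_genome(10), 5)

    def test_monotone_in_threshold(self):
        genome = build_genome(50, gh=[1, 4, 9, 20, 33, 34, 48])
        fracs = [clustered_fraction(genome, t) for t in range(1, 26)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


# ---------------------------------------------------------------------------
# Exhaustive equivalence and invariances
# ---------------------------------------------------------------------------


def all_small_cases(max_n=8, max_gh=3):
    for n in range(2, max_n + 1):
        for k in range(1, max_gh + 1):
            for positions in itertools.combinations(range(1, n + 1), k):
                for topology in ("circular", "linear"):
                    yield n, positions, topology


class TestEnumerationEquivalence:
    def test_ssc_matches_brute_force_on_all_small_replicons(self):
        for n, positions, topology in all_small_cases():
            genome = build_genome(n, gh=positions, topology=topology)
            got = synteny_scores(genome).ssc
            want = tuple(brute_ssc(positions, n, topology == "circular"))
            assert got == want, (n, positions, topology)

    def test_clusters_match_brute_force_on_all_small_replicons(self):
        for n, positions, topology in all_small_cases():
            for threshold in (1, 2, 3):
                genome = build_genome(n, gh=positions, topology=topology)
                got = cluster_partition(find_clusters(genome, threshold))
                want = brute_clusters(
                    positions, n, topology == "circular", threshold
                )
                assert got == want, (n, positions, topology, threshold)


class TestInvariances:
    @pytest.mark.parametrize("shift", [1, 3, 7])
    def test_rotation_preserves_ssc_multiset_and_partition_shape(self, shift):
        n, positions = 12, [2, 3, 8, 11]
        rotated = [(p - 1 + shift) % n + 1 for p in positions]
        base = build_genome(n, gh=positions)
        moved = build_genome(n, gh=rotated)
        assert sorted(synteny_scores(base).ssc) == sorted(synteny_scores(moved).ssc)
        base_sizes = sorted(c.size for c in find_clusters(base, 3))
        moved_sizes = sorted(c.size for c in find_clusters(moved, 3))
        assert base_sizes == moved_sizes

    @pytest.mark.parametrize("topology", ["circular", "linear"])
    def test_reversal_preserves_ssc_multiset(self, topology):
        n, positions = 11, [1, 4, 5, 9]
        reversed_positions = [n - p + 1 for p in positions]
        fwd = build_genome(n, gh=positions, topology=topology)
        rev = build_genome(n, gh=reversed_positions, topology=topology)
        assert sorted(synteny_scores(fwd).ssc) == sorted(synteny_scores(rev).ssc)
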