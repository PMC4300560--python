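"""Evidence chopping, filtering, clustering, voting and catalog comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ncrnakit import mirna
from ncrnakit._util import revcomp
from ncrnakit.mirna import (
    EvidenceHit,
    call_genes,
    chop_scaffold,
    cluster_hits,
    compare_catalogs,
    filter_confidence,
    map_matures,
)
from conftest import random_dna


def hit(start, end, source="s1", strand="+", conf=0.9, scaffold="scaf", name=""):
    return EvidenceHit(source, scaffold, start, end, strand, conf, name)


class TestChopScaffold:
    def test_single_window(self):
        assert chop_scaffold("A" * 521) == [(0, 521)]

    def test_two_windows_overlap_176(self):
        wins = chop_scaffold("A" * 866)
        assert wins == [(0, 521), (345, 866)]
        assert wins[0][1] - wins[1][0] == 176

    @given(st.integers(1, 5000))
    def test_windows_cover_scaffold_with_exact_overlap(self, n):
        wins = chop_scaffold("A" * n)
        covered = set()
        for s, e in wins:
            covered.update(range(s, e))
        assert covered == set(range(n))
        for (s1, e1), (s2, _) in zip(wins, wins[1:]):
            if e1 - s1 == 521:  # full windows overlap exactly 176
                assert e1 - s2 == 176


class TestFilterConfidence:
    THRESH = {"ab_initio": 0.80, "rnaz": 0.90}

    def test_ab_initio_threshold_boundary(self):
        kept = filter_confidence(
            [hit(0, 80, "ab_initio", conf=0.79), hit(0, 80, "ab_initio", conf=0.80)],
            self.THRESH,
        )
        assert [h.confidence for h in kept] == [0.80]

    def test_comparative_screen_threshold(self):
        assert filter_confidence([hit(0, 80, "rnaz", conf=0.89)], self.THRESH) == []

    def test_zero_threshold_is_identity(self):
        hits = [hit(0, 80, "ab_initio", conf=0.01)]
        assert filter_confidence(hits, {"ab_initio": 0.0}) == hits

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            filter_confidence([hit(0, 80, "mystery")], self.THRESH)


def brute_force_clusters(hits):
    """O(n^2) transitive closure on the pairwise join rule."""
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = hits[i], hits[j]
            if a.scaffold != b.scaffold or a.strand != b.strand:
                continue
            overlap = a.start < b.end and b.start < a.end
            near = abs(a.start - b.start) < 40
            if overlap or near:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hits[i])
    return {
        frozenset((h.source, h.start, h.end, h.strand) for h in g)
        for g in groups.values()
    }


class TestClusterHits:
    def test_starts_within_40_join(self):
        clusters = cluster_hits([hit(100, 180), hit(139, 220, "s2")])
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (100, 220)

    def test_gap_and_start_delta_41_split(self):
        clusters = cluster_hits([hit(100, 130), hit(141, 171)])
        assert len(clusters) == 2

    def test_opposite_strands_never_join(self):
        clusters = cluster_hits([hit(100, 180, strand="+"), hit(100, 180, strand="-")])
        assert len(clusters) == 2

    def test_transitive_chain_joins(self):
        # A-B within 40, B-C within 40, A-C not: single linkage joins all
        clusters = cluster_hits([hit(0, 20), hit(35, 55), hit(70, 90)])
        assert len(clusters) == 1

    def test_matches_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(777)
        for _ in range(200):
            n = int(rng.integers(2, 100))
            hits = []
            for i in range(n):
                s = int(rng.integers(0, 2000))
                hits.append(
                    hit(
                        s,
                        s + int(rng.integers(20, 120)),
                        source=f"s{rng.integers(0, 5)}",
                        strand="+" if rng.random() < 0.5 else "-",
                        scaffold=f"sc{rng.integers(0, 2)}",
                    )
                )
            got = {
                frozenset((h.source, h.start, h.end, h.strand) for h in c.hits)
                for c in cluster_hits(hits)
            }
            assert got == brute_force_clusters(hits)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        hits = [
            hit(int(s), int(s) + 50, source=f"s{i % 3}")
            for i, s in enumerate(rng.integers(0, 500, size=20))
        ]
        a = cluster_hits(hits)
        b = cluster_hits(list(reversed(hits)))
        assert [(c.start, c.end, len(c.hits)) for c in a] == [
            (c.start, c.end, len(c.hits)) for c in b
        ]


class TestCallGenes:
    def test_two_sources_one_long_hit_accepted(self):
        c = cluster_hits([hit(0, 85, "s1"), hit(10, 70, "s2")])
        assert len(call_genes(c)) == 1

    def test_all_hits_at_most_70_rejected(self):
        c = cluster_hits([hit(0, 70, "s1"), hit(5, 75 - 5, "s2")])
        assert call_genes(c) == []

    def test_single_source_rejected_despite_length(self):
        c = cluster_hits([hit(0, 100, "s1"), hit(20, 120, "s1")])
        assert call_genes(c) == []

    def test_span_semantics_flag(self):
        # two 45 bp hits spanning 80 bp together: rejected on hit length,
        # accepted on merged-span semantics
        c = cluster_hits([hit(0, 45, "s1"), hit(35, 80, "s2")])
        assert call_genes(c) == []
        c = cluster_hits([hit(0, 45, "s1"), hit(35, 80, "s2")])
        assert len(call_genes(c, span_semantics=True)) == 1


class TestMapMatures:
    def test_planted_mature_found_exactly(self, rng):
        scaf = random_dna(rng, 400)
        mat = scaf[100:122]
        hits = map_matures({"s": scaf}, {"mir-x": mat})
        plus = [h for h in hits if h.strand == "+"]
        assert any(h.start == 100 and h.end == 122 for h in plus)
        assert all(h.confidence == 1.0 for h in hits)

    def test_one_mismatch_kills_hit(self, rng):
        scaf = random_dna(rng, 300)
        mat = list(scaf[50:72])
        mat[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mat[10]]
        hits = map_matures({"s": scaf}, {"m": "".join(mat)})
        assert all(not (h.start == 50 and h.strand == "+") for h in hits)

    def test_palindrome_reported_on_both_strands(self):
        pal = "ACGTACGTACGTACGTACGT"  # 20 nt, its own reverse complement
        assert pal == revcomp(pal)
        scaf = "T" * 50 + pal + "G" * 50
        hits = map_matures({"s": scaf}, {"p": pal})
        strands = {(h.start, h.strand) for h in hits}
        assert (50, "+") in strands and (50, "-") in strands

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError, match="18-30"):
            map_matures({"s": "ACGT"}, {"short": "ACGTACGT"})


class TestCompareCatalogs:
    def _genes(self, coords, scaffold="s", strand="+"):
        return [
            mirna.MiRNACandidate(scaffold, strand, a, b, [hit(a, b, scaffold=scaffold, strand=strand)])
            for a, b in coords
        ]

    def test_self_comparison_fully_common(self):
        g = self._genes([(0, 80), (200, 290)])
        rep = compare_catalogs(g, g)
        assert rep.common == 2 and rep.pct_common == 100.0

    def test_printed_percent_common(self):
        # 53 of 96 genes shared -> 55.2%
        this = self._genes([(i * 200, i * 200 + 80) for i in range(96)])
        other = self._genes([(i * 200, i * 200 + 80) for i in range(53)])
        rep = compare_catalogs(this, other)
        assert rep.common == 53
        assert rep.pct_common == 55.2

    def test_disjoint_sets(self):
        rep = compare_catalogs(self._genes([(0, 80)]), self._genes([(500, 580)]))
        assert rep.common == 0 and rep.pct_common == 0.0

    def test_strand_mismatch_not_common(self):
        rep = compare_catalogs(
            self._genes([(0, 80)], strand="+"), self._genes([(0, 80)], strand="-")
        )
        assert rep.common == 0


def test_hits_tsv_round_trip(tmp_path):
    hits = [hit(10, 90, "s1", name="mir-1"), hit(200, 280, "s2", strand="-")]
    path = tmp_path / "hits.tsv"
    mirna.write_hits_tsv(hits, path)
    assert mirna.read_hits_tsv(path) == hits
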