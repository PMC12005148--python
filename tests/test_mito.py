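"""Mitochondrial labelling, inverted repeats, and repeat clustering."""

import numpy as np
import pytest

from _oracles import brute_inverted_repeats
from ambistop.core import PROTOZOAN_MITO_CODE, Sequence, reverse_complement, translate
from ambistop.mito import (
    cluster_repeats,
    contig_report,
    find_inverted_repeats,
    identify_mito_queries,
    label_mito_contigs,
)


def random_dna(rng, n, at=0.5):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="module")
def mito_setup(small_bundle):
    queries = identify_mito_queries(small_bundle.genome, small_bundle.mito_refs)
    labelled, hits = label_mito_contigs(small_bundle.genome, queries)
    return queries, labelled, hits


class TestReciprocalLabelling:
    def test_best_hits_lie_on_planted_mito_contigs(self, mito_setup, small_bundle):
        queries, _labelled, _hits = mito_setup
        assert set(queries) == {"cox1", "cox3", "cob"}
        for gene, query in queries.items():
            template_prot = translate(
                small_bundle.mito_templates[gene], PROTOZOAN_MITO_CODE, "strict"
            )
            assert query.residues == template_prot

    def test_labelled_set_equals_planted_truth(self, mito_setup, small_bundle):
        _q, labelled, _hits = mito_setup
        assert labelled == sorted(small_bundle.truth["mito_genes"].contig.unique())

    def test_gene_copies_match_truth(self, mito_setup, small_bundle):
        """Hits of at least the minimum alignable length equal the planted
        copies (full copies exactly; fragment ends may pick up a few chance
        matches in the flanking spacer), with correct fragment status."""
        _q, _labelled, hits = mito_setup
        truth = small_bundle.truth["mito_genes"]
        expected = [
            r for r in truth.itertuples() if r.end - r.start >= 300
        ]
        assert len(hits) == len(expected)
        for r in expected:
            match = [
                h for h in hits
                if h.contig == r.contig and h.gene == r.gene and h.strand == r.strand
                and abs(h.interval.start - r.start) <= 30
                and abs(h.interval.end - r.end) <= 30
            ]
            assert len(match) == 1, (r.contig, r.gene, r.start)
            assert match[0].fragment == (not r.full)
            if r.full:
                assert (match[0].interval.start, match[0].interval.end) == (r.start, r.end)

    def test_assembly_without_mito_reports_absent(self, small_bundle):
        nuclear_only = [s for s in small_bundle.genome if s.id.startswith(("nuc", "host", "bact"))]
        queries = identify_mito_queries(nuclear_only, small_bundle.mito_refs)
        assert queries == {}

    def test_diverged_pseudocopy_not_labelled(self, small_bundle):
        """A nuclear-style contig with a ~60%-identity pseudo-copy fails the
        95% identity gate."""
        rng = np.random.default_rng(17)
        template = small_bundle.mito_templates["cox1"]
        codons = [template[i : i + 3] for i in range(0, len(template), 3)]
        for i in rng.choice(len(codons), size=int(0.4 * len(codons)), replace=False):
            codons[int(i)] = random_dna(rng, 3)
        decoy = Sequence("decoy", random_dna(rng, 500) + "".join(codons) + random_dna(rng, 500))
        queries = identify_mito_queries(small_bundle.genome, small_bundle.mito_refs)
        labelled, _hits = label_mito_contigs(list(small_bundle.genome) + [decoy], queries)
        assert "decoy" not in labelled

    def test_fragment_threshold(self, small_bundle):
        rng = np.random.default_rng(18)
        template = small_bundle.mito_templates["cox1"]
        full = Sequence("full", random_dna(rng, 300) + template + random_dna(rng, 300))
        frag = Sequence("frag", random_dna(rng, 300) + template[:300] + random_dna(rng, 300))
        queries = identify_mito_queries([full], small_bundle.mito_refs)
        _labelled, hits = label_mito_contigs([full, frag], queries)
        by_contig = {h.contig: h for h in hits if h.gene == "cox1"}
        assert by_contig["full"].fragment is False
        assert by_contig["frag"].fragment is True

    def test_best_hit_invariant_to_contig_order(self, small_bundle):
        a = identify_mito_queries(small_bundle.genome, small_bundle.mito_refs)
        b = identify_mito_queries(small_bundle.genome[::-1], small_bundle.mito_refs)
        assert {k: v.residues for k, v in a.items()} == {k: v.residues for k, v in b.items()}


class TestInvertedRepeats:
    @staticmethod
    def _plant(rng, unit, left, middle, right):
        """Embed unit ... revcomp(unit) with flank bases chosen so the
        planted pair cannot be extended outward by chance."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        left, middle, right = list(left), list(middle), list(right)
        # a-left with b-right extension: s[a_start-1] vs comp(s[b_end])
        left[-1] = next(b for b in "ACGT" if b != comp[right[0]])
        # a-right with b-left extension: s[a_end] vs comp(s[b_start-1])
        middle[0] = next(b for b in "ACGT" if b != comp[middle[-1]])
        return "".join(left) + unit + "".join(middle) + reverse_complement(unit) + "".join(right)

    def test_planted_pair_found_exactly(self):
        rng = np.random.default_rng(19)
        u = random_dna(rng, 60)
        s = self._plant(rng, u, random_dna(rng, 800), random_dna(rng, 500), random_dna(rng, 640))
        pairs = [p for p in find_inverted_repeats(Sequence("c", s), min_len=50)]
        assert len(pairs) == 1
        assert pairs[0].length == 60
        assert (pairs[0].a_start, pairs[0].b_start) == (800, 1360)

    def test_min_len_boundary(self):
        rng = np.random.default_rng(20)
        u = random_dna(rng, 49)
        s = self._plant(rng, u, random_dna(rng, 300), random_dna(rng, 200), random_dna(rng, 300))
        assert find_inverted_repeats(Sequence("c", s), min_len=50) == []
        assert len(find_inverted_repeats(Sequence("c", s), min_len=49)) == 1

    def test_matches_quadratic_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for trial in range(6):
            s = random_dna(rng, 2000)
            u = random_dna(rng, int(rng.integers(20, 80)))
            ins = 200 + 300 * trial
            s = s[: ins] + u + s[ins + len(u) : 1500] + reverse_complement(u) + s[1500 + len(u) :]
            got = {
                (p.a_start, p.a_end, p.b_start, p.b_end)
                for p in find_inverted_repeats(Sequence("c", s), min_len=11)
            }
            assert got == brute_inverted_repeats(s, 11)

    def test_pairs_are_exact_and_maximal(self, small_bundle):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
        for seq in small_bundle.genome:
            if not seq.id.startswith("mito"):
                continue
            s = seq.residues
            for p in find_inverted_repeats(seq, min_len=50):
                a = s[p.a_start : p.a_end]
                b = s[p.b_start : p.b_end]
                assert a == reverse_complement(b)
                if p.a_start > 0 and p.b_end < len(s):
                    assert s[p.a_start - 1] != comp[s[p.b_end]]
                if p.a_end < len(s) and p.b_start > 0:
                    assert s[p.a_end] != comp[s[p.b_start - 1]]

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(29)
        u = random_dna(rng, 40)
        s = random_dna(rng, 200) + u + random_dna(rng, 100) + reverse_complement(u) + random_dna(rng, 160)
        fwd = find_inverted_repeats(Sequence("c", s), min_len=20)
        rev = find_inverted_repeats(Sequence("c", reverse_complement(s)), min_len=20)
        n = len(s)
        mirrored = {(n - p.b_end, n - p.b_start, n - p.a_end, n - p.a_start) for p in fwd}
        assert {(p.a_start, p.a_end, p.b_start, p.b_end) for p in rev} == mirrored


class TestClustering:
    def test_identical_repeats_one_cluster(self):
        rng = np.random.default_rng(33)
        u = random_dna(rng, 120)
        s = random_dna(rng, 50) + u + random_dna(rng, 50) + reverse_complement(u) + random_dna(rng, 50)
        contig = Sequence("c", s)
        pairs = [(contig, p) for p in find_inverted_repeats(contig, min_len=100)]
        clusters = cluster_repeats(pairs * 3)
        assert len(clusters) == 1

    def test_two_divergent_families_two_clusters(self):
        rng = np.random.default_rng(34)
        u1 = random_dna(rng, 150)
        chars = list(u1)
        for i in rng.choice(150, size=45, replace=False):  # 30% divergence
            chars[int(i)] = "ACGT"[(("ACGT".index(chars[int(i)])) + 1) % 4]
        u2 = "".join(chars)
        def contig_for(u, name):
            s = random_dna(rng, 60) + u + random_dna(rng, 60) + reverse_complement(u) + random_dna(rng, 60)
            return Sequence(name, s)
        c1, c2 = contig_for(u1, "c1"), contig_for(u2, "c2")
        pairs = [(c1, p) for p in find_inverted_repeats(c1, 100)] + [
            (c2, p) for p in find_inverted_repeats(c2, 100)
        ]
        clusters = cluster_repeats(pairs, identity=0.95)
        assert len(clusters) == 2

    def test_bundle_recovers_planted_families(self, small_bundle):
        by_id = {s.id: s for s in small_bundle.genome}
        pairs = []
        for cid in sorted(small_bundle.truth["mito_genes"].contig.unique()):
            for p in find_inverted_repeats(by_id[cid], min_len=50):
                pairs.append((by_id[cid], p))
        truth = small_bundle.truth["mito_repeats"]
        got = {(c.id, p.a_start, p.a_end, p.b_start, p.b_end) for c, p in pairs}
        exp = {(r.contig, r.a_start, r.a_end, r.b_start, r.b_end) for r in truth.itertuples()}
        assert got == exp
        clusters = cluster_repeats(pairs)
        assert len(clusters) == truth.family.nunique()
        assert sum(len(c.member_ids) for c in clusters) == len(pairs)

    def test_representative_is_longest_member(self, small_bundle):
        by_id = {s.id: s for s in small_bundle.genome}
        pairs = []
        for cid in sorted(small_bundle.truth["mito_genes"].contig.unique()):
            pairs.extend((by_id[cid], p) for p in find_inverted_repeats(by_id[cid], 50))
        for cluster in cluster_repeats(pairs):
            assert cluster.representative_id in cluster.member_ids


class TestContigReport:
    def test_empty_inputs(self):
        df, summary = contig_report([], [], [])
        assert len(df) == 0 and summary["n_pairs"] == 0.0

    def test_summary_bookkeeping(self, mito_setup, small_bundle):
        _q, _labelled, hits = mito_setup
        by_id = {s.id: s for s in small_bundle.genome}
        pairs = []
        for cid in sorted(small_bundle.truth["mito_genes"].contig.unique()):
            pairs.extend((by_id[cid], p) for p in find_inverted_repeats(by_id[cid], 50))
        clusters = cluster_repeats(pairs)
        df, summary = contig_report(small_bundle.genome, hits, pairs, clusters)
        assert summary["n_pairs"] == float(len(pairs))
        assert summary["n_clusters"] == float(len(clusters))
        gene_rows = df[df.kind.isin(["full_gene", "fragment"])]
        assert len(gene_rows) == len(hits)
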