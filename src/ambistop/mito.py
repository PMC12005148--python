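"""Mitochondrial contig identification and inverted-repeat cartography.

Organellar contigs of dinoflagellate-like genomes carry only three protein
genes (cox1, cox3, cob).  Identification is reciprocal: distant reference
proteins are first aligned across the assembly under the protozoan
mitochondrial code (UGA = Trp) to pick the species' own best-hit copies;
those translated copies then become the queries, and every contig carrying a
near-identical hit (default >=95% identity over >=100 codons) is labelled
mitochondrial.  Gene copies are scored full vs fragment against the longest
copy found.  Intergenic regions are scanned for *exact, maximal* inverted
repeats (>= 50 nt by default) which are then clustered greedily at 95%
identity over the shorter sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence as TypingSequence, Tuple

import pandas as pd

from .align import (
    CodonAlignment,
    QueryKmerIndex,
    ScoringScheme,
    align_codon_frame,
    diagonal_coverage,
    nucleotide_align,
    translate_frames,
)
from .core import Interval, PROTOZOAN_MITO_CODE, Sequence, reverse_complement

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass
class MitoGeneHit:
    gene: str
    contig: str
    interval: Interval
    strand: str
    identity: float
    fraction_of_full_length: float
    fragment: bool


@dataclass(frozen=True)
class InvertedRepeatPair:
    """Two windows on one contig that are exact reverse complements; the pair
    is maximal (not extendable outward on either side)."""

    contig: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    @property
    def palindromic_overlap(self) -> bool:
        return self.b_start < self.a_end


@dataclass
class RepeatCluster:
    representative_id: str
    representative_seq: str
    member_ids: List[str]
    identity_threshold: float


# ---------------------------------------------------------------------------
# Reciprocal homology labelling

def _best_hits_for_query(
    query: Sequence,
    assembly: TypingSequence[Sequence],
    k: int = 4,
    min_diag_score: int = 40,
    scheme: Optional[ScoringScheme] = None,
) -> List[CodonAlignment]:
    """All seeded codon-DP alignments of ``query`` across the assembly under
    the protozoan mitochondrial code."""
    scheme = scheme or ScoringScheme()
    index = QueryKmerIndex([query], k)
    hits = []
    for contig in assembly:
        if len(contig.residues) < 3 * k:
            continue
        for strand in ("+", "-"):
            text = contig.residues if strand == "+" else reverse_complement(contig.residues)
            for frame, aa_text in enumerate(translate_frames(text, PROTOZOAN_MITO_CODE)):
                seeded = False
                for (_qi, _diag), qposs in index.scan(aa_text).items():
                    if diagonal_coverage(qposs, k) >= min_diag_score:
                        seeded = True
                        break
                if not seeded:
                    continue
                aln = align_codon_frame(
                    query,
                    contig,
                    strand,
                    frame,
                    scheme,
                    PROTOZOAN_MITO_CODE,
                    contig_id=contig.id,
                )
                if aln is not None:
                    hits.append(aln)
    return hits


def identify_mito_queries(
    assembly: TypingSequence[Sequence],
    reference_proteins: TypingSequence[Sequence],
    min_score: int = 60,
    scheme: Optional[ScoringScheme] = None,
) -> Dict[str, Sequence]:
    """For each reference protein, translate the single best assembly hit
    into a species-specific query.  Genes with no hit above ``min_score`` are
    skipped (reported absent)."""
    queries: Dict[str, Sequence] = {}
    for ref in reference_proteins:
        hits = [
            h
            for h in _best_hits_for_query(ref, assembly, scheme=scheme)
            if h.score >= min_score
        ]
        if not hits:
            continue
        best = sorted(
            hits,
            key=lambda h: (-h.score, h.target.contig_id, h.target.start, h.strand),
        )[0]
        gene = ref.id.removesuffix("_ref")
        aa = []
        for codon in best.codons:
            if "N" in codon or codon in PROTOZOAN_MITO_CODE.stop_codons:
                aa.append("X")
            else:
                aa.append(PROTOZOAN_MITO_CODE.codon_to_aa[codon])
        queries[gene] = Sequence(gene, "".join(aa), "protein")
    return queries


def label_mito_contigs(
    assembly: TypingSequence[Sequence],
    mito_queries: Dict[str, Sequence],
    min_identity: float = 0.95,
    min_codons: int = 100,
    scheme: Optional[ScoringScheme] = None,
) -> Tuple[List[str], List[MitoGeneHit]]:
    """Label every contig carrying a near-identical copy of a species query.

    Returns the sorted labelled contig ids and all passing gene hits with
    fragment status (fraction of the longest copy < 0.9).
    """
    passing: List[Tuple[str, CodonAlignment]] = []
    for gene in sorted(mito_queries):
        query = mito_queries[gene]
        for aln in _best_hits_for_query(query, assembly, scheme=scheme):
            if aln.identity >= min_identity and aln.n_codons >= min_codons:
                passing.append((gene, aln))
    full_len: Dict[str, int] = {}
    for gene, aln in passing:
        full_len[gene] = max(full_len.get(gene, 0), aln.n_codons)
    for gene, query in mito_queries.items():
        full_len.setdefault(gene, len(query.residues))
    hits = []
    labelled = set()
    for gene, aln in passing:
        frac = aln.n_codons / full_len[gene]
        hits.append(
            MitoGeneHit(
                gene=gene,
                contig=aln.target.contig_id,
                interval=aln.target,
                strand=aln.strand,
                identity=aln.identity,
                fraction_of_full_length=frac,
                fragment=frac < 0.9,
            )
        )
        labelled.add(aln.target.contig_id)
    hits.sort(key=lambda h: (h.contig, h.interval.start, h.gene))
    return sorted(labelled), hits


# ---------------------------------------------------------------------------
# Inverted repeats

def find_inverted_repeats(
    seq: Sequence, min_len: int = 50, include_palindromic: bool = True
) -> List[InvertedRepeatPair]:
    """All maximal exact inverted-repeat pairs of length >= ``min_len``.

    A pair is two windows with ``window_a == revcomp(window_b)`` and
    ``a.start < b.start``; maximality means the match cannot be extended
    outward on either flank.  Overlapping (palindromic) pairs are included
    unless ``include_palindromic`` is false.
    """
    s = seq.residues
    n = len(s)
    if n < 2 * 1:
        return []
    t = reverse_complement(s)
    k = max(4, min(min_len, 16))
    if n < k:
        return []
    tpos: Dict[str, List[int]] = {}
    for p in range(n - k + 1):
        tpos.setdefault(t[p : p + k], []).append(p)
    out = []
    seen = set()
    for i in range(n - k + 1):
        entry = tpos.get(s[i : i + k])
        if not entry:
            continue
        for p in entry:
            if i > 0 and p > 0 and s[i - 1] == t[p - 1]:
                continue  # not the leftmost seed of this run
            run_key = (i, p)
            if run_key in seen:
                continue
            seen.add(run_key)
            L = k
            while i + L < n and p + L < n and s[i + L] == t[p + L]:
                L += 1
            # verify the seed actually starts a run of >= k (true by construction)
            if L < min_len:
                continue
            a_start = i
            b_start = n - p - L
            if a_start > b_start:
                continue  # mirror duplicate
            if a_start == b_start:
                continue  # a window matching itself
            pair = InvertedRepeatPair(seq.id, a_start, a_start + L, b_start, b_start + L)
            if pair.palindromic_overlap and not include_palindromic:
                continue
            out.append(pair)
    out.sort(key=lambda r: (r.a_start, r.b_start, r.length))
    return out


def repeat_unit(seq: Sequence, pair: InvertedRepeatPair) -> str:
    return seq.residues[pair.a_start : pair.a_end]


# ---------------------------------------------------------------------------
# Clustering

def cluster_repeats(
    pairs: List[Tuple[Sequence, InvertedRepeatPair]],
    identity: float = 0.95,
) -> List[RepeatCluster]:
    """Greedy centroid clustering of repeat-unit sequences.

    Units are sorted by length descending; each joins the first cluster
    whose representative it matches at >= ``identity`` over the shorter
    sequence (either orientation, as nucleotide clustering tools do by
    default), else founds a new cluster.  The representative is therefore
    always the longest member.
    """
    units = []
    for idx, (contig, pair) in enumerate(pairs):
        uid = f"{contig.id}:{pair.a_start}-{pair.a_end}/{pair.b_start}-{pair.b_end}"
        units.append((uid, repeat_unit(contig, pair)))
    units.sort(key=lambda u: (-len(u[1]), u[0]))
    clusters: List[RepeatCluster] = []
    for uid, unit in units:
        placed = False
        for cluster in clusters:
            rep = cluster.representative_seq
            # identity over the shorter sequence, as fixed-threshold greedy
            # clustering tools define it: matched columns / shorter length
            frac = 0.0
            for text in (unit, reverse_complement(unit)):
                aln = nucleotide_align(Sequence("u", text), Sequence("r", rep))
                frac = max(frac, aln.matches / min(len(unit), len(rep)))
            if frac >= identity:
                cluster.member_ids.append(uid)
                placed = True
                break
        if not placed:
            clusters.append(
                RepeatCluster(
                    representative_id=uid,
                    representative_seq=unit,
                    member_ids=[uid],
                    identity_threshold=identity,
                )
            )
    return clusters


# ---------------------------------------------------------------------------
# Reporting

def contig_report(
    contigs: TypingSequence[Sequence],
    hits: List[MitoGeneHit],
    pairs: List[Tuple[Sequence, InvertedRepeatPair]],
    clusters: Optional[List[RepeatCluster]] = None,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Ordered per-contig feature map (gene copies and repeat blocks) plus
    summary counts."""
    family_of: Dict[str, int] = {}
    if clusters:
        for fam, cluster in enumerate(clusters):
            for uid in cluster.member_ids:
                family_of[uid] = fam
    rows = []
    for hit in hits:
        rows.append(
            {
                "contig": hit.contig,
                "feature": hit.gene,
                "start": hit.interval.start,
                "end": hit.interval.end,
                "strand": hit.strand,
                "kind": "fragment" if hit.fragment else "full_gene",
                "detail": f"identity={hit.identity:.3f};fraction={hit.fraction_of_full_length:.3f}",
            }
        )
    for contig, pair in pairs:
        uid = f"{contig.id}:{pair.a_start}-{pair.a_end}/{pair.b_start}-{pair.b_end}"
        fam = family_of.get(uid, -1)
        for s, e in ((pair.a_start, pair.a_end), (pair.b_start, pair.b_end)):
            rows.append(
                {
                    "contig": contig.id,
                    "feature": f"repeat_fam{fam}" if fam >= 0 else "repeat",
                    "start": s,
                    "end": e,
                    "strand": ".",
                    "kind": "inverted_repeat",
                    "detail": f"pair={uid}",
                }
            )
    df = pd.DataFrame(
        rows, columns=["contig", "feature", "start", "end", "strand", "kind", "detail"]
    )
    if len(df):
        df = df.sort_values(["contig", "start", "end"], kind="stable").reset_index(drop=True)
    lengths = [p.length for _c, p in pairs]
    summary = {
        "n_contigs": float(len({c.id for c, _p in pairs} | {h.contig for h in hits})),
        "n_pairs": float(len(pairs)),
        "n_clusters": float(len(clusters) if clusters else 0),
        "min_pair_len": float(min(lengths)) if lengths else 0.0,
        "max_pair_len": float(max(lengths)) if lengths else 0.0,
    }
    return df, summary
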