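"""Discovery of stop-codon-containing genes (SCGs) in unannotated space.

The procedure mirrors a conservative two-pass annotation of a genome with an
ambiguous genetic code: an ordinary annotator only calls genes that can lack
in-frame stops, and this pipeline then searches the *unannotated* remainder
by homology.  Stages:

1. complement the existing annotation per contig (``extract_unannotated``);
2. seed each region (plus flanks) against a reference proteome with exact
   amino-acid k-mers over six readthrough frames, then run the stop-tolerant
   codon DP on every seeded (query, strand, frame) triple;
3. alignments without in-frame stops are routed to a stop-free side channel
   for re-annotation review, as are alignments that mostly overlap existing
   annotation (the search is confined to unannotated space);
4. overlapping candidates from different queries are resolved greedily by
   score ("only the best-scoring alignment is kept");
5. loci whose evidence splits one query across two genomic frames are
   flagged as frameshifts and discarded;
6. surviving models are checked for transcript support (>=90% identity and
   >=80% coverage of the model) and their in-frame stops masked as ``X``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence as TypingSequence, Tuple

import pandas as pd

from .align import (
    CodonAlignment,
    QueryKmerIndex,
    ScoringScheme,
    align_codon_frame,
    align_protein_pair,
    diagonal_coverage,
    nucleotide_align,
    translate_frames,
)
from .core import Interval, STANDARD_CODE, Sequence, reverse_complement
from .io import GffRecord


@dataclass
class ScgParams:
    """Tunable thresholds of the discovery pipeline."""

    min_region_len: int = 300
    flank: int = 2000
    k: int = 4
    min_diag_score: int = 40
    min_score: int = 60
    min_tx_identity: float = 0.90
    min_tx_cov: float = 0.80
    max_annotated_overlap: float = 0.2
    frameshift_gap: int = 100
    min_frameshift_aa: int = 20
    max_frameshift_query_overlap: int = 15
    scheme: ScoringScheme = field(default_factory=ScoringScheme)


@dataclass
class ScgModel:
    """An accepted SCG model: a stop-containing, frameshift-free alignment
    with masked protein and transcript-support status."""

    id: str
    alignment: CodonAlignment
    protein_masked: str
    genomic_seq: str
    transcript_supported: Optional[bool] = None
    frameshift_flag: bool = False

    @property
    def interval(self) -> Interval:
        return self.alignment.target

    @property
    def strand(self) -> str:
        return self.alignment.strand

    @property
    def query_id(self) -> str:
        return self.alignment.query_id

    @property
    def score(self) -> int:
        return self.alignment.score

    @property
    def stops(self) -> List[Tuple[int, str]]:
        return self.alignment.stops

    @property
    def query_coverage(self) -> float:
        return self.alignment.query_coverage


@dataclass
class ScgStats:
    n_scg: int
    n_transcript_supported: int
    mean_stops: Optional[float]
    stop_mix: Optional[Tuple[float, float, float]]  # fTAA, fTAG, fTGA
    mean_len_aa: Optional[float]
    stop_counts: Dict[str, int]

    @property
    def empty(self) -> bool:
        return self.n_scg == 0


@dataclass
class ScgResult:
    models: List[ScgModel]
    stats: ScgStats
    stop_free: List[CodonAlignment]
    frameshifted: List[ScgModel]
    regions: List[Interval]


# ---------------------------------------------------------------------------
# Region extraction

def extract_unannotated(
    genome: TypingSequence[Sequence],
    annotation: TypingSequence[GffRecord],
    min_len: int = 300,
) -> List[Interval]:
    """Per-contig complement of annotated gene features, dropping segments
    shorter than ``min_len``."""
    lengths = {s.id: len(s.residues) for s in genome}
    by_contig: Dict[str, List[Tuple[int, int]]] = {s.id: [] for s in genome}
    for rec in annotation:
        if rec.type != "gene":
            continue
        cid = rec.interval.contig_id
        if cid not in lengths:
            raise ValueError(f"annotation references unknown contig {cid!r}")
        if rec.interval.end > lengths[cid]:
            raise ValueError(f"feature {rec.interval} exceeds contig length {lengths[cid]}")
        by_contig[cid].append((rec.interval.start, rec.interval.end))
    regions: List[Interval] = []
    for contig in genome:
        n = lengths[contig.id]
        pos = 0
        for s, e in sorted(by_contig[contig.id]):
            if s > pos and s - pos >= min_len:
                regions.append(Interval(contig.id, pos, s))
            pos = max(pos, e)
        if n > pos and n - pos >= min_len:
            regions.append(Interval(contig.id, pos, n))
    return regions


# ---------------------------------------------------------------------------
# Candidate search

def genomic_frame(aln: CodonAlignment, contig_len: int) -> int:
    """Window-independent reading frame of an alignment on its contig."""
    if aln.strand == "+":
        return aln.target.start % 3
    return (contig_len - aln.target.end) % 3


def _annotated_overlap_fraction(aln: CodonAlignment, gene_spans: List[Tuple[int, int]]) -> float:
    iv = aln.target
    total = 0
    for s, e in gene_spans:
        total += max(0, min(iv.end, e) - max(iv.start, s))
    return total / iv.length


def find_scg_candidates(
    genome: TypingSequence[Sequence],
    regions: TypingSequence[Interval],
    proteome: TypingSequence[Sequence],
    params: Optional[ScgParams] = None,
    annotation: TypingSequence[GffRecord] = (),
) -> Tuple[List[CodonAlignment], List[CodonAlignment]]:
    """Seeded, stop-tolerant alignment of the proteome to candidate regions.

    Returns ``(scg_candidates, stop_free)``: alignments with at least one
    in-frame stop continue towards SCG model building; stop-free alignments
    (and alignments mostly covering already-annotated genes) are reported
    separately for re-annotation review.
    """
    params = params or ScgParams()
    if not proteome:
        raise ValueError("empty proteome")
    genome_by_id = {s.id: s for s in genome}
    gene_spans: Dict[str, List[Tuple[int, int]]] = {}
    for rec in annotation:
        if rec.type == "gene":
            gene_spans.setdefault(rec.interval.contig_id, []).append(
                (rec.interval.start, rec.interval.end)
            )
    index = QueryKmerIndex(proteome, params.k)

    candidates: List[CodonAlignment] = []
    stop_free: List[CodonAlignment] = []
    seen = set()
    for region in regions:
        contig = genome_by_id[region.contig_id]
        ws = max(0, region.start - params.flank)
        we = min(len(contig.residues), region.end + params.flank)
        window = Sequence(contig.id, contig.residues[ws:we])
        for strand in ("+", "-"):
            text = window.residues if strand == "+" else reverse_complement(window.residues)
            for frame, aa_text in enumerate(translate_frames(text, STANDARD_CODE)):
                seeded = set()
                for (qi, _diag), qposs in index.scan(aa_text).items():
                    if qi in seeded:
                        continue
                    if diagonal_coverage(qposs, params.k) >= params.min_diag_score:
                        seeded.add(qi)
                for qi in sorted(seeded):
                    aln = align_codon_frame(
                        proteome[qi],
                        window,
                        strand,
                        frame,
                        params.scheme,
                        STANDARD_CODE,
                        region_start=ws,
                        contig_id=contig.id,
                    )
                    if aln is None or aln.score < params.min_score:
                        continue
                    key = (
                        aln.query_id,
                        aln.target.contig_id,
                        aln.target.start,
                        aln.target.end,
                        aln.strand,
                    )
                    if key in seen:
                        continue
                    seen.add(key)
                    if _annotated_overlap_fraction(
                        aln, gene_spans.get(contig.id, [])
                    ) > params.max_annotated_overlap:
                        stop_free.append(aln)
                    elif aln.stops:
                        candidates.append(aln)
                    else:
                        stop_free.append(aln)
    return candidates, stop_free


# ---------------------------------------------------------------------------
# Overlap resolution and frameshift filtering

def _sort_key(aln: CodonAlignment):
    return (
        -aln.score,
        aln.target.contig_id,
        aln.target.start,
        -(aln.target.length),
        aln.query_id,
    )


def resolve_overlaps(cands: List[CodonAlignment]) -> List[CodonAlignment]:
    """Greedy best-score-first resolution: an alignment is kept iff it does
    not overlap (same contig and strand, >=1 bp) an already-kept one."""
    kept: List[CodonAlignment] = []
    kept_by_key: Dict[Tuple[str, str], List[CodonAlignment]] = {}
    for aln in sorted(cands, key=_sort_key):
        key = (aln.target.contig_id, aln.strand)
        if any(aln.target.overlaps(other.target) for other in kept_by_key.get(key, [])):
            continue
        kept.append(aln)
        kept_by_key.setdefault(key, []).append(aln)
    return sorted(kept, key=lambda a: (a.target.contig_id, a.target.start, a.strand))


def _query_span(aln: CodonAlignment) -> Tuple[int, int]:
    qpos = [q for q, _c, st in aln.aligned_pairs if q >= 0]
    return min(qpos), max(qpos) + 1


def flag_frameshifts(
    kept: List[CodonAlignment],
    all_cands: List[CodonAlignment],
    contig_lengths: Dict[str, int],
    params: Optional[ScgParams] = None,
) -> Tuple[List[CodonAlignment], List[CodonAlignment]]:
    """Remove kept alignments whose query has a second, frame-discordant
    partial alignment nearby.

    Two alignments of the same query on the same contig and strand are
    frameshift evidence when their genomic frames differ, their footprints
    overlap or lie within ``frameshift_gap`` bp, and they cover essentially
    disjoint query segments (overlap at most
    ``max_frameshift_query_overlap`` residues - local alignment extends a
    few chance matches past an indel breakpoint) of at least
    ``min_frameshift_aa`` unique residues each.
    """
    params = params or ScgParams()
    by_query: Dict[str, List[CodonAlignment]] = {}
    for aln in all_cands:
        by_query.setdefault(aln.query_id, []).append(aln)
    clean: List[CodonAlignment] = []
    flagged: List[CodonAlignment] = []
    for aln in kept:
        n = contig_lengths[aln.target.contig_id]
        frame_a = genomic_frame(aln, n)
        qa_lo, qa_hi = _query_span(aln)
        is_shifted = False
        for other in by_query.get(aln.query_id, []):
            if other is aln:
                continue
            if (
                other.target.contig_id != aln.target.contig_id
                or other.strand != aln.strand
            ):
                continue
            if (
                other.target.start == aln.target.start
                and other.target.end == aln.target.end
            ):
                continue
            if genomic_frame(other, n) == frame_a:
                continue
            gap = max(
                aln.target.start - other.target.end,
                other.target.start - aln.target.end,
            )
            if gap > params.frameshift_gap:
                continue
            qb_lo, qb_hi = _query_span(other)
            q_ovl = max(0, min(qa_hi, qb_hi) - max(qa_lo, qb_lo))
            if (
                q_ovl <= params.max_frameshift_query_overlap
                and (qa_hi - qa_lo) - q_ovl >= params.min_frameshift_aa
                and (qb_hi - qb_lo) - q_ovl >= params.min_frameshift_aa
            ):
                is_shifted = True
                break
        (flagged if is_shifted else clean).append(aln)
    return clean, flagged


# ---------------------------------------------------------------------------
# Model building, masking, transcript support

def mask_stops(alignment: CodonAlignment) -> str:
    """Readthrough translation of the aligned codons with every standard-code
    stop rendered as ``X``; length equals the aligned codon count."""
    out = []
    for codon in alignment.codons:
        if codon in STANDARD_CODE.stop_codons or "N" in codon:
            out.append("X")
        else:
            out.append(STANDARD_CODE.codon_to_aa[codon])
    return "".join(out)


def build_models(
    kept: List[CodonAlignment], genome: TypingSequence[Sequence]
) -> List[ScgModel]:
    genome_by_id = {s.id: s for s in genome}
    models = []
    ordered = sorted(kept, key=lambda a: (a.target.contig_id, a.target.start, a.strand))
    for i, aln in enumerate(ordered):
        contig = genome_by_id[aln.target.contig_id]
        text = contig.residues[aln.target.start : aln.target.end]
        if aln.strand == "-":
            text = reverse_complement(text)
        models.append(
            ScgModel(
                id=f"scg{i + 1:04d}",
                alignment=aln,
                protein_masked=mask_stops(aln),
                genomic_seq=text,
            )
        )
    return models


def check_transcript_support(
    models: List[ScgModel],
    transcripts: TypingSequence[Sequence],
    params: Optional[ScgParams] = None,
    prefilter_k: int = 21,
    min_shared_kmers: int = 3,
    max_candidates: int = 5,
) -> List[ScgModel]:
    """Set ``transcript_supported`` on every model.

    A model is supported iff its best-scoring transcript alignment reaches
    ``min_tx_identity`` identity with at least ``min_tx_cov`` of the model
    covered.  Exact-k-mer sharing preselects transcripts so only plausible
    partners are aligned.
    """
    params = params or ScgParams()
    tx_index: Dict[str, set] = {}
    tx_by_id = {t.id: t for t in transcripts}
    for t in transcripts:
        res = t.residues
        for i in range(len(res) - prefilter_k + 1):
            tx_index.setdefault(res[i : i + prefilter_k], set()).add(t.id)
    for model in models:
        counts: Dict[str, int] = {}
        res = model.genomic_seq
        for i in range(len(res) - prefilter_k + 1):
            for tid in tx_index.get(res[i : i + prefilter_k], ()):
                counts[tid] = counts.get(tid, 0) + 1
        ranked = sorted(
            (tid for tid, c in counts.items() if c >= min_shared_kmers),
            key=lambda tid: (-counts[tid], tid),
        )[:max_candidates]
        best = None
        for tid in ranked:
            aln = nucleotide_align(Sequence("m", model.genomic_seq), tx_by_id[tid])
            if best is None or aln.score > best.score:
                best = aln
        model.transcript_supported = bool(
            best is not None
            and best.identity >= params.min_tx_identity
            and best.coverage_of_a >= params.min_tx_cov
        )
    return models


# ---------------------------------------------------------------------------
# Statistics

def compute_scg_stats(models: List[ScgModel]) -> ScgStats:
    stop_counts = {"TAA": 0, "TAG": 0, "TGA": 0}
    if not models:
        return ScgStats(0, 0, None, None, None, stop_counts)
    total_stops = 0
    total_len = 0
    supported = 0
    for m in models:
        total_stops += len(m.stops)
        total_len += len(m.protein_masked)
        if m.transcript_supported:
            supported += 1
        for _ci, codon in m.stops:
            stop_counts[codon] += 1
    pooled = sum(stop_counts.values())
    mix = (
        tuple(stop_counts[c] / pooled for c in ("TAA", "TAG", "TGA"))
        if pooled
        else None
    )
    return ScgStats(
        n_scg=len(models),
        n_transcript_supported=supported,
        mean_stops=total_stops / len(models),
        stop_mix=mix,
        mean_len_aa=total_len / len(models),
        stop_counts=stop_counts,
    )


# ---------------------------------------------------------------------------
# Orchestration

def run_pipeline(
    genome: TypingSequence[Sequence],
    annotation: TypingSequence[GffRecord],
    proteome: TypingSequence[Sequence],
    transcripts: TypingSequence[Sequence],
    params: Optional[ScgParams] = None,
) -> ScgResult:
    """End-to-end SCG discovery on one assembly."""
    params = params or ScgParams()
    regions = extract_unannotated(genome, annotation, params.min_region_len)
    cands, stop_free = find_scg_candidates(genome, regions, proteome, params, annotation)
    kept = resolve_overlaps(cands)
    contig_lengths = {s.id: len(s.residues) for s in genome}
    clean, flagged_alns = flag_frameshifts(kept, cands, contig_lengths, params)
    models = build_models(clean, genome)
    check_transcript_support(models, transcripts, params)
    flagged_models = [
        ScgModel(
            id=f"fs{i + 1:04d}",
            alignment=aln,
            protein_masked=mask_stops(aln),
            genomic_seq="",
            frameshift_flag=True,
        )
        for i, aln in enumerate(flagged_alns)
    ]
    return ScgResult(
        models=models,
        stats=compute_scg_stats(models),
        stop_free=stop_free,
        frameshifted=flagged_models,
        regions=list(regions),
    )


# ---------------------------------------------------------------------------
# Ortholog length ratios and the eRF1 motif

@dataclass
class LengthRatioReport:
    rows: pd.DataFrame  # protein_id, own_len, best_hit, best_len, ratio
    mean_ratio: Optional[float]
    n_singletons: int


def length_ratio_report(
    proteins: TypingSequence[Sequence], groups: Dict[str, str]
) -> LengthRatioReport:
    """Per protein, the ratio of its length to its best-scoring orthogroup
    member's length (ties broken towards the longer member, then id)."""
    by_group: Dict[str, List[Sequence]] = {}
    prot_by_id = {p.id: p for p in proteins}
    for pid, gid in groups.items():
        if pid in prot_by_id:
            by_group.setdefault(gid, []).append(prot_by_id[pid])
    rows = []
    singles = 0
    for gid in sorted(by_group):
        members = by_group[gid]
        if len(members) < 2:
            singles += 1
            continue
        for prot in members:
            best = None
            best_key = None
            for other in members:
                if other.id == prot.id:
                    continue
                score = align_protein_pair(prot, other)
                key = (score, len(other.residues), [other.id])
                if best is None or (key[0], key[1]) > (best_key[0], best_key[1]) or (
                    (key[0], key[1]) == (best_key[0], best_key[1]) and other.id < best.id
                ):
                    best, best_key = other, key
            rows.append(
                {
                    "protein_id": prot.id,
                    "own_len": len(prot.residues),
                    "best_hit": best.id,
                    "best_len": len(best.residues),
                    "ratio": len(prot.residues) / len(best.residues),
                }
            )
    df = pd.DataFrame(rows, columns=["protein_id", "own_len", "best_hit", "best_len", "ratio"])
    mean = float(df["ratio"].mean()) if len(df) else None
    return LengthRatioReport(rows=df, mean_ratio=mean, n_singletons=singles)


_ERF1_RE = re.compile(r"[A-Z]IKS")


def scan_erf1_motif(proteins: TypingSequence[Sequence]) -> Dict[str, str]:
    """Report the tetrapeptide at the eRF1 stop-recognition site.

    Searches the N-terminal half for the NIKS motif or a variant of it
    (x-IKS); canonical N/R first letters are preferred, and "absent" is
    reported when nothing matches.
    """
    out: Dict[str, str] = {}
    for prot in proteins:
        half = len(prot.residues) // 2
        matches = [
            m.group(0)
            for m in _ERF1_RE.finditer(prot.residues)
            if m.start() <= half
        ]
        preferred = [m for m in matches if m[0] in "NR"]
        if preferred:
            out[prot.id] = preferred[0]
        elif matches:
            out[prot.id] = matches[0]
        else:
            out[prot.id] = "absent"
    return out


# ---------------------------------------------------------------------------
# Truth comparison helper

def evaluate_recovery(
    models: List[ScgModel], truth: pd.DataFrame, min_reciprocal: float = 0.9
) -> Tuple[float, float]:
    """(precision, recall) of model intervals against planted loci, matched
    by same-strand reciprocal overlap >= ``min_reciprocal``."""
    truth_ivs = [
        Interval(r.contig, int(r.start), int(r.end), r.strand)
        for r in truth.itertuples()
    ]
    matched_truth = set()
    matched_models = 0
    for model in models:
        iv = model.interval
        for ti, tv in enumerate(truth_ivs):
            if tv.strand != model.strand:
                continue
            ov = iv.overlap_len(tv)
            if ov >= min_reciprocal * iv.length and ov >= min_reciprocal * tv.length:
                matched_models += 1
                matched_truth.add(ti)
                break
    precision = matched_models / len(models) if models else 1.0
    recall = len(matched_truth) / len(truth_ivs) if truth_ivs else 1.0
    return precision, recall
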