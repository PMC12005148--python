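"""Six-frame seed search and frameshift-free, stop-tolerant local alignment.

The codon aligner runs Smith-Waterman between a protein query and the codons
of a genomic region in a fixed frame.  Stop codons of the active genetic code
enter the DP as ``X`` (scored through the substitution matrix's X column) or,
optionally, at a fixed per-column penalty.  Frameshifts are deliberately not
modelled here - candidate loci whose evidence spans two frames are handled
downstream by the gene-discovery stage.

Scoring defaults are BLOSUM62 with gap open 11 / extend 1 for proteins and
match +1 / mismatch -2 with gap open 5 / extend 2 for nucleotides; a gap of
length L costs ``open + extend * L``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence as TypingSequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from ._sw import sw_affine, traceback
from .core import GeneticCode, Interval, STANDARD_CODE, Sequence, reverse_complement

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_X_INDEX = _AA_INDEX["X"]
_STAR_INDEX = _AA_INDEX["*"]

NT_ALPHABET = "ACGTN"
_NT_INDEX = {c: i for i, c in enumerate(NT_ALPHABET)}


@lru_cache(maxsize=None)
def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as an int32 matrix over :data:`AA_ALPHABET`."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = int(mat[a, b])
    return out


@lru_cache(maxsize=None)
def nucleotide_matrix(match: int = 1, mismatch: int = -2) -> np.ndarray:
    out = np.full((5, 5), mismatch, np.int32)
    for i in range(4):  # N never matches, not even itself
        out[i, i] = match
    return out


def encode_protein(residues: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, _X_INDEX) for c in residues], np.uint8)


def encode_nucleotides(residues: str) -> np.ndarray:
    return np.array([_NT_INDEX.get(c, 4) for c in residues], np.uint8)


@dataclass
class ScoringScheme:
    """Protein-vs-codon scoring parameters.

    ``stop_policy`` selects how a stop codon in the target is scored:
    ``"matrix"`` renders it as X and uses the matrix's X column; ``"penalty"``
    scores any column pairing it at a flat ``stop_penalty``.
    """

    gap_open: int = 11
    gap_extend: int = 1
    stop_policy: str = "matrix"
    stop_penalty: int = 0

    def matrix(self) -> np.ndarray:
        base = blosum62_matrix()
        if self.stop_policy == "matrix":
            return base
        if self.stop_policy != "penalty":
            raise ValueError(f"unknown stop_policy {self.stop_policy!r}")
        out = base.copy()
        out[_STAR_INDEX, :] = self.stop_penalty
        out[:, _STAR_INDEX] = self.stop_penalty
        return out

    @property
    def stop_index(self) -> int:
        return _X_INDEX if self.stop_policy == "matrix" else _STAR_INDEX


@dataclass(frozen=True)
class SeedHit:
    """A merged diagonal of exact k-mer matches between a protein query and
    one frame-translation of the target."""

    query_id: str
    target: Interval
    frame: int
    strand: str
    diagonal: int
    score: int  # number of query positions covered by exact k-mer matches


@dataclass
class CodonAlignment:
    """A frameshift-free local alignment of a protein to a codon-framed
    genomic window, with per-codon states and the in-frame stop inventory."""

    query_id: str
    target: Interval
    strand: str
    frame: int
    score: int
    aligned_pairs: List[Tuple[int, int, str]]  # (query_pos, codon_index, state)
    codons: List[str]  # gene-sense codons of the aligned target window
    identity: float
    query_coverage: float
    stops: List[Tuple[int, str]]  # (codon_index within alignment, codon)

    @property
    def n_codons(self) -> int:
        return len(self.codons)


def _frame_codons(text: str, frame: int) -> List[str]:
    usable = (len(text) - frame) // 3
    return [text[frame + 3 * i : frame + 3 * i + 3] for i in range(usable)]


def _codon_scoring_letters(codons: List[str], code: GeneticCode, scheme: ScoringScheme) -> np.ndarray:
    idx = np.empty(len(codons), np.uint8)
    for i, codon in enumerate(codons):
        if "N" in codon:
            idx[i] = _X_INDEX
        elif codon in code.stop_codons:
            idx[i] = scheme.stop_index
        else:
            idx[i] = _AA_INDEX.get(code.codon_to_aa[codon], _X_INDEX)
    return idx


def _codon_aa(codon: str, code: GeneticCode) -> str:
    if "N" in codon:
        return "X"
    if codon in code.stop_codons:
        return "X"
    return code.codon_to_aa[codon]


def align_codon_frame(
    query: Sequence,
    region: Sequence,
    strand: str,
    frame: int,
    scheme: Optional[ScoringScheme] = None,
    code: GeneticCode = STANDARD_CODE,
    region_start: int = 0,
    contig_id: Optional[str] = None,
) -> Optional[CodonAlignment]:
    """Local alignment of ``query`` against the codons of one frame of
    ``region``; returns None when the best local score is zero."""
    if not query.residues:
        raise ValueError("empty query")
    if len(region.residues) < 3:
        raise ValueError("region shorter than one codon")
    scheme = scheme or ScoringScheme()
    text = region.residues if strand == "+" else reverse_complement(region.residues)
    codons = _frame_codons(text, frame)
    if not codons:
        return None
    q = encode_protein(query.residues)
    t = _codon_scoring_letters(codons, code, scheme)
    score, bi, bj, ptrH, ptrE, ptrF = sw_affine(
        q, t, scheme.matrix(), scheme.gap_open, scheme.gap_extend
    )
    if score <= 0:
        return None
    cols, q0, t0 = traceback(ptrH, ptrE, ptrF, bi, bj)
    t_lo, t_hi = t0, bj  # codon index range [t_lo, t_hi)
    aln_codons = codons[t_lo:t_hi]

    aligned_pairs: List[Tuple[int, int, str]] = []
    stops: List[Tuple[int, str]] = []
    matches = 0
    aligned_cols = 0
    q_consumed = 0
    for state, qi_, tj_ in cols:
        if state == "diag":
            codon = codons[tj_]
            ci = tj_ - t_lo
            if codon in code.stop_codons:
                st = "stop"
            elif query.residues[qi_] == _codon_aa(codon, code):
                st = "match"
                matches += 1
            else:
                st = "sub"
            aligned_pairs.append((qi_, ci, st))
            aligned_cols += 1
            q_consumed += 1
        elif state == "qgap":
            aligned_pairs.append((-1, tj_ - t_lo, "qgap"))
        else:
            aligned_pairs.append((qi_, -1, "tgap"))
            q_consumed += 1
    for ci, codon in enumerate(aln_codons):
        if codon in code.stop_codons:
            stops.append((ci, codon))

    n = len(text)
    if strand == "+":
        g_start = region_start + frame + 3 * t_lo
        g_end = region_start + frame + 3 * t_hi
    else:
        g_start = region_start + n - (frame + 3 * t_hi)
        g_end = region_start + n - (frame + 3 * t_lo)
    interval = Interval(contig_id or region.id, g_start, g_end, strand)
    identity = matches / aligned_cols if aligned_cols else 0.0
    return CodonAlignment(
        query_id=query.id,
        target=interval,
        strand=strand,
        frame=frame,
        score=int(score),
        aligned_pairs=aligned_pairs,
        codons=aln_codons,
        identity=identity,
        query_coverage=q_consumed / len(query.residues),
        stops=stops,
    )


def align_codon_dp(
    query: Sequence,
    region: Sequence,
    strand: str = "+",
    scheme: Optional[ScoringScheme] = None,
    code: GeneticCode = STANDARD_CODE,
    region_start: int = 0,
    contig_id: Optional[str] = None,
) -> Optional[CodonAlignment]:
    """Best codon-framed local alignment over the three frames of ``strand``.

    Frame ties resolve to the lowest frame index.
    """
    best: Optional[CodonAlignment] = None
    for frame in (0, 1, 2):
        if len(region.residues) - frame < 3:
            continue
        aln = align_codon_frame(
            query, region, strand, frame, scheme, code, region_start, contig_id
        )
        if aln is not None and (best is None or aln.score > best.score):
            best = aln
    return best


# ---------------------------------------------------------------------------
# Seeding

class QueryKmerIndex:
    """Exact amino-acid k-mer index over a set of protein queries."""

    def __init__(self, queries: TypingSequence[Sequence], k: int = 4):
        if k < 3:
            raise ValueError("k must be >= 3")
        self.k = k
        self.queries = list(queries)
        self.index: Dict[str, List[Tuple[int, int]]] = {}
        for qi, query in enumerate(self.queries):
            res = query.residues
            for pos in range(len(res) - k + 1):
                self.index.setdefault(res[pos : pos + k], []).append((qi, pos))

    def scan(self, aa_text: str) -> Dict[Tuple[int, int], List[int]]:
        """Map (query_index, diagonal) -> sorted query positions with exact
        k-mer matches against ``aa_text``."""
        k = self.k
        hits: Dict[Tuple[int, int], List[int]] = {}
        get = self.index.get
        for tpos in range(len(aa_text) - k + 1):
            entry = get(aa_text[tpos : tpos + k])
            if entry is None:
                continue
            for qi, qpos in entry:
                hits.setdefault((qi, tpos - qpos), []).append(qpos)
        return hits


def diagonal_coverage(qpositions: List[int], k: int) -> int:
    """Number of distinct query positions covered by k-mers starting at the
    given (sorted) positions."""
    covered = 0
    prev_end = -1
    for p in qpositions:
        end = p + k
        if p > prev_end:
            covered += end - p
        else:
            covered += end - prev_end
        prev_end = max(prev_end, end)
    return covered


def translate_frames(text: str, code: GeneticCode = STANDARD_CODE) -> List[str]:
    """Readthrough translation of the three forward frames of ``text``."""
    out = []
    for frame in range(3):
        aas = []
        for codon in _frame_codons(text, frame):
            if "N" in codon:
                aas.append("X")
            elif codon in code.stop_codons:
                aas.append(code.readthrough_map.get(codon, "X"))
            else:
                aas.append(code.codon_to_aa[codon])
        out.append("".join(aas))
    return out


def seed_search(
    query: Sequence,
    target: Sequence,
    k: int = 4,
    min_diag_score: int = 40,
    code: GeneticCode = STANDARD_CODE,
) -> List[SeedHit]:
    """Exact k-mer diagonals between ``query`` and all six readthrough frame
    translations of ``target``, merged per diagonal; diagonals whose covered
    query length falls below ``min_diag_score`` are dropped."""
    if len(target.residues) < 3 * k:
        raise ValueError(f"target shorter than 3k ({3 * k})")
    index = QueryKmerIndex([query], k)
    hits: List[SeedHit] = []
    n = len(target.residues)
    for strand in ("+", "-"):
        text = target.residues if strand == "+" else reverse_complement(target.residues)
        for frame, aa_text in enumerate(translate_frames(text, code)):
            for (qi, diag), qposs in sorted(index.scan(aa_text).items()):
                cov = diagonal_coverage(qposs, k)
                if cov < min_diag_score:
                    continue
                q_lo = qposs[0]
                q_hi = qposs[-1] + k
                t_lo_aa = q_lo + diag
                t_hi_aa = q_hi + diag
                if strand == "+":
                    g_start = frame + 3 * t_lo_aa
                    g_end = frame + 3 * t_hi_aa
                else:
                    g_start = n - (frame + 3 * t_hi_aa)
                    g_end = n - (frame + 3 * t_lo_aa)
                hits.append(
                    SeedHit(
                        query_id=query.id,
                        target=Interval(target.id, g_start, g_end, strand),
                        frame=frame,
                        strand=strand,
                        diagonal=diag,
                        score=cov,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# Nucleotide alignment

@dataclass
class NucleotideAlignment:
    score: int
    identity: float
    coverage_of_a: float
    a_range: Tuple[int, int]
    b_range: Tuple[int, int]
    matches: int = 0
    aligned_columns: int = 0


def nucleotide_align(
    a: Sequence,
    b: Sequence,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> NucleotideAlignment:
    if not a.residues or not b.residues:
        raise ValueError("empty input")
    q = encode_nucleotides(a.residues)
    t = encode_nucleotides(b.residues)
    score, bi, bj, ptrH, ptrE, ptrF = sw_affine(
        q, t, nucleotide_matrix(match, mismatch), gap_open, gap_extend
    )
    if score <= 0:
        return NucleotideAlignment(0, 0.0, 0.0, (0, 0), (0, 0), 0, 0)
    cols, q0, t0 = traceback(ptrH, ptrE, ptrF, bi, bj)
    matches = 0
    aligned_cols = 0
    a_consumed = 0
    for state, qi_, tj_ in cols:
        if state == "diag":
            aligned_cols += 1
            a_consumed += 1
            if a.residues[qi_] == b.residues[tj_] and a.residues[qi_] != "N":
                matches += 1
        elif state == "tgap":
            a_consumed += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    return NucleotideAlignment(
        score=int(score),
        identity=identity,
        coverage_of_a=a_consumed / len(a.residues),
        a_range=(q0, bi),
        b_range=(t0, bj),
        matches=matches,
        aligned_columns=aligned_cols,
    )


def nucleotide_identity(a: Sequence, b: Sequence, **kwargs) -> Tuple[float, float]:
    """Best local alignment identity of ``a`` vs ``b`` and the fraction of
    ``a`` consumed by it (match +1 / mismatch -2 / gap open 5 / extend 2)."""
    aln = nucleotide_align(a, b, **kwargs)
    return aln.identity, aln.coverage_of_a


def align_protein_pair(a: Sequence, b: Sequence, scheme: Optional[ScoringScheme] = None) -> int:
    """Local protein-protein alignment score (BLOSUM62 by default)."""
    if not a.residues or not b.residues:
        raise ValueError("empty input")
    scheme = scheme or ScoringScheme()
    score, *_ = sw_affine(
        encode_protein(a.residues),
        encode_protein(b.residues),
        scheme.matrix(),
        scheme.gap_open,
        scheme.gap_extend,
    )
    return int(score)
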