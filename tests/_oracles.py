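"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately written with a different algorithm than the
implementation it checks: cubic DP instead of Gotoh, per-base bitmaps
instead of interval arithmetic, full diagonal scans instead of seeded
extension, and direct bracket counting instead of loop location.
"""

from Bio.Align import substitution_matrices

from ambistop.core import reverse_complement

_BLOSUM = substitution_matrices.load("BLOSUM62")


def brute_local_affine(q, t, sub, gap_open, gap_extend):
    """Optimal local alignment score by cubic DP (gap of length L costs
    gap_open + gap_extend * L)."""
    n, m = len(q), len(t)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            v = H[i - 1][j - 1] + sub(q[i - 1], t[j - 1])
            for k in range(1, j + 1):
                cand = H[i][j - k] - gap_open - gap_extend * k
                if cand > v:
                    v = cand
            for k in range(1, i + 1):
                cand = H[i - k][j] - gap_open - gap_extend * k
                if cand > v:
                    v = cand
            if v < 0:
                v = 0
            H[i][j] = v
            if v > best:
                best = v
    return best


def blosum_sub(a, b):
    return int(_BLOSUM[a, b])


def nt_sub(a, b, match=1, mismatch=-2):
    if a == b and a != "N":
        return match
    return mismatch


def brute_codon_score(query, region, strand, code, gap_open=11, gap_extend=1):
    """Best local protein-vs-codon score over the three frames of one strand,
    with the code's stop codons entered as X."""
    text = region if strand == "+" else reverse_complement(region)
    best = 0
    for frame in range(3):
        letters = []
        for i in range(frame, len(text) - 2, 3):
            codon = text[i : i + 3]
            if "N" in codon or codon in code.stop_codons:
                letters.append("X")
            else:
                letters.append(code.codon_to_aa[codon])
        if not letters:
            continue
        score = brute_local_affine(query, "".join(letters), blosum_sub, gap_open, gap_extend)
        best = max(best, score)
    return best


def bitmap_union_cov(length, spans):
    """Per-base bitmap union fraction."""
    hit = [False] * length
    for s, e in spans:
        for i in range(s, e):
            hit[i] = True
    return sum(hit) / length if length else 0.0


def bitmap_complement(length, spans, min_len):
    """Per-base complement segments of >= min_len."""
    covered = [False] * length
    for s, e in spans:
        for i in range(s, e):
            covered[i] = True
    out = []
    start = None
    for i in range(length + 1):
        free = i < length and not covered[i]
        if free and start is None:
            start = i
        elif not free and start is not None:
            if i - start >= min_len:
                out.append((start, i))
            start = None
    return out


def brute_inverted_repeats(s, min_len):
    """All maximal inverted-repeat pairs by full diagonal scan of s against
    revcomp(s); returns {(a_start, a_end, b_start, b_end)} with a < b."""
    n = len(s)
    t = reverse_complement(s)
    out = set()

    def emit(start, d, run):
        if run < min_len:
            return
        a = start
        b = n - (start - d) - run
        if a < b:
            out.add((a, a + run, b, b + run))

    for d in range(-(n - 1), n):
        i = max(0, d)
        p = i - d
        start = None
        while i < n and p < n:
            if s[i] == t[p]:
                if start is None:
                    start = i
            else:
                if start is not None:
                    emit(start, d, i - start)
                    start = None
            i += 1
            p += 1
        if start is not None:
            emit(start, d, i - start)
    return out


def brute_stem_count(structure, anticodon_pos):
    """Count consecutive matched pairs enclosing the anticodon with no
    unpaired bases between the stem and the loop, by direct pair counting."""
    stack = []
    pairs = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs[stack.pop()] = i
    lo = anticodon_pos
    while lo > 0 and structure[lo - 1] == ".":
        lo -= 1
    hi = anticodon_pos + 3
    while hi < len(structure) and structure[hi] == ".":
        hi += 1
    count = 0
    for i, j in pairs.items():
        if i < lo and j >= hi:
            inner_ok = all(c == "(" for c in structure[i + 1 : lo])
            outer_ok = all(c == ")" for c in structure[hi : j])
            if inner_ok and outer_ok and j - (hi - lo) >= 0:
                count += 1
    return count


def max_weight_independent_set(intervals):
    """Exhaustive max-total-score set of pairwise non-overlapping intervals;
    ``intervals`` is a list of (start, end, score)."""
    best = 0
    n = len(intervals)
    for mask in range(1 << n):
        chosen = [intervals[i] for i in range(n) if mask >> i & 1]
        ok = all(
            a[1] <= b[0] or b[1] <= a[0]
            for x, a in enumerate(chosen)
            for b in chosen[x + 1 :]
        )
        if ok:
            best = max(best, sum(c[2] for c in chosen))
    return best
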