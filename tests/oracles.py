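"""Independent reference implementations used only to check the package.

These deliberately re-derive results by the most transparent route available
(plain-Python dynamic programming over every cell path, exhaustive
enumeration) and share no code with the implementation under test.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_score(a, b, sub, gap_open, gap_extend, mode="local"):
    """Affine-gap alignment optimum by explicit three-state DP.

    Gap convention: a gap of length L costs gap_open + (L-1)*gap_extend.
    ``sub(x, y)`` returns the substitution score.
    """
    n, m = len(a), len(b)
    # M: a[i-1] aligned to b[j-1]; X: gap in b (a residue unmatched);
    # Y: gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    local = mode == "local"
    best = 0.0 if local else NEG
    M[0][0] = 0.0
    if not local:
        for i in range(1, n + 1):
            X[i][0] = gap_open + (i - 1) * gap_extend
        for j in range(1, m + 1):
            Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                if local:
                    prev = max(prev, 0.0)
                M[i][j] = prev + sub(a[i - 1], b[j - 1])
            if i > 0:
                X[i][j] = max(
                    X[i][j],
                    (M[i - 1][j] + gap_open) if M[i - 1][j] > NEG else NEG,
                    (X[i - 1][j] + gap_extend) if X[i - 1][j] > NEG else NEG,
                    (Y[i - 1][j] + gap_open) if Y[i - 1][j] > NEG else NEG,
                )
            if j > 0:
                Y[i][j] = max(
                    Y[i][j],
                    (M[i][j - 1] + gap_open) if M[i][j - 1] > NEG else NEG,
                    (X[i][j - 1] + gap_open) if X[i][j - 1] > NEG else NEG,
                    (Y[i][j - 1] + gap_extend) if Y[i][j - 1] > NEG else NEG,
                )
            if local:
                best = max(best, M[i][j])
    if local:
        return best
    return max(M[n][m], X[n][m], Y[n][m])


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def enumerate_motif_hits(seq, elements, both_strands=True):
    """Try every (offset, run-length combination, strand) explicitly.

    ``elements`` is a list of (allowed_base_set, min_repeat, max_repeat).
    Returns a set of (start, end, strand) with 0-based half-open plus-strand
    coordinates.
    """
    seq = seq.upper()

    def expansions(elems):
        if not elems:
            yield []
            return
        bases, lo, hi = elems[0]
        for rest in expansions(elems[1:]):
            for k in range(lo, hi + 1):
                yield [bases] * k + rest

    hits = set()
    n = len(seq)
    for cols in expansions(list(elements)):
        L = len(cols)
        for s in range(n - L + 1):
            if all(seq[s + i] in cols[i] for i in range(L)):
                hits.add((s, s + L, "+"))
            if both_strands and all(
                _COMP.get(seq[s + i], "?") in cols[L - 1 - i] for i in range(L)
            ):
                hits.add((s, s + L, "-"))
    return hits
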