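"""Pairwise protein comparison: local alignment hits with e-values, global
Needleman–Wunsch identity/gap statistics, and all-vs-all hit generation.

Two conventions matter throughout:

* Affine gaps score ``gap_open`` for the first residue of a gap and
  ``gap_extend`` for each further residue (Bio.Align convention).
* Percent identity and percent gaps are both taken over the full alignment
  length (gap columns included), so identity% + mismatch% + gap% = 100.

The e-value attached to a local score is the Karlin–Altschul closed form
``E = K·m·n·exp(−λ·S)``; it stands in for a database search engine's
statistics and is only meaningful when λ and K match the scoring system.
The shipped λ=0.267, K=0.041 are the published gapped-BLOSUM62 constants for
gap penalties 11/1 (see DEFAULT_SCAN_PARAMS); very weak gap penalties push
local alignment out of the logarithmic regime and no λ exists for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_db import GenomeDB


@dataclass
class AlignmentParams:
    """Scoring and statistics parameters for local hit generation.

    Defaults mirror the historical blastp run this pipeline reimplements:
    BLOSUM62, open gap −1, extend gap −1, word size 3, extension threshold 11.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = -1
    gap_extend: int = -1
    seed_word_size: int = 3
    seed_threshold: int = 11
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    effective_db_letters: int | None = None
    evalue_ceiling: float = 10.0

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap scores are penalties and must be <= 0")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")

    def matrix(self):
        return substitution_matrices.load(self.substitution_matrix)


#: statistically coherent parameter set used by the pipeline's default
#: configuration: λ/K above are published for BLOSUM62 with gap 11/1.
DEFAULT_SCAN_PARAMS = AlignmentParams(gap_open=-11, gap_extend=-1)


@dataclass
class PairwiseHit:
    query_id: str
    subject_id: str
    bit_or_raw_score: float
    evalue: float
    identity_pct: float
    aln_length: int
    gap_pct: float

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise ValueError("self-hits are excluded")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")


@dataclass
class GlobalAlignmentStats:
    identity_pct: float
    gap_pct: float
    aln_length: int


def _aligner(params: AlignmentParams, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = params.matrix()
    al.open_gap_score = float(params.gap_open)
    al.extend_gap_score = float(params.gap_extend)
    return al


def _simple_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float,
                    mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = float(match)
    al.mismatch_score = float(mismatch)
    al.open_gap_score = float(gap_open)
    al.extend_gap_score = float(gap_extend)
    return al


def _stats_from_alignment(aln) -> tuple[float, float, int]:
    c = aln.counts()  # gaps, identities, mismatches
    length = c.gaps + c.identities + c.mismatches
    return (100.0 * c.identities / length, 100.0 * c.gaps / length, length)


def align_local(a: str, b: str, params: AlignmentParams) -> tuple[float, float, int]:
    """Optimal affine-gap Smith–Waterman; returns (score, identity_pct, aln_length).

    Identity is taken over the best local alignment's columns (gaps included).
    """
    if not a or not b:
        raise ValueError("align_local requires non-empty sequences")
    al = _aligner(params, "local")
    alns = al.align(a, b)
    if alns.score <= 0:
        # no positive-scoring local alignment exists (empty alignment optimal)
        return 0.0, 0.0, 0
    best = alns[0]
    ident, _gap, length = _stats_from_alignment(best)
    return float(best.score), ident, length


def local_score(a: str, b: str, params: AlignmentParams) -> float:
    """Score-only fast path (no traceback)."""
    if not a or not b:
        raise ValueError("align_local requires non-empty sequences")
    return float(_aligner(params, "local").score(a, b))


def evalue_from_score(score: float, m: int, n: int, params: AlignmentParams) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λ·S)."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    if params.ka_lambda <= 0 or params.ka_k <= 0:
        raise ValueError("lambda and K must be positive")
    # evaluate in log space; floor far below any usable threshold guards
    # against float underflow for near-identical long sequences
    log10_e = math.log10(params.ka_k * m * n) - params.ka_lambda * score / math.log(10.0)
    return 10.0 ** max(log10_e, -300.0)


def align_global(
    a: str,
    b: str,
    *,
    matrix: str | None = "BLOSUM62",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> GlobalAlignmentStats:
    """Needleman–Wunsch global alignment statistics.

    With ``matrix=None`` a simple match/mismatch scheme is used instead of a
    substitution matrix (handy for toy examples and tests).
    """
    if not a or not b:
        raise ValueError("align_global requires non-empty sequences")
    if matrix is not None:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = substitution_matrices.load(matrix)
        al.open_gap_score = float(gap_open)
        al.extend_gap_score = float(gap_extend)
    else:
        al = _simple_aligner(match, mismatch, gap_open, gap_extend, "global")
    best = al.align(a, b)[0]
    ident, gap, length = _stats_from_alignment(best)
    return GlobalAlignmentStats(identity_pct=ident, gap_pct=gap, aln_length=length)


def all_vs_all(db: GenomeDB, params: AlignmentParams) -> list[PairwiseHit]:
    """All ordered-pair local hits whose e-value passes the report ceiling.

    Each unordered pair is aligned once (local DP is symmetric for a symmetric
    matrix); the two directed hits differ only in their e-values, which use
    m = query length and n = effective database letters.
    """
    ids = sorted(db.orf_index)
    if not ids:
        raise ValueError("all_vs_all requires a non-empty database")
    seqs = {i: db[i].protein_seq for i in ids}
    n_eff = params.effective_db_letters or sum(len(s) for s in seqs.values())
    scorer = _aligner(params, "local")
    hits: list[PairwiseHit] = []
    for qa, qb in combinations(ids, 2):
        sa, sb = seqs[qa], seqs[qb]
        score = float(scorer.score(sa, sb))
        e_ab = evalue_from_score(score, len(sa), n_eff, params)
        e_ba = evalue_from_score(score, len(sb), n_eff, params)
        if min(e_ab, e_ba) > params.evalue_ceiling:
            continue
        ident, gap, length = _stats_from_alignment(scorer.align(sa, sb)[0])
        hits.append(PairwiseHit(qa, qb, score, e_ab, ident, length, gap))
        hits.append(PairwiseHit(qb, qa, score, e_ba, ident, length, gap))
    return hits


def group_identity_summary(
    group_a: Iterable[str],
    group_b: Iterable[str],
    db: GenomeDB,
    **scores,
) -> tuple[float, float, int]:
    """Mean global identity% and gap% over all cross pairs of two ORF groups.

    For identical groups the average runs over unordered distinct pairs;
    identical ids are never compared with themselves.
    """
    ga, gb = sorted(set(group_a)), sorted(set(group_b))
    if not ga or not gb:
        raise ValueError("groups must be non-empty")
    if ga == gb:
        pairs = list(combinations(ga, 2))
    else:
        pairs = [(x, y) for x in ga for y in gb if x != y]
    if not pairs:
        raise ValueError("no distinct pairs to compare")
    idents, gaps = [], []
    for x, y in pairs:
        st = align_global(db[x].protein_seq, db[y].protein_seq, **scores)
        idents.append(st.identity_pct)
        gaps.append(st.gap_pct)
    return (sum(idents) / len(pairs), sum(gaps) / len(pairs), len(pairs))


# ---------------------------------------------------------------------------
# blast outfmt-6 compatible hit table I/O

_OUTFMT6 = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def write_hits(hits: Sequence[PairwiseHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_OUTFMT6) + "\n")
        for h in hits:
            n_ident = round(h.identity_pct * h.aln_length / 100.0)
            n_gap = round(h.gap_pct * h.aln_length / 100.0)
            mismatch = h.aln_length - n_ident - n_gap
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct:.3f}\t{h.aln_length}\t"
                f"{mismatch}\t0\t0\t0\t0\t0\t{h.evalue:.6g}\t{h.bit_or_raw_score:.1f}\n"
            )


def read_hits(path: str | Path) -> list[PairwiseHit]:
    """Read a blast outfmt-6 style TSV (header optional, extra columns ignored)."""
    hits: list[PairwiseHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] == "qseqid":
                continue
            if f[0] == f[1]:  # self-hits dropped on read
                continue
            pident, length = float(f[2]), int(f[3])
            mismatch = int(f[4])
            n_ident = round(pident * length / 100.0)
            gap_pct = 100.0 * max(0, length - n_ident - mismatch) / length if length else 0.0
            hits.append(
                PairwiseHit(
                    query_id=f[0], subject_id=f[1], bit_or_raw_score=float(f[11]),
                    evalue=float(f[10]), identity_pct=pident, aln_length=length,
                    gap_pct=gap_pct,
                )
            )
    return hits
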