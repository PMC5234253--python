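"""Degenerate promoter-motif scanning.

Motif grammar (as printed in the transcription-factor literature):

* plain IUPAC letters — ``A C G T`` plus ambiguity codes ``H`` (not G),
  ``D`` (not C), ``N`` (any);
* parenthesised alternatives — ``(G/C)`` matches G or C;
* variable-length runs — ``(T)4-6`` matches 4 to 6 consecutive T
  (underscores around the counts, as in ``(T)_4-6_``, are tolerated).

Built-in patterns: the Haa1 acetic-acid-responsive element
``(G/C)(A/C)GG(G/C)G`` and the two published Cup2/Ace1 sites
``TC(T)4-6GCTG`` and ``HTHNNGCTGD``.

Scanning reports every match at every offset on both strands; a variable-run
motif reports each feasible run length as a separate hit.  Matching is
implemented with look-ahead regular expressions so overlapping hits are all
found.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

HAA1_MOTIF = "(G/C)(A/C)GG(G/C)G"
CUP2_MOTIF_TRUN = "TC(T)4-6GCTG"
CUP2_MOTIF_HTH = "HTHNNGCTGD"
PAPER_MOTIFS = {
    "Haa1_ACRE": HAA1_MOTIF,
    "Cup2_Trun": CUP2_MOTIF_TRUN,
    "Cup2_HTH": CUP2_MOTIF_HTH,
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DegenerateMotif:
    name: str
    elements: list[tuple[frozenset, int, int]]  # (allowed bases, min_repeat, max_repeat)

    @property
    def min_len(self) -> int:
        return sum(lo for _, lo, _ in self.elements)

    @property
    def max_len(self) -> int:
        return sum(hi for _, _, hi in self.elements)


@dataclass
class MotifHit:
    motif_name: str
    start: int  # 0-based on the + strand
    end: int  # exclusive
    strand: str  # '+' or '-'
    matched_text: str  # the matched bases read 5'->3' on the hit's strand


class MotifParseError(ValueError):
    pass


def parse_motif(spec: str, name: str | None = None) -> DegenerateMotif:
    """Parse a degenerate motif string into its element list."""
    if not spec:
        raise MotifParseError("empty motif spec")
    elements: list[tuple[frozenset, int, int]] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "(":
            close = spec.find(")", i)
            if close < 0:
                raise MotifParseError(f"unclosed '(' at position {i}")
            inner = spec[i + 1 : close]
            parts = inner.split("/") if "/" in inner else [inner]
            bases: set[str] = set()
            for p in parts:
                if len(p) != 1 or p.upper() not in IUPAC:
                    raise MotifParseError(f"bad alternative {p!r} at position {i}")
                bases |= IUPAC[p.upper()]
            i = close + 1
            # optional repeat count: 4 or 4-6, with tolerated underscores
            m = re.match(r"_?(\d+)(?:-(\d+))?_?", spec[i:])
            if m and m.group(1):
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                if not 1 <= lo <= hi:
                    raise MotifParseError(f"bad repeat range at position {i}")
                i += m.end()
            else:
                lo = hi = 1
            elements.append((frozenset(bases), lo, hi))
        elif ch.upper() in IUPAC:
            elements.append((IUPAC[ch.upper()], 1, 1))
            i += 1
        else:
            raise MotifParseError(f"unexpected character {ch!r} at position {i}")
    return DegenerateMotif(name=name or spec, elements=elements)


def _expansions(motif: DegenerateMotif) -> list[list[frozenset]]:
    """All fixed-length expansions of variable-run elements."""
    out: list[list[frozenset]] = [[]]
    for bases, lo, hi in motif.elements:
        nxt = []
        for prefix in out:
            for n in range(lo, hi + 1):
                nxt.append(prefix + [bases] * n)
        out = nxt
    return out


def _regex_for(cols: list[frozenset]) -> re.Pattern:
    # look-ahead capture so overlapping matches are all reported
    body = "".join("[" + "".join(sorted(c)) + "]" for c in cols)
    return re.compile(f"(?=({body}))")


def scan_sequence(
    seq: str, motif: DegenerateMotif, both_strands: bool = True
) -> list[MotifHit]:
    """All matches of *motif* in *seq*; hits sorted by (start, end, strand)."""
    seq = seq.upper()
    hits: list[MotifHit] = []
    n = len(seq)
    for cols in _expansions(motif):
        pat = _regex_for(cols)
        for m in pat.finditer(seq):
            s = m.start()
            hits.append(MotifHit(motif.name, s, s + len(cols), "+", m.group(1)))
        if both_strands:
            rc = reverse_complement(seq)
            for m in pat.finditer(rc):
                s_rc, e_rc = m.start(), m.start() + len(cols)
                hits.append(MotifHit(motif.name, n - e_rc, n - s_rc, "-", m.group(1)))
    # distinct expansions can produce the same concrete match; report each
    # location/strand once
    uniq = {(h.start, h.end, h.strand): h for h in hits}
    return sorted(uniq.values(), key=lambda h: (h.start, h.end, h.strand))


def classify_promoter(
    seq: str, motifs: Iterable[DegenerateMotif], both_strands: bool = True
) -> dict[str, bool]:
    """Presence/absence call per motif (>= 1 hit on either strand)."""
    return {m.name: bool(scan_sequence(seq, m, both_strands)) for m in motifs}


def paper_motifs() -> list[DegenerateMotif]:
    return [parse_motif(spec, name) for name, spec in PAPER_MOTIFS.items()]


def write_hits_bed(hits_by_seq: Mapping[str, list[MotifHit]], path: str | Path) -> None:
    """BED-like TSV: seq_id, start, end, motif_name, strand (0-based half-open)."""
    with open(path, "w") as fh:
        for seq_id in sorted(hits_by_seq):
            for h in hits_by_seq[seq_id]:
                fh.write(f"{seq_id}\t{h.start}\t{h.end}\t{h.motif_name}\t{h.strand}\n")
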