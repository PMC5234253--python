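"""Multi-genome ORF database with canonical naming and ordinal gene order.

Each strain contributes a protein FASTA plus a gene-order table (headered TSV
or GFF3).  ORFs get canonical lower-case ids ``<code>_<strain>_<localid>`` and
0-based ordinal ranks along their scaffold; synteny downstream operates on
these ranks, never on base-pair coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

log = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: scaffold name used for ORFs present in the FASTA but absent from the
#: gene-order table (unanchored contigs etc.)
UNPLACED_SCAFFOLD = "unplaced"


@dataclass
class OrfRecord:
    orf_id: str
    species_code: str
    strain_index: int
    scaffold_id: str
    ordinal: int
    strand: str  # '+', '-' or '?'
    protein_seq: str

    def __post_init__(self) -> None:
        if len(self.protein_seq) < 1:
            raise ValueError(f"empty protein sequence for {self.orf_id}")
        if self.strand not in ("+", "-", "?"):
            raise ValueError(f"bad strand {self.strand!r} for {self.orf_id}")

    @property
    def length(self) -> int:
        return len(self.protein_seq)


@dataclass
class GenomeRecord:
    species_code: str
    strain_index: int
    pre_post_wgd: str  # 'pre' or 'post'
    orfs: list[OrfRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pre_post_wgd not in ("pre", "post"):
            raise ValueError(f"pre_post_wgd must be 'pre' or 'post', got {self.pre_post_wgd!r}")


class GenomeDB:
    """Consolidated ORF database over many genomes.

    Provides id lookup and scaffold-ordered access used by the
    gene-neighbourhood (synteny) stage.
    """

    def __init__(self, genomes: list[GenomeRecord]):
        self.genomes = list(genomes)
        self.orf_index: dict[str, OrfRecord] = {}
        self._scaffolds: dict[tuple[str, int, str], list[str]] = {}
        for g in self.genomes:
            for orf in g.orfs:
                if orf.orf_id in self.orf_index:
                    raise ValueError(f"duplicate orf_id across genomes: {orf.orf_id}")
                self.orf_index[orf.orf_id] = orf
        for g in self.genomes:
            by_scaf: dict[str, list[OrfRecord]] = {}
            for orf in g.orfs:
                by_scaf.setdefault(orf.scaffold_id, []).append(orf)
            for scaf, orfs in by_scaf.items():
                orfs.sort(key=lambda o: o.ordinal)
                ordinals = [o.ordinal for o in orfs]
                if ordinals != list(range(len(orfs))):
                    raise ValueError(
                        f"ordinals on scaffold {scaf} of {g.species_code}_{g.strain_index} "
                        f"are not consecutive 0..n-1"
                    )
                self._scaffolds[(g.species_code, g.strain_index, scaf)] = [o.orf_id for o in orfs]

    @property
    def total_orf_count(self) -> int:
        return len(self.orf_index)

    def __contains__(self, orf_id: str) -> bool:
        return orf_id in self.orf_index

    def __getitem__(self, orf_id: str) -> OrfRecord:
        return self.orf_index[orf_id]

    def wgd_flag(self, orf_id: str) -> str:
        orf = self.orf_index[orf_id]
        for g in self.genomes:
            if g.species_code == orf.species_code and g.strain_index == orf.strain_index:
                return g.pre_post_wgd
        raise KeyError(orf_id)

    def scaffold_orfs(self, species_code: str, strain_index: int, scaffold_id: str) -> list[str]:
        return self._scaffolds[(species_code, strain_index, scaffold_id)]


def _clean_protein(seq: str, rec_id: str) -> str:
    seq = seq.upper().rstrip("*")
    if not set(seq) <= STANDARD_AA | {"X"}:
        bad = sorted(set(seq) - STANDARD_AA - {"X"})
        log.warning("non-standard residues %s in %s mapped to X", "".join(bad), rec_id)
        seq = re.sub(f"[^{''.join(sorted(STANDARD_AA))}X]", "X", seq)
    return seq


def _read_order_tsv(path: Path) -> list[tuple[str, str, str]]:
    """Return [(raw_orf_id, scaffold_id, strand)] in file order."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for need in ("orf_id", "scaffold_id"):
            if need not in cols:
                raise ValueError(f"gene-order table {path} lacks column {need!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            strand = parts[cols["strand"]] if "strand" in cols and len(parts) > cols["strand"] else "?"
            if strand not in ("+", "-"):
                strand = "?"
            rows.append((parts[cols["orf_id"]], parts[cols["scaffold_id"]], strand))
    return rows


def _read_order_gff3(path: Path) -> list[tuple[str, str, str]]:
    """Genes ranked by start coordinate per seqid; ID attribute is the orf id."""
    genes: list[tuple[str, int, str, str]] = []  # (seqid, start, id, strand)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID")
            if gid is None:
                raise ValueError(f"GFF3 gene without ID attribute in {path}")
            strand = f[6] if f[6] in ("+", "-") else "?"
            genes.append((f[0], int(f[3]), gid, strand))
    genes.sort(key=lambda t: (t[0], t[1]))
    return [(gid, seqid, strand) for seqid, _, gid, strand in genes]


def canonical_orf_id(species_code: str, strain_index: int, local_id: str) -> str:
    return f"{species_code.lower()}_{strain_index}_{local_id.lower()}"


def load_genome(
    proteome_fasta: str | Path,
    gene_order_table: str | Path | None,
    species_code: str,
    strain_index: int,
    wgd_status: str,
) -> GenomeRecord:
    """Load one strain's proteome + gene order into a :class:`GenomeRecord`.

    ORFs present in the FASTA but missing from the order table go to a
    per-genome ``unplaced`` scaffold in input order.
    """
    if len(species_code) != 4 or not species_code.isalpha():
        raise ValueError(f"species_code must be exactly 4 letters, got {species_code!r}")
    seqs: dict[str, str] = {}
    fasta_order: list[str] = []
    for rec in SeqIO.parse(str(proteome_fasta), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {proteome_fasta}")
        seqs[rec.id] = _clean_protein(str(rec.seq), rec.id)
        fasta_order.append(rec.id)

    if gene_order_table is None:
        rows: list[tuple[str, str, str]] = []
    else:
        p = Path(gene_order_table)
        with open(p) as fh:
            first = fh.readline()
        if first.startswith("##gff") or p.suffix.lower() in (".gff", ".gff3"):
            rows = _read_order_gff3(p)
        else:
            rows = _read_order_tsv(p)

    placed: set[str] = set()
    per_scaffold: dict[str, list[tuple[str, str]]] = {}
    for raw_id, scaf, strand in rows:
        if raw_id not in seqs:
            raise ValueError(f"gene-order row {raw_id!r} has no FASTA record")
        if raw_id in placed:
            raise ValueError(f"ORF {raw_id!r} listed twice in gene-order table")
        placed.add(raw_id)
        per_scaffold.setdefault(scaf, []).append((raw_id, strand))
    unplaced = [rid for rid in fasta_order if rid not in placed]
    if unplaced:
        per_scaffold[UNPLACED_SCAFFOLD] = [(rid, "?") for rid in unplaced]

    orfs: list[OrfRecord] = []
    for scaf, entries in per_scaffold.items():
        for ordinal, (raw_id, strand) in enumerate(entries):
            orfs.append(
                OrfRecord(
                    orf_id=canonical_orf_id(species_code, strain_index, raw_id),
                    species_code=species_code.lower(),
                    strain_index=strain_index,
                    scaffold_id=scaf,
                    ordinal=ordinal,
                    strand=strand,
                    protein_seq=seqs[raw_id],
                )
            )
    return GenomeRecord(species_code.lower(), strain_index, wgd_status, orfs)


def compile_db(genomes: Iterable[GenomeRecord]) -> GenomeDB:
    genomes = list(genomes)
    keys = [(g.species_code, g.strain_index) for g in genomes]
    if len(set(keys)) != len(keys):
        raise ValueError("genomes must be pairwise distinct in (species_code, strain_index)")
    return GenomeDB(genomes)


def get_neighbour_ids(db: GenomeDB, orf_id: str, k: int) -> list[tuple[str, int]]:
    """Up to *k* genes on each side of *orf_id* on its scaffold.

    Returns ``[(neighbour_id, signed_offset)]`` with offsets strictly
    increasing in −k..−1 ∪ +1..+k, truncated at scaffold ends; never crosses
    scaffolds.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if orf_id not in db:
        raise KeyError(f"unknown orf_id {orf_id!r}")
    orf = db[orf_id]
    order = db.scaffold_orfs(orf.species_code, orf.strain_index, orf.scaffold_id)
    i = orf.ordinal
    out = []
    for j in range(max(0, i - k), i):
        out.append((order[j], j - i))
    for j in range(i + 1, min(len(order), i + k + 1)):
        out.append((order[j], j - i))
    return out


# ---------------------------------------------------------------------------
# I/O round-trip helpers


def write_genome(genome: GenomeRecord, fasta_path: str | Path, order_path: str | Path) -> None:
    """Write a genome back to FASTA + gene-order TSV (local ids, reload-safe)."""
    prefix = f"{genome.species_code}_{genome.strain_index}_"
    by_scaf: dict[str, list[OrfRecord]] = {}
    for orf in genome.orfs:
        by_scaf.setdefault(orf.scaffold_id, []).append(orf)
    with open(fasta_path, "w") as fa, open(order_path, "w") as tab:
        tab.write("orf_id\tscaffold_id\trank_hint\tstrand\n")
        for scaf in by_scaf:
            orfs = sorted(by_scaf[scaf], key=lambda o: o.ordinal)
            for orf in orfs:
                local = orf.orf_id.removeprefix(prefix)
                fa.write(f">{local}\n{orf.protein_seq}\n")
                if scaf != UNPLACED_SCAFFOLD:
                    tab.write(f"{local}\t{scaf}\t{orf.ordinal}\t{orf.strand}\n")


def write_manifest(db: GenomeDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("orf_id\tspecies_code\tstrain\tscaffold\tordinal\tstrand\tlength\n")
        for orf_id in sorted(db.orf_index):
            o = db[orf_id]
            fh.write(
                f"{o.orf_id}\t{o.species_code}\t{o.strain_index}\t{o.scaffold_id}\t"
                f"{o.ordinal}\t{o.strand}\t{o.length}\n"
            )
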