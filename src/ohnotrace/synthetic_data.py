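"""WGD-aware genome-evolution simulator with ground truth.

Generates per-species proteomes + gene orders along a species tree containing
a whole-genome duplication (WGD) on one branch, emulating the evolutionary
scenario of a duplicated transcription-factor family in budding yeasts:

* a query family, single-copy before the WGD and (mostly) two-copy after it,
  carrying a conserved N-terminal DNA-binding domain that never mutates;
* progressive length reduction (truncation) of one post-WGD sub-lineage,
  restricted to the region downstream of the conserved domain;
* a "distant relative" family sharing a diverged copy of the conserved
  domain, so that relaxing the similarity threshold eventually merges it
  with the query family (the copper-fist scenario);
* background gene families of varying effective sizes, used as synteny
  anchors, placed on a conserved ancestral gene order;
* WGD as full gene-order doubling onto paired scaffolds followed by
  Bernoulli retention per gene copy (at least one copy always kept), which
  preserves neighbour structure so synteny is recoverable;
* optional gene-order shuffling by random segment inversions.

Every run returns a :class:`~ohnotrace.genome_db.GenomeDB` plus
:class:`TruthTables` holding family membership, ohnolog pairs and the
sub-lineage of every query-family ORF — the oracle for end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import yaml

from .genome_db import GenomeDB, GenomeRecord, OrfRecord, compile_db, write_genome

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: 12 leaves, 6 of them descending from the WGD branch (stem of `postwgd`).
#: Within-clade leaf depth 0.12, stems 0.28: same-track neighbours stay
#: strongly similar while cross-track / cross-era pairs are far apart.
DEFAULT_SPECIES_TREE = (
    "((((wgda:0.04,wgdb:0.04):0.04,(wgdc:0.04,wgdd:0.04):0.04):0.04,"
    "(wgde:0.08,wgdf:0.08):0.04)postwgd:0.28,"
    "(((prea:0.04,preb:0.04):0.04,(prec:0.04,pred:0.04):0.04):0.04,"
    "(pree:0.08,pref:0.08):0.04)preclade:0.28);"
)

SUBLINEAGE_HAA1 = "HAA1-like"
SUBLINEAGE_CUP2 = "CUP2-like"
SUBLINEAGE_PRE = "PROTOPLOID"

QUERY_FAMILY = "fam_query"
DISTANT_FAMILY = "fam01"


@dataclass
class SimulationConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    wgd_branch: str = "postwgd"
    n_background_families: int = 30
    query_family: bool = True
    retention_prob: float = 0.9
    sub_rate: float = 2.0
    indel_rate: float = 0.001
    conserved_prefix_len: int = 124
    ancestral_query_len: int = 620
    truncation_target_range: tuple[int, int] | None = (221, 356)
    shuffle_rate: float = 0.0
    background_len_range: tuple[int, int] = (140, 240)
    distant_relative: bool = True
    distant_prefix_divergence: float = 0.67
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (self.retention_prob, self.distant_prefix_divergence):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.conserved_prefix_len >= self.ancestral_query_len:
            raise ValueError("conserved prefix must be shorter than the ancestral protein")
        if self.truncation_target_range is not None:
            lo, hi = self.truncation_target_range
            if not (self.conserved_prefix_len < lo <= hi < self.ancestral_query_len):
                raise ValueError("truncation target range must fit between prefix and full length")
        if self.n_background_families < 6:
            raise ValueError("need at least 6 background families for synteny anchors")


@dataclass
class TruthTables:
    family_membership: dict[str, str] = field(default_factory=dict)
    ohnolog_pairs: list[tuple[str, str]] = field(default_factory=list)
    sublineage: dict[str, str] = field(default_factory=dict)
    ancestral_order: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    # ^ per genome: [(orf_id, family, copy_tag)] in scaffold order

    def query_seed(self) -> str:
        """Deterministic seed ORF: first full-length post-WGD query copy."""
        haa1 = sorted(o for o, s in self.sublineage.items() if s == SUBLINEAGE_HAA1)
        if haa1:
            return haa1[0]
        return sorted(self.sublineage)[0]

    def query_members(self) -> set[str]:
        return set(self.sublineage)


@dataclass
class _Gene:
    family: str
    copy_tag: str  # '0' before WGD, 'a'/'b' after
    seq: str
    strand: str


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def _mutate_fraction(rng: np.random.Generator, seq: str, frac: float, start: int = 0) -> str:
    """Substitute ~frac of sites (from `start` on) to a different residue."""
    arr = np.array(list(seq))
    idx = np.arange(start, len(arr))[rng.random(len(arr) - start) < frac]
    for i in idx:
        choices = AA[AA != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr)


def evolve_sequence(
    seq: str,
    branch_length: float,
    sub_rate: float,
    indel_rate: float,
    conserved_prefix_len: int,
    rng: np.random.Generator,
) -> str:
    """Evolve a protein along a branch.

    Substitutions hit each mutable site with probability
    ``1 − exp(−sub_rate · branch_length)``; insertions/deletions occur as
    Poisson events outside the conserved prefix with expected count
    ``indel_rate · branch_length · n_mutable_sites`` and geometric block
    lengths (mean 2).  The first ``conserved_prefix_len`` residues are never
    touched.
    """
    if branch_length <= 0 or (sub_rate == 0 and indel_rate == 0):
        return seq
    p = 1.0 - np.exp(-sub_rate * branch_length)
    seq = _mutate_fraction(rng, seq, p, start=conserved_prefix_len)
    mutable = len(seq) - conserved_prefix_len
    if indel_rate > 0 and mutable > 0:
        n_events = rng.poisson(indel_rate * branch_length * mutable)
        for _ in range(n_events):
            block = int(rng.geometric(0.5))
            if rng.random() < 0.5 and len(seq) - conserved_prefix_len > block + 10:
                pos = int(rng.integers(conserved_prefix_len, len(seq) - block + 1))
                seq = seq[:pos] + seq[pos + block :]
            else:
                pos = int(rng.integers(conserved_prefix_len, len(seq) + 1))
                seq = seq[:pos] + _random_protein(rng, block) + seq[pos:]
    return seq


def apply_truncation(
    seq: str,
    target_range: tuple[int, int],
    conserved_prefix_len: int,
    rng: np.random.Generator,
) -> str:
    """Remove deletion blocks downstream of the conserved prefix until the
    length falls inside *target_range*.  A sequence already at or below the
    range maximum is returned unchanged."""
    lo, hi = target_range
    if lo > hi or lo <= conserved_prefix_len:
        raise ValueError("infeasible truncation target range")
    if len(seq) <= hi:
        return seq
    target = int(rng.integers(lo, hi + 1))
    while len(seq) > target:
        block = min(len(seq) - target, int(rng.integers(10, 61)))
        pos = int(rng.integers(conserved_prefix_len, len(seq) - block + 1))
        seq = seq[:pos] + seq[pos + block :]
    return seq


def _apply_inversions(genes: list[_Gene], n_events: int, rng: np.random.Generator) -> None:
    flip = {"+": "-", "-": "+", "?": "?"}
    for _ in range(n_events):
        if len(genes) < 2:
            return
        i = int(rng.integers(0, len(genes) - 1))
        j = int(rng.integers(i + 1, len(genes) + 1))
        seg = genes[i:j][::-1]
        for g in seg:
            g.strand = flip[g.strand]
        genes[i:j] = seg


def _ancestral_state(cfg: SimulationConfig, rng: np.random.Generator):
    """Two ancestral scaffolds: the query sits mid-scaffold among background
    anchors; the distant relative lives on a separate scaffold so it never
    enters the query's neighbourhood window."""
    n_bg = cfg.n_background_families
    fams = [f"fam{i:02d}" for i in range(1, n_bg + 1)]
    lo, hi = cfg.background_len_range
    seqs: dict[str, str] = {}
    query_prefix = _random_protein(rng, cfg.conserved_prefix_len)
    if cfg.query_family:
        seqs[QUERY_FAMILY] = query_prefix + _random_protein(
            rng, cfg.ancestral_query_len - cfg.conserved_prefix_len
        )
    for fam in fams:
        length = int(rng.integers(lo, hi + 1))
        if fam == DISTANT_FAMILY and cfg.distant_relative:
            prefix = _mutate_fraction(rng, query_prefix, cfg.distant_prefix_divergence)
            seqs[fam] = prefix + _random_protein(rng, max(20, length - len(prefix)))
        else:
            seqs[fam] = _random_protein(rng, length)

    n_side = min(4, n_bg - 2)  # companions of the distant relative
    side_fams = fams[-n_side:]
    main_fams = [f for f in fams[:-n_side] if f != DISTANT_FAMILY]
    main_genes = [_Gene(f, "0", seqs[f], "+" if rng.random() < 0.5 else "-") for f in main_fams]
    if cfg.query_family:
        mid = len(main_genes) // 2
        main_genes.insert(mid, _Gene(QUERY_FAMILY, "0", seqs[QUERY_FAMILY], "+"))
    side_genes = [_Gene(DISTANT_FAMILY, "0", seqs[DISTANT_FAMILY], "+")] if cfg.distant_relative else []
    side_genes += [_Gene(f, "0", seqs[f], "+" if rng.random() < 0.5 else "-") for f in side_fams]
    return [("sA", main_genes), ("sB", side_genes)]


def _has_frozen_prefix(cfg: SimulationConfig, family: str) -> bool:
    return family == QUERY_FAMILY or (family == DISTANT_FAMILY and cfg.distant_relative)


def simulate(config: SimulationConfig) -> tuple[GenomeDB, TruthTables]:
    """Run the generative model; deterministic for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.species_tree, schema="newick")
    state0 = _ancestral_state(config, rng)

    genomes: list[GenomeRecord] = []
    truth = TruthTables()

    def node_name(node) -> str | None:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def clone_state(state):
        return [
            (name, [_Gene(g.family, g.copy_tag, g.seq, g.strand) for g in genes])
            for name, genes in state
        ]

    def descend(node, state, post_wgd: bool) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            cstate = clone_state(state)
            child_post = post_wgd
            if node_name(child) == config.wgd_branch:
                # WGD at the base of this branch: double every scaffold, then
                # let the two copies evolve independently along the stem
                doubled = []
                for name, genes in cstate:
                    a = [_Gene(g.family, "a", g.seq, g.strand) for g in genes]
                    b = [_Gene(g.family, "b", g.seq, g.strand) for g in genes]
                    doubled.append((f"{name}_a", a))
                    doubled.append((f"{name}_b", b))
                cstate = doubled
                child_post = True
            for _, genes in cstate:
                for g in genes:
                    prefix = config.conserved_prefix_len if _has_frozen_prefix(config, g.family) else 0
                    g.seq = evolve_sequence(
                        g.seq, bl, config.sub_rate, config.indel_rate, prefix, rng
                    )
                if config.shuffle_rate > 0:
                    _apply_inversions(genes, int(rng.poisson(config.shuffle_rate)), rng)
            if child.is_leaf():
                genomes.append(_finalize_leaf(config, node_name(child), cstate, child_post, rng, truth))
            else:
                descend(child, cstate, child_post)

    descend(tree.seed_node, state0, False)
    db = compile_db(genomes)
    return db, truth


def _finalize_leaf(
    cfg: SimulationConfig,
    leaf_name: str,
    state,
    post_wgd: bool,
    rng: np.random.Generator,
    truth: TruthTables,
) -> GenomeRecord:
    code = leaf_name.lower()
    if len(code) != 4 or not code.isalpha():
        raise ValueError(f"leaf names must be 4-letter species codes, got {leaf_name!r}")

    if post_wgd:
        # Bernoulli retention per duplicated copy; at least one copy per family
        by_family: dict[str, list[_Gene]] = {}
        for _, genes in state:
            for g in genes:
                by_family.setdefault(g.family, []).append(g)
        dropped: set[int] = set()
        for fam in sorted(by_family):
            copies = by_family[fam]
            if len(copies) < 2:
                continue
            keep = [rng.random() < cfg.retention_prob for _ in copies]
            if not any(keep):
                keep[int(rng.integers(0, len(copies)))] = True
            for g, k in zip(copies, keep):
                if not k:
                    dropped.add(id(g))
        state = [(name, [g for g in genes if id(g) not in dropped]) for name, genes in state]

    # truncation of the CUP2-like sub-lineage (post-WGD copy 'b' of the query)
    if cfg.truncation_target_range is not None:
        for _, genes in state:
            for g in genes:
                if g.family == QUERY_FAMILY and g.copy_tag == "b":
                    g.seq = apply_truncation(
                        g.seq, cfg.truncation_target_range, cfg.conserved_prefix_len, rng
                    )

    orfs: list[OrfRecord] = []
    counter = 0
    ohnolog_candidates: dict[tuple[str, str], str] = {}
    order_rows: list[tuple[str, str, str]] = []
    for scaf_name, genes in state:
        for ordinal, g in enumerate(genes):
            orf_id = f"{code}_1_g{counter:04d}"
            counter += 1
            orfs.append(
                OrfRecord(orf_id, code, 1, scaf_name, ordinal, g.strand, g.seq)
            )
            truth.family_membership[orf_id] = g.family
            order_rows.append((orf_id, g.family, g.copy_tag))
            if g.family == QUERY_FAMILY:
                if not post_wgd:
                    truth.sublineage[orf_id] = SUBLINEAGE_PRE
                elif g.copy_tag == "a":
                    truth.sublineage[orf_id] = SUBLINEAGE_HAA1
                else:
                    truth.sublineage[orf_id] = SUBLINEAGE_CUP2
            if post_wgd:
                key = (g.family, "pair")
                if key in ohnolog_candidates:
                    truth.ohnolog_pairs.append((ohnolog_candidates.pop(key), orf_id))
                else:
                    ohnolog_candidates[key] = orf_id
    truth.ancestral_order[code] = order_rows
    return GenomeRecord(code, 1, "post" if post_wgd else "pre", orfs)


# ---------------------------------------------------------------------------
# file emission (same formats genome_db consumes)


def write_simulation(
    db: GenomeDB, truth: TruthTables, config: SimulationConfig, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genomes.tsv", "w") as idx:
        idx.write("species_code\tstrain_index\twgd_status\tproteome_fasta\tgene_order_table\n")
        for genome in db.genomes:
            stem = f"{genome.species_code}_{genome.strain_index}"
            write_genome(genome, outdir / f"{stem}.faa", outdir / f"{stem}.order.tsv")
            idx.write(
                f"{genome.species_code}\t{genome.strain_index}\t{genome.pre_post_wgd}\t"
                f"{stem}.faa\t{stem}.order.tsv\n"
            )
    with open(outdir / "truth_family.tsv", "w") as fh:
        fh.write("orf_id\tfamily\n")
        for orf_id in sorted(truth.family_membership):
            fh.write(f"{orf_id}\t{truth.family_membership[orf_id]}\n")
    with open(outdir / "truth_sublineage.tsv", "w") as fh:
        fh.write("orf_id\tsublineage\n")
        for orf_id in sorted(truth.sublineage):
            fh.write(f"{orf_id}\t{truth.sublineage[orf_id]}\n")
    with open(outdir / "truth_ohnologs.tsv", "w") as fh:
        fh.write("orf_a\torf_b\n")
        for a, b in sorted(truth.ohnolog_pairs):
            fh.write(f"{a}\t{b}\n")
    cfg = asdict(config)
    if config.truncation_target_range is not None:
        cfg["truncation_target_range"] = list(config.truncation_target_range)
    cfg["background_len_range"] = list(config.background_len_range)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("truncation_target_range", "background_len_range"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)
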