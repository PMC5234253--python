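"""End-to-end orchestration: ingest → all-vs-all → network → sweep →
retrieve → classify → synteny → report.

A run is configured either with real inputs (per-strain FASTA + gene-order
files) or with the bundled genome-evolution simulator; exactly one of the
two.  Every stage writes its artifact to the output directory and the run
ends with a ``summary.json`` that is byte-identical across reruns with the
same configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import classify as _classify
from . import pairwise as _pairwise
from . import simnet as _simnet
from . import synteny as _synteny
from .genome_db import GenomeDB, compile_db, load_genome, write_manifest
from .pairwise import AlignmentParams, DEFAULT_SCAN_PARAMS
from .synthetic_data import SimulationConfig, TruthTables, simulate, write_simulation

#: truth sub-lineage label -> expected assigned role
_TRUTH_ROLE = {
    "HAA1-like": _classify.ROLE_HAA1,
    "CUP2-like": _classify.ROLE_CUP2,
    "PROTOPLOID": _classify.ROLE_PROTOPLOID,
}


@dataclass
class GenomeInput:
    proteome_fasta: str
    gene_order_table: str | None
    species_code: str
    strain_index: int
    wgd_status: str


@dataclass
class PipelineConfig:
    simulation: SimulationConfig | None = None
    genomes: list[GenomeInput] = field(default_factory=list)
    params: AlignmentParams = field(default_factory=lambda: dataclasses.replace(DEFAULT_SCAN_PARAMS))
    seed_orf_id: str | None = None  # None => simulator's suggested seed
    exponent_cut: int | str = "auto"
    length_cutoff: int = _classify.DEFAULT_LENGTH_CUTOFF
    neighbour_k: int = _synteny.DEFAULT_NEIGHBOUR_K
    strong_cutoff: float = _synteny.DEFAULT_STRONG_CUTOFF
    outgroup_id: str | None = None
    outdir: str = "ohnotrace_out"
    seed: int | None = None  # overrides the simulation seed when set

    def __post_init__(self) -> None:
        if (self.simulation is None) == (not self.genomes):
            # either both missing or both present
            if self.simulation is None and not self.genomes:
                raise ValueError("provide either real genome inputs or a simulation config")
            if self.simulation is not None and self.genomes:
                raise ValueError("real inputs and simulation are mutually exclusive")


def load_pipeline_config(data: dict | str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file or an equivalent dict."""
    if not isinstance(data, dict):
        with open(data) as fh:
            data = yaml.safe_load(fh)
    data = dict(data)
    sim = data.pop("simulation", None)
    if sim is not None:
        for key in ("truncation_target_range", "background_len_range"):
            if sim.get(key) is not None:
                sim[key] = tuple(sim[key])
        sim = SimulationConfig(**sim)
    genomes = [GenomeInput(**g) for g in data.pop("genomes", [])]
    align = data.pop("alignment", None)
    params = AlignmentParams(**align) if align else dataclasses.replace(DEFAULT_SCAN_PARAMS)
    return PipelineConfig(simulation=sim, genomes=genomes, params=params, **data)


def load_workspace(workspace: str | Path) -> GenomeDB:
    """Load a directory written by the simulator (or laid out the same way):
    a ``genomes.tsv`` index plus per-strain FASTA and gene-order files."""
    workspace = Path(workspace)
    records = []
    with open(workspace / "genomes.tsv") as fh:
        header = fh.readline()
        assert header.startswith("species_code")
        for line in fh:
            if not line.strip():
                continue
            code, strain, wgd, fasta, order = line.rstrip("\n").split("\t")
            records.append(
                load_genome(workspace / fasta, workspace / order, code, int(strain), wgd)
            )
    return compile_db(records)


def build_input_db(config: PipelineConfig) -> tuple[GenomeDB, TruthTables | None]:
    if config.simulation is not None:
        sim_cfg = config.simulation
        if config.seed is not None:
            sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
        db, truth = simulate(sim_cfg)
        return db, truth
    records = [
        load_genome(g.proteome_fasta, g.gene_order_table, g.species_code, g.strain_index, g.wgd_status)
        for g in config.genomes
    ]
    return compile_db(records), None


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written as
    ``summary.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # stage 1: database
    db, truth = build_input_db(config)
    write_manifest(db, outdir / "manifest.tsv")
    if truth is not None and config.simulation is not None:
        sim_cfg = config.simulation
        if config.seed is not None:
            sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
        write_simulation(db, truth, sim_cfg, outdir / "simulated_input")

    # stage 2: all-vs-all hits
    hits = _pairwise.all_vs_all(db, config.params)
    _pairwise.write_hits(hits, outdir / "hits.tsv")

    # stage 3: similarity network
    net = _simnet.build_network(hits, db.orf_index.keys())
    _simnet.write_edge_list(net, outdir / "network.tsv")

    # stage 4: seed, sweep, plateaus, cut
    seed_orf = config.seed_orf_id
    if seed_orf is None:
        if truth is None:
            raise ValueError("seed_orf_id is required for real inputs")
        seed_orf = truth.query_seed()
    if seed_orf not in db:
        raise KeyError(f"seed ORF {seed_orf!r} not in database")
    curve = _simnet.sweep_thresholds(net, seed_orf)
    plateaus = _simnet.detect_plateaus(curve)
    if config.exponent_cut == "auto":
        cut = _simnet.auto_plateau_cut(curve)
    else:
        cut = int(config.exponent_cut)
    _simnet.write_curve_report(curve, plateaus, cut, outdir / "curve.json")

    # stage 5: family retrieval + whole-db clustering at the cut
    family = _simnet.retrieve_cluster(net, seed_orf, cut)
    _simnet.write_membership(family, outdir / "family_members.tsv")
    clustering = _simnet.clustering_at(net, cut)
    cluster_sizes: dict[str, int] = {}
    for label in clustering.values():
        cluster_sizes[label] = cluster_sizes.get(label, 0) + 1

    # stage 6: roles + NJ tree
    members = sorted(family.member_ids)
    lengths = {m: db[m].length for m in members}
    wgd_flags = {m: db.wgd_flag(m) for m in members}
    clusters = _classify.assign_roles(
        members, lengths, wgd_flags, config.length_cutoff, config.outgroup_id
    )
    roles = _classify.role_map(clusters)
    _classify.write_cluster_report(clusters, db, outdir / "roles.tsv")
    newick = None
    if len(members) >= 3:
        dm = _classify.pairwise_distances(
            members, db,
            gap_open=config.params.gap_open, gap_extend=config.params.gap_extend,
        )
        newick = _classify.nj_tree(dm)
        (outdir / "tree.nwk").write_text(newick + "\n")

    # stage 7: synteny sub-lineages
    windows = {
        m: _synteny.extract_window(db, m, clustering, config.neighbour_k) for m in members
    }
    lineage = _synteny.build_lineage_graph(
        members, windows, cluster_sizes, wgd_flags, roles,
        strong_cutoff=config.strong_cutoff, net=net,
    )
    _synteny.write_edges(lineage.edges, outdir / "synteny_edges.tsv")
    _synteny.write_partition(lineage, outdir / "sublineages.tsv")
    _synteny.write_window_detail(windows, outdir / "neighbourhoods.tsv")

    # stage 8: summary
    summary: dict = {
        "seed_orf_id": seed_orf,
        "exponent_cut": cut,
        "counts": {
            "orfs": db.total_orf_count,
            "hits": len(hits),
            "network_edges": net.graph.number_of_edges(),
            "family_members": len(members),
            "plateaus": len(plateaus),
            "sublineages": len(lineage.blocks()),
        },
        "roles": {role: sum(1 for r in roles.values() if r == role) for role in sorted(set(roles.values()))},
        "plateaus": [
            {"exponent_lo": s.exponent_lo, "exponent_hi": s.exponent_hi, "count": s.count}
            for s in plateaus
        ],
    }
    if truth is not None:
        summary["truth_eval"] = evaluate_against_truth(
            truth, set(members), roles, lineage
        )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def evaluate_against_truth(
    truth: TruthTables,
    retrieved: set[str],
    roles: dict[str, str],
    lineage: "_synteny.LineageGraph",
) -> dict:
    """Precision/recall of family retrieval, role accuracy, and adjusted Rand
    index of the synteny sub-lineage partition against the simulator truth."""
    from sklearn.metrics import adjusted_rand_score

    true_members = truth.query_members()
    tp = len(retrieved & true_members)
    precision = tp / len(retrieved) if retrieved else 0.0
    recall = tp / len(true_members) if true_members else 0.0

    common = sorted(retrieved & true_members)
    correct = sum(1 for m in common if roles.get(m) == _TRUTH_ROLE[truth.sublineage[m]])
    role_accuracy = correct / len(common) if common else 0.0

    in_partition = [m for m in common if m in lineage.partition]
    if len(in_partition) >= 2:
        labels_true = [truth.sublineage[m] for m in in_partition]
        labels_pred = [lineage.partition[m] for m in in_partition]
        ari = float(adjusted_rand_score(labels_true, labels_pred))
    else:
        ari = 0.0
    return {
        "family_precision": precision,
        "family_recall": recall,
        "role_accuracy": role_accuracy,
        "sublineage_ari": ari,
        "n_true_members": len(true_members),
        "n_retrieved": len(retrieved),
    }


def default_simulated_config(outdir: str | Path, seed: int = 1) -> PipelineConfig:
    """The package's reference study conditions: 12 leaves (6 post-WGD),
    30 background families, retention 0.9, no shuffling."""
    return PipelineConfig(
        simulation=SimulationConfig(seed=seed),
        outdir=str(outdir),
    )
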