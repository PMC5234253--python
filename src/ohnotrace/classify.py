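"""Phylogenetic grouping of retrieved family members.

The family splits into three functional roles using two criteria: protein
length and the taxonomic position of the encoding genome relative to the
whole-genome duplication (WGD).  Post-WGD members below a length cutoff are
the short, truncated sub-lineage (Cup2-like); post-WGD members above it are
the full-length sub-lineage (Haa1-like); pre-WGD (protoploid) genomes carry
a single ancestral-type copy.  A neighbor-joining tree over global-alignment
distances provides a desk-scale phylogeny; its Newick output can seed a full
Bayesian/ML analysis externally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import skbio
from skbio.tree import nj

from .genome_db import GenomeDB
from .pairwise import align_global

ROLE_HAA1 = "HAA1_orthologue"
ROLE_CUP2 = "CUP2_orthologue"
ROLE_PROTOPLOID = "PROTOPLOID_single"
ROLE_OUTGROUP = "OUTGROUP"

#: default protein-length cutoff (aa) separating the truncated sub-lineage
#: (empirically 221-356 aa) from full-length members (empirically 525-893 aa)
DEFAULT_LENGTH_CUTOFF = 450


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class PhyloCluster:
    label: str
    member_ids: list[str]
    length_min: int
    length_max: int
    length_mean: float
    assigned_role: str
    roles: dict[str, str] = field(default_factory=dict)  # member -> role


def pairwise_distances(member_ids: Iterable[str], db: GenomeDB, **scores) -> DistanceMatrix:
    """d(i,j) = 1 − identity/100 from global alignment of the two proteins."""
    ids = sorted(set(member_ids))
    if len(ids) < 2:
        raise ValueError("need at least two members")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            st = align_global(db[ids[i]].protein_seq, db[ids[j]].protein_seq, **scores)
            d[i, j] = d[j, i] = 1.0 - st.identity_pct / 100.0
    return DistanceMatrix(ids=ids, d=d)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as Newick text (unrooted, binary)."""
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    skdm = skbio.DistanceMatrix(dm.d, ids=dm.ids)
    tree = nj(skdm)
    return str(tree).strip()


def assign_roles(
    member_ids: Iterable[str],
    lengths: Mapping[str, int],
    wgd_flags: Mapping[str, str],
    length_cutoff: int = DEFAULT_LENGTH_CUTOFF,
    outgroup_id: str | None = None,
) -> list[PhyloCluster]:
    """Partition members into role clusters by length and WGD taxonomy.

    Every member gets exactly one role; an explicitly designated outgroup is
    pulled out first and never enters the three functional roles.
    """
    members = sorted(set(member_ids))
    role_of: dict[str, str] = {}
    for m in members:
        if m not in wgd_flags:
            raise KeyError(f"missing pre/post-WGD flag for {m}")
        if outgroup_id is not None and m == outgroup_id:
            role_of[m] = ROLE_OUTGROUP
        elif wgd_flags[m] == "pre":
            role_of[m] = ROLE_PROTOPLOID
        elif lengths[m] < length_cutoff:
            role_of[m] = ROLE_CUP2
        else:
            role_of[m] = ROLE_HAA1
    clusters: list[PhyloCluster] = []
    order = [ROLE_HAA1, ROLE_CUP2, ROLE_PROTOPLOID, ROLE_OUTGROUP]
    labels = "ABCDEFGH"
    for i, role in enumerate([r for r in order if r in set(role_of.values())]):
        ids = [m for m in members if role_of[m] == role]
        ls = [lengths[m] for m in ids]
        clusters.append(
            PhyloCluster(
                label=labels[i],
                member_ids=ids,
                length_min=min(ls),
                length_max=max(ls),
                length_mean=sum(ls) / len(ls),
                assigned_role=role,
                roles={m: role for m in ids},
            )
        )
    return clusters


def role_map(clusters: Iterable[PhyloCluster]) -> dict[str, str]:
    out: dict[str, str] = {}
    for c in clusters:
        out.update(c.roles)
    return out


def write_cluster_report(
    clusters: Iterable[PhyloCluster],
    db: GenomeDB,
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("orf_id\tcluster_label\trole\tlength\tspecies_code\twgd_flag\n")
        for c in clusters:
            for m in c.member_ids:
                orf = db[m]
                fh.write(
                    f"{m}\t{c.label}\t{c.assigned_role}\t{orf.length}\t"
                    f"{orf.species_code}\t{db.wgd_flag(m)}\n"
                )
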