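# ohnotrace

Comparative-genomics toolkit for tracing a gene family across a
whole-genome duplication (WGD): similarity-network retrieval of the family,
length/taxonomy classification of its members, and reconstruction of the
post-WGD ohnolog sub-lineages from gene-neighbourhood (synteny) evidence.

## The problem

Budding yeasts of the family Saccharomycetaceae descend from an ancient
whole-genome duplication. A gene that was single-copy in the "protoploid"
(pre-WGD) species can survive as an ohnolog pair in post-WGD species — often
with the two copies diverging dramatically, e.g. one copy keeping the
full-length protein while the other loses most of its sequence outside a
conserved N-terminal DNA-binding domain. Resolving which present-day genes
belong to which sub-lineage requires more than sequence similarity: the
chromosomal neighbourhood of each copy carries the decisive signal.

`ohnotrace` implements that analysis end to end, for users who have
per-strain protein FASTA files plus gene-order tables (TSV or GFF3):

1. **genome_db** — compile translated ORFs into a multi-genome database with
   canonical ids `<code>_<strain>_<localid>` and 0-based ordinal gene order
   per scaffold.
2. **pairwise** — all-vs-all gapped local alignment (affine Smith–Waterman,
   BLOSUM62) with Karlin–Altschul e-values `E = K·m·n·exp(−λS)`, and global
   Needleman–Wunsch identity/gap statistics for cross-group comparisons.
   A blast outfmt-6 reader lets precomputed hit tables stand in for the
   internal engine at full-proteome scale.
3. **simnet** — the similarity network: nodes are ORFs, an undirected edge
   keeps the minimum e-value of the two directed hits. A family is retrieved
   by breadth-first traversal from a seed protein over edges with
   `E ≤ 10^x`; sweeping the exponent `x` from −60 to −1 yields a retrieval
   curve whose plateaus mark stable family boundaries and whose jumps mark
   merges with ever more remote families.
4. **classify** — members split into functional roles by protein length and
   WGD taxonomy (post-WGD short copies vs full-length copies vs protoploid
   singles), plus a neighbor-joining tree over global-alignment distances.
5. **synteny** — 15-gene windows on each side of every family member, each
   neighbour labelled with its own similarity family; queries are connected
   by shared neighbour families and each edge is scored by closeness ×
   similarity × rarity of the shared neighbours. Connected components of the
   strong edges are the sub-lineages.
6. **motif** — degenerate promoter-motif scanning (IUPAC codes,
   alternatives like `(G/C)`, variable runs like `(T)4-6`) with the
   Haa1/Cup2 binding sites built in.
7. **synthetic_data** — a WGD-aware genome-evolution simulator that emits
   the same file formats plus ground-truth tables, so the entire pipeline is
   validated against known truth.
8. **pipeline / CLI** — one orchestrated run (`run-all`) or individual
   stages, all deterministic for a fixed seed.

## Worked example

Run the full analysis on the bundled simulator's reference conditions
(12 species, 6 of them post-WGD, 30 background gene families, duplicate
retention probability 0.9):

```python
from ohnotrace.pipeline import default_simulated_config, run

summary = run(default_simulated_config("out", seed=1))
print(summary["exponent_cut"], summary["counts"], summary["truth_eval"])
```

which prints (seed 1):

```
-4
{'orfs': 528, 'hits': 36174, 'network_edges': 18087, 'family_members': 18,
 'plateaus': 4, 'sublineages': 3}
{'family_precision': 1.0, 'family_recall': 1.0, 'n_retrieved': 18,
 'n_true_members': 18, 'role_accuracy': 1.0, 'sublineage_ari': 1.0}
```

Reading this: the sweep found a wide plateau of 18 proteins ending at E−4 —
at E−3 a distant family sharing only the conserved DNA-binding domain merges
in, so the auto-cut stops just short of it. The 18 retrieved proteins are
exactly the simulated query family (precision = recall = 1). Length/taxonomy
classification recovers every role (6 full-length post-WGD, 6 truncated
post-WGD, 6 protoploid), and the synteny graph splits them into exactly
three sub-lineages that match the simulated history (adjusted Rand index 1):
the two post-WGD ohnolog tracks and the protoploid group.

The same run from a shell:

```
ohnotrace run-all --config pipeline.yaml --seed 1 --out out/
```

writes `manifest.tsv`, `hits.tsv`, `network.tsv`, `curve.json`,
`family_members.tsv`, `roles.tsv`, `tree.nwk`, `synteny_edges.tsv`,
`sublineages.tsv` and `summary.json`. Stage subcommands (`simulate`,
`build-db`, `all-vs-all`, `network`, `sweep`, `retrieve`, `classify`,
`synteny`, `motif-scan`) reproduce the same artifacts piecewise.

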