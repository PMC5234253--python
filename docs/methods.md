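# Methods

## Similarity network and family retrieval

All translated ORFs are compared all-vs-all with affine-gap Smith–Waterman
local alignment (Bio.Align, BLOSUM62). Gap convention throughout: a gap of
length L scores `gap_open + (L−1)·gap_extend`. Each pair's score is turned
into an expectation value with the Karlin–Altschul closed form
`E = K·m·n·exp(−λS)`, with `m` the query length and `n` the effective
database size (total residues by default). E-values are evaluated in log
space and floored at 1e−300 to avoid float underflow for near-identical
long proteins; the floor is far below any usable threshold.

Directed hits passing a permissive report ceiling (E ≤ 10) are collapsed
onto an undirected network keeping the *minimum* of the two directed
e-values — a single passing direction creates the edge, which is the
order-independent, permissive reading of "pairwise similarity exists".

A family is the set of nodes reachable from a seed protein by breadth-first
traversal over edges with `E ≤ 10^x`. Sweeping integer exponents x from −60
to −1 gives the retrieval curve; maximal runs of constant count (tolerance
0 by default, exposed as a parameter since plateau boundaries are
ultimately a judgement call) are the plateaus. The suggested automatic cut
is the most permissive exponent of the widest plateau — the last threshold
that still excludes the next merge event. It is logged as a suggestion and
always overridable: choosing the cut is expert judgement when a remotely
similar family (here, one sharing only the conserved DNA-binding domain)
sits just beyond the family boundary.

### Alignment statistics parameters

`AlignmentParams` defaults mirror the historical search this pipeline
reimplements: BLOSUM62 with open/extend gap penalties of 1, word size 3,
extension threshold 11. Those gap penalties are so weak that local
alignment leaves the logarithmic (Karlin–Altschul) regime — random
200-residue pairs then score in the hundreds, and no valid λ exists. The
pipeline's default parameter set (`DEFAULT_SCAN_PARAMS`) therefore scores
with gap open 11 / extend 1, the combination for which the shipped
constants λ = 0.267, K = 0.041 are the published gapped-BLOSUM62 values.
With that coherent set, unrelated 180-aa pairs land at E ≈ 100 and only a
small tail passes the report ceiling, while 50%-diverged homologues sit
near E ≈ 1e−44 — the separation the threshold sweep relies on. Both
parameter sets are plain dataclass fields and can be overridden per run.

Identity and gap percentages — local and global — are taken over all
alignment columns (gaps included), so identity% + mismatch% + gap% = 100
and the identity and gap figures for a pair refer to the same alignment.
Group-level comparisons are arithmetic means over all cross pairs
(unordered distinct pairs when a group is compared with itself).

## Classification

Retrieved members are partitioned into roles by two criteria: the genome's
position relative to the WGD (a user-supplied flag per genome) and protein
length. Post-WGD members shorter than the length cutoff are the truncated
sub-lineage (Cup2-like); post-WGD members at or above it are full-length
(Haa1-like); pre-WGD members are protoploid singles. The default cutoff of
450 aa bisects the empirical gap between the truncated (221–356 aa) and
full-length (≥ 525 aa) size ranges and is exposed as a parameter. An
explicitly designated outgroup id is excluded from the three roles; there
is no automatic outgroup detection.

The desk-scale phylogeny is neighbor joining (scikit-bio) on distances
`d = 1 − identity/100` from global alignments. NJ is consistent on additive
matrices (verified by Robinson–Foulds tests); it replaces Bayesian/ML
inference here, and the Newick output can seed such an external analysis.

## Synteny scoring and sub-lineage partition

Each query gene contributes a window of up to 15 neighbours per side
(ordinal gene ranks, never base pairs; windows stop at scaffold ends and
never cross scaffolds; strand is recorded but not used). Neighbours are
labelled with their similarity-network family — connected components of the
network at the same exponent cut used for retrieval — and unclustered
neighbours get per-window singleton labels that can never match.

For two queries, each family label present in both windows yields one
shared pair, using the instance closest to the query in each window (ties
on |offset| break toward the upstream instance for determinism). The edge
strength is

    strength = Σ_pairs  c · s · r
    c = 1 / max(|offset_a|, |offset_b|)        (closeness)
    s = min(1, −log10(pair e-value) / 60)      (neighbour similarity; 1 if
                                                no e-value is recorded)
    r = 2 / cluster_size                       (rarity: a two-member family,
                                                the smallest that can match,
                                                scores 1)

Each factor lies in [0, 1], so a single adjacent, rare, highly similar
neighbour pair already contributes 1.0, while matches through large
promiscuous families are discounted — a small family makes a chance
co-occurrence next to two queries unlikely. The three factors implement the
classic synteny criteria (closeness to the query, similarity of the
connecting neighbours, size of their family); the multiplicative form and
constants are this package's concrete instantiation since only the criteria
themselves, not a formula, are established. Both flanks are scored jointly;
no both-flank support is required.

Edges with strength ≥ 0.5 (`strong_cutoff`, configurable) are "strong";
sub-lineages are the connected components of the strong-edge subgraph,
annotated with the majority role of their members. The 0.5 default was
calibrated on the simulator's reference conditions so that same-track
ohnolog edges (typically strength 1.5–2.5) are strong and cross-track or
chance edges (≤ ~0.1) are not.

## The simulator

`synthetic_data.simulate` generates proteomes + gene orders along a species
tree (dendropy-parsed Newick; default 12 leaves, 6 descending from the
labelled WGD branch, within-clade leaf depth 0.12 and stem length 0.28).
It emulates the features of the real system that the pipeline's inferences
depend on:

* **Query family** — ancestral protein of 620 aa (echoing the protoploid
  mean) whose first 124 residues (the DNA-binding domain) never mutate;
  the rest evolves by per-site substitution with probability
  `1 − exp(−sub_rate·t)` (uniform replacement, no rate matrix) and Poisson
  indels of geometric length outside the prefix.
* **WGD** — the labelled branch doubles every scaffold into paired "a"/"b"
  tracks that then evolve independently; at each post-WGD leaf every
  duplicated gene copy survives with `retention_prob` (default 0.9), at
  least one copy per family always kept.
* **Truncation** — the "b" copy of the query in each post-WGD genome is cut
  down to 221–356 aa by random deletion blocks strictly downstream of the
  conserved prefix, reproducing the progressive size reduction of the short
  sub-lineage.
* **Distant relative** — one background family carries the query's
  conserved prefix mutated at 67% of sites and thereafter frozen. Its
  members merge with the query family only at weak thresholds (≈ E−9 under
  default divergences), giving the retrieval curve its characteristic
  late-merge jump; it is placed on a separate scaffold so it never appears
  in query neighbourhood windows.
* **Background families** — 30 by default, lengths 140–240 aa, arranged in
  a conserved ancestral gene order with the query mid-scaffold; optional
  shuffling applies Poisson-many segment inversions per branch.
* **Divergence calibration** — sub_rate 2.0 with the default tree places
  same-track neighbour pairs at ≈ E−40..E−80 (well inside any sensible
  cut) and cross-track or pre-vs-post pairs at ≈ E−4 (outside it), so the
  two ohnolog tracks and the protoploid group have separable neighbourhood
  labels. These defaults define the package's reference study conditions.

Everything is driven by one `numpy` generator seeded from the config, so a
fixed config is byte-reproducible, including the emitted files.

What the simulator does *not* model: amino-acid rate matrices or
site-rate heterogeneity, codon/nucleotide evolution, gene conversion
between ohnologs, horizontal transfer, unequal family-specific rates, and
assembly artefacts (fragments, pseudogenes). Perfect end-to-end recovery on
simulated data therefore demonstrates the internal consistency of the
pipeline — retrieval, classification and synteny agree with a known
history under realistic divergence — not its robustness to every
real-data pathology.

## Problem sizes and determinism

The reference conditions (528 ORFs, ≈ 139k aligned pairs) keep a full
pipeline run around 1–2 minutes on one core; unit tests use a 4-leaf,
8-family system. All randomness flows from explicit seeds; reruns with the
same configuration produce byte-identical summaries, which the test suite
asserts.

## Known limitations

* The internal aligner is exact dynamic programming; at full-proteome scale
  (hundreds of thousands of ORFs) a precomputed blast outfmt-6 hit table
  should be supplied instead (`pairwise.read_hits`).
* Role assignment presumes a bimodal length distribution; families without
  a truncation event need a different classifier.
* The majority-role annotation of a sub-lineage can be misleading for
  chimeric cases (e.g. a single surviving copy whose neighbourhood mixes
  both tracks).
* Automatic cut selection assumes the widest plateau is the family
  boundary; with multiple equally wide plateaus the more stringent one is
  chosen, and the choice should always be reviewed against the curve.
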