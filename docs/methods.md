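# Methods

## Model and procedure

`pogscan` detects conserved gene neighborhoods in three stages.

**1. Proximal orthologous gene (POG) pairs.** For each chromosome the
search span is the mean gene length on that chromosome multiplied by the
window size (default 6 genes), so the window adapts to local gene density
and genome compaction. Two genes form a proximal pair when they lie on the
same chromosome, their start coordinates differ by at most the span, and
they belong to two *different* orthogroups. Same-orthogroup pairs are
excluded by construction, so tandem arrays cannot seed a neighborhood by
themselves. Occurrences are aggregated across genomes into one record per
unordered orthogroup pair.

Measuring proximity between start coordinates (rather than midpoints or
inter-gene gaps) keeps the predicate monotone in the span and independent
of gene length asymmetries; a gene-rank alternative (index distance
≤ window_size − 1) is available via `Parameters.proximity_metric="index"`.

**2. Conservation criteria.** A pair is retained when it satisfies any
requested criterion:

* **Criterion 1** — proximal in at least `min_genomes_c1` (default 4)
  ingroup genomes whose taxonomic classes number at least `min_classes`
  (default 2). The class requirement is enforced explicitly; with a panel
  whose classes have at most 3 members each it is implied by the genome
  count, but enforcing it keeps the rule correct for arbitrary panels.
* **Criterion 2** — proximal in the single configured outgroup genome and
  in enough ingroup genomes to reach `min_genomes_c23` (default 3) species
  in total. Exactly one outgroup must be configured when this criterion is
  requested; `detect()` skips it automatically when no outgroup exists.
* **Criterion 3** — *cooccurring*: proximal in every genome in which both
  orthogroups have at least one member, with at least `min_genomes_c23`
  such genomes spanning at least `min_classes` classes.

Flags are computed independently and unioned, so a neighborhood reports
every criterion that any of its supporting pairs satisfies.

**3. Assembly, ranking, filtering.** Per genome, each supporting gene-pair
occurrence of a retained pair defines a window: the inclusive gene-index
interval between the two genes. Windows sharing a gene are merged
transitively (sort by interval start, sweep); merged intervals supported
by at least `min_pog_pairs` (default 2) *distinct* retained pairs are
neighborhoods. Two distinct pairs may share one orthogroup, so three genes
suffice. Families are connected components of the graph linking
neighborhoods that share a retained pair; they are assigned at assembly
time and survive the later filters unchanged.

The rank score of a neighborhood with gene set G and orthogroups O is

    rank = rank_scale × Σ_{og ∈ O} (clustered(og) / total(og)) / |G|

where `clustered(og)` counts members of `og` inside *any* candidate
neighborhood (before the uniqueness filter) across all genomes, and
`total(og)` is the orthogroup's full membership. The numerator is counted
globally rather than per neighborhood: the score is meant to reward
orthogroups whose members are generally confined to neighborhoods, and the
global count makes scores of cross-genome copies of the same cluster
consistent. `rank_scale` defaults to 10, so scores lie in (0, 10].

The uniqueness filter sweeps neighborhoods in descending rank and drops
any whose genes intersect an already retained one; ties break toward more
genes, then the lexicographically smallest gene-id tuple, making the sweep
deterministic. Clean-up then removes genes participating in no supporting
occurrence (interlopers inside the merged window). Finally, when
annotations are supplied, neighborhoods in which at least half of the
*annotated* genes match "histone" (case-insensitive) are dropped —
histone clusters are conserved tandem arrays that satisfy the criteria
trivially. The one-half threshold is this package's operationalization;
unannotated neighborhoods are never dropped, since the filter requires
positive evidence.

## Coexpression test

Mutual rank (MR) is the geometric mean of the two directional
coexpression ranks of a gene pair; lower is more coexpressed. The
neighborhood score is the sum of pairwise MR over its genes after keeping
one representative per orthogroup (the first in chromosomal order), with
each pairwise MR capped at `mr_cap` (default 1000) so extreme
non-coexpression cannot dominate.

Representative reduction, rather than dropping same-orthogroup *pairs*
from the sum, keeps the effective neighborhood size well defined, which
the size-matched null requires; the pair-exclusion variant is available
as `same_og_mode="pairs"`. Missing MR values inside a tested neighborhood
are charged at the cap — a conservative choice that biases toward
non-significance — and are counted in the output. A neighborhood with
fewer than two scorable genes, or with no MR coverage at all, is reported
untestable (score `None`), never as score 0 or "not significant".

The null distribution for effective size k draws `bootstrap_n` (default
5000) contiguous runs of k genes, uniform over all valid start positions
across chromosomes, and scores each run identically (runs that reduce
below two scorable genes are redrawn, with bounded retries). Contiguous
runs, not arbitrary gene sets, preserve the positional autocorrelation the
test conditions on. The significance threshold is the lower-tail
order statistic at rank ⌈q·N⌉ of the sorted null scores (the 50th
smallest of 5000 at q = 0.01); a neighborhood is significant when
score ≤ threshold, ties included. One null is computed and cached per
effective size, on an RNG substream keyed by (seed, size) so the set of
tested neighborhoods cannot perturb any null. No multiple-testing
correction is applied across sizes.

## Synthetic data

The generator emulates the target study design: `n_ingroup` genomes
(default 9) striped over `n_classes` taxonomic classes (default 3) plus
one outgroup in its own class; two chromosomes of 100 genes per genome;
lognormal gene lengths (median ≈ 2 kb, σ = 0.6 on the log scale) and
lognormal intergenic gaps (median ≈ 1.1 kb), giving windows of roughly
14 kb at window size 6. Each planted cluster is a run of
`planted_cluster_size` (default 4) adjacent genes whose orthogroups recur
adjacently — with per-genome order permuted — in `planted_presence`
(default 5) carrier genomes chosen round-robin over the class-striped
panel, so carriers always span ≥ 2 classes. Clusters sit on a fixed slot
grid with ≥ 12 genes of singleton-orthogroup padding, so ground truth is
unambiguous. Background genes get singleton orthogroups by default;
`background_shared_og_fraction` adds small cross-genome orthogroups at
random positions (orthology without synteny — detection noise), and
`shuffle_fraction` swaps background orthogroup labels within genomes.
Mutual-rank tables cover all gene pairs of one genome: iid
Uniform(1, 1000) background with designated coexpressed blocks set to
`mr_block_strength` (default 5).

What passing tests on this generator show: the detector recovers exactly
the planted families under the stated criteria, rejects sub-threshold
presence, and the coexpression test is calibrated under an iid null. What
they do not show: robustness to orthology inference errors, residual
ancestral synteny in the background, fragmented assemblies, or
correlation-structured (non-iid) MR matrices — real data properties the
generator intentionally omits.

## Numerical and interface choices

* Coordinates are 1-based inclusive end-to-end (GFF3 convention); gene
  length is `end − start + 1`; chromosome order is by `(start, end,
  gene_id)`, which also breaks ties for overlapping gene models.
* Genes absent from every orthogroup stay in the layouts — they occupy
  window space and dilute rank scores — but can never form pairs.
* An optional regex strips transcript suffixes from GFF3 IDs so they
  match protein-based orthogroup tables; the default is exact match.
* All randomness flows from one seed; per-purpose substreams are derived
  with `numpy` seed sequences so adding a stage does not perturb earlier
  draws. Identical inputs and seed give byte-identical output TSVs; the
  run manifest (with its timestamp) is a separate side-car JSON so data
  files stay reproducible.
* Problem sizes in the test suite and acceptance script — e.g. 200
  randomized ≤ 5 × ≤ 50-gene genome sets for oracle comparisons, 20 × 5000
  bootstrap draws for the closed-form threshold check, 10 planted clusters
  for recovery — were chosen as the smallest sizes at which the checked
  properties are sharp (exact equality, 3 Monte-Carlo SEs, ± 2 SE
  calibration).

## Known limitations

* Large windows can fuse adjacent distinct neighborhoods; merged windows
  are not split.
* Criterion 2 supports exactly one outgroup genome.
* The ranking numerator counts clustered members globally; a
  per-neighborhood variant would score isolated copies lower.
* The bootstrap null conditions on run length, not on local gene density
  or chromosome; densely sampled expression compendia with block
  structure (e.g. co-regulated tandem arrays) violate the iid background
  the calibration property assumes.
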