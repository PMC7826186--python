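# pogscan

Detection of evolutionarily conserved gene neighborhoods across eukaryotic
genomes from gene coordinates and orthogroup assignments, with a
mutual-rank coexpression significance test.

## The problem

Functionally cooperating genes are occasionally kept in physical proximity
over long evolutionary times — biosynthetic gene clusters, detoxification
modules, tandem regulatory units. In lineages where functional annotation
is sparse (green algae are the motivating case), conserved gene
neighborhoods are a source of guilt-by-association function predictions
that needs no expression data or annotation: if two genes sit next to each
other in many distantly related genomes, the arrangement is unlikely to be
an accident of genome shuffling.

`pogscan` searches a panel of genomes for **Proximal Orthologous Gene
(POG) pairs**: unordered pairs of orthogroups (OrthoFinder-style gene
families) whose members lie within a search window on the same chromosome,
with the pairing recurring across genomes. The per-chromosome window span
is

```
span_c = mean gene length on chromosome c × window_size      (default 6)
```

and two genes are proximal when their start coordinates differ by at most
`span_c`. A pair is retained when it meets at least one of three
conservation criteria:

1. proximal in ≥ 4 ingroup genomes spanning ≥ 2 taxonomic classes;
2. proximal in the designated outgroup genome and in enough ingroup
   genomes to total ≥ 3 species (deep conservation);
3. *cooccurring*: proximal in **every** genome where both orthogroups are
   present, ≥ 3 such genomes, ≥ 2 classes.

Per genome, each supporting gene pair spans a window (the inclusive gene
interval between the two genes); overlapping windows are merged, and any
merged interval backed by ≥ 2 distinct retained POG pairs is a
**neighborhood**. Neighborhoods sharing a retained pair across genomes
form a **family**. Each neighborhood is scored

```
rank = 10 × Σ_og (clustered members of og / total members of og) / n_genes
```

favoring small, fully clustered orthogroups; a greedy sweep in descending
rank removes neighborhoods overlapping a better-ranked one, genes
supporting no retained pair are pruned, and histone tandem arrays
(detected by annotation keyword) are excluded.

Coexpression support is tested with **mutual ranks** (MR; the geometric
mean of the two directional coexpression ranks of a gene pair — lower
means more coexpressed). A neighborhood's score is the sum of pairwise MR
over its genes after reducing each orthogroup to one representative, with
each MR capped at 1000. Significance is empirical: 5000 random contiguous
gene runs of the same size are scored, and a neighborhood is significant
when its score falls within the lowest 1% of that size-matched null.

## Inputs

* per-genome gene models in GFF3 (gene-level features with `ID`);
* orthogroup membership in the OrthoFinder `Orthogroups.tsv` dialect;
* a taxonomy config (YAML or TSV) mapping each genome to its GFF file, a
  taxonomic class, and an `ingroup`/`outgroup` role;
* optionally a gene→description table (histone filter) and a mutual-rank
  table (long TSV or square matrix).

## Worked example

Simulate a 10-genome panel (9 ingroup genomes in 3 taxonomic classes plus
one outgroup) with 3 planted conserved neighborhoods carried by 5 genomes
each, then run detection and the coexpression test:

```
$ cat sim.yaml
n_ingroup: 9
n_classes: 3
outgroup: true
n_planted_clusters: 3
planted_presence: 5
seed: 42

$ pogscan simulate --config sim.yaml --out-dir fixtures
wrote fixtures with 3 planted clusters to fixtures

$ pogscan detect --taxonomy fixtures/taxonomy.yaml \
    --orthogroups fixtures/Orthogroups.tsv \
    --out nbhd.tsv --families-out fam.tsv --seed 42
wrote 15 neighborhoods to nbhd.tsv

$ pogscan summarize --neighborhoods nbhd.tsv \
    --taxonomy fixtures/taxonomy.yaml --orthogroups fixtures/Orthogroups.tsv
families by class combination:
  class1+class2+class3	3
neighborhoods per genome:
  genome01	1
  genome02	2
  ...
```

The 15 neighborhoods are the 3 planted clusters × 5 carrier genomes,
grouped into exactly 3 cross-genome families, each spanning all three
ingroup classes. A row of `nbhd.tsv`:

```
NB00001  FAM0001  genome01  chr1  genome01_chr1_g0007,...  OGP001_1,...  1;3  10.000000  5
```

`criteria = 1;3` — the pair evidence satisfies both the 4-genome/2-class
rule and the cooccurrence rule; `rank_score = 10.0` is the maximum,
reached because every orthogroup in the neighborhood is fully clustered.

```
$ pogscan coexpress --neighborhoods nbhd.tsv --mr fixtures/mr.tsv \
    --orthogroups fixtures/Orthogroups.tsv --taxonomy fixtures/taxonomy.yaml \
    --genome genome01 --seed 42 --out coexpr.tsv
tested 1 neighborhoods, 1 significant

$ grep -v '^#' coexpr.tsv
neighborhood_id  effective_size  score      threshold   n_boot  significant  n_missing_mr  seed
NB00001          4               30.000000  866.145500  5000    true         0             42
```

The planted low-MR block scores 30 (six pairs at MR 5), far below the
866.1 cutoff marking the lowest 1% of 5000 size-4 random gene runs, so the
neighborhood is called significantly coexpressed.

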