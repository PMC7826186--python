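"""Conserved gene-neighborhood detection.

The method looks for Proximal Orthologous Gene (POG) pairs: two genes from
*different* orthogroups lying within a search window on the same
chromosome, with the same orthogroup pairing recurring across genomes.
The per-chromosome window span in bp is the mean gene length on that
chromosome multiplied by the window size (default 6 genes).

A pair is retained when it meets at least one of three conservation
criteria:

1. proximal in at least ``min_genomes_c1`` ingroup genomes spanning at
   least ``min_classes`` taxonomic classes;
2. proximal in the single outgroup genome and in enough ingroup genomes
   to reach ``min_genomes_c23`` species in total;
3. cooccurring — proximal in *every* genome where both orthogroups are
   present, with at least ``min_genomes_c23`` such genomes spanning at
   least ``min_classes`` classes.

Per genome, each supporting gene-pair occurrence defines a window (the
inclusive gene interval between the two genes); overlapping windows are
merged transitively, and a merged interval with at least ``min_pog_pairs``
distinct flagged pairs is a neighborhood. Neighborhoods sharing a flagged
pair across genomes form a family. Neighborhoods are then ranked (favoring
small orthogroups), filtered to gene-disjoint winners, cleaned of genes
that support no flagged pair, and optionally stripped of histone tandem
arrays.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .io_model import Gene, GenomeRecord, GenomeSet, Parameters

__all__ = [
    "PogPair",
    "Neighborhood",
    "window_span",
    "find_pog_occurrences",
    "collect_pog_pairs",
    "apply_criterion1",
    "apply_criterion2",
    "apply_criterion3",
    "flag_pairs",
    "assemble_neighborhoods",
    "rank_neighborhoods",
    "filter_unique",
    "cleanup",
    "exclude_histones",
    "summarize_taxonomy",
    "detect",
]

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]
Occurrence = tuple[str, str, str]  # (chrom_id, gene_id_a, gene_id_b)


def pair_key(og_a: str, og_b: str) -> PairKey:
    """Canonical unordered orthogroup-pair key (lexicographic)."""
    if og_a == og_b:
        raise ValueError(f"a POG pair needs two distinct orthogroups: {og_a}")
    return (og_a, og_b) if og_a < og_b else (og_b, og_a)


@dataclass
class PogPair:
    """An unordered orthogroup pair with per-genome proximity evidence."""

    og_a: str
    og_b: str
    # genome id -> list of (chrom, gene_a, gene_b) proximal occurrences
    support: dict[str, list[Occurrence]] = field(default_factory=dict)
    # genomes where both orthogroups have >= 1 member (proximal or not)
    present_in: frozenset[str] = frozenset()
    criteria: set[int] = field(default_factory=set)

    @property
    def key(self) -> PairKey:
        return (self.og_a, self.og_b)

    def support_genomes(self) -> frozenset[str]:
        return frozenset(self.support)


@dataclass
class Neighborhood:
    """A per-genome gene run supported by >= min_pog_pairs flagged pairs."""

    neighborhood_id: str
    genome_id: str
    chrom_id: str
    genes: list[str]  # gene ids in chromosomal order
    orthogroups: frozenset[str]
    supporting_pairs: frozenset[PairKey]
    # pair key -> occurrences inside this neighborhood (for clean-up)
    pair_occurrences: dict[PairKey, list[tuple[str, str]]]
    criteria: frozenset[int]
    rank_score: Optional[float] = None
    family_id: Optional[str] = None


# ---------------------------------------------------------------------------
# Windows and occurrences


def window_span(chromosome: Sequence[Gene], window_size: int) -> float:
    """Search span in bp: mean gene length on the chromosome x window size."""
    if not chromosome:
        raise ValueError("window_span: empty chromosome")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    mean_len = sum(g.length for g in chromosome) / len(chromosome)
    return mean_len * window_size


def find_pog_occurrences(
    genome: GenomeRecord,
    spans: Mapping[str, float],
    params: Parameters,
) -> dict[PairKey, list[Occurrence]]:
    """All proximal different-orthogroup gene pairs in one genome.

    Proximity is measured between gene start coordinates against the
    chromosome's bp span (default), or as gene-rank distance
    ``<= window_size - 1`` when ``params.proximity_metric == "index"``.
    Genes without an orthogroup are skipped; same-orthogroup pairs (tandem
    arrays) never count.
    """
    occurrences: dict[PairKey, list[Occurrence]] = defaultdict(list)
    for chrom_id, genes in genome.chromosomes.items():
        if params.proximity_metric == "bp":
            span = spans[chrom_id]
        n = len(genes)
        for i in range(n):
            gi = genes[i]
            for j in range(i + 1, n):
                gj = genes[j]
                if params.proximity_metric == "bp":
                    if gj.start - gi.start > span:
                        break  # genes sorted by start
                else:
                    if gj.index - gi.index > params.window_size - 1:
                        break
                if gi.orthogroup_id is None or gj.orthogroup_id is None:
                    continue
                if gi.orthogroup_id == gj.orthogroup_id:
                    continue
                key = pair_key(gi.orthogroup_id, gj.orthogroup_id)
                occurrences[key].append((chrom_id, gi.gene_id, gj.gene_id))
    return dict(occurrences)


def compute_spans(genome: GenomeRecord, window_size: int) -> dict[str, float]:
    return {
        chrom_id: window_span(genes, window_size)
        for chrom_id, genes in genome.chromosomes.items()
    }


def collect_pog_pairs(
    genome_set: GenomeSet, params: Parameters
) -> dict[PairKey, PogPair]:
    """Aggregate proximal occurrences across all genomes into PogPairs."""
    pairs: dict[PairKey, PogPair] = {}
    for genome in genome_set.genomes.values():
        spans = compute_spans(genome, params.window_size)
        for key, occs in find_pog_occurrences(genome, spans, params).items():
            pair = pairs.get(key)
            if pair is None:
                pair = PogPair(og_a=key[0], og_b=key[1])
                pairs[key] = pair
            pair.support[genome.genome_id] = occs
    # presence: genomes where both orthogroups have members
    for pair in pairs.values():
        og_a_members = genome_set.orthogroups.get(pair.og_a, {})
        og_b_members = genome_set.orthogroups.get(pair.og_b, {})
        pair.present_in = frozenset(
            g for g in genome_set.genomes
            if og_a_members.get(g) and og_b_members.get(g)
        )
    return pairs


# ---------------------------------------------------------------------------
# Criteria


def _classes_of(genome_set: GenomeSet, genome_ids: Iterable[str]) -> set[str]:
    return {genome_set.genomes[g].taxonomic_class for g in genome_ids}


def apply_criterion1(
    pairs: Mapping[PairKey, PogPair], genome_set: GenomeSet, params: Parameters
) -> None:
    """Flag pairs proximal in >= min_genomes_c1 ingroup genomes across
    >= min_classes taxonomic classes."""
    ingroup = set(genome_set.ingroup_ids())
    for pair in pairs.values():
        supp = pair.support_genomes() & ingroup
        if (len(supp) >= params.min_genomes_c1
                and len(_classes_of(genome_set, supp)) >= params.min_classes):
            pair.criteria.add(1)


def apply_criterion2(
    pairs: Mapping[PairKey, PogPair], genome_set: GenomeSet, params: Parameters
) -> None:
    """Flag pairs proximal in the outgroup genome plus enough ingroup
    genomes to reach min_genomes_c23 species in total."""
    outgroups = genome_set.outgroup_ids()
    if len(outgroups) != 1:
        raise ValueError(
            f"criterion 2 requires exactly one outgroup genome, "
            f"found {len(outgroups)}"
        )
    out_id = outgroups[0]
    ingroup = set(genome_set.ingroup_ids())
    need_in = params.min_genomes_c23 - 1
    for pair in pairs.values():
        supp = pair.support_genomes()
        if out_id in supp and len(supp & ingroup) >= need_in:
            pair.criteria.add(2)


def apply_criterion3(
    pairs: Mapping[PairKey, PogPair], genome_set: GenomeSet, params: Parameters
) -> None:
    """Flag cooccurring pairs: proximal in every genome where both
    orthogroups are present, with >= min_genomes_c23 such genomes spanning
    >= min_classes classes."""
    for pair in pairs.values():
        supp = pair.support_genomes()
        if (supp == pair.present_in
                and len(supp) >= params.min_genomes_c23
                and len(_classes_of(genome_set, supp)) >= params.min_classes):
            pair.criteria.add(3)


def flag_pairs(
    pairs: dict[PairKey, PogPair],
    genome_set: GenomeSet,
    params: Parameters,
    criteria: Sequence[int] = (1, 2, 3),
) -> dict[PairKey, PogPair]:
    """Apply the requested criteria; return only pairs with >= 1 flag."""
    if 1 in criteria:
        apply_criterion1(pairs, genome_set, params)
    if 2 in criteria:
        apply_criterion2(pairs, genome_set, params)
    if 3 in criteria:
        apply_criterion3(pairs, genome_set, params)
    return {k: p for k, p in pairs.items() if p.criteria}


# ---------------------------------------------------------------------------
# Assembly


def assemble_neighborhoods(
    flagged_pairs: Mapping[PairKey, PogPair],
    genome_set: GenomeSet,
    params: Parameters,
) -> list[Neighborhood]:
    """Merge overlapping windows into candidate neighborhoods, per genome.

    Each supporting occurrence of a flagged pair defines a window: the
    inclusive gene-index interval between its two genes. Windows sharing a
    gene are merged transitively; merged intervals backed by at least
    ``min_pog_pairs`` distinct flagged pairs are emitted. Family ids are
    connected components of the neighborhood graph linked by shared
    flagged pairs.
    """
    neighborhoods: list[Neighborhood] = []
    for genome in genome_set.genomes.values():
        for chrom_id, genes in genome.chromosomes.items():
            windows: list[tuple[int, int, PairKey, tuple[str, str]]] = []
            for key, pair in flagged_pairs.items():
                for occ_chrom, ga, gb in pair.support.get(genome.genome_id, []):
                    if occ_chrom != chrom_id:
                        continue
                    ia = genome_set.gene(genome.genome_id, ga).index
                    ib = genome_set.gene(genome.genome_id, gb).index
                    lo, hi = (ia, ib) if ia <= ib else (ib, ia)
                    windows.append((lo, hi, key, (ga, gb)))
            if not windows:
                continue
            windows.sort(key=lambda w: (w[0], w[1]))
            merged: list[list] = []  # [lo, hi, {key: [(ga,gb)...]}]
            for lo, hi, key, occ in windows:
                if merged and lo <= merged[-1][1]:  # shares >= 1 gene index
                    merged[-1][1] = max(merged[-1][1], hi)
                    merged[-1][2].setdefault(key, []).append(occ)
                else:
                    merged.append([lo, hi, {key: [occ]}])
            for lo, hi, by_pair in merged:
                if len(by_pair) < params.min_pog_pairs:
                    continue
                run = genes[lo:hi + 1]
                ogs = frozenset(
                    g.orthogroup_id for g in run if g.orthogroup_id
                )
                neighborhoods.append(Neighborhood(
                    neighborhood_id="",  # assigned below
                    genome_id=genome.genome_id,
                    chrom_id=chrom_id,
                    genes=[g.gene_id for g in run],
                    orthogroups=ogs,
                    supporting_pairs=frozenset(by_pair),
                    pair_occurrences={k: list(v) for k, v in by_pair.items()},
                    criteria=frozenset().union(
                        *(flagged_pairs[k].criteria for k in by_pair)
                    ),
                ))
    neighborhoods.sort(key=lambda n: (n.genome_id, n.chrom_id, n.genes[0]))
    for i, nbhd in enumerate(neighborhoods, start=1):
        nbhd.neighborhood_id = f"NB{i:05d}"
    _assign_families(neighborhoods)
    return neighborhoods


def _assign_families(neighborhoods: Sequence[Neighborhood]) -> None:
    graph = nx.Graph()
    by_pair: dict[PairKey, list[str]] = defaultdict(list)
    for nbhd in neighborhoods:
        graph.add_node(nbhd.neighborhood_id)
        for key in nbhd.supporting_pairs:
            by_pair[key].append(nbhd.neighborhood_id)
    for members in by_pair.values():
        for other in members[1:]:
            graph.add_edge(members[0], other)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: c[0],
    )
    family_of: dict[str, str] = {}
    for i, comp in enumerate(components, start=1):
        for nid in comp:
            family_of[nid] = f"FAM{i:04d}"
    for nbhd in neighborhoods:
        nbhd.family_id = family_of[nbhd.neighborhood_id]


# ---------------------------------------------------------------------------
# Ranking, uniqueness, clean-up, histone exclusion


def rank_neighborhoods(
    neighborhoods: Sequence[Neighborhood],
    genome_set: GenomeSet,
    params: Parameters,
) -> list[Neighborhood]:
    """Score each candidate, weighting small orthogroups.

    score = rank_scale x [ sum over orthogroups in the neighborhood of
    (orthogroup members inside any candidate neighborhood / total members
    of the orthogroup across all genomes) ] / (genes in the neighborhood).

    Clustered-member counts are global over the full candidate set, so the
    whole candidate list must be passed at once.
    """
    clustered: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for nbhd in neighborhoods:
        for gid in nbhd.genes:
            gene = genome_set.gene(nbhd.genome_id, gid)
            if gene.orthogroup_id is not None:
                clustered[gene.orthogroup_id].add((nbhd.genome_id, gid))
    out = []
    for nbhd in neighborhoods:
        if not nbhd.orthogroups:
            raise ValueError(
                f"{nbhd.neighborhood_id}: no orthogroup-assigned genes"
            )
        total = 0.0
        for og in sorted(nbhd.orthogroups):
            size = genome_set.orthogroup_size(og)
            total += len(clustered[og]) / size
        score = params.rank_scale * total / len(nbhd.genes)
        out.append(replace(nbhd, rank_score=score))
    return out


def _unique_sort_key(nbhd: Neighborhood):
    return (-nbhd.rank_score, -len(nbhd.genes), tuple(sorted(nbhd.genes)),
            nbhd.genome_id)


def filter_unique(neighborhoods: Sequence[Neighborhood]) -> list[Neighborhood]:
    """Greedy sweep in descending rank order; drop any neighborhood whose
    genes intersect an already-retained one. Ties break toward more genes,
    then the lexicographically smallest gene-id tuple."""
    retained: list[Neighborhood] = []
    taken: set[tuple[str, str]] = set()
    for nbhd in sorted(neighborhoods, key=_unique_sort_key):
        keys = {(nbhd.genome_id, g) for g in nbhd.genes}
        if keys & taken:
            continue
        retained.append(nbhd)
        taken |= keys
    return retained


def cleanup(nbhd: Neighborhood) -> Neighborhood:
    """Drop genes that participate in no supporting POG-pair occurrence.

    Gene order and the supporting-pair set are preserved; only interloper
    genes inside the merged window are removed.
    """
    keep: set[str] = set()
    for occs in nbhd.pair_occurrences.values():
        for ga, gb in occs:
            keep.add(ga)
            keep.add(gb)
    genes = [g for g in nbhd.genes if g in keep]
    return replace(nbhd, genes=genes)


def exclude_histones(
    neighborhoods: Sequence[Neighborhood],
    genome_set: GenomeSet,
    params: Parameters,
) -> list[Neighborhood]:
    """Drop neighborhoods dominated by histone annotations.

    Histone genes form conserved tandem arrays that satisfy the proximity
    criteria trivially. A neighborhood is dropped when at least half of
    its *annotated* genes match the keyword "histone" (case-insensitive).
    Unannotated neighborhoods are never dropped. Disabled via
    ``params.histone_filter = False``.
    """
    if not params.histone_filter:
        return list(neighborhoods)
    out = []
    for nbhd in neighborhoods:
        annotated = [
            genome_set.gene(nbhd.genome_id, g).annotation
            for g in nbhd.genes
            if genome_set.gene(nbhd.genome_id, g).annotation is not None
        ]
        n_hist = sum(1 for a in annotated if "histone" in a.lower())
        if annotated and n_hist * 2 >= len(annotated):
            logger.info(
                "histone filter: dropping %s (%d/%d annotated genes)",
                nbhd.neighborhood_id, n_hist, len(annotated),
            )
            continue
        out.append(nbhd)
    return out


# ---------------------------------------------------------------------------
# Summary


def summarize_taxonomy(
    neighborhoods: Sequence[Neighborhood],
    genome_set: GenomeSet,
) -> tuple[dict[str, int], dict[str, int]]:
    """Family counts per taxonomic-class combination + per-genome counts.

    Returns ``(class_combo -> n_families, genome_id -> n_neighborhoods)``;
    a combination key is the sorted class names joined by "+".
    """
    fam_genomes: dict[str, set[str]] = defaultdict(set)
    per_genome: dict[str, int] = defaultdict(int)
    for nbhd in neighborhoods:
        fam_genomes[nbhd.family_id].add(nbhd.genome_id)
        per_genome[nbhd.genome_id] += 1
    combos: dict[str, int] = defaultdict(int)
    for genomes in fam_genomes.values():
        classes = sorted(_classes_of(genome_set, genomes))
        combos["+".join(classes)] += 1
    return dict(combos), dict(per_genome)


# ---------------------------------------------------------------------------
# Full pipeline


def detect(
    genome_set: GenomeSet,
    params: Parameters,
    criteria: Optional[Sequence[int]] = None,
) -> list[Neighborhood]:
    """Run detection end to end.

    collect pairs -> flag criteria -> assemble -> rank -> uniqueness
    filter -> clean-up -> histone exclusion. Returns the final
    neighborhood list (gene-disjoint, each gene supporting >= 1 flagged
    pair).

    ``criteria`` defaults to (1, 2, 3) when an outgroup genome is
    configured and to (1, 3) otherwise; requesting criterion 2 explicitly
    without an outgroup is an error.
    """
    if criteria is None:
        criteria = (1, 2, 3) if genome_set.outgroup_ids() else (1, 3)
    pairs = collect_pog_pairs(genome_set, params)
    logger.info("proximal orthogroup pairs: %d", len(pairs))
    flagged = flag_pairs(pairs, genome_set, params, criteria)
    logger.info("flagged pairs: %d", len(flagged))
    candidates = assemble_neighborhoods(flagged, genome_set, params)
    logger.info("candidate neighborhoods: %d", len(candidates))
    ranked = rank_neighborhoods(candidates, genome_set, params)
    unique = filter_unique(ranked)
    logger.info("after uniqueness filter: %d", len(unique))
    cleaned = [cleanup(n) for n in unique]
    final = exclude_histones(cleaned, genome_set, params)
    logger.info("final neighborhoods: %d", len(final))
    return final
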