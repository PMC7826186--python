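"""Synthetic multi-genome data with planted conserved neighborhoods.

Emulates the study design the detector targets: a panel of ingroup
genomes drawn from a few taxonomic classes plus one distant outgroup,
orthogroups over all genomes, and a mutual-rank coexpression matrix for
one designated genome. Ground truth is explicit: each planted cluster is
a run of adjacent genes whose orthogroups recur adjacently in a configured
subset of genomes, padded on both sides by singleton-orthogroup background
so truth evaluation is unambiguous.

Defaults mirror a 10-genome setup: 9 ingroup genomes over 3 taxonomic
classes plus 1 outgroup in its own class, lognormal gene lengths around
~2 kb, and planted clusters of 4 genes carried by 5 ingroup genomes
spanning 2 classes (enough to satisfy the strictest criterion).

What this emulates and what it does not: gene layouts, orthogroup tables
and MR matrices have the right shapes and the planted signal is real, but
background gene order is random (no residual ancestral synteny), orthology
is error-free, and MR values are iid rather than correlation-structured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .io_model import (
    Gene,
    GenomeRecord,
    GenomeSet,
    MutualRankTable,
    write_gff3,
    write_mutual_ranks,
    write_orthogroups,
)

__all__ = [
    "SimulationConfig",
    "PlantedCluster",
    "simulate_genome_set",
    "simulate_mutual_ranks",
    "write_fixture_dir",
]


@dataclass
class PlantedCluster:
    """Ground truth for one planted conserved neighborhood."""

    cluster_id: str
    orthogroups: list[str]
    carriers: list[str]          # genome ids carrying the cluster
    genes: dict[str, list[str]]  # genome id -> member gene ids (adjacent)


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    ``planted_presence`` is the number of ingroup genomes carrying each
    cluster (chosen to span >= 2 classes); ``planted_in_outgroup`` adds the
    outgroup as a carrier. ``background_shared_og_fraction`` turns that
    fraction of background genes into members of small cross-genome
    orthogroups placed at random (order-scrambled) positions — orthology
    signal without synteny, i.e. detection noise.
    """

    n_ingroup: int = 9
    n_classes: int = 3
    outgroup: bool = True
    chromosomes_per_genome: int = 2
    genes_per_chromosome: int = 100
    gene_length_mean_log: float = 7.6     # lognormal, ~2 kb median
    gene_length_sigma_log: float = 0.6
    gap_mean_log: float = 7.0             # intergenic gap, ~1.1 kb median
    gap_sigma_log: float = 0.8
    n_planted_clusters: int = 3
    planted_cluster_size: int = 4
    planted_presence: int = 5
    planted_in_outgroup: bool = False
    background_shared_og_fraction: float = 0.0
    background_og_size: int = 3
    shuffle_fraction: float = 0.0
    mr_block_strength: float = 5.0
    mr_background_low: float = 1.0
    mr_background_high: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ingroup < 1 or self.n_classes < 1:
            raise ValueError("need >= 1 ingroup genome and >= 1 class")
        if self.n_classes > self.n_ingroup:
            raise ValueError("more classes than ingroup genomes")
        if self.planted_presence > self.n_ingroup:
            raise ValueError("planted_presence exceeds ingroup size")
        if self.planted_cluster_size < 2:
            raise ValueError("planted clusters need >= 2 genes")
        if not (0.0 <= self.background_shared_og_fraction <= 1.0):
            raise ValueError("background_shared_og_fraction in [0, 1]")
        if not (0.0 <= self.shuffle_fraction <= 1.0):
            raise ValueError("shuffle_fraction in [0, 1]")
        if self.planted_cluster_size > self.genes_per_chromosome:
            raise ValueError("planted cluster larger than a chromosome")


def _genome_panel(config: SimulationConfig) -> list[tuple[str, str, str]]:
    """(genome_id, taxonomic_class, role) for the whole panel."""
    panel = []
    for i in range(config.n_ingroup):
        cls = f"class{(i % config.n_classes) + 1}"
        panel.append((f"genome{i + 1:02d}", cls, "ingroup"))
    if config.outgroup:
        panel.append(("outgroup01", "outclass", "outgroup"))
    return panel


def _layout_chromosome(
    genome_id: str, chrom_id: str, n_genes: int, rng: np.random.Generator,
    config: SimulationConfig,
) -> list[Gene]:
    lengths = np.rint(rng.lognormal(
        config.gene_length_mean_log, config.gene_length_sigma_log, n_genes
    )).astype(int)
    gaps = np.rint(rng.lognormal(
        config.gap_mean_log, config.gap_sigma_log, n_genes
    )).astype(int)
    lengths = np.maximum(lengths, 50)
    gaps = np.maximum(gaps, 1)
    genes = []
    pos = 1
    for i in range(n_genes):
        start = pos + int(gaps[i])
        end = start + int(lengths[i]) - 1
        genes.append(Gene(
            gene_id=f"{genome_id}_{chrom_id}_g{i + 1:04d}",
            genome_id=genome_id, chrom_id=chrom_id,
            start=start, end=end,
            strand="+" if rng.random() < 0.5 else "-",
            index=i,
        ))
        pos = end
    return genes


def simulate_genome_set(
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> tuple[GenomeSet, list[PlantedCluster]]:
    """Generate a GenomeSet plus the planted-cluster truth table.

    Each planted cluster occupies ``planted_cluster_size`` adjacent gene
    slots in every carrier genome, with at least one window-length of
    singleton-padding separating clusters (clusters are spread across
    chromosomes and placed on a fixed grid). Carrier sets are chosen to
    span >= 2 taxonomic classes whenever ``planted_presence >= 2``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = _genome_panel(config)
    ingroup_ids = [g for g, _, r in panel if r == "ingroup"]

    slot_stride = config.planted_cluster_size + 12  # >= one window of padding
    max_slots = (config.chromosomes_per_genome
                 * max(0, config.genes_per_chromosome
                       // slot_stride))
    if config.n_planted_clusters > max_slots:
        raise ValueError(
            f"cannot place {config.n_planted_clusters} clusters of size "
            f"{config.planted_cluster_size} in "
            f"{config.chromosomes_per_genome} x "
            f"{config.genes_per_chromosome}-gene chromosomes"
        )
    if config.planted_cluster_size > config.genes_per_chromosome:
        raise ValueError("planted cluster larger than a chromosome")

    # carrier choice: round-robin offset so clusters differ, classes spanned
    clusters: list[PlantedCluster] = []
    for c in range(config.n_planted_clusters):
        # contiguous run over the class-striped ingroup list spans classes
        offset = c % config.n_ingroup
        carriers = [ingroup_ids[(offset + k) % config.n_ingroup]
                    for k in range(config.planted_presence)]
        if config.planted_in_outgroup and config.outgroup:
            carriers = carriers + ["outgroup01"]
        clusters.append(PlantedCluster(
            cluster_id=f"CL{c + 1:03d}",
            orthogroups=[f"OGP{c + 1:03d}_{m + 1}"
                         for m in range(config.planted_cluster_size)],
            carriers=carriers,
            genes={},
        ))

    genomes: dict[str, GenomeRecord] = {}
    orthogroups: dict[str, dict[str, list[str]]] = {}
    og_counter = 0

    # background shared orthogroups: groups of genomes that share a gene
    shared_assignments: dict[tuple[str, str, int], str] = {}
    if config.background_shared_og_fraction > 0:
        n_bg = int(config.background_shared_og_fraction
                   * config.genes_per_chromosome
                   * config.chromosomes_per_genome)
        all_ids = [g for g, _, _ in panel]
        for s in range(n_bg):
            og_id = f"OGS{s + 1:05d}"
            members = rng.choice(
                all_ids, size=min(config.background_og_size, len(all_ids)),
                replace=False,
            )
            for gid in members:
                chrom = int(rng.integers(config.chromosomes_per_genome))
                slot = int(rng.integers(config.genes_per_chromosome))
                shared_assignments[(gid, f"chr{chrom + 1}", slot)] = og_id

    for genome_id, _cls, _role in panel:
        chroms: dict[str, list[Gene]] = {}
        for ci in range(config.chromosomes_per_genome):
            chrom_id = f"chr{ci + 1}"
            chroms[chrom_id] = _layout_chromosome(
                genome_id, chrom_id, config.genes_per_chromosome, rng, config
            )
        genomes[genome_id] = GenomeRecord(
            genome_id=genome_id,
            taxonomic_class=next(c for g, c, _ in panel if g == genome_id),
            role=next(r for g, _, r in panel if g == genome_id),
            chromosomes=chroms,
        )

    # assign orthogroups: planted clusters on a deterministic slot grid
    placement: dict[tuple[str, str, int], str] = {}  # (genome,chrom,idx)->og
    for c, cluster in enumerate(clusters):
        chrom_i = c % config.chromosomes_per_genome
        slot_i = c // config.chromosomes_per_genome
        base = slot_i * slot_stride + 6  # leading padding
        chrom_id = f"chr{chrom_i + 1}"
        for genome_id in cluster.carriers:
            member_ids = []
            # per-genome internal order permuted: conservation of content
            # and adjacency, not of orientation/order
            order = rng.permutation(config.planted_cluster_size)
            for k in range(config.planted_cluster_size):
                idx = base + k
                og = cluster.orthogroups[int(order[k])]
                placement[(genome_id, chrom_id, idx)] = og
                member_ids.append(
                    genomes[genome_id].chromosomes[chrom_id][idx].gene_id
                )
            cluster.genes[genome_id] = member_ids

    for genome_id, _cls, _role in panel:
        rec = genomes[genome_id]
        for chrom_id, genes in rec.chromosomes.items():
            for gene in genes:
                key = (genome_id, chrom_id, gene.index)
                if key in placement:
                    og_id = placement[key]
                elif key in shared_assignments:
                    og_id = shared_assignments[key]
                else:
                    og_counter += 1
                    og_id = f"OGB{og_counter:06d}"  # singleton background
                orthogroups.setdefault(og_id, {}).setdefault(
                    genome_id, []
                ).append(gene.gene_id)

    if config.shuffle_fraction > 0:
        _shuffle_background(genomes, orthogroups, placement, rng,
                            config.shuffle_fraction)

    gs = GenomeSet(genomes=genomes, orthogroups=orthogroups)
    return gs, clusters


def _shuffle_background(
    genomes: dict[str, GenomeRecord],
    orthogroups: dict[str, dict[str, list[str]]],
    placement: dict,
    rng: np.random.Generator,
    fraction: float,
) -> None:
    """Swap orthogroup labels between random background gene pairs within
    each genome, scrambling any residual background order conservation."""
    gene_og = {
        (gid, members_gid): og
        for og, per in orthogroups.items()
        for gid, mem in per.items()
        for members_gid in mem
    }
    for genome_id, rec in genomes.items():
        background = [
            g for g in rec.genes()
            if (genome_id, g.chrom_id, g.index) not in placement
        ]
        n_swap = int(fraction * len(background) / 2)
        for _ in range(n_swap):
            i, j = rng.integers(len(background), size=2)
            a, b = background[int(i)], background[int(j)]
            og_a = gene_og[(genome_id, a.gene_id)]
            og_b = gene_og[(genome_id, b.gene_id)]
            if og_a == og_b:
                continue
            mem_a = orthogroups[og_a][genome_id]
            mem_b = orthogroups[og_b][genome_id]
            mem_a[mem_a.index(a.gene_id)] = b.gene_id
            mem_b[mem_b.index(b.gene_id)] = a.gene_id
            gene_og[(genome_id, a.gene_id)] = og_b
            gene_og[(genome_id, b.gene_id)] = og_a


def simulate_mutual_ranks(
    genome: GenomeRecord,
    config: SimulationConfig,
    coexpressed_blocks: Sequence[Sequence[str]] = (),
    seed: Optional[int] = None,
) -> MutualRankTable:
    """Mutual-rank table with full coverage of one genome's genes.

    Background pairs are iid Uniform(mr_background_low, mr_background_high);
    pairs inside a designated coexpressed block get ``mr_block_strength``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gene_ids = [g.gene_id for g in genome.genes()]
    block_pairs: set[tuple[str, str]] = set()
    for block in coexpressed_blocks:
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                a, b = block[i], block[j]
                block_pairs.add((a, b) if a < b else (b, a))
    table = MutualRankTable()
    n = len(gene_ids)
    values = rng.uniform(config.mr_background_low, config.mr_background_high,
                         n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = gene_ids[i], gene_ids[j]
            key = (a, b) if a < b else (b, a)
            if key in block_pairs:
                table.set(a, b, config.mr_block_strength)
            else:
                table.set(a, b, float(values[k]))
            k += 1
    return table


def write_fixture_dir(
    out_dir: str | Path,
    config: SimulationConfig,
    seed: Optional[int] = None,
    mr_genome: Optional[str] = None,
    mr_blocks_from_truth: bool = True,
) -> tuple[GenomeSet, list[PlantedCluster]]:
    """Simulate and write a complete fixture directory.

    Emits one GFF3 per genome, ``Orthogroups.tsv``, ``taxonomy.yaml``,
    ``truth.tsv`` and — for ``mr_genome`` (default: the first ingroup
    genome) — ``mr.tsv`` with planted clusters as low-MR blocks when
    ``mr_blocks_from_truth`` is set. Same seed, same bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    use_seed = config.seed if seed is None else seed
    gs, clusters = simulate_genome_set(config, seed=use_seed)

    tax_records = []
    for genome_id, rec in gs.genomes.items():
        gff_name = f"{genome_id}.gff3"
        write_gff3(list(rec.genes()), out / gff_name)
        tax_records.append({
            "genome_id": genome_id,
            "taxonomic_class": rec.taxonomic_class,
            "role": rec.role,
            "gff": gff_name,
        })
    (out / "taxonomy.yaml").write_text(
        yaml.safe_dump({"genomes": tax_records}, sort_keys=False)
    )
    write_orthogroups(gs.orthogroups, list(gs.genomes), out / "Orthogroups.tsv")

    with open(out / "truth.tsv", "w") as fh:
        fh.write("cluster_id\torthogroups\tcarriers\tgenes\n")
        for cl in clusters:
            gene_field = ";".join(
                f"{g}:{','.join(cl.genes[g])}" for g in cl.carriers
            )
            fh.write(
                f"{cl.cluster_id}\t{','.join(cl.orthogroups)}\t"
                f"{','.join(cl.carriers)}\t{gene_field}\n"
            )

    if mr_genome is None:
        ingroups = [g for g, r in gs.genomes.items() if r.role == "ingroup"]
        mr_genome = ingroups[0] if ingroups else list(gs.genomes)[0]
    blocks = []
    if mr_blocks_from_truth:
        blocks = [cl.genes[mr_genome] for cl in clusters
                  if mr_genome in cl.genes]
    table = simulate_mutual_ranks(
        gs.genomes[mr_genome], config, coexpressed_blocks=blocks,
        seed=use_seed + 1,
    )
    write_mutual_ranks(table, out / "mr.tsv")

    (out / "sim_config.yaml").write_text(
        yaml.safe_dump({**asdict(config), "seed": use_seed},
                       sort_keys=False)
    )
    return gs, clusters
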