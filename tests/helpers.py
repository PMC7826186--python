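"""Shared builders for randomized small genome sets used across tests."""

from __future__ import annotations

import numpy as np

from pogscan.io_model import Gene, GenomeRecord, GenomeSet, Parameters


def make_genome(genome_id: str, chrom_layouts: dict[str, list[tuple]],
                taxonomic_class: str = "classA",
                role: str = "ingroup") -> GenomeRecord:
    """chrom_layouts: chrom_id -> [(gene_id, start, end), ...]."""
    chroms = {}
    for chrom_id, rows in chrom_layouts.items():
        genes = [
            Gene(gene_id=gid, genome_id=genome_id, chrom_id=chrom_id,
                 start=s, end=e)
            for gid, s, e in rows
        ]
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(genes):
            g.index = i
        chroms[chrom_id] = genes
    return GenomeRecord(genome_id=genome_id, taxonomic_class=taxonomic_class,
                        role=role, chromosomes=chroms)


def assemble_genome_set(genomes: list[GenomeRecord],
                        og_of: dict[tuple[str, str], str]) -> GenomeSet:
    """Build a GenomeSet from explicit (genome_id, gene_id) -> og labels."""
    orthogroups: dict[str, dict[str, list[str]]] = {}
    for (genome_id, gene_id), og in og_of.items():
        orthogroups.setdefault(og, {}).setdefault(genome_id, []).append(
            gene_id
        )
    return GenomeSet(genomes={g.genome_id: g for g in genomes},
                     orthogroups=orthogroups)


def random_genome_set(rng: np.random.Generator,
                      max_genomes: int = 5,
                      max_genes: int = 50,
                      with_outgroup: bool | None = None) -> GenomeSet:
    """A small random genome set with recurring orthogroup labels.

    Orthogroup labels are drawn from a small pool so proximal pairings
    recur across genomes often enough to exercise every criterion.
    """
    n_genomes = int(rng.integers(2, max_genomes + 1))
    if with_outgroup is None:
        with_outgroup = bool(rng.random() < 0.5) and n_genomes >= 3
    pool = [f"OG{i:03d}" for i in range(int(rng.integers(6, 16)))]
    classes = ["classA", "classB", "classC"]
    genomes = []
    og_of: dict[tuple[str, str], str] = {}
    for gi in range(n_genomes):
        genome_id = f"G{gi + 1}"
        role = ("outgroup"
                if with_outgroup and gi == n_genomes - 1 else "ingroup")
        cls = ("outclass" if role == "outgroup"
               else classes[gi % len(classes)])
        n_chrom = int(rng.integers(1, 3))
        layouts = {}
        n_total = int(rng.integers(8, max_genes + 1))
        per_chrom = max(2, n_total // n_chrom)
        gcount = 0
        for ci in range(n_chrom):
            rows = []
            pos = 1
            for _ in range(per_chrom):
                gcount += 1
                gid = f"{genome_id}_g{gcount:03d}"
                start = pos + int(rng.integers(1, 2000))
                end = start + int(rng.integers(100, 3000))
                rows.append((gid, start, end))
                pos = end
                if rng.random() < 0.85:
                    og_of[(genome_id, gid)] = str(rng.choice(pool))
            layouts[f"chr{ci + 1}"] = rows
        genomes.append(make_genome(genome_id, layouts, cls, role))
    return assemble_genome_set(genomes, og_of)


def random_params(rng: np.random.Generator) -> Parameters:
    return Parameters(
        window_size=int(rng.choice([2, 4, 6])),
        min_genomes_c1=int(rng.choice([2, 3, 4])),
        min_classes=int(rng.choice([1, 2])),
        min_genomes_c23=int(rng.choice([2, 3])),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
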