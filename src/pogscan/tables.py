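"""Plain-TSV output tables with '#' provenance headers.

All data files the pipeline emits are tab-separated text. Comment lines
starting with '#' record the tool version, the full parameter snapshot and
the seed, so a result file is self-describing; identical inputs and seed
reproduce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .coexpression import CoexpressionResult
from .io_model import GenomeSet, Parameters
from .neighborhoods import Neighborhood

__all__ = [
    "write_neighborhoods_tsv",
    "read_neighborhoods_tsv",
    "write_families_tsv",
    "write_coexpression_tsv",
    "write_summary_tsv",
]


def _header(params: Optional[Parameters]) -> str:
    lines = [f"# pogscan {__version__}"]
    if params is not None:
        lines.append("# parameters: "
                     + json.dumps(params.as_dict(), sort_keys=True))
        lines.append(f"# seed: {params.seed}")
    return "\n".join(lines) + "\n"


def write_neighborhoods_tsv(
    neighborhoods: Sequence[Neighborhood],
    path: str | Path,
    params: Optional[Parameters] = None,
) -> None:
    cols = ["neighborhood_id", "family_id", "genome_id", "chrom_id",
            "gene_ids", "orthogroup_ids", "criteria", "rank_score",
            "n_pog_pairs"]
    with open(path, "w") as fh:
        fh.write(_header(params))
        fh.write("\t".join(cols) + "\n")
        for n in neighborhoods:
            score = "" if n.rank_score is None else f"{n.rank_score:.6f}"
            fh.write("\t".join([
                n.neighborhood_id,
                n.family_id or "",
                n.genome_id,
                n.chrom_id,
                ",".join(n.genes),
                ",".join(sorted(n.orthogroups)),
                ";".join(str(c) for c in sorted(n.criteria)),
                score,
                str(len(n.supporting_pairs)),
            ]) + "\n")


def read_neighborhoods_tsv(path: str | Path) -> list[Neighborhood]:
    """Read a neighborhoods TSV back into (partial) Neighborhood objects.

    Supporting-pair occurrence detail is not serialized, so
    ``pair_occurrences`` comes back empty and ``supporting_pairs`` is a
    placeholder of the recorded size; genes, ids, criteria and scores are
    faithful.
    """
    out: list[Neighborhood] = []
    with open(path) as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rec = dict(zip(header, line.split("\t")))
            n_pairs = int(rec["n_pog_pairs"])
            out.append(Neighborhood(
                neighborhood_id=rec["neighborhood_id"],
                genome_id=rec["genome_id"],
                chrom_id=rec["chrom_id"],
                genes=rec["gene_ids"].split(",") if rec["gene_ids"] else [],
                orthogroups=frozenset(
                    rec["orthogroup_ids"].split(",")
                    if rec["orthogroup_ids"] else []
                ),
                supporting_pairs=frozenset(
                    (f"?", f"?{i}") for i in range(n_pairs)
                ),
                pair_occurrences={},
                criteria=frozenset(
                    int(c) for c in rec["criteria"].split(";") if c
                ),
                rank_score=(float(rec["rank_score"])
                            if rec["rank_score"] else None),
                family_id=rec["family_id"] or None,
            ))
    return out


def write_families_tsv(
    neighborhoods: Sequence[Neighborhood],
    genome_set: GenomeSet,
    path: str | Path,
    params: Optional[Parameters] = None,
) -> None:
    """One row per family: members, shared orthogroups, class combination."""
    families: dict[str, list[Neighborhood]] = {}
    for n in neighborhoods:
        families.setdefault(n.family_id, []).append(n)
    with open(path, "w") as fh:
        fh.write(_header(params))
        fh.write("family_id\tgenome_ids\tshared_orthogroups\t"
                 "class_combination\n")
        for fam_id in sorted(families):
            members = families[fam_id]
            genomes = sorted({n.genome_id for n in members})
            shared = frozenset.intersection(
                *(n.orthogroups for n in members)
            )
            classes = sorted({
                genome_set.genomes[g].taxonomic_class for g in genomes
            })
            fh.write("\t".join([
                fam_id,
                ",".join(genomes),
                ",".join(sorted(shared)),
                "+".join(classes),
            ]) + "\n")


def write_coexpression_tsv(
    results: Sequence[CoexpressionResult],
    path: str | Path,
    params: Optional[Parameters] = None,
) -> None:
    def fmt(x, spec="{:.6f}"):
        return "" if x is None else spec.format(x)

    with open(path, "w") as fh:
        fh.write(_header(params))
        fh.write("neighborhood_id\teffective_size\tscore\tthreshold\t"
                 "n_boot\tsignificant\tn_missing_mr\tseed\n")
        for r in results:
            sig = "" if r.significant is None else str(r.significant).lower()
            fh.write("\t".join([
                r.neighborhood_id, str(r.effective_size),
                fmt(r.score), fmt(r.threshold), str(r.null_n), sig,
                str(r.n_missing_mr), str(r.seed),
            ]) + "\n")


def write_summary_tsv(
    combos: dict[str, int],
    per_genome: dict[str, int],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pogscan {__version__}\n")
        fh.write("record_type\tkey\tcount\n")
        for combo in sorted(combos):
            fh.write(f"family_class_combination\t{combo}\t{combos[combo]}\n")
        for genome in sorted(per_genome):
            fh.write(f"genome_neighborhoods\t{genome}\t{per_genome[genome]}\n")
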