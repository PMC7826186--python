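"""Domain types and file I/O for conserved gene-neighborhood detection.

The package works from three kinds of primary input:

* per-genome gene models (GFF3, gene-level features, 1-based inclusive
  coordinates),
* an orthogroup membership table in the OrthoFinder ``Orthogroups.tsv``
  dialect (tab-separated; first column the orthogroup id, one column per
  genome, cells comma-separated gene ids),
* a taxonomy configuration (YAML or TSV) mapping each genome to a
  taxonomic class and to its role as ingroup or outgroup.

Optional inputs are a functional-annotation table (gene id -> free-text
description, used by the histone-array exclusion filter) and a mutual-rank
coexpression table (long format or square labelled matrix).

Coordinates stay 1-based inclusive end-to-end; gene length is
``end - start + 1``. Gene order on a chromosome is the 0-based ``index``
obtained by sorting on ``(start, end, gene_id)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml
from gffutils.feature import feature_from_line

__all__ = [
    "Gene",
    "GenomeRecord",
    "GenomeSet",
    "Parameters",
    "MutualRankTable",
    "GFF3ParseError",
    "read_gff3",
    "write_gff3",
    "read_orthogroups",
    "write_orthogroups",
    "read_taxonomy",
    "read_annotations",
    "read_mutual_ranks",
    "write_mutual_ranks",
    "load_genome_set",
]


class GFF3ParseError(ValueError):
    """Raised for malformed GFF3 input, naming the offending line."""


@dataclass
class Gene:
    """One gene model.

    ``start``/``end`` are 1-based inclusive (GFF3 convention); ``index`` is
    the 0-based rank of the gene on its chromosome ordered by
    ``(start, end, gene_id)``.
    """

    gene_id: str
    genome_id: str
    chrom_id: str
    start: int
    end: int
    strand: str = "."
    index: int = -1
    orthogroup_id: Optional[str] = None
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """One genome: taxonomy metadata plus ordered per-chromosome gene lists."""

    genome_id: str
    taxonomic_class: str
    role: str  # "ingroup" | "outgroup"
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in {"ingroup", "outgroup"}:
            raise ValueError(
                f"genome {self.genome_id}: role must be ingroup|outgroup, "
                f"got {self.role!r}"
            )
        if not self.taxonomic_class:
            raise ValueError(f"genome {self.genome_id}: empty taxonomic_class")

    def genes(self) -> Iterable[Gene]:
        for chrom in self.chromosomes.values():
            yield from chrom

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes.values())


@dataclass
class GenomeSet:
    """All genomes under comparison plus the orthogroup map.

    ``orthogroups`` maps orthogroup id -> {genome id -> [gene ids]}. On
    construction every orthogroup member is resolved against the gene
    layouts; members are required to resolve uniquely and a gene may belong
    to at most one orthogroup. Orthogroup ids are stamped onto the ``Gene``
    objects.
    """

    genomes: dict[str, GenomeRecord]
    orthogroups: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ValueError("GenomeSet requires at least one genome")
        self._gene_index: dict[tuple[str, str], Gene] = {}
        for rec in self.genomes.values():
            for gene in rec.genes():
                key = (rec.genome_id, gene.gene_id)
                if key in self._gene_index:
                    raise ValueError(
                        f"duplicate gene id {gene.gene_id!r} in genome "
                        f"{rec.genome_id!r}"
                    )
                self._gene_index[key] = gene
        seen: dict[tuple[str, str], str] = {}
        for og_id, per_genome in self.orthogroups.items():
            for genome_id, members in per_genome.items():
                if genome_id not in self.genomes:
                    raise ValueError(
                        f"orthogroup {og_id}: unknown genome {genome_id!r}"
                    )
                for gid in members:
                    key = (genome_id, gid)
                    if key not in self._gene_index:
                        raise ValueError(
                            f"orthogroup {og_id}: gene {gid!r} not found in "
                            f"genome {genome_id!r}"
                        )
                    prev = seen.get(key)
                    if prev is not None and prev != og_id:
                        raise ValueError(
                            f"gene {gid!r} ({genome_id}) listed in two "
                            f"orthogroups: {prev}, {og_id}"
                        )
                    seen[key] = og_id
                    self._gene_index[key].orthogroup_id = og_id

    def gene(self, genome_id: str, gene_id: str) -> Gene:
        return self._gene_index[(genome_id, gene_id)]

    def has_gene(self, genome_id: str, gene_id: str) -> bool:
        return (genome_id, gene_id) in self._gene_index

    def ingroup_ids(self) -> list[str]:
        return [g for g, r in self.genomes.items() if r.role == "ingroup"]

    def outgroup_ids(self) -> list[str]:
        return [g for g, r in self.genomes.items() if r.role == "outgroup"]

    def orthogroup_size(self, og_id: str) -> int:
        """Total number of member genes across all genomes."""
        return sum(len(v) for v in self.orthogroups.get(og_id, {}).values())

    def set_annotations(
        self, genome_id: str, annotations: Mapping[str, str]
    ) -> None:
        for gid, desc in annotations.items():
            key = (genome_id, gid)
            if key in self._gene_index:
                self._gene_index[key].annotation = desc


@dataclass
class Parameters:
    """Every numeric setting of the detection and coexpression pipeline.

    window_size
        Search window in genes. The per-chromosome span in bp is the mean
        gene length on the chromosome times this value. Default 6.
    min_genomes_c1
        Criterion 1: minimum ingroup genomes in which a pair must be
        proximal. Default 4.
    min_classes
        Minimum distinct taxonomic classes among supporting genomes
        (criteria 1 and 3). Default 2.
    min_genomes_c23
        Relaxed species minimum for criteria 2 and 3. Default 3.
    min_pog_pairs
        Distinct proximal-orthologous-gene pairs required to call a
        neighborhood. Default 2.
    rank_scale
        Multiplier of the neighborhood rank score. Default 10.
    mr_cap
        Mutual ranks above this contribute the cap. Default 1000.
    bootstrap_n
        Random neighborhoods per null distribution. Default 5000.
    quantile
        Lower-tail significance quantile. Default 0.01.
    seed
        Master seed for every random draw.
    histone_filter
        Drop neighborhoods dominated by histone annotations. Default True.
    proximity_metric
        "bp" (start-coordinate distance vs the bp span, default) or
        "index" (gene-rank distance <= window_size - 1).
    """

    window_size: int = 6
    min_genomes_c1: int = 4
    min_classes: int = 2
    min_genomes_c23: int = 3
    min_pog_pairs: int = 2
    rank_scale: float = 10.0
    mr_cap: float = 1000.0
    bootstrap_n: int = 5000
    quantile: float = 0.01
    seed: int = 0
    histone_filter: bool = True
    proximity_metric: str = "bp"

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0.0 < self.quantile < 1.0):
            raise ValueError("quantile must lie strictly between 0 and 1")
        for name in ("min_genomes_c1", "min_classes", "min_genomes_c23",
                     "min_pog_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bootstrap_n < 1:
            raise ValueError("bootstrap_n must be >= 1")
        if self.mr_cap <= 0 or self.rank_scale <= 0:
            raise ValueError("mr_cap and rank_scale must be positive")
        if self.proximity_metric not in {"bp", "index"}:
            raise ValueError("proximity_metric must be 'bp' or 'index'")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class MutualRankTable:
    """Symmetric gene-by-gene mutual ranks with missing-data semantics.

    Mutual rank is the geometric mean of the two directional coexpression
    ranks of a gene pair; lower means more strongly coexpressed. Lookups
    are unordered; a pair absent from the table returns ``None``.
    """

    def __init__(self, pairs: Optional[Mapping[tuple[str, str], float]] = None):
        self._mr: dict[tuple[str, str], float] = {}
        self._genes: set[str] = set()
        if pairs:
            for (a, b), value in pairs.items():
                self.set(a, b, value)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        if a == b:
            raise ValueError(f"mutual rank of a gene with itself: {a!r}")
        return (a, b) if a < b else (b, a)

    def set(self, a: str, b: str, value: float) -> None:
        value = float(value)
        if not value > 0:
            raise ValueError(
                f"mutual rank must be positive: ({a},{b}) = {value}"
            )
        key = self._key(a, b)
        prev = self._mr.get(key)
        if prev is not None and prev != value:
            raise ValueError(
                f"conflicting mutual ranks for pair {key}: {prev} vs {value}"
            )
        self._mr[key] = value
        self._genes.add(a)
        self._genes.add(b)

    def lookup(self, a: str, b: str) -> Optional[float]:
        return self._mr.get(self._key(a, b))

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._genes)

    def __len__(self) -> int:
        return len(self._mr)

    def items(self) -> Iterable[tuple[tuple[str, str], float]]:
        return self._mr.items()


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path: str | Path,
    genome_id: str,
    feature_type: str = "gene",
    id_regex: Optional[str] = None,
) -> list[Gene]:
    """Parse gene-level features from a GFF3 file.

    Only records whose type equals ``feature_type`` are kept; each must
    carry an ``ID`` attribute. ``id_regex``, if given, is a pattern whose
    matches are stripped from the ID (e.g. ``r"\\.t\\d+$"`` to remove
    transcript suffixes) so ids line up with orthogroup tables. Per
    chromosome, genes are sorted by ``(start, end, gene_id)`` and given
    0-based indices.
    """
    strip = re.compile(id_regex) if id_regex else None
    by_chrom: dict[str, list[Gene]] = {}
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            if line.startswith(">"):  # embedded FASTA without ##FASTA marker
                break
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated "
                    f"columns, found {len(cols)}"
                )
            if cols[2] != feature_type:
                continue
            try:
                feat = feature_from_line(line)
                start, end = int(cols[3]), int(cols[4])
            except Exception as exc:
                raise GFF3ParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            ids = feat.attributes.get("ID")
            if not ids:
                raise GFF3ParseError(
                    f"{path}: line {lineno}: {feature_type} feature lacks "
                    "an ID attribute"
                )
            gid = strip.sub("", ids[0]) if strip else ids[0]
            if gid in seen_ids:
                raise GFF3ParseError(
                    f"{path}: line {lineno}: duplicate gene ID {gid!r} in "
                    f"genome {genome_id!r}"
                )
            seen_ids.add(gid)
            strand = cols[6] if cols[6] in {"+", "-"} else "."
            by_chrom.setdefault(cols[0], []).append(
                Gene(gene_id=gid, genome_id=genome_id, chrom_id=cols[0],
                     start=start, end=end, strand=strand)
            )
    out: list[Gene] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(genes):
            g.index = i
        out.extend(genes)
    return out


def write_gff3(genes: Sequence[Gene], path: str | Path,
               source: str = "pogscan") -> None:
    """Write gene features as GFF3 (chromosome order, then start)."""
    ordered = sorted(genes, key=lambda g: (g.chrom_id, g.start, g.end, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ordered:
            fh.write(
                f"{g.chrom_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Orthogroups (OrthoFinder Orthogroups.tsv dialect)


def read_orthogroups(path: str | Path) -> dict[str, dict[str, list[str]]]:
    """Read an ``Orthogroups.tsv``-style table.

    First column: orthogroup id (header cell ignored). Remaining columns:
    one per genome; cells hold comma-separated gene ids or are empty.
    A gene listed under two orthogroups is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    genome_ids = list(df.columns[1:])
    result: dict[str, dict[str, list[str]]] = {}
    owner: dict[tuple[str, str], str] = {}
    for row in df.itertuples(index=False):
        og_id = row[0]
        if og_id in result:
            raise ValueError(f"{path}: duplicate orthogroup id {og_id!r}")
        per_genome: dict[str, list[str]] = {}
        for genome_id, cell in zip(genome_ids, row[1:]):
            members = [tok.strip() for tok in cell.split(",") if tok.strip()]
            for gid in members:
                key = (genome_id, gid)
                if key in owner:
                    raise ValueError(
                        f"{path}: gene {gid!r} ({genome_id}) appears in "
                        f"orthogroups {owner[key]} and {og_id}"
                    )
                owner[key] = og_id
            per_genome[genome_id] = members
        result[og_id] = per_genome
    return result


def write_orthogroups(
    orthogroups: Mapping[str, Mapping[str, Sequence[str]]],
    genome_ids: Sequence[str],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(genome_ids) + "\n")
        for og_id in sorted(orthogroups):
            cells = [
                ", ".join(orthogroups[og_id].get(g, [])) for g in genome_ids
            ]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Taxonomy / annotations / mutual ranks


def read_taxonomy(path: str | Path) -> list[dict]:
    """Read the genome panel configuration.

    YAML: a list (or a mapping with key ``genomes``) of records with keys
    ``genome_id``, ``taxonomic_class``, ``role`` (ingroup|outgroup),
    ``gff`` and optional ``annotation``. TSV: the same fields as columns.
    Relative paths are kept as written; ``load_genome_set`` resolves them
    against the config file's directory.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        if isinstance(data, Mapping):
            data = data.get("genomes", data)
        records = list(data)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        records = df.to_dict("records")
    out = []
    for rec in records:
        out.append({
            "genome_id": str(rec["genome_id"]),
            "taxonomic_class": str(rec["taxonomic_class"]),
            "role": str(rec["role"]),
            "gff": rec.get("gff"),
            "annotation": rec.get("annotation") or None,
        })
    return out


def read_annotations(path: str | Path) -> dict[str, str]:
    """Gene id -> free-text description, two-column TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation table needs >= 2 columns")
    first = df.iloc[0]
    if first[0].lower() in {"gene_id", "gene", "id"}:
        df = df.iloc[1:]
    return dict(zip(df[0], df[1]))


def read_mutual_ranks(path: str | Path) -> MutualRankTable:
    """Read a mutual-rank table, long format or square labelled matrix.

    Long format: three columns ``gene_a  gene_b  mr`` (header optional).
    Square: first column row labels, header column labels; the matrix must
    be symmetric where both triangles are present. Empty / NA cells in a
    matrix mean "missing". Duplicated consistent pairs are accepted;
    conflicting values are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = MutualRankTable()
    if df.shape[1] == 3:
        header = list(df.columns)
        rows = [tuple(header)] if _looks_like_long_row(header) else []
        rows += [tuple(r) for r in df.itertuples(index=False)]
        for a, b, raw in rows:
            try:
                value = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: unparseable mutual rank {raw!r} for "
                    f"pair ({a}, {b})"
                ) from exc
            table.set(a, b, value)
    else:
        labels = list(df.columns[1:])
        for row in df.itertuples(index=False):
            a = row[0]
            for b, raw in zip(labels, row[1:]):
                if a == b or raw == "" or raw.lower() in {"na", "nan"}:
                    continue
                try:
                    value = float(raw)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: unparseable mutual rank {raw!r} at "
                        f"({a}, {b})"
                    ) from exc
                table.set(a, b, value)
    return table


def _looks_like_long_row(cells: Sequence[str]) -> bool:
    """True when a 3-tuple is a data row (third cell numeric), not a header."""
    try:
        float(cells[2])
    except (ValueError, TypeError):
        return False
    return True


def write_mutual_ranks(table: MutualRankTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tmr\n")
        for (a, b), value in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Assembly


def load_genome_set(
    taxonomy_path: str | Path,
    orthogroups_path: str | Path,
    feature_type: str = "gene",
    id_regex: Optional[str] = None,
) -> GenomeSet:
    """Assemble a :class:`GenomeSet` from a taxonomy config + orthogroup TSV.

    GFF and annotation paths in the taxonomy config are resolved relative
    to the config file's own directory. Genomes named in the orthogroup
    table but absent from the taxonomy config are an error.
    """
    base = Path(taxonomy_path).parent
    records = read_taxonomy(taxonomy_path)
    genomes: dict[str, GenomeRecord] = {}
    annotations: dict[str, dict[str, str]] = {}
    for rec in records:
        gff = Path(rec["gff"])
        if not gff.is_absolute():
            gff = base / gff
        genes = read_gff3(gff, rec["genome_id"], feature_type=feature_type,
                          id_regex=id_regex)
        chroms: dict[str, list[Gene]] = {}
        for g in genes:
            chroms.setdefault(g.chrom_id, []).append(g)
        genomes[rec["genome_id"]] = GenomeRecord(
            genome_id=rec["genome_id"],
            taxonomic_class=rec["taxonomic_class"],
            role=rec["role"],
            chromosomes=chroms,
        )
        if rec["annotation"]:
            ann = Path(rec["annotation"])
            if not ann.is_absolute():
                ann = base / ann
            annotations[rec["genome_id"]] = read_annotations(ann)
    orthogroups = read_orthogroups(orthogroups_path)
    for per_genome in orthogroups.values():
        for genome_id in per_genome:
            if genome_id not in genomes:
                raise ValueError(
                    f"orthogroup table names genome {genome_id!r} absent "
                    "from the taxonomy config"
                )
    gs = GenomeSet(genomes=genomes, orthogroups=orthogroups)
    for genome_id, ann in annotations.items():
        gs.set_annotations(genome_id, ann)
    return gs
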