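"""Literal brute-force reference implementation used as a test oracle.

Everything here is written as a direct transcription of the method's
definitions — exhaustive pair enumeration, set-based fixpoint window
merging — with no sharing of code paths with the package. It is
deliberately slow and simple.
"""

from __future__ import annotations

from itertools import combinations

from pogscan.io_model import GenomeSet, Parameters


def brute_occurrences(genome_set: GenomeSet, params: Parameters):
    """occurrences[(og_a, og_b)][genome_id] = set of (chrom, ga, gb).

    Tests every unordered gene pair on every chromosome literally.
    """
    occ: dict = {}
    for genome in genome_set.genomes.values():
        for chrom_id, genes in genome.chromosomes.items():
            mean_len = sum(g.end - g.start + 1 for g in genes) / len(genes)
            span = mean_len * params.window_size
            for a, b in combinations(genes, 2):
                if params.proximity_metric == "bp":
                    close = abs(a.start - b.start) <= span
                else:
                    close = abs(a.index - b.index) <= params.window_size - 1
                if not close:
                    continue
                if a.orthogroup_id is None or b.orthogroup_id is None:
                    continue
                if a.orthogroup_id == b.orthogroup_id:
                    continue
                key = tuple(sorted((a.orthogroup_id, b.orthogroup_id)))
                lo, hi = sorted((a, b), key=lambda g: g.index)
                occ.setdefault(key, {}).setdefault(
                    genome.genome_id, set()
                ).add((chrom_id, lo.gene_id, hi.gene_id))
    return occ


def brute_flagged(genome_set: GenomeSet, params: Parameters,
                  criteria=(1, 2, 3)):
    """key -> set of criteria, evaluated literally per definition."""
    occ = brute_occurrences(genome_set, params)
    ingroup = {g for g, r in genome_set.genomes.items() if r.role == "ingroup"}
    outgroup = [g for g, r in genome_set.genomes.items()
                if r.role == "outgroup"]

    def classes(genome_ids):
        return {genome_set.genomes[g].taxonomic_class for g in genome_ids}

    flagged: dict = {}
    for key, support in occ.items():
        og_a, og_b = key
        crits = set()
        supp = set(support)
        if 1 in criteria:
            in_supp = supp & ingroup
            if (len(in_supp) >= params.min_genomes_c1
                    and len(classes(in_supp)) >= params.min_classes):
                crits.add(1)
        if 2 in criteria and len(outgroup) == 1:
            if (outgroup[0] in supp
                    and len(supp & ingroup) >= params.min_genomes_c23 - 1):
                crits.add(2)
        if 3 in criteria:
            present = {
                g for g in genome_set.genomes
                if genome_set.orthogroups.get(og_a, {}).get(g)
                and genome_set.orthogroups.get(og_b, {}).get(g)
            }
            if (supp == present
                    and len(supp) >= params.min_genomes_c23
                    and len(classes(supp)) >= params.min_classes):
                crits.add(3)
        if crits:
            flagged[key] = crits
    return flagged, occ


def brute_neighborhoods(genome_set: GenomeSet, params: Parameters,
                        criteria=(1, 2, 3)):
    """Candidate neighborhoods by set-based fixpoint window merging.

    Returns a set of (genome_id, chrom_id, frozenset(gene_ids),
    frozenset(pair_keys)) for merged windows with >= min_pog_pairs
    distinct flagged pairs.
    """
    flagged, occ = brute_flagged(genome_set, params, criteria)
    result = set()
    for genome in genome_set.genomes.values():
        for chrom_id, genes in genome.chromosomes.items():
            by_id = {g.gene_id: g for g in genes}
            windows = []  # gene-id sets, one per flagged occurrence here
            for key in flagged:
                for (c, ga, gb) in occ[key].get(genome.genome_id, ()):
                    if c != chrom_id:
                        continue
                    ia, ib = by_id[ga].index, by_id[gb].index
                    members = frozenset(
                        g.gene_id for g in genes
                        if min(ia, ib) <= g.index <= max(ia, ib)
                    )
                    windows.append(set(members))
            # fixpoint transitive merge of gene-sharing windows
            changed = True
            while changed:
                changed = False
                for i in range(len(windows)):
                    for j in range(i + 1, len(windows)):
                        if windows[i] & windows[j]:
                            windows[i] |= windows[j]
                            del windows[j]
                            changed = True
                            break
                    if changed:
                        break
            for w in windows:
                pairs = frozenset(
                    key for key in flagged
                    if any(c == chrom_id and ga in w and gb in w
                           for (c, ga, gb) in occ[key].get(
                               genome.genome_id, ()))
                )
                if len(pairs) >= params.min_pog_pairs:
                    result.add((genome.genome_id, chrom_id,
                                frozenset(w), pairs))
    return result
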