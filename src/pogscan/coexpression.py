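"""Mutual-rank coexpression scoring of gene neighborhoods.

A neighborhood's coexpression score is the sum of pairwise mutual ranks
(MR) over its genes after reducing each orthogroup to one representative
(tandem duplicates would otherwise score against themselves), with every
pairwise MR capped at ``mr_cap`` (default 1000). Lower scores mean
stronger coexpression.

Significance is calibrated empirically: for each effective neighborhood
size k, ``bootstrap_n`` (default 5000) random contiguous runs of k genes
are drawn from the genome layout and scored identically; a neighborhood is
significant when its score falls within the lowest ``quantile`` (default
1%) of that size-matched null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_model import GenomeRecord, MutualRankTable, Parameters
from .neighborhoods import Neighborhood

__all__ = [
    "CoexpressionResult",
    "coexpression_score",
    "bootstrap_null",
    "test_neighborhoods",
]


@dataclass
class CoexpressionResult:
    neighborhood_id: str
    effective_size: int          # genes entering pairwise scoring
    score: Optional[float]       # None when untestable
    null_n: int
    threshold: Optional[float]   # empirical lower-tail quantile of the null
    significant: Optional[bool]  # None when untestable
    n_missing_mr: int
    seed: int


def _reduce_same_orthogroup(
    genes: Sequence[str],
    gene_to_og: Mapping[str, Optional[str]],
    mode: str = "representative",
) -> list[str]:
    """Keep the first gene (input = chromosomal order) of each orthogroup.

    Genes without an orthogroup are all kept. ``mode="pairs"`` keeps every
    gene (same-orthogroup *pairs* are then skipped during summation)."""
    if mode == "pairs":
        return list(genes)
    seen: set[str] = set()
    kept = []
    for g in genes:
        og = gene_to_og.get(g)
        if og is None:
            kept.append(g)
        elif og not in seen:
            seen.add(og)
            kept.append(g)
    return kept


def coexpression_score(
    genes: Sequence[str],
    mr_table: MutualRankTable,
    gene_to_og: Mapping[str, Optional[str]],
    params: Parameters,
    same_og_mode: str = "representative",
) -> tuple[Optional[float], int, int]:
    """Capped sum of pairwise mutual ranks after same-orthogroup reduction.

    Returns ``(score, effective_size, n_missing)``. Missing MR values are
    charged at the cap (conservative: pushes the score up, away from
    significance) and counted. The score is ``None`` — undefined, not
    zero — when fewer than two genes survive reduction, and also when *no*
    pair has MR coverage at all (nothing was measured).
    """
    kept = _reduce_same_orthogroup(genes, gene_to_og, same_og_mode)
    if len(kept) < 2:
        return None, len(kept), 0
    total = 0.0
    n_missing = 0
    n_pairs = 0
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept[i], kept[j]
            if same_og_mode == "pairs":
                og_a, og_b = gene_to_og.get(a), gene_to_og.get(b)
                if og_a is not None and og_a == og_b:
                    continue
            n_pairs += 1
            mr = mr_table.lookup(a, b)
            if mr is None:
                n_missing += 1
                total += params.mr_cap
            else:
                total += min(mr, params.mr_cap)
    if n_pairs == 0 or n_missing == n_pairs:
        return None, len(kept), n_missing
    return total, len(kept), n_missing


def bootstrap_null(
    size_k: int,
    genome_layout: GenomeRecord,
    mr_table: MutualRankTable,
    gene_to_og: Mapping[str, Optional[str]],
    params: Parameters,
    rng: Optional[np.random.Generator] = None,
    same_og_mode: str = "representative",
) -> tuple[np.ndarray, float]:
    """Null coexpression-score distribution for neighborhoods of size k.

    Draws ``params.bootstrap_n`` contiguous runs of ``size_k`` genes,
    uniform over all valid start positions across chromosomes, scores each
    run exactly like a real neighborhood, and returns the sorted scores
    plus the lower-tail empirical quantile: the ceil(q*N)-th smallest
    score. Runs yielding an undefined score are redrawn (bounded retries).
    """
    if size_k < 2:
        raise ValueError("bootstrap_null: size_k must be >= 2")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    starts: list[tuple[str, int]] = []
    for chrom_id, genes in genome_layout.chromosomes.items():
        for s in range(len(genes) - size_k + 1):
            starts.append((chrom_id, s))
    if not starts:
        raise ValueError(
            f"no chromosome in genome {genome_layout.genome_id!r} holds "
            f"{size_k} genes"
        )
    scores = np.empty(params.bootstrap_n)
    max_tries = 100 * params.bootstrap_n
    tries = 0
    filled = 0
    while filled < params.bootstrap_n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "bootstrap_null: too many undefined-score redraws; the "
                "mutual-rank table does not cover the genome layout"
            )
        chrom_id, s = starts[rng.integers(len(starts))]
        run = [g.gene_id
               for g in genome_layout.chromosomes[chrom_id][s:s + size_k]]
        score, _, _ = coexpression_score(
            run, mr_table, gene_to_og, params, same_og_mode
        )
        if score is None:
            continue
        scores[filled] = score
        filled += 1
    scores.sort()
    idx = math.ceil(params.quantile * params.bootstrap_n) - 1
    return scores, float(scores[idx])


def test_neighborhoods(
    neighborhoods: Sequence[Neighborhood],
    mr_table: MutualRankTable,
    genome_layout: GenomeRecord,
    gene_to_og: Mapping[str, Optional[str]],
    params: Parameters,
    same_og_mode: str = "representative",
) -> list[CoexpressionResult]:
    """Score neighborhoods and call significance against size-matched nulls.

    One null distribution is computed (and cached) per effective size; a
    neighborhood is significant when score <= threshold. Neighborhoods
    with an undefined score (too few scorable genes, or no MR coverage)
    are reported untestable: score, threshold and significant are None.
    Null draws use an RNG substream keyed by the effective size, so the
    set of neighborhoods tested does not perturb any null.
    """
    null_cache: dict[int, tuple[np.ndarray, float]] = {}
    results = []
    for nbhd in neighborhoods:
        score, eff, n_missing = coexpression_score(
            nbhd.genes, mr_table, gene_to_og, params, same_og_mode
        )
        if score is None:
            results.append(CoexpressionResult(
                neighborhood_id=nbhd.neighborhood_id, effective_size=eff,
                score=None, null_n=0, threshold=None, significant=None,
                n_missing_mr=n_missing, seed=params.seed,
            ))
            continue
        if eff not in null_cache:
            rng = np.random.default_rng([params.seed, eff])
            null_cache[eff] = bootstrap_null(
                eff, genome_layout, mr_table, gene_to_og, params, rng,
                same_og_mode,
            )
        _, threshold = null_cache[eff]
        results.append(CoexpressionResult(
            neighborhood_id=nbhd.neighborhood_id, effective_size=eff,
            score=score, null_n=params.bootstrap_n, threshold=threshold,
            significant=score <= threshold, n_missing_mr=n_missing,
            seed=params.seed,
        ))
    return results
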