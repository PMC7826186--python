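"""The detection algorithm: windows, criteria, assembly, ranking, filters."""

import numpy as np
import pytest

from pogscan.io_model import Parameters
from pogscan.neighborhoods import (
    Neighborhood,
    PogPair,
    assemble_neighborhoods,
    apply_criterion1,
    apply_criterion2,
    apply_criterion3,
    cleanup,
    collect_pog_pairs,
    detect,
    exclude_histones,
    filter_unique,
    find_pog_occurrences,
    flag_pairs,
    rank_neighborhoods,
    summarize_taxonomy,
    window_span,
)

from helpers import assemble_genome_set, make_genome, random_genome_set
from _reference import brute_flagged, brute_neighborhoods, brute_occurrences


# ---------------------------------------------------------------------------
# window span


class TestWindowSpan:
    def test_mean_length_times_window(self):
        genome = make_genome("G1", {"chr1": [
            ("a", 1, 1000), ("b", 2000, 3999), ("c", 5000, 7999)]})
        # lengths 1000, 2000, 3000 -> mean 2000; x6 = 12000
        assert window_span(genome.chromosomes["chr1"], 6) == 12000.0

    def test_single_gene(self):
        genome = make_genome("G1", {"chr1": [("a", 1, 500)]})
        assert window_span(genome.chromosomes["chr1"], 6) == 3000.0

    def test_window_one_is_mean_length(self):
        genome = make_genome("G1", {"chr1": [
            ("a", 1, 100), ("b", 500, 1200)]})
        chrom = genome.chromosomes["chr1"]
        mean = sum(g.length for g in chrom) / 2
        assert window_span(chrom, 1) == mean

    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError):
            window_span([], 6)


# ---------------------------------------------------------------------------
# occurrences


def _two_gene_set(start_b, og_b="OGB"):
    genome = make_genome("G1", {"chr1": [
        ("a", 1000, 2999), ("b", start_b, start_b + 1999)]})
    return assemble_genome_set(
        [genome], {("G1", "a"): "OGA", ("G1", "b"): og_b})


class TestFindPogOccurrences:
    def test_pair_within_span(self):
        gs = _two_gene_set(5000)
        params = Parameters(window_size=6)
        spans = {"chr1": 12000.0}
        occ = find_pog_occurrences(gs.genomes["G1"], spans, params)
        assert occ == {("OGA", "OGB"): [("chr1", "a", "b")]}

    def test_same_orthogroup_pair_excluded(self):
        """Tandem duplicates never self-seed a pair."""
        gs = _two_gene_set(5000, og_b="OGA")
        occ = find_pog_occurrences(
            gs.genomes["G1"], {"chr1": 12000.0}, Parameters())
        assert occ == {}

    def test_pair_beyond_span_excluded(self):
        gs = _two_gene_set(50000)
        occ = find_pog_occurrences(
            gs.genomes["G1"], {"chr1": 12000.0}, Parameters())
        assert occ == {}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        """8 random genes: occurrences equal brute-force over all 28 pairs."""
        rng = np.random.default_rng(seed)
        pos = 1
        rows = []
        og_of = {}
        for i in range(8):
            start = pos + int(rng.integers(1, 8000))
            end = start + int(rng.integers(100, 4000))
            rows.append((f"g{i}", start, end))
            pos = end
            og_of[("G1", f"g{i}")] = f"OG{rng.integers(4)}"
        gs = assemble_genome_set([make_genome("G1", {"chr1": rows})], og_of)
        params = Parameters(window_size=6)
        genome = gs.genomes["G1"]
        span = window_span(genome.chromosomes["chr1"], 6)
        got = find_pog_occurrences(genome, {"chr1": span}, params)
        expected = brute_occurrences(gs, params)
        got_flat = {(k, o) for k, occs in got.items() for o in occs}
        exp_flat = {(k, o) for k, per in expected.items()
                    for o in per.get("G1", ())}
        assert got_flat == exp_flat


# ---------------------------------------------------------------------------
# criteria


def _panel(proximal_in, present_far_in=(), classes=None, outgroup=None):
    """Genomes where OGA/OGB are adjacent (proximal_in), co-present but
    distant (present_far_in), or absent (everything else named)."""
    classes = classes or {}
    genomes = []
    og_of = {}
    for gid in list(proximal_in) + list(present_far_in):
        far = gid in present_far_in
        b_start = 10_000_000 if far else 4000
        genomes.append(make_genome(
            gid,
            {"chr1": [("a", 1000, 2999), ("b", b_start, b_start + 1999)]},
            taxonomic_class=classes.get(gid, "classA"),
            role="outgroup" if gid == outgroup else "ingroup",
        ))
        og_of[(gid, "a")] = "OGA"
        og_of[(gid, "b")] = "OGB"
    return assemble_genome_set(genomes, og_of)


def _the_pair(gs, params=None):
    pairs = collect_pog_pairs(gs, params or Parameters())
    return pairs[("OGA", "OGB")]


class TestCriterion1:
    def test_four_genomes_two_classes_flagged(self):
        gs = _panel(["G1", "G2", "G3", "G4"],
                    classes={"G1": "cX", "G2": "cX", "G3": "cY", "G4": "cY"})
        pairs = collect_pog_pairs(gs, Parameters())
        apply_criterion1(pairs, gs, Parameters())
        assert 1 in pairs[("OGA", "OGB")].criteria

    def test_five_genomes_one_class_not_flagged(self):
        gs = _panel(["G1", "G2", "G3", "G4", "G5"])  # all classA
        pairs = collect_pog_pairs(gs, Parameters())
        apply_criterion1(pairs, gs, Parameters())
        assert pairs[("OGA", "OGB")].criteria == set()

    def test_three_genomes_below_threshold(self):
        gs = _panel(["G1", "G2", "G3"],
                    classes={"G1": "cX", "G2": "cY", "G3": "cY"})
        pairs = collect_pog_pairs(gs, Parameters())
        apply_criterion1(pairs, gs, Parameters())
        assert pairs[("OGA", "OGB")].criteria == set()

    def test_outgroup_support_does_not_count(self):
        gs = _panel(["G1", "G2", "G3", "K"], outgroup="K",
                    classes={"G1": "cX", "G2": "cX", "G3": "cY"})
        pairs = collect_pog_pairs(gs, Parameters())
        apply_criterion1(pairs, gs, Parameters())
        assert pairs[("OGA", "OGB")].criteria == set()


class TestCriterion2:
    def test_outgroup_plus_two_ingroups_flagged(self):
        gs = _panel(["G1", "G2", "K"], outgroup="K")
        pairs = collect_pog_pairs(gs, Parameters())
        apply_criterion2(pairs, gs, Parameters())
        assert 2 in pairs[("OGA", "OGB")].criteria

    def test_no_outgroup_support_not_flagged(self):
        gs = _panel(["G1", "G2", "G3", "G4", "G5"], present_far_in=["K"],
                    outgroup="K")
        pairs = collect_pog_pairs(gs, Parameters())
        apply_criterion2(pairs, gs, Parameters())
        assert pairs[("OGA", "OGB")].criteria == set()

    def test_below_three_species_not_flagged(self):
        gs = _panel(["G1", "K"], outgroup="K")
        pairs = collect_pog_pairs(gs, Parameters())
        apply_criterion2(pairs, gs, Parameters())
        assert pairs[("OGA", "OGB")].criteria == set()

    def test_missing_outgroup_is_an_error(self):
        gs = _panel(["G1", "G2", "G3"])
        pairs = collect_pog_pairs(gs, Parameters())
        with pytest.raises(ValueError, match="outgroup"):
            apply_criterion2(pairs, gs, Parameters())


class TestCriterion3:
    def test_cooccurring_in_three_genomes_flagged(self):
        gs = _panel(["G1", "G2", "G3"],
                    classes={"G1": "cX", "G2": "cY", "G3": "cY"})
        pairs = collect_pog_pairs(gs, Parameters())
        apply_criterion3(pairs, gs, Parameters())
        assert 3 in pairs[("OGA", "OGB")].criteria

    def test_present_but_not_proximal_somewhere_not_flagged(self):
        gs = _panel(["G1", "G2", "G3"], present_far_in=["G4"],
                    classes={"G1": "cX", "G2": "cY", "G3": "cY"})
        pairs = collect_pog_pairs(gs, Parameters())
        apply_criterion3(pairs, gs, Parameters())
        assert pairs[("OGA", "OGB")].criteria == set()

    def test_two_genomes_below_minimum(self):
        gs = _panel(["G1", "G2"], classes={"G1": "cX", "G2": "cY"})
        pairs = collect_pog_pairs(gs, Parameters())
        apply_criterion3(pairs, gs, Parameters())
        assert pairs[("OGA", "OGB")].criteria == set()


# ---------------------------------------------------------------------------
# assembly


def _flagged_pair(og_a, og_b, genome_id, ga, gb, criteria={1}):
    pair = PogPair(og_a=min(og_a, og_b), og_b=max(og_a, og_b))
    pair.support[genome_id] = [("chr1", ga, gb)]
    pair.criteria = set(criteria)
    return pair


class TestAssembleNeighborhoods:
    def _gs(self):
        genome = make_genome("G1", {"chr1": [
            ("g1", 1000, 1999), ("g2", 3000, 3999), ("g3", 5000, 5999),
            ("g4", 100000, 100999), ("g5", 102000, 102999)]})
        og_of = {("G1", f"g{i}"): f"OG{i}" for i in range(1, 6)}
        return assemble_genome_set([genome], og_of)

    def test_single_pair_is_not_a_neighborhood(self):
        gs = self._gs()
        pairs = {("OG1", "OG2"):
                 _flagged_pair("OG1", "OG2", "G1", "g1", "g2")}
        assert assemble_neighborhoods(pairs, gs, Parameters()) == []

    def test_transitive_window_merge(self):
        """(A,B) on g1,g2 and (B,C) on g2,g3 merge into one 3-gene
        neighborhood with two supporting pairs."""
        gs = self._gs()
        pairs = {
            ("OG1", "OG2"): _flagged_pair("OG1", "OG2", "G1", "g1", "g2"),
            ("OG2", "OG3"): _flagged_pair("OG2", "OG3", "G1", "g2", "g3"),
        }
        (nbhd,) = assemble_neighborhoods(pairs, gs, Parameters())
        assert nbhd.genes == ["g1", "g2", "g3"]
        assert nbhd.supporting_pairs == {("OG1", "OG2"), ("OG2", "OG3")}

    def test_no_merge_across_disjoint_windows(self):
        gs = self._gs()
        pairs = {
            ("OG1", "OG2"): _flagged_pair("OG1", "OG2", "G1", "g1", "g2"),
            ("OG4", "OG5"): _flagged_pair("OG4", "OG5", "G1", "g4", "g5"),
        }
        assert assemble_neighborhoods(pairs, gs, Parameters()) == []

    def test_shared_pair_links_family_across_genomes(self):
        genomes = []
        og_of = {}
        for gid in ("G1", "G2"):
            genomes.append(make_genome(gid, {"chr1": [
                ("a", 1000, 1999), ("b", 3000, 3999), ("c", 5000, 5999)]}))
            og_of.update({(gid, "a"): "OGA", (gid, "b"): "OGB",
                          (gid, "c"): "OGC"})
        gs = assemble_genome_set(genomes, og_of)
        pairs = {}
        for og1, og2, ga, gb in (("OGA", "OGB", "a", "b"),
                                 ("OGB", "OGC", "b", "c")):
            pair = PogPair(og_a=og1, og_b=og2)
            pair.criteria = {1}
            for gid in ("G1", "G2"):
                pair.support[gid] = [("chr1", ga, gb)]
            pairs[(og1, og2)] = pair
        nbhds = assemble_neighborhoods(pairs, gs, Parameters())
        assert len(nbhds) == 2
        assert len({n.family_id for n in nbhds}) == 1


# ---------------------------------------------------------------------------
# ranking


def _candidate(nid, genome_id, genes, ogs, score=None):
    return Neighborhood(
        neighborhood_id=nid, genome_id=genome_id, chrom_id="chr1",
        genes=list(genes), orthogroups=frozenset(ogs),
        supporting_pairs=frozenset({("X", "Y"), ("Y", "Z")}),
        pair_occurrences={}, criteria=frozenset({1}), rank_score=score,
    )


class TestRanking:
    def _gs_two_ogs(self, extra_members=0):
        """OGX and OGY each have 2 clustered members + 2 unclustered
        (+ extra_members more unclustered)."""
        genomes, og_of = [], {}
        for gid in ("G1", "G2", "G3", "G4"):
            rows = [("a", 1000, 1999), ("b", 3000, 3999)]
            for e in range(extra_members):
                rows.append((f"x{e}", 100000 + 10000 * e,
                             100999 + 10000 * e))
            genomes.append(make_genome(gid, {"chr1": rows}))
            og_of[(gid, "a")] = "OGX"
            og_of[(gid, "b")] = "OGY"
            for e in range(extra_members):
                og_of[(gid, f"x{e}")] = "OGX" if e % 2 == 0 else "OGY"
        return assemble_genome_set(genomes, og_of)

    def test_hand_computed_score(self):
        """2 genes from orthogroups of size 4 with 2 clustered members each:
        10 x (0.5 + 0.5) / 2 = 5.0."""
        gs = self._gs_two_ogs()
        cands = [
            _candidate("N1", "G1", ["a", "b"], ["OGX", "OGY"]),
            _candidate("N2", "G2", ["a", "b"], ["OGX", "OGY"]),
        ]
        ranked = rank_neighborhoods(cands, gs, Parameters())
        assert ranked[0].rank_score == pytest.approx(5.0, abs=1e-9)

    def test_fully_clustered_singletons_reach_max(self):
        genomes = [make_genome("G1", {"chr1": [
            ("a", 1000, 1999), ("b", 3000, 3999), ("c", 5000, 5999)]})]
        og_of = {("G1", "a"): "O1", ("G1", "b"): "O2", ("G1", "c"): "O3"}
        gs = assemble_genome_set(genomes, og_of)
        cands = [_candidate("N1", "G1", ["a", "b", "c"],
                            ["O1", "O2", "O3"])]
        (ranked,) = rank_neighborhoods(cands, gs, Parameters())
        assert ranked.rank_score == pytest.approx(10.0, abs=1e-9)

    def test_doubling_orthogroup_size_halves_score(self):
        cands = [
            _candidate("N1", "G1", ["a", "b"], ["OGX", "OGY"]),
            _candidate("N2", "G2", ["a", "b"], ["OGX", "OGY"]),
        ]
        base = rank_neighborhoods(cands, self._gs_two_ogs(), Parameters())
        doubled = rank_neighborhoods(
            cands, self._gs_two_ogs(extra_members=2), Parameters())
        assert doubled[0].rank_score == pytest.approx(
            base[0].rank_score / 2, abs=1e-9)

    def test_scores_bounded_by_rank_scale(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            gs = random_genome_set(rng, max_genomes=4, max_genes=30)
            params = Parameters(min_genomes_c1=2, min_classes=1,
                                min_genomes_c23=2)
            pairs = flag_pairs(collect_pog_pairs(gs, params), gs, params,
                               criteria=(1, 3))
            cands = assemble_neighborhoods(pairs, gs, params)
            for n in rank_neighborhoods(cands, gs, params):
                assert 0 < n.rank_score <= params.rank_scale + 1e-12


class TestFilterUnique:
    def test_lower_ranked_overlap_dropped(self):
        a = _candidate("N1", "G1", ["g1", "g2"], ["O1", "O2"], score=7.1)
        b = _candidate("N2", "G1", ["g2", "g3"], ["O2", "O3"], score=4.3)
        assert filter_unique([b, a]) == [a]

    def test_disjoint_all_retained(self):
        a = _candidate("N1", "G1", ["g1", "g2"], ["O1", "O2"], score=7.1)
        b = _candidate("N2", "G1", ["g3", "g4"], ["O3", "O4"], score=1.0)
        assert set(n.neighborhood_id for n in filter_unique([a, b])) == {
            "N1", "N2"}

    def test_same_genes_different_genomes_do_not_collide(self):
        a = _candidate("N1", "G1", ["g1", "g2"], ["O1", "O2"], score=7.1)
        b = _candidate("N2", "G2", ["g1", "g2"], ["O1", "O2"], score=4.3)
        assert len(filter_unique([a, b])) == 2

    def test_tie_breaks_toward_larger_then_lexicographic(self):
        big = _candidate("N1", "G1", ["g1", "g2", "g3"],
                         ["O1", "O2", "O3"], score=5.0)
        small = _candidate("N2", "G1", ["g3", "g4"], ["O3", "O4"], score=5.0)
        assert filter_unique([small, big]) == [big]
        first = _candidate("N3", "G1", ["g1", "g9"], ["O1", "O9"], score=5.0)
        second = _candidate("N4", "G1", ["g2", "g9"], ["O2", "O9"], score=5.0)
        assert filter_unique([second, first]) == [first]

    def test_output_pairwise_disjoint(self):
        rng = np.random.default_rng(9)
        cands = []
        for i in range(200):
            genes = [f"g{j}" for j in rng.choice(60, size=3, replace=False)]
            cands.append(_candidate(
                f"N{i}", f"G{rng.integers(3)}", genes,
                [f"O{g}" for g in genes], score=float(rng.random()) * 10))
        retained = filter_unique(cands)
        seen = set()
        for n in retained:
            keys = {(n.genome_id, g) for g in n.genes}
            assert not keys & seen
            seen |= keys


class TestCleanup:
    def test_unsupported_gene_removed(self):
        nbhd = _candidate("N1", "G1", ["g1", "g2", "gX", "g3"],
                          ["O1", "O2", "O3"])
        nbhd.pair_occurrences = {
            ("O1", "O2"): [("g1", "g2")],
            ("O2", "O3"): [("g2", "g3")],
        }
        cleaned = cleanup(nbhd)
        assert cleaned.genes == ["g1", "g2", "g3"]
        assert cleaned.supporting_pairs == nbhd.supporting_pairs

    def test_fully_supported_neighborhood_unchanged(self):
        nbhd = _candidate("N1", "G1", ["g1", "g2"], ["O1", "O2"])
        nbhd.pair_occurrences = {("O1", "O2"): [("g1", "g2")]}
        assert cleanup(nbhd).genes == ["g1", "g2"]

    def test_order_preserved(self):
        nbhd = _candidate("N1", "G1", ["g1", "gX", "g2", "gY", "g3"],
                          ["O1", "O2", "O3"])
        nbhd.pair_occurrences = {
            ("O1", "O2"): [("g1", "g2")],
            ("O2", "O3"): [("g2", "g3")],
        }
        assert cleanup(nbhd).genes == ["g1", "g2", "g3"]


class TestExcludeHistones:
    def _gs(self, annotations):
        genome = make_genome("G1", {"chr1": [
            ("g1", 1000, 1999), ("g2", 3000, 3999),
            ("g3", 5000, 5999), ("g4", 7000, 7999)]})
        gs = assemble_genome_set(
            [genome], {("G1", f"g{i}"): f"O{i}" for i in range(1, 5)})
        gs.set_annotations("G1", annotations)
        return gs

    def test_histone_dominated_dropped(self):
        gs = self._gs({"g1": "Histone H4", "g2": "histone H3",
                       "g3": "Histone H2A", "g4": "kinase"})
        nbhd = _candidate("N1", "G1", ["g1", "g2", "g3", "g4"],
                          ["O1", "O2", "O3", "O4"])
        assert exclude_histones([nbhd], gs, Parameters()) == []

    def test_unannotated_retained(self):
        gs = self._gs({})
        nbhd = _candidate("N1", "G1", ["g1", "g2"], ["O1", "O2"])
        assert exclude_histones([nbhd], gs, Parameters()) == [nbhd]

    def test_filter_off_is_identity(self):
        gs = self._gs({"g1": "Histone H4", "g2": "histone H3"})
        nbhd = _candidate("N1", "G1", ["g1", "g2"], ["O1", "O2"])
        params = Parameters(histone_filter=False)
        assert exclude_histones([nbhd], gs, params) == [nbhd]


class TestSummarize:
    def _gs(self, classes):
        genomes = [
            make_genome(gid, {"chr1": [("a", 1000, 1999)]},
                        taxonomic_class=cls)
            for gid, cls in classes.items()
        ]
        return assemble_genome_set(
            genomes, {(g, "a"): f"O_{g}" for g in classes})

    def test_single_family_combo(self):
        gs = self._gs({"G1": "X", "G2": "Y"})
        nbhds = []
        for gid in ("G1", "G2"):
            n = _candidate(f"N_{gid}", gid, ["a"], [f"O_{gid}"])
            n.family_id = "FAM0001"
            nbhds.append(n)
        combos, per_genome = summarize_taxonomy(nbhds, gs)
        assert combos == {"X+Y": 1}
        assert per_genome == {"G1": 1, "G2": 1}

    def test_counts_partition_families(self):
        rng = np.random.default_rng(2)
        gs = self._gs({"G1": "X", "G2": "Y", "G3": "Z"})
        nbhds = []
        for i in range(40):
            gid = f"G{rng.integers(1, 4)}"
            n = _candidate(f"N{i}", gid, ["a"], [f"O_{gid}"])
            n.family_id = f"FAM{rng.integers(1, 11):04d}"
            nbhds.append(n)
        combos, _ = summarize_taxonomy(nbhds, gs)
        assert sum(combos.values()) == len({n.family_id for n in nbhds})
        # independent tally
        fams = {}
        for n in nbhds:
            fams.setdefault(n.family_id, set()).add(
                gs.genomes[n.genome_id].taxonomic_class)
        expected = {}
        for classes in fams.values():
            expected["+".join(sorted(classes))] = expected.get(
                "+".join(sorted(classes)), 0) + 1
        assert combos == expected


# ---------------------------------------------------------------------------
# pipeline-level properties (small versions; the full-size runs live in
# the acceptance suite)


class TestPipelineProperties:
    def test_flagged_pairs_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            gs = random_genome_set(rng, max_genomes=5, max_genes=40)
            params = Parameters(min_genomes_c1=2, min_classes=1,
                                min_genomes_c23=2)
            criteria = (1, 2, 3) if gs.outgroup_ids() else (1, 3)
            got = flag_pairs(collect_pog_pairs(gs, params), gs, params,
                             criteria)
            expected, _ = brute_flagged(gs, params, criteria)
            assert {k: p.criteria for k, p in got.items()} == expected

    def test_neighborhoods_match_brute_force(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            gs = random_genome_set(rng, max_genomes=5, max_genes=40)
            params = Parameters(min_genomes_c1=2, min_classes=1,
                                min_genomes_c23=2)
            criteria = (1, 2, 3) if gs.outgroup_ids() else (1, 3)
            flagged = flag_pairs(collect_pog_pairs(gs, params), gs, params,
                                 criteria)
            got = {
                (n.genome_id, n.chrom_id, frozenset(n.genes),
                 n.supporting_pairs)
                for n in assemble_neighborhoods(flagged, gs, params)
            }
            assert got == brute_neighborhoods(gs, params, criteria)

    def test_window_monotonicity(self):
        """Enlarging the window never removes a flagged pair."""
        rng = np.random.default_rng(44)
        for _ in range(10):
            gs = random_genome_set(rng, max_genomes=4, max_genes=30)
            small = Parameters(window_size=3, min_genomes_c1=2,
                               min_classes=1, min_genomes_c23=2)
            large = Parameters(window_size=8, min_genomes_c1=2,
                               min_classes=1, min_genomes_c23=2)
            crit = (1, 2, 3) if gs.outgroup_ids() else (1, 3)
            f_small = flag_pairs(collect_pog_pairs(gs, small), gs, small,
                                 crit)
            f_large = flag_pairs(collect_pog_pairs(gs, large), gs, large,
                                 crit)
            assert set(f_small) <= set(f_large)

    def test_detect_respects_criteria_subset(self):
        rng = np.random.default_rng(46)
        gs = random_genome_set(rng, max_genomes=5, max_genes=40,
                               with_outgroup=False)
        params = Parameters(min_genomes_c1=2, min_classes=1,
                            min_genomes_c23=2)
        for n in detect(gs, params, criteria=(3,)):
            assert n.criteria == {3}

    def test_rank_invariant_under_genome_relabeling(self):
        rng = np.random.default_rng(47)
        gs = random_genome_set(rng, max_genomes=4, max_genes=30)
        params = Parameters(min_genomes_c1=2, min_classes=1,
                            min_genomes_c23=2)
        nbhds = detect(gs, params, criteria=(1, 3))
        # relabel: reverse genome insertion order
        relabeled = type(gs)(
            genomes={k: gs.genomes[k] for k in reversed(list(gs.genomes))},
            orthogroups=gs.orthogroups,
        )
        nbhds2 = detect(relabeled, params, criteria=(1, 3))
        scores = sorted((frozenset(n.genes), round(n.rank_score, 12))
                        for n in nbhds)
        scores2 = sorted((frozenset(n.genes), round(n.rank_score, 12))
                         for n in nbhds2)
        assert scores == scores2
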