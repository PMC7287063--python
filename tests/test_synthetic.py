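"""Determinism and planted-truth round-trips of the synthetic generators."""

import io

import numpy as np
import pytest

from symbiophylo.binning import gc_profile
from symbiophylo.provenance import classify_origin, detect_lineage_specific, rank_hits
from symbiophylo.supermatrix import select_markers, trim_gap_fraction, trim_termini_identity
from symbiophylo.synthetic import (
    SimulationConfig,
    TreeScenario,
    hits_from_tsv,
    simulate_alignment,
    simulate_gene_tree,
    simulate_hit_table,
    simulate_marker_matrix,
    simulate_metagenome,
)
from symbiophylo.taxonomy import toy_taxonomy
from symbiophylo.treetests import GeneTree, alpha_origin_test, confirm_hgt, root_tree

TREE, CMAP = toy_taxonomy()


class TestMetagenome:
    def test_gc_modes_near_configured_medians(self):
        fasta, _, truth = simulate_metagenome(SimulationConfig(seed=1))
        recs = gc_profile(io.StringIO(fasta))
        host = np.median([r.gc for r in recs.values() if truth.contig_bin[r.contig_id] == "host"])
        symb = np.median([r.gc for r in recs.values() if truth.contig_bin[r.contig_id] == "symbiont"])
        assert host == pytest.approx(0.51, abs=0.01)
        assert symb == pytest.approx(0.64, abs=0.01)

    def test_seed_determinism_byte_identical(self):
        out1 = simulate_metagenome(SimulationConfig(seed=7, n_host_contigs=50, n_symbiont_contigs=50))
        out2 = simulate_metagenome(SimulationConfig(seed=7, n_host_contigs=50, n_symbiont_contigs=50))
        assert out1[0] == out2[0] and out1[1] == out2[1]
        out3 = simulate_metagenome(SimulationConfig(seed=8, n_host_contigs=50, n_symbiont_contigs=50))
        assert out3[0] != out1[0]

    def test_zero_sd_gives_exact_composition(self):
        cfg = SimulationConfig(seed=2, host_gc_sd=0.0, symbiont_gc_sd=0.0,
                               n_host_contigs=30, n_symbiont_contigs=30)
        fasta, _, truth = simulate_metagenome(cfg)
        for rec in gc_profile(io.StringIO(fasta)).values():
            target = 0.51 if truth.contig_bin[rec.contig_id] == "host" else 0.64
            # exact up to rounding GC count to an integer
            assert abs(rec.gc - target) <= 0.5 / rec.length + 1e-12

    def test_genes_tiled_without_overlap(self):
        fasta, gene_map, _ = simulate_metagenome(
            SimulationConfig(seed=3, n_host_contigs=40, n_symbiont_contigs=40)
        )
        lengths = {r.contig_id: r.length for r in gc_profile(io.StringIO(fasta)).values()}
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for line in gene_map.strip().split("\n")[1:]:
            gene, contig, start, end, strand = line.split("\t")
            start, end = int(start), int(end)
            assert 1 <= start <= end <= lengths[contig]
            per_contig.setdefault(contig, []).append((start, end))
        for spans in per_contig.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_truth_bookkeeping(self):
        cfg = SimulationConfig(seed=4, n_host_contigs=25, n_symbiont_contigs=35)
        _, _, truth = simulate_metagenome(cfg)
        bins = list(truth.contig_bin.values())
        assert bins.count("host") == 25 and bins.count("symbiont") == 35

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_host_contigs=0)
        with pytest.raises(ValueError):
            SimulationConfig(host_gc_median=1.2)


class TestHitTable:
    ORIGINS = {
        "g1": "diatoms",
        "g2": "stramenopiles",
        "g3": "eukaryota",
        "g4": "chlorobi",
        "g5": "alphaproteobacteria",
        "g6": "verrucomicrobia",
    }

    def test_noise_free_round_trip(self):
        tsv, truth = simulate_hit_table(self.ORIGINS, TREE, CMAP, seed=0)
        by_gene = hits_from_tsv(tsv)
        for gene, origin in self.ORIGINS.items():
            call = classify_origin(rank_hits(by_gene[gene]), CMAP)
            assert call.label == origin
            assert truth.gene_origin[gene] == origin

    def test_hgt_candidates_flagged(self):
        tsv, _ = simulate_hit_table(self.ORIGINS, TREE, CMAP, seed=0)
        by_gene = hits_from_tsv(tsv)
        for gene in ("g4", "g5", "g6"):
            assert classify_origin(rank_hits(by_gene[gene]), CMAP).hgt_candidate
        for gene in ("g1", "g2", "g3"):
            assert not classify_origin(rank_hits(by_gene[gene]), CMAP).hgt_candidate

    def test_evalues_strictly_ordered_within_gene(self):
        tsv, _ = simulate_hit_table(self.ORIGINS, TREE, CMAP, seed=0)
        for hits in hits_from_tsv(tsv).values():
            evs = [h.evalue for h in hits]
            assert len(set(evs)) == len(evs)

    def test_lineage_specific_planting(self):
        tsv, _ = simulate_hit_table({"ls1": "lineage_specific"}, TREE, CMAP, seed=1)
        hits = hits_from_tsv(tsv)["ls1"]
        assert detect_lineage_specific(hits, {"araphid_pennate"}, CMAP)
        # and an ordinary diatom gene is not called lineage-specific
        tsv2, _ = simulate_hit_table({"g1": "diatoms"}, TREE, CMAP, seed=1)
        assert not detect_lineage_specific(
            hits_from_tsv(tsv2)["g1"], {"araphid_pennate"}, CMAP
        )

    def test_noise_inserts_spurious_top_hit(self):
        tsv, _ = simulate_hit_table({"g1": "diatoms"}, TREE, CMAP, hit_noise=1.0, seed=2)
        hits = sorted(hits_from_tsv(tsv)["g1"], key=lambda h: h.evalue)
        assert hits[0].evalue < 1e-50  # spurious hit outranks the planted pair

    def test_unknown_origin_rejected(self):
        with pytest.raises(ValueError, match="unknown planted origin"):
            simulate_hit_table({"g1": "atlantis"}, TREE, CMAP)

    def test_determinism(self):
        a, _ = simulate_hit_table(self.ORIGINS, TREE, CMAP, seed=9)
        b, _ = simulate_hit_table(self.ORIGINS, TREE, CMAP, seed=9)
        assert a == b


class TestGeneTrees:
    def roundtrip(self, scenario, seed=0):
        newick, leafmap, truth = simulate_gene_tree(scenario, CMAP, seed=seed)
        gt = GeneTree.from_newick(newick, leafmap)
        if scenario.kind == "hgt_sister":
            outgroup = {c for l, c in leafmap.items()
                        if l != "QUERY" and c != scenario.donor}
            rooted = root_tree(gt, outgroup, "QUERY")
            verdict, _ = confirm_hgt(rooted, "QUERY", scenario.donor, CMAP)
            return verdict == "confirmed", truth
        res = alpha_origin_test(gt, "QUERY", CMAP)
        return res.verdict, truth

    @pytest.mark.parametrize("support, confirmed", [(90, True), (51, True), (50, False), (40, False)])
    def test_sister_support_scenarios(self, support, confirmed):
        got, truth = self.roundtrip(TreeScenario("hgt_sister", support=support))
        assert got is confirmed and truth is confirmed

    def test_mixed_sister_scenario(self):
        got, truth = self.roundtrip(TreeScenario("hgt_sister", support=90, mixed_sister=True))
        assert got is False and truth is False

    @pytest.mark.parametrize("flag", [True, False])
    def test_paraphyly_scenarios(self, flag):
        got, truth = self.roundtrip(TreeScenario("alpha_paraphyly", paraphyly_true=flag))
        assert got is flag and truth is flag

    def test_support_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="support"):
            TreeScenario("hgt_sister", support=101)

    def test_determinism(self):
        sc = TreeScenario("hgt_sister", support=75)
        assert simulate_gene_tree(sc, CMAP, seed=3) == simulate_gene_tree(sc, CMAP, seed=3)


class TestMarkerMatrix:
    def test_selection_recovers_planted_set(self):
        planted = {"m001", "m004", "m007"}
        matrix, truth = simulate_marker_matrix(100, 10, planted, seed=3)
        assert set(select_markers(matrix)) == planted
        assert {m for m, p in truth.marker_pass.items() if p} == planted

    def test_failing_markers_hit_exact_boundaries(self):
        matrix, _ = simulate_marker_matrix(100, 4, {"m000"}, seed=0)
        presence = matrix.status.isin({"complete", "fragmented"}).mean(axis=0)
        mean_copy = matrix.copy_number.mean(axis=0)
        failing = [m for m in matrix.markers if m != "m000"]
        for m in failing:
            assert presence[m] <= 0.60 or mean_copy[m] >= 1.5

    def test_all_fail_gives_empty_selection(self):
        matrix, _ = simulate_marker_matrix(50, 5, set(), seed=1)
        assert select_markers(matrix) == []

    def test_zero_taxa_rejected(self):
        with pytest.raises(ValueError, match="n_taxa"):
            simulate_marker_matrix(0, 5, set())


class TestAlignment:
    def test_conserved_block_round_trip(self):
        aln = simulate_alignment(10, 30, [(5, 20)], seed=2)
        _, kept = trim_termini_identity(aln)
        assert kept == (5, 20)

    def test_gap_column_round_trip(self):
        aln = simulate_alignment(10, 10, [(1, 10)], gap_columns={4: 0.6}, seed=2)
        _, cols = trim_gap_fraction(aln, 0.5)
        assert 3 not in cols and len(cols) == 9

    def test_gapless_alignment_unchanged_by_gap_trim(self):
        aln = simulate_alignment(8, 15, [(1, 15)], seed=1)
        trimmed, cols = trim_gap_fraction(aln, 0.5)
        assert trimmed.rows == aln.rows and len(cols) == 15

    def test_block_bounds_validated(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_alignment(5, 10, [(0, 5)])
        with pytest.raises(ValueError, match="length"):
            simulate_alignment(5, 0, [])
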