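"""Ranked-hit origin classification, lineage-specific and chimera detection."""

import itertools
import random

import pytest

from symbiophylo.provenance import (
    Hit,
    classify_origin,
    contig_context_filter,
    detect_chimera,
    detect_lineage_specific,
    rank_hits,
)
from symbiophylo.taxonomy import toy_taxonomy

TREE, CMAP = toy_taxonomy()

DIATOMS = {"araphid_pennate", "raphid_pennate", "polar_centric", "radial_centric"}
ALPHAS = {"rhodobacterales", "rhizobiales"}
CHLOROBI = {"chlorobi_a", "chlorobi_b"}
VERRUCO = {"verrucomicrobia_a", "verrucomicrobia_b"}
STRAMENOPILES = DIATOMS | {"pelagophytes"}
EUKARYOTES = STRAMENOPILES | {"haptophytes", "chlorophytes"}
PROKARYOTES = ALPHAS | CHLOROBI | VERRUCO | {"gammaproteobacteria"}


def H(cat, ev, bs=100.0, qr=None, gene="g1"):
    return Hit(gene, f"{cat}|{ev}|{bs}", cat, ev, bs, qr)


class TestRankHits:
    def test_dedup_keeps_best_per_category(self):
        ranked = rank_hits([H("araphid_pennate", 1e-40), H("araphid_pennate", 1e-50)])
        assert len(ranked) == 1 and ranked[0].evalue == 1e-50

    def test_rank_by_evalue_after_dedup(self):
        hits = [H("haptophytes", 1e-30), H("chlorophytes", 1e-20), H("haptophytes", 1e-10)]
        ranked = rank_hits(hits)
        assert [(h.category, h.evalue) for h in ranked] == [
            ("haptophytes", 1e-30),
            ("chlorophytes", 1e-20),
        ]

    def test_tie_break_bitscore_then_subject(self):
        a, b = H("haptophytes", 1e-20, 200.0), H("chlorophytes", 1e-20, 180.0)
        assert rank_hits([b, a])[0] is a
        c = Hit("g1", "aaa", "haptophytes", 1e-20, 200.0)
        d = Hit("g1", "bbb", "chlorophytes", 1e-20, 200.0)
        assert rank_hits([d, c])[0] is c

    def test_input_order_invariance(self):
        hits = [
            H("araphid_pennate", 1e-50),
            H("raphid_pennate", 1e-45),
            H("haptophytes", 1e-30),
            H("araphid_pennate", 1e-20),
        ]
        expected = rank_hits(hits)
        rng = random.Random(7)
        for _ in range(50):
            shuffled = hits[:]
            rng.shuffle(shuffled)
            assert rank_hits(shuffled) == expected

    def test_empty_and_mixed_queries(self):
        assert rank_hits([]) == []
        with pytest.raises(ValueError, match="multiple queries"):
            rank_hits([H("haptophytes", 1e-5, gene="g1"), H("haptophytes", 1e-5, gene="g2")])


def origin_oracle(c1: str, c2: str):
    """Hand-written rule table over the toy taxonomy: (level, label, hgt)."""
    pair = {c1, c2}
    if pair <= DIATOMS:
        return ("lineage", "diatoms", False)
    if pair <= ALPHAS:
        return ("prokaryote-lineage", "alphaproteobacteria", True)
    if pair <= CHLOROBI:
        return ("prokaryote-lineage", "chlorobi", True)
    if pair <= VERRUCO:
        return ("prokaryote-lineage", "verrucomicrobia", True)
    if pair <= STRAMENOPILES:
        return ("stramenopile", "stramenopiles", False)
    if pair <= EUKARYOTES:
        return ("eukaryote", "eukaryota", False)
    if pair <= PROKARYOTES:
        return ("prokaryote-lineage", "bacteria", False)
    return ("unresolved", "cellular", False)


class TestClassifyOrigin:
    @pytest.mark.parametrize(
        "c1, c2, level, label, hgt",
        [
            ("araphid_pennate", "raphid_pennate", "lineage", "diatoms", False),
            ("araphid_pennate", "pelagophytes", "stramenopile", "stramenopiles", False),
            ("araphid_pennate", "haptophytes", "eukaryote", "eukaryota", False),
            ("rhodobacterales", "rhizobiales", "prokaryote-lineage",
             "alphaproteobacteria", True),
            ("araphid_pennate", "gammaproteobacteria", "unresolved", "cellular", False),
        ],
    )
    def test_stated_rules(self, c1, c2, level, label, hgt):
        call = classify_origin([H(c1, 1e-50), H(c2, 1e-40)], CMAP)
        assert (call.level, call.label, call.hgt_candidate) == (level, label, hgt)

    def test_single_hit_unresolved(self):
        call = classify_origin(rank_hits([H("araphid_pennate", 1e-50)]), CMAP)
        assert call.level == "unresolved" and not call.hgt_candidate

    def test_exhaustive_pairs_match_oracle(self):
        cats = sorted(CMAP.categories)
        for c1, c2 in itertools.permutations(cats, 2):
            call = classify_origin([H(c1, 1e-50), H(c2, 1e-40)], CMAP)
            assert (call.level, call.label, call.hgt_candidate) == origin_oracle(c1, c2), (
                c1, c2,
            )

    def test_pure_function_of_ranked_list(self):
        raw = [
            H("chlorobi_a", 1e-50),
            H("chlorobi_b", 1e-45),
            H("haptophytes", 1e-30),
            H("chlorobi_a", 1e-10),
        ]
        expected = classify_origin(rank_hits(raw), CMAP)
        rng = random.Random(3)
        for _ in range(30):
            shuffled = raw[:]
            rng.shuffle(shuffled)
            call = classify_origin(rank_hits(shuffled), CMAP)
            assert (call.level, call.label, call.hgt_candidate) == (
                expected.level, expected.label, expected.hgt_candidate,
            )

    def test_unknown_category_rejected(self):
        with pytest.raises(Exception, match="unknown category"):
            classify_origin([H("martian", 1e-10), H("haptophytes", 1e-5)], CMAP)


class TestLineageSpecific:
    FOCAL = {"araphid_pennate"}

    def test_weak_off_clade_hits_ignored(self):
        hits = [H("araphid_pennate", 1e-30), H("araphid_pennate", 1e-12),
                H("haptophytes", 1e-3)]
        assert detect_lineage_specific(hits, self.FOCAL, CMAP)

    def test_strong_off_clade_hit_disqualifies(self):
        hits = [H("araphid_pennate", 1e-30), H("chlorophytes", 1e-8)]
        assert not detect_lineage_specific(hits, self.FOCAL, CMAP)

    def test_no_strong_hits_is_negative(self):
        assert not detect_lineage_specific([H("araphid_pennate", 1e-3)], self.FOCAL, CMAP)
        assert not detect_lineage_specific([], self.FOCAL, CMAP)

    def test_threshold_is_strict(self):
        # a hit exactly at the threshold does not count as "below"
        assert not detect_lineage_specific([H("araphid_pennate", 1e-5)], self.FOCAL, CMAP)

    def test_monotone_in_threshold(self):
        # lowering evalue_max can only drop hits, never add non-focal ones
        hits = [H("araphid_pennate", 1e-30), H("chlorophytes", 1e-8),
                H("haptophytes", 1e-3)]
        thresholds = [1e-2, 1e-5, 1e-9, 1e-10, 1e-31]
        calls = [detect_lineage_specific(hits, self.FOCAL, CMAP, t) for t in thresholds]
        # once the off-clade 1e-8 hit falls outside the threshold the call turns
        # true, and excluding everything turns it false again; a false call
        # never turns true through extra non-focal hits entering the window
        assert calls == [False, False, True, True, False]


class TestChimera:
    def test_two_confident_segments(self):
        hits = [
            H("verrucomicrobia_a", 1e-40, 300, (1, 150)),
            H("verrucomicrobia_b", 1e-38, 280, (1, 150)),
            H("araphid_pennate", 1e-35, 260, (160, 300)),
            H("raphid_pennate", 1e-33, 250, (160, 300)),
        ]
        call = detect_chimera(hits, CMAP)
        assert call.is_chimera
        assert [s for s, _ in call.segments] == [(1, 150), (160, 300)]
        levels = [c.level for _, c in call.segments]
        assert levels == ["prokaryote-lineage", "lineage"]

    def test_full_length_single_origin(self):
        hits = [H("araphid_pennate", 1e-40, 300, (1, 300)),
                H("raphid_pennate", 1e-38, 280, (1, 300))]
        call = detect_chimera(hits, CMAP)
        assert not call.is_chimera and len(call.segments) == 1

    def test_unresolved_segment_blocks_chimera(self):
        hits = [
            H("verrucomicrobia_a", 1e-40, 300, (1, 150)),
            H("verrucomicrobia_b", 1e-38, 280, (1, 150)),
            H("araphid_pennate", 1e-35, 260, (160, 300)),  # single hit: unresolved
        ]
        call = detect_chimera(hits, CMAP)
        assert not call.is_chimera

    def test_min_segment_length(self):
        hits = [
            H("verrucomicrobia_a", 1e-40, 300, (1, 30)),
            H("verrucomicrobia_b", 1e-39, 290, (1, 30)),
            H("araphid_pennate", 1e-35, 260, (100, 300)),
            H("raphid_pennate", 1e-33, 250, (100, 300)),
        ]
        call = detect_chimera(hits, CMAP, min_segment_len=50)
        assert len(call.segments) == 1 and not call.is_chimera

    def test_ranges_required(self):
        with pytest.raises(ValueError, match="ranges required"):
            detect_chimera([H("araphid_pennate", 1e-10)], CMAP)


class TestContigContext:
    def _calls(self, mapping):
        out = {}
        for gene, cats in mapping.items():
            out[gene] = classify_origin(
                rank_hits([H(c, 10.0 ** -(50 - 5 * i), gene=gene)
                           for i, c in enumerate(cats)]),
                CMAP,
            )
        return out

    def test_retained_with_diatom_context(self):
        calls = self._calls({
            "hgt1": ["chlorobi_a", "chlorobi_b"],
            "d1": ["araphid_pennate", "raphid_pennate"],
            "d2": ["araphid_pennate", "polar_centric"],
        })
        gene_map = {"hgt1": "c1", "d1": "c1", "d2": "c1"}
        verdicts = contig_context_filter(["hgt1"], calls, gene_map, CMAP)
        assert verdicts == {"hgt1": "retained"}

    def test_lone_gene_flagged(self):
        calls = self._calls({"hgt1": ["chlorobi_a", "chlorobi_b"]})
        verdicts = contig_context_filter(["hgt1"], calls, {"hgt1": "c9"}, CMAP)
        assert verdicts == {"hgt1": "flagged_contaminant"}

    def test_bacterial_context_flagged(self):
        calls = self._calls({
            "hgt1": ["chlorobi_a", "chlorobi_b"],
            "b1": ["rhodobacterales", "rhizobiales"],
        })
        gene_map = {"hgt1": "c2", "b1": "c2"}
        verdicts = contig_context_filter(["hgt1"], calls, gene_map, CMAP)
        assert verdicts == {"hgt1": "flagged_contaminant"}

    def test_missing_gene_rejected(self):
        with pytest.raises(KeyError, match="missing"):
            contig_context_filter(["gX"], {}, {}, CMAP)
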