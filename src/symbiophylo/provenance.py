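"""Gene-origin classification from ranked homology hits.

Each gene carries a table of similarity hits against libraries grouped into
taxonomic sub-categories.  The classifier reduces the table to one best hit
per sub-category ("non-redundant" hits), ranks those by e-value, and reads
the gene's evolutionary affinity off the first two ranks:

* two sub-categories of one lineage -> that lineage (e.g. two diatom
  subgroups -> diatom origin); a non-host lineage additionally flags the gene
  as an HGT candidate;
* a diatom plus a non-diatom stramenopile -> stramenopile origin;
* a diatom plus a non-stramenopile eukaryote -> eukaryote origin;
* conflicting eukaryote/prokaryote pairs -> unresolved at the cellular root.

Lineage-specific genes are those whose only strong hits (e-value strictly
below a threshold, default 1e-5) all fall inside a focal set of close-relative
libraries.  Chimeric "S-genes" are detected by clustering query-coordinate
ranges of the hits and classifying each segment independently; HGT candidates
on contigs that carry no independently verified host gene are flagged as
probable contaminants rather than transfers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .taxonomy import CategoryMap, TaxonomyError, lca

__all__ = [
    "Hit",
    "OriginCall",
    "ChimeraCall",
    "rank_hits",
    "classify_origin",
    "detect_lineage_specific",
    "detect_chimera",
    "contig_context_filter",
]

LINEAGE_SPECIFIC_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class Hit:
    """One similarity hit of a query gene against a categorised library."""

    query_id: str
    subject_id: str
    category: str
    evalue: float
    bitscore: float = 0.0
    query_range: tuple[int, int] | None = None  # 1-based inclusive

    def __post_init__(self):
        if self.evalue <= 0:
            raise ValueError(f"evalue must be positive, got {self.evalue}")
        if self.query_range is not None and self.query_range[0] > self.query_range[1]:
            raise ValueError(f"invalid query_range {self.query_range}")


@dataclass
class OriginCall:
    gene_id: str
    level: str  # sub-category | lineage | stramenopile | eukaryote | prokaryote-lineage | unresolved
    label: str | None
    top_two: tuple[str, str] | None
    hgt_candidate: bool
    evidence: list[Hit] = field(default_factory=list)

    @property
    def confident(self) -> bool:
        return self.level != "unresolved"


@dataclass
class ChimeraCall:
    gene_id: str
    segments: list[tuple[tuple[int, int], OriginCall]]
    is_chimera: bool


def _hit_sort_key(h: Hit):
    # ascending e-value, then descending bitscore, then subject id
    return (h.evalue, -h.bitscore, h.subject_id)


def rank_hits(hits: list[Hit]) -> list[Hit]:
    """Reduce to the best hit per sub-category, ranked by ascending e-value.

    Ties break by higher bitscore then lexicographic subject id, so the
    result is deterministic and invariant to input order.  An empty input
    yields an empty list.
    """
    if not hits:
        return []
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    best: dict[str, Hit] = {}
    for h in hits:
        cur = best.get(h.category)
        if cur is None or _hit_sort_key(h) < _hit_sort_key(cur):
            best[h.category] = h
    return sorted(best.values(), key=_hit_sort_key)


def classify_origin(ranked: list[Hit], category_map: CategoryMap) -> OriginCall:
    """Assign an evolutionary affinity from the first two non-redundant hits.

    ``ranked`` must already be the output of :func:`rank_hits`.  Fewer than
    two non-redundant hits leaves the gene unresolved.
    """
    for h in ranked:
        category_map.require(h.category)
    gene_id = ranked[0].query_id if ranked else ""
    if len(ranked) < 2:
        return OriginCall(gene_id, "unresolved", None, None, False, list(ranked))

    c1, c2 = ranked[0].category, ranked[1].category
    f1, f2 = category_map.flags[c1], category_map.flags[c2]
    top_two = (c1, c2)

    lin1, lin2 = category_map.lineage_of(c1), category_map.lineage_of(c2)
    # two sub-categories concentrate in one lineage only when their shared
    # parent is a true lineage rank, i.e. below the domain level (a leaf that
    # hangs directly off a domain node is a singleton lineage and cannot
    # corroborate itself)
    if lin1 == lin2 and category_map.tree.nodes[lin1].depth >= 2:
        level = "prokaryote-lineage" if f1.is_prokaryote else "lineage"
        return OriginCall(gene_id, level, lin1, top_two, not f1.is_diatom, list(ranked))
    if f1.is_stramenopile and f2.is_stramenopile:
        label = lca(category_map.tree, [c1, c2])
        return OriginCall(gene_id, "stramenopile", label, top_two, False, list(ranked))
    if f1.is_eukaryote and f2.is_eukaryote:
        label = lca(category_map.tree, [c1, c2])
        return OriginCall(gene_id, "eukaryote", label, top_two, False, list(ranked))
    if f1.is_prokaryote and f2.is_prokaryote:
        # two different prokaryote lineages: placed at their shared ancestor but
        # not concentrated in one lineage, hence no HGT flag
        label = lca(category_map.tree, [c1, c2])
        return OriginCall(gene_id, "prokaryote-lineage", label, top_two, False, list(ranked))
    # eukaryote vs prokaryote conflict: unplaced at the cellular root
    return OriginCall(
        gene_id, "unresolved", category_map.tree.root_id, top_two, False, list(ranked)
    )


def detect_lineage_specific(
    hits: list[Hit],
    focal_categories: set[str],
    category_map: CategoryMap,
    evalue_max: float = LINEAGE_SPECIFIC_EVALUE_MAX,
    self_library: str | None = None,
) -> bool:
    """True iff all hits stronger than ``evalue_max`` lie in the focal clade.

    The comparison is strict (``evalue < evalue_max``); genes with no strong
    hit at all are not lineage-specific.  Hits from the query's own library
    (``self_library``) are ignored.
    """
    for c in focal_categories:
        category_map.require(c)
    strong = [
        h
        for h in hits
        if h.evalue < evalue_max and (self_library is None or h.category != self_library)
    ]
    return bool(strong) and all(h.category in focal_categories for h in strong)


def _overlap_frac_of_shorter(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return inter / shorter


def _supergroup(category_map: CategoryMap, label: str) -> str:
    """Child of the root on ``label``'s root path (the domain-level supergroup)."""
    path = category_map.tree.root_path(label)
    return path[1] if len(path) > 1 else path[0]


def detect_chimera(
    hits: list[Hit],
    category_map: CategoryMap,
    min_segment_len: int = 50,
    overlap_frac: float = 0.5,
) -> ChimeraCall:
    """Segment a gene's ranged hits and classify each segment independently.

    Hits are clustered by single linkage on the rule "pairwise overlap exceeds
    ``overlap_frac`` of the shorter range"; clusters whose spans still overlap
    are merged, and clusters spanning fewer than ``min_segment_len`` positions
    are dropped.  The gene is chimeric when at least two segments obtain
    confident origins in different domain-level supergroups.
    """
    ranged = [h for h in hits if h.query_range is not None]
    if not ranged:
        raise ValueError("ranges required: no hit carries a query_range")
    gene_id = ranged[0].query_id

    # single-linkage union-find on the reciprocal-overlap rule
    parent = list(range(len(ranged)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ranged)):
        for j in range(i + 1, len(ranged)):
            if (
                _overlap_frac_of_shorter(ranged[i].query_range, ranged[j].query_range)
                > overlap_frac
            ):
                parent[find(i)] = find(j)

    clusters: dict[int, list[Hit]] = {}
    for i, h in enumerate(ranged):
        clusters.setdefault(find(i), []).append(h)

    def span(cluster: list[Hit]) -> tuple[int, int]:
        return (
            min(h.query_range[0] for h in cluster),
            max(h.query_range[1] for h in cluster),
        )

    groups = sorted(clusters.values(), key=lambda c: span(c))
    # merge clusters whose spans overlap at all, keeping segments disjoint
    merged: list[list[Hit]] = []
    for g in groups:
        if merged and span(g)[0] <= span(merged[-1])[1]:
            merged[-1].extend(g)
        else:
            merged.append(g)

    segments: list[tuple[tuple[int, int], OriginCall]] = []
    for g in merged:
        s = span(g)
        if s[1] - s[0] + 1 < min_segment_len:
            continue
        call = classify_origin(rank_hits(g), category_map)
        segments.append((s, call))

    confident_groups = {
        _supergroup(category_map, call.label)
        for _, call in segments
        if call.confident and call.label is not None
    }
    return ChimeraCall(gene_id, segments, len(confident_groups) >= 2)


def _is_diatom_origin(call: OriginCall, category_map: CategoryMap) -> bool:
    """Confident origin at the diatom lineage or a diatom sub-category."""
    if not call.confident or call.label is None:
        return False
    if call.label in category_map.categories:
        return category_map.is_diatom(call.label)
    leaves = category_map.tree.leaves_under(call.label)
    return bool(leaves) and all(
        category_map.is_diatom(c) for c in leaves if c in category_map.categories
    )


def contig_context_filter(
    hgt_genes: list[str],
    origin_calls: dict[str, OriginCall],
    gene_to_contig: dict[str, str],
    category_map: CategoryMap,
) -> dict[str, str]:
    """Screen HGT candidates by the taxonomic context of their contig.

    A candidate is ``retained`` when its contig carries at least one *other*
    gene of verified diatom origin, and ``flagged_contaminant`` otherwise
    (a foreign-origin gene alone on a foreign-looking contig is better
    explained as co-assembled contamination than as transfer).
    """
    contig_genes: dict[str, list[str]] = {}
    for gene, contig in gene_to_contig.items():
        contig_genes.setdefault(contig, []).append(gene)

    verdicts: dict[str, str] = {}
    for gene in hgt_genes:
        if gene not in gene_to_contig:
            raise KeyError(f"gene {gene!r} missing from gene map")
        contig = gene_to_contig[gene]
        has_host_context = any(
            other != gene
            and other in origin_calls
            and _is_diatom_origin(origin_calls[other], category_map)
            for other in contig_genes[contig]
        )
        verdicts[gene] = "retained" if has_host_context else "flagged_contaminant"
    return verdicts
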