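"""Tree-topology decision rules for HGT confirmation and commensal screening.

Three rules operate on single-gene trees whose leaves are labelled with
taxonomic categories and whose internal nodes carry integer bootstrap
supports (0-100):

* **HGT confirmation** — a candidate transfer is confirmed when the query's
  sister group in the rooted gene tree consists exclusively of leaves from
  the predicted donor category and the supporting split has bootstrap
  support strictly greater than a cutoff (default 50).
* **Alpha-proteobacterial origin** — a query is of probable
  alpha-proteobacterial origin when some split of the unrooted tree places
  it inside a (possibly paraphyletic) group of alpha-proteobacteria and
  eukaryotes while excluding every non-alpha prokaryote.
* **Library screen** — a sequence library is called as carrying an
  alpha-proteobacterial commensal when at least ``min_markers`` (default 2)
  of a panel of single-copy marker genes (default panel size 27) pass the
  alpha-origin test.

Trees are parsed from Newick via dendropy; internal node labels are read as
supports of the edge above the node.  The topology tests themselves run on a
plain adjacency representation so that rooting never silently migrates a
support value onto a different split.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

from .taxonomy import CategoryMap

__all__ = [
    "GeneTree",
    "RootedNode",
    "SisterResult",
    "ParaphylyResult",
    "LibraryVerdict",
    "root_tree",
    "sister_group",
    "confirm_hgt",
    "alpha_origin_test",
    "screen_library",
]


def _edge_key(u: str, v: str) -> frozenset:
    return frozenset((u, v))


class GeneTree:
    """Unrooted leaf-labelled tree with per-edge support and length.

    ``leaf_categories`` maps each leaf label to a sub-category of the
    analysis taxonomy.  Internal nodes get synthetic ids; a degree-2 root
    written into the Newick is suppressed (its two edges merge, keeping the
    annotated support).
    """

    def __init__(
        self,
        adjacency: dict[str, set[str]],
        supports: dict[frozenset, int | None],
        lengths: dict[frozenset, float],
        leaves: set[str],
        leaf_categories: dict[str, str],
    ):
        self.adjacency = adjacency
        self.supports = supports
        self.lengths = lengths
        self.leaves = leaves
        self.leaf_categories = dict(leaf_categories)
        if len(leaves) < 3:
            raise ValueError("gene tree needs >=3 leaves")
        missing = leaves - set(self.leaf_categories)
        if missing:
            raise ValueError(f"leaves without category: {sorted(missing)}")

    @classmethod
    def from_newick(cls, source, leaf_categories: dict[str, str]) -> "GeneTree":
        """Parse Newick text (string, path or file object)."""
        if hasattr(source, "read"):
            text = source.read()
        else:
            s = str(source)
            text = s if s.lstrip().startswith("(") else open(s).read()
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
        adjacency: dict[str, set[str]] = {}
        supports: dict[frozenset, int | None] = {}
        lengths: dict[frozenset, float] = {}
        leaves: set[str] = set()
        ids: dict[int, str] = {}
        counter = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("unlabelled leaf in Newick input")
                nid = node.taxon.label
                leaves.add(nid)
            else:
                nid = f"__internal_{counter}"
                counter += 1
            if nid in adjacency:
                raise ValueError(f"duplicate leaf label {nid!r}")
            ids[id(node)] = nid
            adjacency[nid] = set()
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            u, v = ids[id(node.parent_node)], ids[id(node)]
            adjacency[u].add(v)
            adjacency[v].add(u)
            key = _edge_key(u, v)
            support = None
            if not node.is_leaf() and node.label is not None:
                try:
                    support = int(round(float(node.label)))
                except ValueError:
                    support = None
            supports[key] = support
            lengths[key] = node.edge.length if node.edge.length is not None else 1.0

        # suppress a degree-2 root: merge its two incident edges
        root_id = ids[id(tree.seed_node)]
        if len(adjacency[root_id]) == 2:
            a, b = sorted(adjacency[root_id])
            ka, kb = _edge_key(root_id, a), _edge_key(root_id, b)
            merged = _edge_key(a, b)
            sup = supports[ka] if supports[ka] is not None else supports[kb]
            lengths_ab = lengths[ka] + lengths[kb]
            for k in (ka, kb):
                del supports[k], lengths[k]
            adjacency[a].discard(root_id)
            adjacency[b].discard(root_id)
            adjacency[a].add(b)
            adjacency[b].add(a)
            del adjacency[root_id]
            supports[merged] = sup
            lengths[merged] = lengths_ab

        gt = cls(adjacency, supports, lengths, leaves, leaf_categories)
        for key, sup in supports.items():
            if sup is not None and not 0 <= sup <= 100:
                raise ValueError(f"support {sup} outside [0, 100]")
        return gt

    def edges(self) -> list[tuple[str, str]]:
        seen, out = set(), []
        for u, nbrs in sorted(self.adjacency.items()):
            for v in sorted(nbrs):
                if _edge_key(u, v) not in seen:
                    seen.add(_edge_key(u, v))
                    out.append((u, v))
        return out

    def side_leaves(self, keep: str, cut: str) -> set[str]:
        """Leaves on the ``keep`` side of the edge (keep, cut)."""
        seen = {cut, keep}
        stack = [keep]
        out = set()
        while stack:
            n = stack.pop()
            if n in self.leaves:
                out.add(n)
            for nbr in self.adjacency[n]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return out


@dataclass
class RootedNode:
    """Node of a rooted view of a gene tree; ``support`` annotates the edge above."""

    node_id: str
    children: list["RootedNode"] = field(default_factory=list)
    parent: "RootedNode | None" = None
    support: int | None = None

    def leaf_set(self) -> set[str]:
        if not self.children:
            return {self.node_id}
        out: set[str] = set()
        for c in self.children:
            out |= c.leaf_set()
        return out

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()


@dataclass
class RootedGeneTree:
    root: RootedNode
    tree: GeneTree
    midpoint_fallback: bool = False

    def find_leaf(self, label: str) -> RootedNode:
        for node in self.root.iter_nodes():
            if not node.children and node.node_id == label:
                return node
        raise KeyError(f"leaf {label!r} not in tree")


@dataclass
class SisterResult:
    query: str
    sister_leaves: set[str]
    sister_categories: set[str]
    support: int | None
    donor_match: bool | None = None


@dataclass
class ParaphylyResult:
    query: str
    verdict: bool
    query_side: set[str]
    other_side: set[str]
    excluded_prokaryotes: set[str]


@dataclass
class LibraryVerdict:
    library: str
    positive: bool
    n_positive: int
    positive_markers: list[str]


def _orient(tree: GeneTree, node_id: str, parent_id: str | None) -> RootedNode:
    support = (
        tree.supports.get(_edge_key(node_id, parent_id)) if parent_id is not None else None
    )
    rn = RootedNode(node_id, support=support)
    for nbr in sorted(tree.adjacency[node_id]):
        if nbr != parent_id:
            child = _orient(tree, nbr, node_id)
            child.parent = rn
            rn.children.append(child)
    return rn


def _root_on_edge(tree: GeneTree, u: str, v: str) -> RootedGeneTree:
    root = RootedNode("__root__")
    for side, other in ((u, v), (v, u)):
        child = _orient(tree, side, other)
        child.support = tree.supports.get(_edge_key(u, v))
        child.parent = root
        root.children.append(child)
    return RootedGeneTree(root, tree)


def _midpoint_edge(tree: GeneTree) -> tuple[str, str]:
    """Edge containing the midpoint of the longest leaf-to-leaf path."""
    import heapq

    def dists_from(start: str) -> dict[str, float]:
        dist = {start: 0.0}
        heap = [(0.0, start)]
        while heap:
            d, n = heapq.heappop(heap)
            if d > dist.get(n, float("inf")):
                continue
            for nbr in tree.adjacency[n]:
                nd = d + tree.lengths[_edge_key(n, nbr)]
                if nd < dist.get(nbr, float("inf")):
                    dist[nbr] = nd
                    heapq.heappush(heap, (nd, nbr))
        return dist

    best = (-1.0, None, None)
    leaf_list = sorted(tree.leaves)
    dist_maps = {}
    for a in leaf_list:
        dist_maps[a] = dists_from(a)
        for b in leaf_list:
            if a < b and dist_maps[a][b] > best[0]:
                best = (dist_maps[a][b], a, b)
    total, a, b = best
    # walk from a toward b until half the path length is covered
    da = dist_maps[a]
    db = dists_from(b)
    on_path = [
        n for n in tree.adjacency if abs(da[n] + db[n] - total) < 1e-9
    ]
    on_path.sort(key=lambda n: da[n])
    half = total / 2.0
    for x, y in zip(on_path, on_path[1:]):
        if da[x] <= half <= da[y]:
            return (x, y)
    return (on_path[0], on_path[1])


def root_tree(
    tree: GeneTree, outgroup_categories: set[str], query: str
) -> RootedGeneTree:
    """Root on the stem edge of the smallest side containing every outgroup leaf.

    Falls back to midpoint rooting (flagged via ``midpoint_fallback``) when no
    such side excludes the query, e.g. when the outgroup is paraphyletic
    around it.
    """
    outgroup_leaves = {
        l for l in tree.leaves if tree.leaf_categories[l] in outgroup_categories
    }
    if not outgroup_leaves:
        raise ValueError("outgroup leaves absent from tree")
    if outgroup_leaves == tree.leaves:
        raise ValueError("outgroup covers every leaf; cannot root")

    # smallest side of any edge that contains every outgroup leaf (the clade
    # the outgroup's stem edge subtends); only then check query exclusion
    best: tuple[int, tuple, str, str] | None = None
    for u, v in tree.edges():
        for keep, cut in ((u, v), (v, u)):
            side = tree.side_leaves(keep, cut)
            if outgroup_leaves <= side:
                cand = (len(side), tuple(sorted(side)), keep, cut)
                if best is None or cand < best:
                    best = cand
    assert best is not None  # the full leaf set always qualifies
    _, side, keep, cut = best
    if query not in side:
        return _root_on_edge(tree, keep, cut)
    rooted = _root_on_edge(tree, *_midpoint_edge(tree))
    rooted.midpoint_fallback = True
    return rooted


def sister_group(rooted: RootedGeneTree, query: str) -> SisterResult:
    """Leaf set of the sibling subtree(s) of the query and the support of the split.

    With a polytomous parent the sister is the union of all non-query sibling
    subtrees.  The support reported is the one annotated on the edge above the
    query's parent (the split separating query+sister from the rest); when the
    parent is the root that split has no annotated edge and support is None.
    """
    leaf = rooted.find_leaf(query)
    parent = leaf.parent
    if parent is None:
        raise ValueError("query at root")
    sister: set[str] = set()
    for child in parent.children:
        if child is not leaf:
            sister |= child.leaf_set()
    cats = {rooted.tree.leaf_categories[l] for l in sister}
    return SisterResult(query, sister, cats, parent.support)


def confirm_hgt(
    rooted: RootedGeneTree,
    query: str,
    donor_category: str,
    category_map: CategoryMap | None = None,
    min_support: int = 50,
) -> tuple[str, SisterResult]:
    """Confirm a candidate transfer by sister-group concordance with the donor.

    Returns ``("confirmed", result)`` when every sister leaf belongs to the
    predicted donor category and the split support strictly exceeds
    ``min_support``; otherwise ``("rejected:<reason>", result)`` with reason
    ``mixed_sister``, ``no_support`` or ``low_support``.
    """
    if category_map is not None:
        category_map.require(donor_category)
    res = sister_group(rooted, query)
    res.donor_match = bool(res.sister_leaves) and res.sister_categories == {
        donor_category
    }
    if not res.donor_match:
        return "rejected:mixed_sister", res
    if res.support is None:
        return "rejected:no_support", res
    if res.support <= min_support:
        return "rejected:low_support", res
    return "confirmed", res


def alpha_origin_test(
    tree: GeneTree, query: str, category_map: CategoryMap
) -> ParaphylyResult:
    """Test whether the query nests among alpha-proteobacteria and eukaryotes.

    True iff some edge of the unrooted tree separates the query, at least one
    alpha-proteobacterial leaf and any eukaryote leaves from *all* non-alpha
    prokaryote leaves.  The maximal qualifying query-side split is reported.
    """
    if query not in tree.leaves:
        raise KeyError(f"query {query!r} not a leaf")

    def klass(leaf: str) -> str:
        cat = tree.leaf_categories[leaf]
        category_map.require(cat)
        if category_map.is_alpha(cat):
            return "alpha"
        if category_map.is_prokaryote(cat):
            return "other_prok"
        return "eukaryote"

    classes = {l: klass(l) for l in tree.leaves if l != query}
    alphas = {l for l, k in classes.items() if k == "alpha"}
    other_proks = {l for l, k in classes.items() if k == "other_prok"}
    if not alphas or not other_proks:
        raise ValueError(
            "underdetermined: need >=1 alpha-proteobacterial and >=1 other "
            "prokaryote leaf besides the query"
        )

    best_side: set[str] | None = None
    for u, v in tree.edges():
        keep = u if query in tree.side_leaves(u, v) else v
        cut = v if keep == u else u
        side = tree.side_leaves(keep, cut)
        if side & other_proks:
            continue
        if not side & alphas:
            continue
        if best_side is None or len(side) > len(best_side):
            best_side = side
    if best_side is None:
        return ParaphylyResult(query, False, {query}, tree.leaves - {query}, other_proks)
    return ParaphylyResult(
        query, True, best_side, tree.leaves - best_side, other_proks
    )


def screen_library(
    marker_verdicts,
    library: str = "",
    min_markers: int = 2,
    marker_panel_size: int = 27,
) -> LibraryVerdict:
    """Per-library commensal verdict from per-marker alpha-origin outcomes.

    ``marker_verdicts`` is a mapping or iterable of ``(marker_id, bool)``
    pairs, at most ``marker_panel_size`` of them; duplicate marker ids are
    rejected.  Positive iff at least ``min_markers`` verdicts are true.
    """
    if isinstance(marker_verdicts, dict):
        pairs = list(marker_verdicts.items())
    else:
        pairs = list(marker_verdicts)
    seen: set[str] = set()
    for marker, _ in pairs:
        if marker in seen:
            raise ValueError(f"duplicate marker id {marker!r}")
        seen.add(marker)
    if len(pairs) > marker_panel_size:
        raise ValueError(
            f"{len(pairs)} verdicts exceed marker panel size {marker_panel_size}"
        )
    positives = sorted(m for m, v in pairs if v)
    return LibraryVerdict(library, len(positives) >= min_markers, len(positives), positives)
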