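"""Hierarchical taxonomic category system and last-common-ancestor queries.

The pipeline classifies genes and contigs against a user-supplied category
system: a rooted tree of named lineage ranks whose *leaves* are the analysis
sub-categories (e.g. ``araphid_pennate``, ``rhodobacterales``).  Each leaf
carries boolean flags placing it in the major supergroups the decision rules
care about (diatom / stramenopile / eukaryote / prokaryote /
alpha-proteobacterium) plus an optional diatom subgroup label.

The category table is a TSV with three columns::

    category_id <TAB> path <TAB> flags

``path`` is the semicolon-delimited lineage from root to leaf (the leaf name
must equal ``category_id``); ``flags`` is a comma-delimited subset of
``diatom, stramenopile, eukaryote, prokaryote, alphaproteobacterium`` plus
optional ``subgroup=<label>`` entries.  A small built-in taxonomy spanning the
diatom subgroups, other stramenopiles, other eukaryotes and four prokaryote
lineages ships for testing; real analyses supply their own table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

__all__ = [
    "TaxonNode",
    "TaxonomyTree",
    "CategoryMap",
    "TaxonomyError",
    "load_taxonomy",
    "lca",
    "toy_taxonomy",
    "TOY_TAXONOMY_TSV",
]

KNOWN_FLAGS = frozenset(
    {"diatom", "stramenopile", "eukaryote", "prokaryote", "alphaproteobacterium"}
)


class TaxonomyError(ValueError):
    """Raised for malformed category tables or invalid taxonomy queries."""


@dataclass(frozen=True)
class TaxonNode:
    """One named rank in the taxonomy; ``parent_id is None`` only at the root."""

    node_id: str
    name: str
    parent_id: str | None
    depth: int


@dataclass(frozen=True)
class CategoryFlags:
    is_diatom: bool = False
    is_stramenopile: bool = False
    is_eukaryote: bool = False
    is_prokaryote: bool = False
    is_alphaproteobacterium: bool = False
    diatom_subgroup: str | None = None


class TaxonomyTree:
    """Rooted tree of :class:`TaxonNode`; node ids are exact case-sensitive strings."""

    def __init__(self, nodes: dict[str, TaxonNode], root_id: str):
        self.nodes = nodes
        self.root_id = root_id
        self._children: dict[str, list[str]] = {nid: [] for nid in nodes}
        for node in nodes.values():
            if node.parent_id is not None:
                self._children[node.parent_id].append(node.node_id)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def children(self, node_id: str) -> list[str]:
        return list(self._children[node_id])

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to and including the root."""
        if node_id not in self.nodes:
            raise TaxonomyError(f"unknown node id: {node_id!r}")
        path = [node_id]
        while (pid := self.nodes[path[-1]].parent_id) is not None:
            path.append(pid)
        return path

    def root_path(self, node_id: str) -> list[str]:
        """Node ids from the root down to ``node_id``."""
        return self.path_to_root(node_id)[::-1]

    def is_ancestor_or_self(self, ancestor: str, node_id: str) -> bool:
        return ancestor in self.path_to_root(node_id)

    def leaves_under(self, node_id: str) -> list[str]:
        if node_id not in self.nodes:
            raise TaxonomyError(f"unknown node id: {node_id!r}")
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            kids = self._children[nid]
            if not kids:
                out.append(nid)
            else:
                stack.extend(kids)
        return sorted(out)


@dataclass
class CategoryMap:
    """Leaf sub-categories with lineage paths and supergroup flags."""

    tree: TaxonomyTree
    categories: set[str] = field(default_factory=set)
    lineage_path: dict[str, list[str]] = field(default_factory=dict)
    flags: dict[str, CategoryFlags] = field(default_factory=dict)

    def __contains__(self, category: str) -> bool:
        return category in self.categories

    def require(self, category: str) -> None:
        if category not in self.categories:
            raise TaxonomyError(f"unknown category: {category!r}")

    def lineage_of(self, category: str) -> str:
        """Immediate lineage rank of a sub-category (parent node of the leaf)."""
        self.require(category)
        parent = self.tree.nodes[category].parent_id
        assert parent is not None  # leaf cannot be the root of a validated table
        return parent

    def is_diatom(self, category: str) -> bool:
        self.require(category)
        return self.flags[category].is_diatom

    def is_prokaryote(self, category: str) -> bool:
        self.require(category)
        return self.flags[category].is_prokaryote

    def is_alpha(self, category: str) -> bool:
        self.require(category)
        return self.flags[category].is_alphaproteobacterium

    def categories_with(self, predicate) -> set[str]:
        return {c for c in self.categories if predicate(self.flags[c])}


def _parse_flags(raw: str, row: int) -> CategoryFlags:
    kw: dict[str, object] = {}
    for token in filter(None, (t.strip() for t in raw.split(","))):
        if token.startswith("subgroup="):
            kw["diatom_subgroup"] = token.split("=", 1)[1]
        elif token in KNOWN_FLAGS:
            kw["is_" + token] = True
        else:
            raise TaxonomyError(f"row {row}: unknown flag {token!r}")
    return CategoryFlags(**kw)


def _check_flag_consistency(cat: str, fl: CategoryFlags, row: int) -> None:
    if fl.is_diatom and not fl.is_stramenopile:
        raise TaxonomyError(f"row {row}: {cat}: diatom implies stramenopile")
    if fl.is_stramenopile and not fl.is_eukaryote:
        raise TaxonomyError(f"row {row}: {cat}: stramenopile implies eukaryote")
    if fl.is_alphaproteobacterium and not fl.is_prokaryote:
        raise TaxonomyError(
            f"row {row}: {cat}: alphaproteobacterium implies prokaryote"
        )
    if fl.is_eukaryote and fl.is_prokaryote:
        raise TaxonomyError(
            f"row {row}: {cat}: eukaryote and prokaryote are mutually exclusive"
        )


def load_taxonomy(source) -> tuple[TaxonomyTree, CategoryMap]:
    """Parse and validate a category TSV into a tree plus category map.

    ``source`` is a path, a file object, or a string containing TSV text.
    Rejects duplicate categories, conflicting parent links and inconsistent
    flags, reporting the offending row number.  Row order is irrelevant: each
    row carries its full root-to-leaf path, so any permutation yields the same
    tree.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        text = s if ("\t" in s or "\n" in s) else open(s).read()

    nodes: dict[str, TaxonNode] = {}
    categories: set[str] = set()
    lineage_path: dict[str, list[str]] = {}
    flags: dict[str, CategoryFlags] = {}
    root_id: str | None = None

    for row, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise TaxonomyError(f"row {row}: expected >=2 tab-separated columns")
        cat = parts[0].strip()
        path = [p.strip() for p in parts[1].split(";") if p.strip()]
        raw_flags = parts[2] if len(parts) > 2 else ""
        if not path:
            raise TaxonomyError(f"row {row}: empty lineage path")
        if path[-1] != cat:
            raise TaxonomyError(
                f"row {row}: path leaf {path[-1]!r} != category id {cat!r}"
            )
        if cat in categories:
            raise TaxonomyError(f"row {row}: duplicate category {cat!r}")
        if len(path) < 2:
            raise TaxonomyError(f"row {row}: category {cat!r} cannot be the root")
        if root_id is None:
            root_id = path[0]
        elif path[0] != root_id:
            raise TaxonomyError(
                f"row {row}: second root {path[0]!r} (tree root is {root_id!r})"
            )
        for depth, nid in enumerate(path):
            parent = path[depth - 1] if depth > 0 else None
            existing = nodes.get(nid)
            if existing is None:
                nodes[nid] = TaxonNode(nid, nid, parent, depth)
            elif existing.parent_id != parent or existing.depth != depth:
                raise TaxonomyError(
                    f"row {row}: node {nid!r} placed inconsistently "
                    f"(parent {existing.parent_id!r} vs {parent!r})"
                )
        categories.add(cat)
        lineage_path[cat] = list(path)
        fl = _parse_flags(raw_flags, row)
        _check_flag_consistency(cat, fl, row)
        flags[cat] = fl

    if root_id is None:
        raise TaxonomyError("no categories")
    # a category must stay a leaf: no other path may pass through it
    for cat in categories:
        for other, path in lineage_path.items():
            if cat != other and cat in path[:-1]:
                raise TaxonomyError(
                    f"category {cat!r} appears as an internal node of {other!r}"
                )

    tree = TaxonomyTree(nodes, root_id)
    return tree, CategoryMap(tree, categories, lineage_path, flags)


def lca(tree: TaxonomyTree, node_ids) -> str:
    """Deepest node whose subtree contains every id in ``node_ids``.

    Commutative and idempotent; singleton sets return their own element.
    """
    ids = list(node_ids)
    if not ids:
        raise TaxonomyError("lca of empty set")
    common: set[str] | None = None
    for nid in ids:
        path = set(tree.path_to_root(nid))
        common = path if common is None else (common & path)
    assert common  # root is always shared
    return max(common, key=lambda nid: tree.nodes[nid].depth)


# --- built-in test taxonomy -------------------------------------------------
# Leaves are the analysis sub-categories; two sub-categories per lineage
# wherever the first-two-hits rule must be able to call that lineage
# confidently (diatoms, alpha-proteobacteria, chlorobi, verrucomicrobia).
TOY_TAXONOMY_TSV = """\
araphid_pennate\tcellular;eukaryota;stramenopiles;diatoms;araphid_pennate\teukaryote,stramenopile,diatom,subgroup=araphid-pennate
raphid_pennate\tcellular;eukaryota;stramenopiles;diatoms;raphid_pennate\teukaryote,stramenopile,diatom,subgroup=raphid-pennate
polar_centric\tcellular;eukaryota;stramenopiles;diatoms;polar_centric\teukaryote,stramenopile,diatom,subgroup=polar-centric
radial_centric\tcellular;eukaryota;stramenopiles;diatoms;radial_centric\teukaryote,stramenopile,diatom,subgroup=radial-centric
pelagophytes\tcellular;eukaryota;stramenopiles;pelagophytes\teukaryote,stramenopile
haptophytes\tcellular;eukaryota;haptophytes\teukaryote
chlorophytes\tcellular;eukaryota;chlorophytes\teukaryote
rhodobacterales\tcellular;bacteria;alphaproteobacteria;rhodobacterales\tprokaryote,alphaproteobacterium
rhizobiales\tcellular;bacteria;alphaproteobacteria;rhizobiales\tprokaryote,alphaproteobacterium
gammaproteobacteria\tcellular;bacteria;gammaproteobacteria\tprokaryote
chlorobi_a\tcellular;bacteria;chlorobi;chlorobi_a\tprokaryote
chlorobi_b\tcellular;bacteria;chlorobi;chlorobi_b\tprokaryote
verrucomicrobia_a\tcellular;bacteria;verrucomicrobia;verrucomicrobia_a\tprokaryote
verrucomicrobia_b\tcellular;bacteria;verrucomicrobia;verrucomicrobia_b\tprokaryote
"""


def toy_taxonomy() -> tuple[TaxonomyTree, CategoryMap]:
    """The bundled 14-category test taxonomy."""
    return load_taxonomy(io.StringIO(TOY_TAXONOMY_TSV))
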