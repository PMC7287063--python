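"""Seeded synthetic inputs with planted ground truth for every pipeline stage.

The study system is a simple two-organism metagenome: a diatom host (contig
GC centred near 0.51) co-assembled with a rhodobacteralean symbiont (GC near
0.64).  These generators emulate each input the pipeline consumes — contigs
with genes tiled on them, ranked homology-hit tables, support-annotated gene
trees, marker status matrices and alignments — while recording the planted
truth so that downstream recovery can be scored exactly.

Design points:

* contig GC is realized constructively (an exact G+C count per contig,
  positions shuffled), so configured medians are met by construction rather
  than by rejection sampling;
* planted-origin hits always receive strictly better e-values than noise
  hits, and e-values within a gene are strictly ordered, so ranking is
  unambiguous (tie handling is exercised by hand-built fixtures, not here);
* gene trees are built by grafting the query onto a scaffold chosen per
  scenario, guaranteeing the planted sister group and support;
* one global seed fans out to per-generator child seeds through
  ``numpy.random.SeedSequence.spawn``, so stages re-run independently still
  reproduce byte-identical files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .supermatrix import Alignment, MarkerMatrix
from .taxonomy import CategoryMap, TaxonomyTree, lca

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_metagenome",
    "simulate_hit_table",
    "simulate_gene_tree",
    "simulate_marker_matrix",
    "simulate_alignment",
    "hits_to_tsv",
    "hits_from_tsv",
]

AT = np.array(list("AT"))
GC = np.array(list("GC"))
AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Parameters of the two-component host+symbiont metagenome emulation.

    GC medians default to the study system (host 0.51, symbiont 0.64); the
    spreads (0.02/0.03) keep the two modes well separated at desk scale while
    still overlapping enough for posterior margins to matter.
    """

    seed: int = 0
    host_gc_median: float = 0.51
    symbiont_gc_median: float = 0.64
    host_gc_sd: float = 0.02
    symbiont_gc_sd: float = 0.03
    n_host_contigs: int = 500
    n_symbiont_contigs: int = 500
    contig_length_mean: int = 4000
    contig_length_sd: int = 1500
    contig_length_min: int = 500
    genes_per_contig_mean: float = 2.0
    gene_length: int = 300
    hit_noise: float = 0.0
    support_low: int = 60
    support_high: int = 100

    def __post_init__(self):
        for name in ("host_gc_median", "symbiont_gc_median"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.host_gc_sd < 0 or self.symbiont_gc_sd < 0:
            raise ValueError("gc sd must be >= 0")
        if self.n_host_contigs <= 0 or self.n_symbiont_contigs <= 0:
            raise ValueError("n_contigs must be positive for both components")


@dataclass
class TruthTable:
    """Planted ground truth keyed by generated record ids."""

    contig_bin: dict[str, str] = field(default_factory=dict)  # contig -> host|symbiont
    gene_contig: dict[str, str] = field(default_factory=dict)
    gene_origin: dict[str, str] = field(default_factory=dict)  # gene -> planted label
    gene_is_hgt: dict[str, bool] = field(default_factory=dict)
    gene_is_chimera: dict[str, bool] = field(default_factory=dict)
    library_contaminated: dict[str, bool] = field(default_factory=dict)
    marker_pass: dict[str, bool] = field(default_factory=dict)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _contig_sequence(length: int, gc_target: float, rng: np.random.Generator) -> str:
    """Sequence with exactly round(gc_target * length) G/C bases, shuffled."""
    n_gc = int(round(gc_target * length))
    bases = np.concatenate(
        [
            GC[rng.integers(0, 2, size=n_gc)],
            AT[rng.integers(0, 2, size=length - n_gc)],
        ]
    )
    rng.shuffle(bases)
    return "".join(bases)


def simulate_metagenome(
    config: SimulationConfig,
) -> tuple[str, str, TruthTable]:
    """Generate contigs FASTA text, a gene-map TSV and the truth table.

    Host and symbiont contigs draw GC targets from normals centred on the
    configured medians (exact at ``gc_sd=0`` up to integer-composition
    rounding); genes are tiled left-to-right without overlap.  The gene map
    columns are ``gene_id, contig_id, start, end, strand`` (1-based
    inclusive).
    """
    rng_gc, rng_len, rng_seq, rng_genes = _child_rngs(config.seed, 4)
    truth = TruthTable()
    fasta = io.StringIO()
    gene_map = io.StringIO()
    gene_map.write("gene_id\tcontig_id\tstart\tend\tstrand\n")

    components = [
        ("host", config.n_host_contigs, config.host_gc_median, config.host_gc_sd),
        (
            "symbiont",
            config.n_symbiont_contigs,
            config.symbiont_gc_median,
            config.symbiont_gc_sd,
        ),
    ]
    gene_counter = 0
    for comp, n, median, sd in components:
        gc_targets = np.clip(rng_gc.normal(median, sd, size=n), 0.0, 1.0) if sd > 0 \
            else np.full(n, median)
        lengths = np.maximum(
            rng_len.normal(config.contig_length_mean, config.contig_length_sd, size=n)
            .round()
            .astype(int),
            config.contig_length_min,
        )
        for i in range(n):
            contig_id = f"{comp}_c{i:05d}"
            seq = _contig_sequence(int(lengths[i]), float(gc_targets[i]), rng_seq)
            fasta.write(f">{contig_id}\n{seq}\n")
            truth.contig_bin[contig_id] = comp
            n_genes = min(
                rng_genes.poisson(config.genes_per_contig_mean),
                int(lengths[i]) // config.gene_length,
            )
            for g in range(n_genes):
                gene_id = f"g{gene_counter:06d}"
                gene_counter += 1
                start = g * config.gene_length + 1
                end = start + config.gene_length - 1
                gene_map.write(f"{gene_id}\t{contig_id}\t{start}\t{end}\t+\n")
                truth.gene_contig[gene_id] = contig_id
    return fasta.getvalue(), gene_map.getvalue(), truth


def _leaf_pair_for_label(
    label: str, tree: TaxonomyTree, category_map: CategoryMap
) -> tuple[str, str]:
    """Two leaf categories whose LCA is exactly ``label``."""
    leaves = [c for c in tree.leaves_under(label) if c in category_map.categories]
    for a in leaves:
        for b in leaves:
            if a < b and lca(tree, [a, b]) == label:
                return a, b
    raise ValueError(f"no leaf pair with LCA {label!r}; cannot plant this origin")


def plan_hits_for_origin(
    gene_id: str,
    origin: str,
    tree: TaxonomyTree,
    category_map: CategoryMap,
    rng: np.random.Generator,
    hit_noise: float = 0.0,
    focal_category: str = "araphid_pennate",
) -> list[tuple[str, str, str, float, float]]:
    """Hit rows (query, subject, category, evalue, bitscore) for one planted gene.

    ``origin`` is either an internal taxonomy node (two sub-categories whose
    LCA is that node are emitted as the top two hits) or the special label
    ``lineage_specific`` (one strong focal hit plus weak off-clade hits above
    the 1e-5 threshold).  With probability ``hit_noise`` a spurious hit from a
    random foreign category is inserted at rank one.
    """
    rows: list[tuple[str, str, str, float, float]] = []
    # strictly descending strength: exponents spaced by whole decades
    exponents = iter(range(50, 2, -3))

    def add(category: str, exponent: int, bitscore: float):
        rows.append(
            (
                gene_id,
                f"{category}|ref{len(rows)}",
                category,
                10.0 ** (-exponent),
                bitscore,
            )
        )

    if hit_noise > 0 and rng.random() < hit_noise:
        foreign = sorted(category_map.categories - {focal_category})
        add(foreign[rng.integers(len(foreign))], 55, 500.0)

    if origin == "lineage_specific":
        add(focal_category, next(exponents), 400.0)
        # off-clade similarity exists but stays above (weaker than) 1e-5
        weak = sorted(category_map.categories - {focal_category})
        add(weak[int(rng.integers(len(weak)))], 3, 50.0)
    else:
        a, b = _leaf_pair_for_label(origin, tree, category_map)
        add(a, next(exponents), 400.0)
        add(b, next(exponents), 380.0)
        # trailing genuine but weaker signal from a random category
        extra = sorted(category_map.categories)
        add(extra[int(rng.integers(len(extra)))], next(exponents), 200.0)
    return rows


def simulate_hit_table(
    gene_origins: dict[str, str],
    tree: TaxonomyTree,
    category_map: CategoryMap,
    hit_noise: float = 0.0,
    seed: int = 0,
) -> tuple[str, TruthTable]:
    """Tabular 12-column hit TSV for genes with planted origins.

    At ``hit_noise=0`` the origin classifier recovers every planted origin
    exactly; planted ``lineage_specific`` genes pass the lineage-specific
    filter with no false positives.
    """
    for origin in gene_origins.values():
        if origin != "lineage_specific" and origin not in tree.nodes:
            raise ValueError(f"unknown planted origin label {origin!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    truth = TruthTable()
    out = io.StringIO()
    for gene_id in sorted(gene_origins):
        origin = gene_origins[gene_id]
        truth.gene_origin[gene_id] = origin
        for q, s, cat, ev, bs in plan_hits_for_origin(
            gene_id, origin, tree, category_map, rng, hit_noise
        ):
            length = 150
            out.write(
                f"{q}\t{s}\t90.0\t{length}\t5\t0\t1\t{length}\t1\t{length}"
                f"\t{ev:.3g}\t{bs:.1f}\t{cat}\n"
            )
    return out.getvalue(), truth


def hits_to_tsv(rows) -> str:
    """Serialize (query, subject, category, evalue, bitscore[, qstart, qend]) rows."""
    out = io.StringIO()
    for r in rows:
        q, s, cat, ev, bs = r[:5]
        qstart, qend = (r[5], r[6]) if len(r) > 5 else (1, 150)
        aln_len = qend - qstart + 1
        out.write(
            f"{q}\t{s}\t90.0\t{aln_len}\t5\t0\t{qstart}\t{qend}\t1\t{aln_len}"
            f"\t{ev:.3g}\t{bs:.1f}\t{cat}\n"
        )
    return out.getvalue()


def hits_from_tsv(text: str):
    """Parse the 12-column tabular format (+category column, + query coords).

    Returns :class:`~symbiophylo.provenance.Hit` objects grouped by query id.
    Columns follow the standard tabular layout (query, subject, identity,
    length, mismatches, gaps, qstart, qend, sstart, send, evalue, bitscore)
    with the library category appended as column 13.
    """
    from .provenance import Hit

    by_gene: dict[str, list[Hit]] = {}
    for ln, line in enumerate(io.StringIO(text), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 13:
            raise ValueError(f"line {ln}: expected >=13 columns, got {len(f)}")
        hit = Hit(
            query_id=f[0],
            subject_id=f[1],
            category=f[12],
            evalue=float(f[10]),
            bitscore=float(f[11]),
            query_range=(int(f[6]), int(f[7])),
        )
        by_gene.setdefault(hit.query_id, []).append(hit)
    return by_gene


@dataclass
class TreeScenario:
    """Specification of one planted gene-tree topology.

    ``kind`` selects the scaffold:

    * ``hgt_sister`` — query's sister clade is ``n_donor`` leaves of
      ``donor`` category with the stated ``support``; outgroup is a mixed
      far clade.  ``mixed_sister=True`` plants one off-donor leaf inside
      the sister clade.
    * ``alpha_paraphyly`` — query nests among alpha-proteobacterial and
      eukaryote leaves with all ``n_other_prok`` non-alpha prokaryotes
      outside (truth True), or with one gamma-proteobacterial leaf grafted
      next to the query (truth False).
    """

    kind: str
    donor: str = "chlorobi_a"
    support: int = 90
    n_donor: int = 2
    mixed_sister: bool = False
    paraphyly_true: bool = True
    n_alpha: int = 3
    n_euk: int = 2
    n_other_prok: int = 5

    def __post_init__(self):
        if not 0 <= self.support <= 100:
            raise ValueError(f"support {self.support} outside [0, 100]")


def simulate_gene_tree(
    scenario: TreeScenario,
    category_map: CategoryMap,
    seed: int = 0,
    query: str = "QUERY",
) -> tuple[str, dict[str, str], bool]:
    """Newick text, leaf->category map and the planted truth flag.

    Supports are written as internal node labels; branch lengths are drawn
    uniformly so midpoint rooting is exercised but the planted topology is
    fixed by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    leafmap: dict[str, str] = {query: "araphid_pennate"}

    def bl() -> str:
        return f":{rng.uniform(0.05, 0.3):.4f}"

    def leaf(name: str, category: str) -> str:
        leafmap[name] = category
        return f"{name}{bl()}"

    if scenario.kind == "hgt_sister":
        category_map.require(scenario.donor)
        donors = [leaf(f"d{i}", scenario.donor) for i in range(scenario.n_donor)]
        if scenario.mixed_sister:
            donors.append(leaf("intruder", "haptophytes"))
        sister = f"({','.join(donors)})95{bl()}" if len(donors) > 1 else donors[0]
        ingroup = f"({query}{bl()},{sister}){scenario.support}{bl()}"
        out = [
            leaf("o1", "chlorophytes"),
            leaf("o2", "gammaproteobacteria"),
            leaf("o3", "raphid_pennate"),
        ]
        newick = f"({ingroup},({out[0]},{out[1]})80{bl()},{out[2]});"
        truth = (not scenario.mixed_sister) and scenario.support > 50
    elif scenario.kind == "alpha_paraphyly":
        alpha_cats = sorted(category_map.categories_with(lambda f: f.is_alphaproteobacterium))
        euk_cats = sorted(
            category_map.categories_with(lambda f: f.is_eukaryote and not f.is_diatom)
        )
        alphas = [
            leaf(f"a{i}", alpha_cats[i % len(alpha_cats)])
            for i in range(scenario.n_alpha)
        ]
        euks = [leaf(f"e{i}", euk_cats[i % len(euk_cats)]) for i in range(scenario.n_euk)]
        proks = [
            leaf(f"p{i}", "gammaproteobacteria") for i in range(scenario.n_other_prok)
        ]
        if scenario.paraphyly_true:
            core = f"(({query}{bl()},{alphas[0]})88{bl()},({alphas[1]},{euks[0]})70{bl()})85{bl()}"
        else:
            intruder = leaf("px", "gammaproteobacteria")
            core = f"(({query}{bl()},{intruder})88{bl()},({alphas[0]},{alphas[1]})70{bl()})85{bl()}"
        rest = alphas[2:] + euks[1:]
        inner_parts = [core] + rest
        inner = f"({','.join(inner_parts)})75{bl()}"
        prok_clade = f"({','.join(proks)})99{bl()}"
        newick = f"({inner},{prok_clade});"
        truth = scenario.paraphyly_true
    else:
        raise ValueError(f"unknown scenario kind {scenario.kind!r}")
    return newick, leafmap, truth


def simulate_marker_matrix(
    n_taxa: int,
    n_markers: int,
    planted_pass: set[str],
    seed: int = 0,
) -> tuple[MarkerMatrix, TruthTable]:
    """Status/copy matrix whose selection outcome is planted per marker.

    Passing markers get presence strictly above 0.60 and mean copy strictly
    below 1.5; failing markers violate exactly one of the two rules (low
    presence, or presence-passing but mean copy >= 1.5), alternating so both
    failure modes are exercised.
    """
    if n_taxa <= 0:
        raise ValueError("n_taxa must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    markers = [f"m{i:03d}" for i in range(n_markers)]
    unknown = planted_pass - set(markers)
    if unknown:
        raise ValueError(f"planted_pass not among markers: {sorted(unknown)}")
    taxa = [f"t{i:03d}" for i in range(n_taxa)]
    status = {}
    copies = {}
    truth = TruthTable()
    fail_mode = 0
    floor_60 = (3 * n_taxa) // 5  # floor(0.60 * n) in exact integer arithmetic
    ceil_150 = (3 * n_taxa + 1) // 2  # ceil(1.50 * n)
    for m in markers:
        passing = m in planted_pass
        truth.marker_pass[m] = passing
        if passing:
            n_present = min(floor_60 + 1, n_taxa)  # strictly > 60%
            force_total = None
        elif fail_mode == 0:
            n_present = floor_60  # presence <= 60%: fails the presence rule
            force_total = None
            fail_mode = 1
        else:
            n_present = min(floor_60 + 1, n_taxa)
            force_total = ceil_150  # mean copy exactly >= 1.5: fails copy rule
            fail_mode = 0
        present_idx = rng.choice(n_taxa, size=n_present, replace=False)
        # present taxa stay 'complete' regardless of copy count: the presence
        # rule counts complete-or-fragmented only, and 'duplicated' is not
        # required for copy >= 2 (only implied the other way round)
        st = np.array(["missing"] * n_taxa, dtype=object)
        cp = np.zeros(n_taxa, dtype=int)
        st[present_idx] = "complete"
        cp[present_idx] = 1
        if force_total is not None and n_present > 0:
            cp[present_idx[0]] += max(force_total - int(cp.sum()), 0)
        elif n_present > 1 and n_present + 1 <= ceil_150 - 1:
            cp[present_idx[0]] += 1  # a little copy variation below the cutoff
        status[m] = st
        copies[m] = cp
    import pandas as pd

    return (
        MarkerMatrix(
            pd.DataFrame(status, index=taxa), pd.DataFrame(copies, index=taxa)
        ),
        truth,
    )


def simulate_alignment(
    n_taxa: int,
    length: int,
    conserved_blocks: list[tuple[int, int]],
    gap_columns: dict[int, float] | None = None,
    seed: int = 0,
) -> Alignment:
    """Amino-acid alignment with planted conserved blocks and gap columns.

    Columns inside a conserved block (1-based inclusive) share one modal
    residue in ceil(0.75 * n_taxa) rows (identity > 0.70); columns outside
    cycle residues so no residue reaches 0.70.  ``gap_columns`` maps 1-based
    column -> gap fraction, realized exactly as round(frac * n_taxa) gaps.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    for start, end in conserved_blocks:
        if not 1 <= start <= end <= length:
            raise ValueError(f"block ({start}, {end}) outside [1, {length}]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    arr = np.empty((n_taxa, length), dtype="U1")
    in_block = np.zeros(length, dtype=bool)
    for start, end in conserved_blocks:
        in_block[start - 1 : end] = True
    n_modal = min(int(np.ceil(0.75 * n_taxa)), n_taxa)
    for j in range(length):
        if in_block[j]:
            modal = AMINO[rng.integers(len(AMINO))]
            col = np.array([modal] * n_modal + list(AMINO[: n_taxa - n_modal]))
            # keep the modal count exact: remaining rows all differ from modal
            others = [a for a in AMINO if a != modal]
            col[n_modal:] = [others[k % len(others)] for k in range(n_taxa - n_modal)]
        else:
            col = np.array([AMINO[(j + k) % len(AMINO)] for k in range(n_taxa)])
        arr[:, j] = col
    if gap_columns:
        for col1, frac in gap_columns.items():
            n_gaps = int(round(frac * n_taxa))
            rows = rng.choice(n_taxa, size=n_gaps, replace=False)
            arr[rows, col1 - 1] = "-"
    taxa = [f"t{i:03d}" for i in range(n_taxa)]
    return Alignment(taxa, ["".join(r) for r in arr])
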