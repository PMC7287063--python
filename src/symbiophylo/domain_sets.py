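"""Protein-domain repertoire comparison across genomes.

Given per-genome domain (e.g. Pfam) copy-count profiles, this module
partitions a focal genome's domain set by presence/absence across reference
genomes (the regions of a Venn diagram, including the "unique to focal"
region outside it), reports the converse core-missing set (present in every
reference, absent from focal), lists high-copy focal-specific domains, and
tests mapped functional terms for over-representation with a one-sided
hypergeometric test and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DomainProfile",
    "RegionReport",
    "region_report",
    "copy_threshold_report",
    "term_enrichment",
]


@dataclass
class DomainProfile:
    """Copy counts of domain accessions in one genome (counts are positive)."""

    genome_id: str
    counts: dict[str, int]

    def __post_init__(self):
        bad = {d: c for d, c in self.counts.items() if c < 1}
        if bad:
            raise ValueError(f"non-positive counts: {bad}")

    @property
    def domains(self) -> set[str]:
        return set(self.counts)

    @classmethod
    def from_tsv(cls, path, genome_id: str | None = None) -> "DomainProfile":
        df = pd.read_csv(path, sep="\t", header=None, names=["domain", "count"],
                         comment="#")
        if df["domain"].duplicated().any():
            dupes = sorted(df.loc[df["domain"].duplicated(), "domain"])
            raise ValueError(f"duplicate accessions: {dupes}")
        gid = genome_id if genome_id is not None else str(path)
        return cls(gid, dict(zip(df["domain"], df["count"].astype(int))))


@dataclass
class RegionReport:
    """Partition of the focal domain set by reference presence pattern.

    ``regions`` maps a tuple of booleans (one per reference, in
    ``reference_ids`` order; True = present in that reference) to the focal
    domains showing that pattern.  ``unique`` is the all-False region;
    ``core_missing`` holds domains present in every reference but absent
    from the focal genome.
    """

    focal_id: str
    reference_ids: list[str]
    regions: dict[tuple[bool, ...], set[str]] = field(default_factory=dict)
    core_missing: set[str] = field(default_factory=set)

    @property
    def unique(self) -> set[str]:
        return self.regions.get((False,) * len(self.reference_ids), set())


def region_report(
    focal: DomainProfile, references: list[DomainProfile]
) -> RegionReport:
    """Classify every focal domain by its presence pattern across references."""
    if not references:
        raise ValueError("at least one reference profile required")
    ids = [focal.genome_id] + [r.genome_id for r in references]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate genome ids: {ids}")
    k = len(references)
    regions: dict[tuple[bool, ...], set[str]] = {
        tuple(bool(b >> i & 1) for i in range(k)): set() for b in range(2**k)
    }
    for domain in focal.domains:
        pattern = tuple(domain in r.domains for r in references)
        regions[pattern].add(domain)
    shared = set.intersection(*(r.domains for r in references))
    return RegionReport(
        focal.genome_id,
        [r.genome_id for r in references],
        regions,
        shared - focal.domains,
    )


def copy_threshold_report(
    profiles: list[DomainProfile],
    focal_id: str,
    min_copies: int = 5,
    require_absent_in_others: bool = True,
) -> list[tuple[str, int]]:
    """High-copy domains of the focal genome, optionally focal-exclusive.

    Lists domains with focal copy count strictly greater than ``min_copies``
    and, if required, zero copies in every other profile; sorted by
    descending focal count, then accession.
    """
    by_id = {p.genome_id: p for p in profiles}
    if focal_id not in by_id:
        raise KeyError(f"focal genome {focal_id!r} not among profiles")
    focal = by_id[focal_id]
    others = [p for p in profiles if p.genome_id != focal_id]
    out = []
    for domain, count in focal.counts.items():
        if count <= min_copies:
            continue
        if require_absent_in_others and any(domain in p.domains for p in others):
            continue
        out.append((domain, count))
    return sorted(out, key=lambda t: (-t[1], t[0]))


def term_enrichment(
    domain_to_terms: dict[str, set[str]],
    foreground: set[str],
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a foreground domain set.

    For each term annotating at least one background domain, computes the
    one-sided upper-tail probability of drawing at least the observed number
    of term-annotated domains in ``len(foreground)`` draws from the
    background, plus Benjamini-Hochberg adjusted values.  Returns a DataFrame
    indexed by term with columns ``count, expected, p, p_adj``.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    for domain in background:
        for term in domain_to_terms.get(domain, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if domain in foreground:
                term_fg[term] = term_fg.get(term, 0) + 1
    terms = sorted(term_bg)
    if not terms:
        return pd.DataFrame(columns=["count", "expected", "p", "p_adj"])
    M, N = len(background), len(foreground)
    rows = []
    for term in terms:
        n = term_bg[term]
        k = term_fg.get(term, 0)
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append((k, N * n / M, min(p, 1.0)))
    df = pd.DataFrame(rows, index=terms, columns=["count", "expected", "p"])
    df["p_adj"] = multipletests(df["p"].values, method="fdr_bh")[1]
    return df
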