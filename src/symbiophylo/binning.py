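"""Host/symbiont contig binning from GC content and LCA annotation.

A co-assembled host+symbiont metagenome shows a bimodal per-contig GC
distribution (diatom host near 51%, rhodobacteralean symbiont near 64%).
The binner fits a two-component univariate normal mixture to per-contig GC
fractions by expectation-maximization (initialized at the 25th/75th
percentiles; components reported in ascending mean order so labels are
stable across runs), hard-assigns contigs by posterior for the high-GC
component, and flags contigs whose posterior falls inside a +/-0.1 band
around 0.5 as low-confidence.  Independently, each contig is annotated with
the last common ancestor of the best-hit categories of its resident genes.
A consensus verdict combines the two evidence channels: agreement wins,
a confident channel beats an unclassified or low-confidence one, and a
confident conflict at the domain level yields "ambiguous".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy.stats import norm

from .provenance import Hit
from .taxonomy import CategoryMap, TaxonomyTree, lca

__all__ = [
    "ContigRecord",
    "MixtureFit",
    "BinAssignment",
    "gc_profile",
    "fit_gc_mixture",
    "lca_annotate_contig",
    "consensus_bin",
]

UNAMBIGUOUS = set("ACGT")
GC_BASES = set("GC")


@dataclass
class ContigRecord:
    contig_id: str
    length: int
    gc: float | None  # None when the contig has no unambiguous bases
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class MixtureFit:
    """Two-component normal mixture over per-contig GC, low-GC component first."""

    means: np.ndarray  # ascending
    sds: np.ndarray
    weights: np.ndarray
    posterior_high: np.ndarray  # P(high-GC component) per contig
    n_iter: int
    loglik_trace: list[float]
    converged: bool
    low_confidence_margin: float = 0.1
    unimodal_warning: bool = False

    @property
    def hard_assignment(self) -> np.ndarray:
        """'high_gc' where posterior >= 0.5, else 'low_gc'."""
        return np.where(self.posterior_high >= 0.5, "high_gc", "low_gc")

    @property
    def low_confidence(self) -> np.ndarray:
        m = self.low_confidence_margin
        return np.abs(self.posterior_high - 0.5) < m


@dataclass
class BinAssignment:
    contig_id: str
    gc: float | None
    gc_bin: str  # low_gc | high_gc
    posterior: float  # posterior for the assigned high/low call's high-GC component
    lca_label: str | None  # taxonomy node id or None = unclassified
    consensus: str  # host | symbiont | ambiguous


def gc_profile(source) -> dict[str, ContigRecord]:
    """Per-contig GC fraction from a FASTA file/handle.

    GC = (G+C)/(A+C+G+T); IUPAC ambiguity codes and N are excluded from the
    denominator.  Contigs with zero unambiguous bases get ``gc=None``.
    """
    records = {}
    for rec in SeqIO.parse(source, "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) == 0:
            raise ValueError(f"empty sequence record {rec.id!r}")
        counts = {b: seq.count(b) for b in UNAMBIGUOUS}
        denom = sum(counts.values())
        gc = (counts["G"] + counts["C"]) / denom if denom else None
        records[rec.id] = ContigRecord(rec.id, len(seq), gc)
    if not records:
        raise ValueError("empty FASTA: no contigs")
    return records


def fit_gc_mixture(
    gc_values,
    max_iter: int = 500,
    tol: float = 1e-8,
    low_confidence_margin: float = 0.1,
    min_sd: float = 1e-4,
) -> MixtureFit:
    """EM fit of a two-component univariate normal mixture to GC fractions.

    Deterministic: means initialize at the 25th/75th percentiles, weights at
    0.5/0.5, both component standard deviations at the overall sd.  Stops when
    the log-likelihood improves by less than ``tol``.  Emits a warning (and
    sets ``unimodal_warning``) when the fitted means are closer than the sum
    of the fitted sds, i.e. the data look unimodal.
    """
    x = np.asarray(list(gc_values), dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need >=2 distinct GC values for a mixture fit")
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[0] == mu[1]:  # heavy ties: fall back to min/max
        mu = np.array([x.min(), x.max()], dtype=float)
    sd = np.full(2, max(x.std(), min_sd))
    w = np.array([0.5, 0.5])

    trace: list[float] = []
    resp = None
    converged = False
    for it in range(1, max_iter + 1):
        logpdf = norm.logpdf(x[:, None], mu[None, :], sd[None, :]) + np.log(w)[None, :]
        mx = logpdf.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logpdf - mx).sum(axis=1))
        loglik = float(lse.sum())
        resp = np.exp(logpdf - lse[:, None])
        if trace and abs(loglik - trace[-1]) < tol:
            trace.append(loglik)
            converged = True
            break
        trace.append(loglik)
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, min_sd**2))

    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    resp = resp[:, order]
    # Ashman's D: a two-normal mixture is bimodal only for D > 2; flag fits
    # below a conservative 2.5 as effectively unimodal
    ashman_d = abs(mu[1] - mu[0]) / np.sqrt((sd[0] ** 2 + sd[1] ** 2) / 2.0)
    unimodal = bool(ashman_d < 2.5)
    if unimodal:
        warnings.warn(
            "unimodal: mixture components overlap (means "
            f"{mu[0]:.4f}/{mu[1]:.4f}, sds {sd[0]:.4f}/{sd[1]:.4f}, D={ashman_d:.2f})"
        )
    return MixtureFit(
        means=mu,
        sds=sd,
        weights=w,
        posterior_high=resp[:, 1],
        n_iter=len(trace),
        loglik_trace=trace,
        converged=converged,
        low_confidence_margin=low_confidence_margin,
        unimodal_warning=unimodal,
    )


def lca_annotate_contig(
    gene_best_hits: list[Hit],
    tree: TaxonomyTree,
    category_map: CategoryMap,
    evalue_max: float = 1e-5,
) -> str | None:
    """LCA taxonomy label for one contig from its genes' best hits.

    Each element of ``gene_best_hits`` is the single best hit of one resident
    gene; genes whose best hit is weaker than ``evalue_max`` are ignored.
    Returns None (unclassified) when no gene qualifies.
    """
    cats = []
    for h in gene_best_hits:
        category_map.require(h.category)
        if h.evalue <= evalue_max:
            cats.append(h.category)
    if not cats:
        return None
    return lca(tree, cats)


def _lca_domain(
    lca_label: str | None, tree: TaxonomyTree, host_domain: str, symbiont_domain: str
) -> str | None:
    """Map an LCA node to 'host'/'symbiont' if it sits inside either domain."""
    if lca_label is None:
        return None
    path = tree.path_to_root(lca_label)
    if host_domain in path:
        return "host"
    if symbiont_domain in path:
        return "symbiont"
    return None  # at or above the cellular root: uninformative


def consensus_bin(
    contig_id: str,
    gc: float | None,
    gc_bin: str,
    posterior_high: float,
    low_confidence: bool,
    lca_label: str | None,
    tree: TaxonomyTree,
    host_domain: str = "eukaryota",
    symbiont_domain: str = "bacteria",
    host_bin: str = "low_gc",
) -> BinAssignment:
    """Combine GC-mixture and LCA evidence into a host/symbiont/ambiguous verdict.

    ``host_bin`` states which mixture component the host occupies (the diatom
    host is the low-GC component in this system).  Agreement, or one channel
    confident while the other is unclassified/low-confidence, yields that
    channel's verdict; a confident domain-level conflict yields ambiguous.
    """
    gc_verdict = "host" if gc_bin == host_bin else "symbiont"
    lca_verdict = _lca_domain(lca_label, tree, host_domain, symbiont_domain)

    if lca_verdict is None:
        consensus = gc_verdict
    elif low_confidence:
        consensus = lca_verdict
    elif gc_verdict == lca_verdict:
        consensus = gc_verdict
    else:
        consensus = "ambiguous"
    return BinAssignment(contig_id, gc, gc_bin, posterior_high, lca_label, consensus)
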