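"""End-to-end synthetic study: simulate, deconvolve, classify, verify, count.

Chains every stage on one seeded synthetic host+symbiont dataset:

1. simulate a two-component metagenome (contigs + gene map) and a hit table
   with planted per-gene origins, including HGT candidates and chimeras;
2. bin contigs by the GC mixture and per-contig LCA consensus;
3. classify gene origins from ranked hits; detect chimeric genes;
4. confirm HGT candidates on simulated gene trees by the sister-group rule;
5. apply the contig-context contaminant filter to confirmed transfers.

Genes that segment into chimeras are handled separately from whole-gene HGT
candidates: a chimeric gene's full-length ranked-hit call mixes its
segments' signals, so it is excluded from the candidate list and reported in
its own tally.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binning, provenance, treetests
from .synthetic import (
    SimulationConfig,
    TreeScenario,
    TruthTable,
    hits_to_tsv,
    hits_from_tsv,
    simulate_gene_tree,
    simulate_hit_table,
    simulate_metagenome,
)
from .taxonomy import CategoryMap, TaxonomyTree, toy_taxonomy

__all__ = ["StudyInputs", "PipelineResult", "simulate_study", "run_pipeline"]

HGT_ORIGINS = ("chlorobi", "alphaproteobacteria", "verrucomicrobia")
HGT_DONOR_LEAF = {
    "chlorobi": "chlorobi_a",
    "alphaproteobacteria": "rhodobacterales",
    "verrucomicrobia": "verrucomicrobia_a",
}


@dataclass
class StudyInputs:
    """One simulated study: raw pipeline inputs plus the planted truth."""

    contigs_fasta: str
    gene_map_tsv: str
    hits_tsv: str
    gene_trees: dict[str, tuple[str, dict[str, str]]]  # gene -> (newick, leafmap)
    hgt_donor: dict[str, str]  # gene -> donor leaf category
    truth: TruthTable
    tree: TaxonomyTree
    category_map: CategoryMap


@dataclass
class PipelineResult:
    bins: pd.DataFrame
    origin_calls: dict[str, provenance.OriginCall]
    chimera_calls: dict[str, provenance.ChimeraCall]
    hgt_verdicts: dict[str, str]  # gene -> confirmed/rejected:<reason>
    context_verdicts: dict[str, str]  # gene -> retained/flagged_contaminant
    counts: dict[str, int] = field(default_factory=dict)
    binning_accuracy: float = float("nan")
    mixture: binning.MixtureFit | None = None


def _chimera_hit_rows(gene_id: str) -> list[tuple]:
    """Ranged hits: bacterial N-terminal half, diatom C-terminal half."""
    return [
        (gene_id, "verrucomicrobia_a|refN0", "verrucomicrobia_a", 1e-40, 320.0, 1, 150),
        (gene_id, "verrucomicrobia_b|refN1", "verrucomicrobia_b", 1e-38, 300.0, 1, 150),
        (gene_id, "araphid_pennate|refC0", "araphid_pennate", 1e-35, 280.0, 160, 300),
        (gene_id, "raphid_pennate|refC1", "raphid_pennate", 1e-33, 260.0, 160, 300),
    ]


def simulate_study(
    seed: int = 0,
    config: SimulationConfig | None = None,
    n_hgt_host: int = 7,
    n_hgt_symbiont: int = 1,
    n_chimera: int = 2,
    hit_noise: float = 0.0,
) -> StudyInputs:
    """Simulate a full host+symbiont dataset with planted HGT and chimeras.

    ``n_hgt_host`` transfers land on host contigs that also carry at least
    one diatom-origin gene (the genuine, contextually verified transfers);
    ``n_hgt_symbiont`` land on symbiont contigs whose other genes are of
    bacterial origin, so the contig-context filter must flag them.
    """
    config = config or SimulationConfig(seed=seed)
    tree, category_map = toy_taxonomy()
    fasta, gene_map_tsv, truth = simulate_metagenome(config)

    gene_map = pd.read_csv(io.StringIO(gene_map_tsv), sep="\t")
    contig_genes: dict[str, list[str]] = {}
    for gene, contig in zip(gene_map["gene_id"], gene_map["contig_id"]):
        contig_genes.setdefault(contig, []).append(gene)

    host_backgrounds = ["diatoms", "diatoms", "diatoms", "stramenopiles", "eukaryota"]
    origins: dict[str, str] = {}
    for contig, genes in contig_genes.items():
        background = "bacteria" if truth.contig_bin[contig] == "symbiont" else None
        for k, gene in enumerate(genes):
            origins[gene] = background or host_backgrounds[k % len(host_backgrounds)]

    # place transfers: host-contig candidates need a diatom-origin co-gene
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    host_multi = sorted(
        c
        for c, genes in contig_genes.items()
        if truth.contig_bin[c] == "host"
        and sum(origins[g] == "diatoms" for g in genes) >= 2
    )
    symbiont_any = sorted(
        c for c, genes in contig_genes.items() if truth.contig_bin[c] == "symbiont"
    )
    if len(host_multi) < n_hgt_host + n_chimera or len(symbiont_any) < n_hgt_symbiont:
        raise ValueError("simulated metagenome too small to place planted genes")
    chosen_host = [host_multi[i] for i in rng.choice(len(host_multi),
                   size=n_hgt_host + n_chimera, replace=False)]
    chosen_symb = [symbiont_any[i] for i in rng.choice(len(symbiont_any),
                   size=n_hgt_symbiont, replace=False)]

    hgt_genes: list[str] = []
    hgt_donor: dict[str, str] = {}
    for i, contig in enumerate(chosen_host[:n_hgt_host]):
        gene = contig_genes[contig][0]
        lineage = HGT_ORIGINS[i % len(HGT_ORIGINS)]
        origins[gene] = lineage
        hgt_genes.append(gene)
        hgt_donor[gene] = HGT_DONOR_LEAF[lineage]
        truth.gene_is_hgt[gene] = True
    for i, contig in enumerate(chosen_symb):
        gene = contig_genes[contig][0]
        lineage = HGT_ORIGINS[i % len(HGT_ORIGINS)]
        origins[gene] = lineage
        hgt_genes.append(gene)
        hgt_donor[gene] = HGT_DONOR_LEAF[lineage]
        truth.gene_is_hgt[gene] = True

    chimera_genes = [contig_genes[c][1] for c in chosen_host[n_hgt_host:]]
    for gene in chimera_genes:
        origins.pop(gene)
        truth.gene_is_chimera[gene] = True

    hits_tsv, hit_truth = simulate_hit_table(
        origins, tree, category_map, hit_noise=hit_noise, seed=seed
    )
    truth.gene_origin.update(hit_truth.gene_origin)
    chimera_rows = []
    for gene in chimera_genes:
        chimera_rows.extend(_chimera_hit_rows(gene))
    hits_tsv += hits_to_tsv(chimera_rows)

    gene_trees: dict[str, tuple[str, dict[str, str]]] = {}
    for i, gene in enumerate(hgt_genes):
        scenario = TreeScenario(kind="hgt_sister", donor=hgt_donor[gene], support=90)
        newick, leafmap, _ = simulate_gene_tree(
            scenario, category_map, seed=seed + 1000 + i, query=gene
        )
        gene_trees[gene] = (newick, {**leafmap, gene: "araphid_pennate"})

    return StudyInputs(
        fasta, gene_map_tsv, hits_tsv, gene_trees, hgt_donor, truth, tree, category_map
    )


def run_pipeline(study: StudyInputs, outdir: str | None = None) -> PipelineResult:
    """Execute every stage on a (simulated or loaded) study and tally results."""
    tree, category_map = study.tree, study.category_map

    # --- binning ---
    contigs = binning.gc_profile(io.StringIO(study.contigs_fasta))
    contig_ids = sorted(contigs)
    gc = np.array([contigs[c].gc for c in contig_ids], dtype=float)
    fit = binning.fit_gc_mixture(gc)
    gc_bin = fit.hard_assignment
    lowconf = fit.low_confidence

    by_gene = hits_from_tsv(study.hits_tsv)
    gene_map = pd.read_csv(io.StringIO(study.gene_map_tsv), sep="\t")
    gene_to_contig = dict(zip(gene_map["gene_id"], gene_map["contig_id"]))
    contig_to_genes: dict[str, list[str]] = {}
    for gene, contig in gene_to_contig.items():
        contig_to_genes.setdefault(contig, []).append(gene)

    assignments = []
    for i, cid in enumerate(contig_ids):
        best_hits = [
            min(by_gene[g], key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
            for g in contig_to_genes.get(cid, [])
            if g in by_gene
        ]
        label = binning.lca_annotate_contig(best_hits, tree, category_map)
        assignments.append(
            binning.consensus_bin(
                cid, float(gc[i]), str(gc_bin[i]), float(fit.posterior_high[i]),
                bool(lowconf[i]), label, tree,
            )
        )
    bins = pd.DataFrame(
        {
            "contig_id": [a.contig_id for a in assignments],
            "gc": [a.gc for a in assignments],
            "gc_bin": [a.gc_bin for a in assignments],
            "posterior": [a.posterior for a in assignments],
            "lca_label": [a.lca_label for a in assignments],
            "consensus": [a.consensus for a in assignments],
        }
    )

    # --- origin classification and chimera detection ---
    origin_calls: dict[str, provenance.OriginCall] = {}
    chimera_calls: dict[str, provenance.ChimeraCall] = {}
    for gene, hits in by_gene.items():
        origin_calls[gene] = provenance.classify_origin(
            provenance.rank_hits(hits), category_map
        )
        chimera_calls[gene] = provenance.detect_chimera(hits, category_map)

    candidates = sorted(
        g
        for g, call in origin_calls.items()
        if call.hgt_candidate and not chimera_calls[g].is_chimera
    )

    # --- tree confirmation ---
    hgt_verdicts: dict[str, str] = {}
    for gene in candidates:
        if gene not in study.gene_trees:
            hgt_verdicts[gene] = "rejected:no_tree"
            continue
        newick, leafmap = study.gene_trees[gene]
        gt = treetests.GeneTree.from_newick(newick, leafmap)
        outgroups = {
            cat
            for leaf, cat in leafmap.items()
            if leaf != gene and cat != study.hgt_donor[gene]
        }
        rooted = treetests.root_tree(gt, outgroups, gene)
        verdict, _ = treetests.confirm_hgt(
            rooted, gene, study.hgt_donor[gene], category_map
        )
        hgt_verdicts[gene] = verdict

    confirmed = sorted(g for g, v in hgt_verdicts.items() if v == "confirmed")
    context_verdicts = provenance.contig_context_filter(
        confirmed, origin_calls, gene_to_contig, category_map
    )

    truth_bins = study.truth.contig_bin
    pred = list(bins["consensus"].values)  # ambiguous counts as an error
    accuracy = float(
        np.mean([pred[i] == truth_bins[c] for i, c in enumerate(contig_ids)])
    )

    counts = {
        "n_contigs": len(contig_ids),
        "n_genes": len(by_gene),
        "n_hgt_candidates": len(candidates),
        "n_hgt_confirmed": len(confirmed),
        "n_hgt_retained": sum(v == "retained" for v in context_verdicts.values()),
        "n_hgt_flagged_contaminant": sum(
            v == "flagged_contaminant" for v in context_verdicts.values()
        ),
        "n_chimeras": sum(c.is_chimera for c in chimera_calls.values()),
    }

    result = PipelineResult(
        bins, origin_calls, chimera_calls, hgt_verdicts, context_verdicts,
        counts, accuracy, fit,
    )
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    result.bins.to_csv(os.path.join(outdir, "bins.tsv"), sep="\t", index=False)
    origins = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in result.origin_calls.values()],
            "level": [c.level for c in result.origin_calls.values()],
            "label": [c.label for c in result.origin_calls.values()],
            "hgt_candidate": [c.hgt_candidate for c in result.origin_calls.values()],
        }
    ).sort_values("gene_id")
    origins.to_csv(os.path.join(outdir, "origins.tsv"), sep="\t", index=False)
    hgt = pd.DataFrame(
        {
            "gene_id": sorted(result.hgt_verdicts),
            "tree_verdict": [result.hgt_verdicts[g] for g in sorted(result.hgt_verdicts)],
            "context": [
                result.context_verdicts.get(g, "") for g in sorted(result.hgt_verdicts)
            ],
        }
    )
    hgt.to_csv(os.path.join(outdir, "hgt_candidates.tsv"), sep="\t", index=False)
    chim = pd.DataFrame(
        {
            "gene_id": sorted(result.chimera_calls),
            "is_chimera": [
                result.chimera_calls[g].is_chimera for g in sorted(result.chimera_calls)
            ],
            "n_segments": [
                len(result.chimera_calls[g].segments)
                for g in sorted(result.chimera_calls)
            ],
        }
    )
    chim[chim["is_chimera"]].to_csv(
        os.path.join(outdir, "chimeras.tsv"), sep="\t", index=False
    )
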