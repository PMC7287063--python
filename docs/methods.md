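# Methods

## The analysis problem

A clonal algal culture sequenced whole carries everything that lives in the
flask. For a diatom host co-cultured with a persistent bacterial commensal,
shotgun assembly yields a simple two-organism metagenome, and every
downstream claim — genome size, gene repertoire, evidence of horizontal gene
transfer (HGT) — depends on first attributing each contig and each gene to
the right organism. symbiophylo implements that provenance analysis as a
reusable, fully testable pipeline: contig deconvolution, per-gene origin
classification, tree-based verification of transfers and commensals, and
construction of the phylogenomic supermatrices used to place the host.

All stages run on synthetic data with planted ground truth, so every
decision rule is exercised end to end without any external database or
search tool.

## Taxonomic category system

Decision rules operate over a user-supplied hierarchy: a rooted tree whose
leaves are the analysis *sub-categories* (the units libraries are grouped
into for homology searches) and whose internal nodes are named lineage
ranks. Each sub-category carries flags (`diatom`, `stramenopile`,
`eukaryote`, `prokaryote`, `alphaproteobacterium`) and an optional diatom
subgroup label; consistency (diatom ⇒ stramenopile ⇒ eukaryote; alpha ⇒
prokaryote; eukaryote/prokaryote exclusive) is validated at load time.
Node ids are case-sensitive exact strings — no fuzzy matching, by design.

A bundled 14-leaf toy taxonomy (four diatom subgroups, pelagophytes,
haptophytes, chlorophytes, two alpha-proteobacterial orders, and
gamma-proteobacteria plus two-leaf chlorobi and verrucomicrobia) supports
the test suite. Chlorobi and verrucomicrobia get two sub-categories each
deliberately: the first-two-hits rule can only call a lineage confidently
when the lineage has at least two sub-categories, and those two phyla serve
as planted HGT donors. Real analyses supply their own table (typically on
the order of 10²  sub-categories).

LCA queries are answered by root-path intersection; correctness is checked
against an independent brute-force oracle on randomized trees.

## Contig deconvolution (binning)

Per-contig GC is (G+C)/(A+C+G+T) with ambiguity codes excluded from the
denominator. The two-organism structure appears as a bimodal GC
distribution; we fit a two-component univariate normal mixture by EM.

Numerical choices:

* initialization at the 25th/75th GC percentiles, weights ½/½, both sds at
  the pooled sd — fully deterministic, no restarts needed at this scale;
* convergence when the log-likelihood improves by < 1e-8 (cap 500
  iterations); component variances floored at (1e-4)²;
* components are reported in ascending-mean order, so "low-GC" and
  "high-GC" labels never switch between runs;
* contigs are hard-assigned by posterior ≥ 0.5 for the high-GC component;
  posteriors within ±0.1 of 0.5 are flagged low-confidence;
* a fit with Ashman's D = |μ₂−μ₁| / √((σ₁²+σ₂²)/2) below 2.5 is flagged
  `unimodal` (a two-normal mixture stops being bimodal near D = 2; we warn
  slightly conservatively);
* contigs are weighted equally, not by length — the transparent default
  when no read-coverage information is available.

Independently, each contig is labelled with the LCA of its genes' single
best hits (best hit per gene, e-value ≤ 1e-5). The consensus verdict is:
agreement wins; a confident LCA at the host or symbiont domain overrides a
low-confidence GC call; a confident GC call stands when the LCA is
unclassified or uninformative (at the cellular root); a confident conflict
yields `ambiguous`. Coverage-aware binning (MetaBAT-style) is out of scope
because the pipeline consumes assemblies, not reads.

## Gene origin classification

For each gene, hits against the categorised libraries are reduced to one
best hit per sub-category ("non-redundant"; ties broken by bitscore, then
subject id) and ranked by e-value. The first two non-redundant hits decide
the call:

* two sub-categories of one lineage → that lineage (e.g. two diatom
  subgroups → diatom origin). If the lineage is not the host clade, the
  gene is flagged an HGT candidate.
* a diatom and a non-diatom stramenopile → stramenopile origin;
* a diatom and a non-stramenopile eukaryote → eukaryote origin;
* two prokaryotes from different lineages → placed at their shared ancestor
  (`prokaryote-lineage` level) but *not* flagged as HGT — the flag requires
  concentration in a single foreign lineage;
* a eukaryote/prokaryote conflict → unresolved at the cellular root;
* fewer than two non-redundant hits → unresolved.

One refinement the rule table forced: "same lineage" means the two leaves
share a parent *below* the domain level. A sub-category hanging directly
off a domain node (e.g. haptophytes directly under eukaryotes) is a
singleton lineage and cannot corroborate itself; without the depth
condition, a haptophyte + chlorophyte pair would be mis-called as a
concentrated "lineage" with an HGT flag.

Lineage-specific genes are those whose hits with e-value strictly below
1e-5 are non-empty and all within the focal set of close-relative
libraries (self-library hits excluded). The strict inequality follows the
threshold's definition; the classifier is monotone in the threshold.

### Chimeric ("S") genes

Genes assembled from segments of different origins are detected from the
query coordinates of their hits: single-linkage clustering under the rule
"overlap exceeds 50% of the shorter range", merging of any still-
overlapping cluster spans, discarding of spans under 50 residues, then
independent rank-and-classify per segment. A gene is chimeric when ≥ 2
segments obtain confident origins in different domain-level supergroups.
The thresholds are config-exposed; segmentation is our own design — the
phenomenon is defined by the finding, not by a published detector. Chimeric
genes are excluded from the whole-gene HGT candidate list (their full-
length ranked call mixes the segments' signals) and tallied separately.

### Contig-context filter

An HGT candidate whose contig carries no *other* gene of verified diatom
origin is better explained as co-assembled contamination than as transfer;
such candidates are flagged rather than retained.

## Tree-topology rules

Trees are parsed from Newick with dendropy (internal node labels read as
integer bootstrap supports of the edge above); the topology tests run on a
plain adjacency representation so that rooting can never silently migrate a
support value to a different split. A degree-2 root is suppressed on input.

* **Rooting**: on the stem edge of the smallest side containing all
  outgroup leaves, provided that side excludes the query; otherwise
  midpoint rooting with an explicit fallback flag.
* **Sister group**: the union of the non-query subtrees under the query's
  parent (so a polytomy yields a mixed sister, which rejects). The support
  of the split is the one annotated on the edge above the parent.
* **HGT confirmation**: confirmed iff every sister leaf is of the predicted
  donor category *and* support is strictly greater than 50. Unannotated
  support rejects (`no_support`) — conservative, rather than assuming 100.
* **Alpha-proteobacterial origin** (commensal rule): true iff some edge of
  the unrooted tree separates the query, ≥ 1 alpha-proteobacterial leaf and
  any eukaryote leaves from *all* non-alpha prokaryote leaves. Eukaryotes
  are allowed inside the group (the group may be paraphyletic); trees
  lacking either an alpha or a non-alpha prokaryote leaf are rejected as
  underdetermined. Verified against a brute-force bipartition-enumeration
  oracle.
* **Library screen**: a library is called commensal-positive when at least
  2 markers from a single-copy alpha-proteobacterial panel (size 27) pass
  the origin test. Monotone in the number of positive markers.

## Supermatrix construction

* **Marker selection**: from a per-taxon status matrix, keep markers
  present (complete or fragmented) in strictly more than 60% of taxa with
  mean copy number strictly below 1.5. The mean is taken over *all* taxa
  (missing = 0 copies); averaging over present taxa only is exposed as an
  alternative through the copy matrix itself. `duplicated` status does not
  count toward presence — the rule names complete-or-fragmented only.
* **Terminal trimming**: column identity = modal non-gap residue count /
  non-gap count; columns with < 2 non-gap residues never qualify (identity
  of one residue is vacuous). Keep first-through-last column with identity
  strictly above 0.70.
* **Gap trimming**: keep columns with non-gap fraction ≥ 0.5 (boundary
  kept, mirroring the reference tool's "minimum fraction without gaps"
  semantics).
* **Concatenation**: row per taxon in the union; absent taxa padded with
  gaps per partition; 1-based inclusive, contiguous partition bounds
  recorded (e.g. markers of 1,616 + 1,473 + 1,132 columns give a 4,221-
  column matrix with bounds 1–1616, 1617–3089, 3090–4221).

Both trims are idempotent and equal independent column-scan oracles on
randomized alignments.

## Domain-repertoire comparison

Per-genome domain profiles (accession → copy count) are compared as sets:
the focal genome's domains are partitioned by their presence pattern across
references (all 2^k Venn regions, with the all-absent region as the
"unique" set), and the converse core-missing set (in every reference,
absent from focal) is reported. The copy-threshold report lists domains
with focal count strictly above 5 and absent everywhere else. Term
over-representation uses the one-sided hypergeometric tail with
Benjamini–Hochberg adjustment — the minimal fully specified choice; the
annotation source, not the test, is what varies between studies.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *structure* of the study system, not its
sequences:

* **Metagenome**: host contigs with GC drawn around median 0.51 (sd 0.02),
  symbiont contigs around 0.64 (sd 0.03), 500 contigs per component;
  contig lengths normal (mean 4,000, sd 1,500, floor 500 bp); genes (300
  bp) tiled without overlap, Poisson(2) per contig. GC is realized
  constructively — an exact G+C count per contig, positions shuffled — so
  configured medians hold by construction rather than asymptotically.
* **Hit tables**: planted-origin hits receive strictly better e-values
  than trailing hits (whole-decade spacing), so ranking is unambiguous;
  tie-break behaviour is tested with hand-built fixtures instead. A
  `hit_noise` probability injects a spurious top-ranked foreign hit.
* **Gene trees**: built by grafting the query onto a scenario-specific
  scaffold, guaranteeing the planted sister group, support value, or
  (para)phyly structure; branch lengths are random so midpoint rooting is
  exercised.
* **Marker matrices / alignments**: pass/fail structure planted exactly at
  the strict thresholds (presence just above/at 60%, mean copy just
  below/at 1.5; conserved-block identity 0.75 vs 0.70 cutoff).

One global seed fans out to per-generator child seeds via
`numpy.random.SeedSequence.spawn`; outputs are byte-identical under a fixed
seed.

Not emulated: real sequence homology (hits are labels, not alignments),
indel evolution, codon structure, read-level error, assembly artifacts,
varying contig coverage, and the reference-set construction that precedes
tree building in practice. Passing recovery tests therefore demonstrates
that the decision rules are implemented exactly and are internally
consistent — not that the upstream search and alignment steps of a real
analysis are error-free.

## Problem sizes and runtime

Default verification sizes: 1,000 contigs (≈ 2,000 genes) for binning and
the end-to-end run, 200 random taxonomies × 20 queries for LCA, the
exhaustive 182-pair origin rule table × 100 input permutations, 500 planted
gene trees (≤ ~40 leaves), 20 libraries for the commensal screen, and 200
random alignments for the trimming oracles. The full suite runs in well
under a minute on one CPU; these sizes give exact (count-based) recovery
checks while keeping iteration fast.

## Known limitations

* The consensus binner assumes exactly two organisms; more complex
  communities need a general binner upstream.
* The origin classifier's escalation ladder is specific to a host-within-
  stramenopiles-within-eukaryotes hierarchy; other hosts require editing
  the flag set, not just the taxonomy table.
* The chimera detector depends on hit query coordinates; libraries reported
  without coordinates cannot be screened.
* Mixture-based binning uses GC only; two organisms with overlapping GC
  distributions (Ashman's D ≲ 2.5) are flagged but not separable by this
  channel.
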