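# Methods

This note documents the statistical procedures, the tunable parameters,
the synthetic-data model, and the numerical choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Regulatory map

**Multiple testing.** Raw eQTL p-values are corrected with the
Benjamini–Hochberg step-up procedure (statsmodels' `fdr_bh`); an
association is retained when its q-value is strictly below `alpha_fdr`
(default 0.05). Correction is applied **per disease**: each association
row is tested once for every disease its SNP is associated with,
mirroring an analysis that processes diseases separately, and a
(SNP, gene, tissue) row survives if it passes in any disease. A SNP's
surviving disease set — not its input disease set — drives the
pleiotropy flag, so a SNP whose associations survive for only one of its
two input diseases is counted as non-pleiotropic.

**Interaction classes.** Distance is measured from the SNP position to
the gene TSS. `cis` means same chromosome and distance ≤ 1 000 000 bp
(inclusive — a pair at exactly 1 Mb is cis, at 1 000 001 bp it is
trans-intrachromosomal). The 1 Mb window is the conventional cis-eQTL
definition and is configurable (`cis_window`).

**Gene categories.** With pleiotropy flags in hand: a gene whose
regulating SNPs are all pleiotropic is *identical*; a gene whose
regulators are all non-pleiotropic and whose disease span is a single
disease is *disease-specific*; every other gene is *shared*. The
"shared" definition follows the more-than-one-disease reading (a gene
becomes shared as soon as non-pleiotropic SNPs from ≥ 2 diseases, or a
mix of pleiotropic and non-pleiotropic regulators, act on it) rather
than a stricter more-than-two-SNP count; the three categories always
partition the mapped gene set. Genes present in the association input
with no surviving association are dropped with a logged count. A gene
regulated in both cis and trans is counted in the cis set, the trans
set, and a separate "both" tally.

**Rounding.** All reported percentages use half-away-from-zero rounding
at the printed precision (`percent`), implemented with decimal
arithmetic so that e.g. 225/4789 → 4.7% and 186/2065 → 9% are exact,
reproducible outputs rather than float artifacts.

## Disease PPI network

Edge retention requires combined score **strictly greater** than
`ppi_score_threshold` (default 0.7, the STRING high-confidence
convention); a reader flag divides STRING's raw 0–1000 integers by 1000.
Self-links are dropped and reciprocal duplicates collapse to one
undirected edge. The disease subnetwork keeps only edges with both
endpoints among the mapped protein-coding genes; nodes isolated within
the subgraph are excluded from the network (and therefore from its node
count), with the excluded count logged — the published node counts do
not say whether edge-less mapped genes were included, and exclusion is
the choice documented here.

## Modules

**Modularity.** Both the double-sum form and the per-community
aggregated form $\sum_c [m_c/m - (D_c/2m)^2]$ are implemented; they are
algebraically identical and the test suite holds them to 1e-12 of each
other. Edges are unweighted (the retained STRING scores do not enter the
quality function).

**Louvain.** The optimizer is written in-package: seed-shuffled sweeps
of single-node moves accepting only strictly positive modularity gains
(tolerance 1e-12), gain ties broken toward the smallest community label,
then aggregation of communities into super-nodes (internal weight
becomes a self-loop contributing twice to the super-node degree), and
repetition until a sweep makes no move. Strict-improvement moves
guarantee termination and a final Q at least that of the singleton
partition; the fixed visit-order rule plus a single integer seed make
the partition fully deterministic. An edge-less graph yields singleton
communities with Q defined as 0 (with a warning). The `resolution`
parameter scales the null term of the gain for exploration only; all
reported quantities use resolution 1, which is the canonical quality
function. Community labels are re-indexed 0..C−1 by each community's
smallest member.

**Null model.** Randomized networks preserve the exact degree sequence
by double-edge swaps (networkx `double_edge_swap`), attempting 10·m
swaps per replicate. Degree preservation keeps the size function
$s_M$ = summed member degree comparable between observed and null
modules, which is what the size-conditioned test requires.

**qs-test.** For each of `n_rand` randomized networks (default 10 000;
tests and the desk-scale pipeline use 100–200) Louvain is re-run and
every detected module contributes one (q, s) draw to the null pool. An
observed module's p-value is the add-one empirical tail
p = (1 + #{null in window with q ≥ q_M}) / (1 + #{null in window}),
where the size window starts at ±10% of $s_M$ (relative) and doubles
until it holds enough draws or spans the whole pool. Significance uses
the Šidák level α′ = 1 − (1 − α)^{1/C} across the C detected modules.

*Window occupancy.* The minimum occupancy is
max(50, ⌈1/α′⌉): with n draws the smallest attainable add-one p is
1/(1+n), so a window holding fewer than 1/α′ draws cannot reject at the
working level no matter how extreme the module is — the occupancy floor
is therefore tied to the resolution the test must deliver, not a fixed
constant. A module whose window is empty even after maximal expansion
is reported with p = 1 and a flag.

## Centrality

Each module is treated as a stand-alone network (n in the formulas is
the module's node count). Degree and closeness centrality use networkx;
closeness follows the reachable-nodes form
$CC_i = (r_i - 1)/\sum_j d(i,j)$, so nodes of a disconnected module are
scored within their component and isolated nodes score 0. Eigenvector
centrality is an in-package power iteration on A + I (the identity
shift suppresses the period-2 oscillation of bipartite graphs without
changing eigenvectors), L2-normalized, entries non-negative,
convergence at max-norm 1e-10, hard failure with the module named after
1000 iterations. On a disconnected module the vector localizes on the
component with the largest adjacency eigenvalue; entries elsewhere are
~0 and are deliberately not rescaled. The central set per module is the
intersection of the top-k of the three rankings with
k = max(1, ⌈0.1·n⌉) — ceiling with a floor of one so small modules
still nominate candidates — and score ties at the rank-k boundary break
by ascending node identifier, making the selection deterministic.

## Enrichment and drugs

The over-representation p-value for a module of n annotated genes
against a set of K annotated genes in a universe of N is the exact
hypergeometric upper tail P(X ≥ overlap) (scipy). The universe is the
annotated-background convention: nodes of the disease network that
appear in at least one set of the collection. BH correction runs per
module across the sets of one collection; separate collections (e.g.
pathway versus ontology libraries) are meant to be tested separately.
Only over-representation is tested. A term's shared-central flag is set
when its module overlap contains at least one gene that is both
shared-category and central in that module; the flag is computed for
every tested term but summarized over enriched terms only, since it
annotates the reported (enriched) results. Top-term listings sort by
q, then p, then set name for stable output.

Druggability: a protein is druggable when it appears with ≥ 1 drug in
the interaction table; drug identity is the case-folded name string and
duplicate rows are ignored. Proteins with more than 20 distinct drugs
are listed as heavily targeted. Background proportions use the supplied
gene universe.

## Synthetic data

The generator emulates the statistical structure of the five real
inputs; defaults are the desk-scale study conditions used by the test
suite and acceptance script.

| parameter | default | meaning |
| --- | --- | --- |
| `n_diseases` | 6 | disease labels D01.. |
| `n_snps` | 200 | unique SNPs on a 5 × 10 Mb genome |
| `n_genes` | 300 | gene universe, uniform TSS |
| `n_tissues` | 10 | tissue labels T01.. |
| `pleiotropy_rate` | 0.09 | fraction of SNPs with ≥ 2 diseases |
| `cis_fraction` | 0.63 | cis share among true associations |
| `true_assoc_rate` | 0.2 | probability a candidate SNP–gene pair is real |
| `effect_p_scale` | 1.0 | true p ~ Beta(0.05·scale, 1) |
| `pairs_per_snp` | 7 | candidate pairs drawn per SNP |
| `n_proteins`, `k_blocks` | 100, 3 | planted-partition PPI |
| `p_in`, `p_out` | 0.5, 0.02 | within/between-block edge probability |
| `score_range` | (0.5, 1.0) | uniform combined scores |
| `trans_single_tissue_rate` | 0.84 | trans pairs observed in one tissue |

Rationale for the non-obvious values: pleiotropy 9% and the
single-tissue rate 84% are the observed large-study proportions;
cis_fraction 0.63 matches a roughly 9:5 cis:trans association split;
seven candidate pairs per SNP reproduce the several-associations-per-
eQTL density that gives genes multiple regulating SNPs and hence a
realistic shared-gene fraction. Pleiotropic SNPs draw their disease
count from {2,3,4,5} with probabilities (0.60, 0.25, 0.10, 0.05),
reflecting that most pleiotropic SNPs link few conditions. True
associations draw p from Beta(0.05, 1) — any distribution
stochastically much smaller than uniform works, since only pass/fail
under BH matters — and null pairs draw p ~ U(0,1). All generated genes
are treated as protein-coding (the association format carries no
biotype column); non-coding filtering is exercised through the
`noncoding` argument of `build_regulatory_map`.

The PPI node pool is drawn from genes with true planted associations
first, topped up from the rest of the universe: the disease network is
induced on mapped genes, and a reference network sampled uniformly from
the gene universe would leave the planted blocks largely unobservable
after FDR filtering. One global seed feeds fixed per-stage substreams,
so identical config + seed gives byte-identical files.

**What the generator does not model** — and hence what passing tests do
not show about real data: linkage disequilibrium and locus clustering
of GWAS hits, MHC-scale haplotype structure, realistic tissue-sharing
correlations, STRING evidence channels, scale-free degree tails beyond
the planted-partition heterogeneity, and annotation hierarchies (gene
sets are flat, partially overlapping random draws). The pipeline's
correctness claims are algorithmic (filtering, classification,
optimization, testing, reporting), not biological.

## Problem sizes

The default test and acceptance conditions are deliberately desk-scale:
200 SNPs / 300 genes / 100 proteins, qs-test with 100–200
randomizations, type-I calibration over 50 Erdős–Rényi G(60, 0.1)
replicates, and brute-force oracles on graphs of ≤ 8 nodes (all set
partitions) and ≤ 30 nodes (dense eigendecomposition, exact rational
hypergeometric tails). The full suite runs in about three minutes on
one CPU; `n_rand` scales linearly for production-size runs.

## Known limitations

* Louvain is a greedy heuristic; optimality is only verified on the
  small fixture graphs, and on large networks the partition (though
  deterministic per seed) can vary across seeds.
* The qs-test conditions on size by a windowed empirical tail; with few
  randomizations the add-one estimator is conservative, and the
  occupancy floor trades size-matching sharpness for resolution.
* Per-disease BH followed by pooling survivors is one defensible
  multiple-testing scope; a single global correction would be stricter.
* Eigenvector centrality on modules with several equally dominant
  disconnected components is not uniquely defined; the iteration
  returns one dominant-component vector.
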