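# aidnet

Systems analysis of the genetic architecture shared across autoimmune
diseases, as a tested, fully offline pipeline.

Autoimmune diseases (multiple sclerosis, Crohn's disease, type-1 diabetes,
lupus, ...) frequently co-occur in individuals and families, yet the GWAS
variants associated with each disease are largely distinct. One route to
reconciling this is regulatory: variants associated with *different*
diseases may converge on the *same* target genes and pathways. `aidnet`
implements that analysis chain for researchers in statistical genetics and
network biology:

1. **Regulatory map.** SNP–gene–tissue associations (eQTL evidence,
   CoDeS3D-style) are filtered by Benjamini–Hochberg FDR < 0.05, applied
   per disease. Each surviving link is classified by genomic geometry —
   *cis* (same chromosome, SNP within 1 Mb of the gene TSS),
   *trans-intrachromosomal*, or *trans-interchromosomal*. SNPs associated
   with ≥ 2 diseases are *pleiotropic*; genes are *identical* (regulated
   only by pleiotropic SNPs), *disease-specific* (non-pleiotropic SNPs of
   a single disease), or *shared* (everything else).
2. **Disease PPI network.** A STRING-style reference interactome (no
   self-links, combined score > 0.7) is induced on the mapped
   protein-coding genes; genes without a qualifying interaction are
   excluded.
3. **Functional modules.** Louvain optimization of modularity

   $$Q = \frac{1}{2m}\sum_{ij}\Big[A_{ij} - \frac{d_i d_j}{2m}\Big]\,\delta(c_i, c_j)$$

   partitions the network; each module M is tested with the **qs-test**:
   its quality $q_M$ (additive modularity term) is compared against
   modules of comparable size $s_M$ (summed member degree) detected in
   degree-preserving randomizations of the network, with Šidák correction
   across modules.
4. **Central proteins.** Within each significant module, degree
   ($DC_i = d_i/(n-1)$), closeness ($CC_i = (r_i-1)/\sum_j d(i,j)$) and
   eigenvector ($EC = \tfrac{1}{\lambda}Ax$) centrality are computed; the
   *central* set is the intersection of the three top deciles.
5. **Enrichment and druggability.** Modules are tested against GMT gene-set
   collections by the hypergeometric upper tail with per-module BH
   correction; terms whose overlap contains a gene that is both
   shared-category and central are flagged (the "asterisk" annotation).
   Central proteins are joined to a drug–gene interaction table to report
   druggable proportions.

Because the original GWAS/GTEx/STRING snapshots cannot be redistributed,
the package ships a first-class synthetic-data generator
(`aidnet.simulate`) that emulates all five inputs with controlled ground
truth — planted pleiotropy rate, cis fraction, signal p-value
distribution, planted PPI blocks and a planted enriched gene set — so
every stage is testable end to end without downloads.

## Worked example

Run the full pipeline on a synthetic study (200 SNPs over 6 diseases,
100 proteins in 3 planted blocks, 100 qs-test randomizations):

```python
from aidnet import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(simulate=SimulationConfig(), n_rand=100, seed=1,
                        outdir="aidnet_results")
summary = run_pipeline(config)
```

which prints (via the summary dict / `aidnet_results/summary.json`):

```
SNPs passing FDR: 152  (pleiotropic: 15, 9.9%)
mapped genes: 170  categories: {'identical': 14, 'shared': 34, 'disease_specific': 122}
Ai-PPIN: 89 nodes, 415 edges, clustering coefficient 0.257
modules: 3 detected, 3 significant (Q = 0.594)
  module 0: 29 proteins, q = 0.199, s = 281, p = 0.0104, significant = True
  module 1: 29 proteins, q = 0.195, s = 258, p = 0.0063, significant = True
  module 2: 31 proteins, q = 0.200, s = 291, p = 0.0132, significant = True
central proteins: 6
enriched terms: 1 (flagged shared-central: 1)
druggable central proteins: 3/6 (50.0%)
planted-block recovery ARI: 1.00
```

Reading this: of the 200 input SNPs, 152 retain at least one FDR-passing
eQTL association, and the observed pleiotropic fraction (9.9%) recovers
the planted rate of 9%. The 170 mapped genes split into the three
regulatory categories; 89 of them form the disease PPI network. Louvain
finds exactly the three planted blocks (adjusted Rand index 1.0 against
the ground-truth labels), all three pass the qs-test, and the planted
positive-control gene set is the one enriched term — flagged because its
overlap contains a shared, central protein.

The same run is available from the shell:

```bash
aidnet run-all --seed 1 --outdir aidnet_results --n-rand 100
```

and each stage separately (`aidnet simulate / map / network / modules /
centrality / enrich / drugs`, see `aidnet --help`). File-based runs take
a YAML config with the five input paths (`aidnet run-all --config
study.yaml`); every published threshold (FDR 0.05, score 0.7, 1 Mb cis
window, top 10%, 10 000 randomizations) is a named, overridable key.

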