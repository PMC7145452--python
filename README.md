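# amynet

Mouse microglia mount a coordinated transcriptional response to amyloid
plaques: a co-expression module of immune genes whose expression rises
with plaque load, partly because microglia proliferate and partly
because individual genes are directly up-regulated by amyloid.  If that
module captures the biology of disease risk, its *human orthologues*
should be enriched for genes carrying Alzheimer's-disease association
signal — including genes whose individual SNPs are too weak for
genome-wide significance but whose combined, LD-aware gene-level
evidence is strong.

`amynet` implements that integrative analysis as a tested, reusable
pipeline, exercised end-to-end on synthetic data with recorded ground
truth:

1. **Co-expression network** (`amynet.network`) — weighted adjacency
   `a_ij = |cor(x_i, x_j)|^beta` with the soft threshold chosen by the
   scale-free topology criterion; topological overlap
   `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`; average-linkage
   clustering of `1 - TOM` into modules; module eigengenes correlated
   against plaque and tau load; top-connectivity sub-network export.
2. **Gene-based GWAS statistics** (`amynet.genestats`) — genomic-control
   correction (`lambda = median(chi2) / 0.45494`), SNP-to-gene-span
   assignment (1-based closed intervals, optional flank), LD from a
   phased reference panel, and the combined statistic
   `X = -2 * sum(log p_i)` referred to an LD-aware null.  The default
   null is an essentially exact conditional-convolution construction
   (factor decomposition of LD + FFT convolution); the classical
   Brown/Kost two-moment scaled chi-square is available as an option.
3. **Enrichment Z-test** (`amynet.enrich`) — observed versus expected
   (`N*alpha`, variance `N*alpha*(1-alpha)`) count of significant
   orthologues, with genes within 0.5 Mb conservatively collapsed into
   one, optional exclusion of established GWAS loci (fixed APOE and HLA
   windows shipped), and a candidate-gene table split into established
   versus novel.
4. **Fold-change trajectories** (`amynet.trajectory`) — per-gene fold
   change versus age-matched wild type with bootstrap intervals, and
   classification against the network-average fold change and a 3.7x
   microglial cell-number reference into direct amyloid responders,
   early-transient responders and proliferation-tracking genes.
5. **Colocalization** (`amynet.coloc`) — Wakefield approximate Bayes
   factors and the five-hypothesis posterior (PP0..PP4) for disease
   versus eQTL signals, plus the hypergeometric gene-list overlap test.
6. **Synthetic data** (`amynet.simulate`) — coupled generators for the
   expression time-course (plaque trajectories per genotype, planted
   module, latent background factors), LD-blocked haplotype panels,
   GWAS/eQTL summary statistics with planted causal genes, and an
   orthologue map — all deterministic under a seed, with the planted
   truth written alongside.

## Worked example

Create `run.yaml`:

```yaml
seed: 7
out_dir: run
simulate:
  n_genes: 1200
  n_module_genes: 150
trajectory:
  n_boot: 1000
```

and run the full pipeline:

```
$ amynet all --config run.yaml
amynet INFO -- stage simulate --
amynet INFO simulate: wrote 9 artifacts
amynet INFO -- stage network --
amynet INFO network: amyloid module 1 with 150 genes (r=0.977)
amynet INFO -- stage genescores --
amynet INFO genescores: scored 1066 genes (lambda=1.016)
amynet INFO -- stage enrich --
amynet INFO enrich: N=115, 10 candidates
amynet INFO -- stage trajectory --
amynet INFO trajectory: {'proliferation_tracking': 129,
                         'direct_amyloid': 10, 'early_transient': 10,
                         'unclassified': 1}
amynet INFO -- stage coloc --
amynet INFO coloc: 2 regions
```

The network stage recovers the planted amyloid module exactly (150
genes, eigengene–plaque correlation r = 0.977).  The enrichment report
(`run/enrichment.tsv`) shows, at the alpha = 0.05 threshold, 13
significant independent genes among N = 115 where 5.75 were expected by
chance (Z = 3.10, one-sided p = 9.6e-4); the candidate table
(`run/candidates.tsv`) lists the significant orthologues sorted by
gene-level p-value, led by genes with p ≈ 2.2e-5.  The colocalization
table separates the planted scenarios cleanly: the eQTL condition
sharing its causal variant with the disease signal gets PP4 ≈ 1, the
condition with a distinct causal variant gets PP3 ≈ 1.

Every output table carries a `#` header with the tool version and
parameters, and each stage writes a provenance sidecar with the seed
and input checksums; rerunning with the same configuration reproduces
the artifacts bit for bit.

Individual stages run as `amynet simulate|network|genescores|enrich|
trajectory|coloc`, each accepting `--config`, `--seed` and `--out-dir`.

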