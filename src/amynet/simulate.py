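"""Coupled synthetic datasets with recorded ground truth.

Five generators share one :class:`~amynet.config.SimConfig`:

* :func:`simulate_expression` — a gene x sample abundance matrix in
  which a planted microglial module tracks the amyloid-load trajectory
  multiplicatively through a cell-number factor, with designated direct
  responders, early-transient responders and proliferation-tracking
  genes; background genes carry latent co-expression factors
  independent of plaque.
* :func:`generate_orthologue_map` — a mouse-to-human symbol map with a
  configurable fraction of unmapped and many-to-one entries.
* :func:`build_annotation` — human gene spans laid out on chromosomes
  with realistic clustering so proximity collapsing has work to do.
* :func:`simulate_panel_and_gwas` — a phased haplotype panel with
  exchangeable-correlation LD blocks (one per gene) and GWAS z-scores
  drawn from a multivariate normal whose covariance equals the realized
  LD, with mean non-zero only at planted causal SNPs.
* :func:`simulate_eqtl` — per-condition eQTL summary statistics whose
  causal variant either coincides with the disease signal or not.

All generators are deterministic given the config seed.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .datatypes import (
    ExpressionDataset,
    GwasSummary,
    ReferencePanel,
    SimTruth,
)
from . import io


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def module_gene_names(config: SimConfig) -> list[str]:
    return [f"Mmod{i:04d}" for i in range(config.n_module_genes)]


def background_gene_names(config: SimConfig) -> list[str]:
    return [f"Mbgd{i:04d}" for i in range(config.n_genes - config.n_module_genes)]


def simulate_expression(config: SimConfig) -> tuple[ExpressionDataset, SimTruth]:
    """Generate the expression time-course and its planted truth.

    Module genes have expected abundance

        baseline_g * microglia_fold(age, genotype) * (1 + beta_g(age) * plaque)

    where ``beta_g`` is elevated for direct responders, transiently
    elevated for early responders and zero for proliferation-tracking
    genes.  Background genes are independent of plaque but load on
    latent factors; the first factor drives the tau_load covariate.
    Noise is log-normal multiplicative.
    """
    rng = _rng(config, 1)
    mod_genes = module_gene_names(config)
    bg_genes = background_gene_names(config)
    genes = mod_genes + bg_genes

    samples, genotype_col, age_col, plaque_col = [], [], [], []
    for g in config.genotypes:
        for a in config.ages_months:
            for r in range(config.replicates_per_cell):
                samples.append(f"{g}_{a:g}m_r{r + 1}")
                genotype_col.append(g)
                age_col.append(a)
                plaque_col.append(config.plaque(g, a))
    n_samp = len(samples)
    age_arr = np.array(age_col)
    plaque_arr = np.array(plaque_col)
    micro_curve = np.array(
        [config.microglia_fold(g, a) for g, a in zip(genotype_col, age_col)]
    )
    # shared per-sample fluctuation in microglial number
    micro_sample = micro_curve * np.exp(
        rng.normal(0.0, config.microglia_jitter_sd, n_samp)
    )

    n_mod = config.n_module_genes
    direct = set(mod_genes[: config.n_direct_responders])
    early = set(
        mod_genes[config.n_direct_responders:
                  config.n_direct_responders + config.n_early_transient]
    )
    prolif = set(mod_genes) - direct - early

    beta = np.zeros(n_mod)
    beta[: config.n_direct_responders] = config.direct_beta * rng.uniform(
        0.9, 1.1, config.n_direct_responders
    )
    bump = np.exp(-(((age_arr - config.early_peak_age) / config.early_width) ** 2))
    amp_early = config.early_amp * rng.uniform(0.9, 1.1, config.n_early_transient)

    baselines = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    )
    log_mu = np.tile(np.log(baselines)[:, None], (1, n_samp))
    log_mu[:n_mod] += np.log(micro_sample)[None, :]
    # amyloid-driven amplitude on top of cell number
    amp = np.zeros((n_mod, n_samp))
    amp += beta[:, None] * plaque_arr[None, :]
    sl = slice(config.n_direct_responders,
               config.n_direct_responders + config.n_early_transient)
    # transient amplitude is amyloid-driven: absent wherever plaque is zero
    amp[sl] += (amp_early[:, None] * bump[None, :]
                * (plaque_arr > 0)[None, :])
    log_mu[:n_mod] += np.log1p(amp)

    # background latent factors, independent of plaque; Zipf-weighted
    # factor sizes, heterogeneous strengths and a fraction of unloaded
    # genes give the connectivity spectrum a realistic heavy tail
    n_bg = len(bg_genes)
    n_f = config.n_background_factors
    factors = rng.normal(size=(n_f, n_samp))
    weights = 1.0 / np.arange(1, n_f + 1) ** config.background_zipf
    weights /= weights.sum()
    membership = rng.choice(n_f, n_bg, p=weights)
    strength = rng.uniform(*config.background_strength, n_f)
    loadings = (strength[membership] * np.abs(rng.normal(0.0, 1.0, n_bg))
                * rng.choice([-1.0, 1.0], n_bg))
    loadings[rng.random(n_bg) < config.background_unloaded_fraction] = 0.0
    log_mu[n_mod:] += loadings[:, None] * factors[membership]

    values = np.exp(log_mu + rng.normal(0.0, config.noise_sd, log_mu.shape))
    tau = 0.2 * plaque_arr + 0.2 * np.exp(0.5 * factors[0])

    ds = ExpressionDataset(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.DataFrame(
            {
                "genotype": genotype_col,
                "age_months": age_col,
                "plaque_load": plaque_arr,
                "tau_load": tau,
            },
            index=pd.Index(samples, name="sample"),
        ),
    )
    membership_map = {g: "amyloid" for g in mod_genes}
    membership_map.update(
        {g: ("background_none" if loadings[i] == 0.0
              else f"background{membership[i]:02d}")
         for i, g in enumerate(bg_genes)}
    )
    truth = SimTruth(
        module_membership=membership_map,
        direct_responders=direct,
        early_transient=early,
        proliferation_tracking=prolif,
    )
    return ds, truth


def generate_orthologue_map(config: SimConfig) -> dict[str, str]:
    """Mouse -> human symbol map by name transformation.

    A configurable fraction of genes is left unmapped (absent from the
    map) and a fraction maps many-to-one onto an existing human symbol.
    """
    rng = _rng(config, 2)
    genes = module_gene_names(config) + background_gene_names(config)
    mapping: dict[str, str] = {}
    humans = [g.upper() for g in genes]
    u = rng.random(len(genes))
    for i, g in enumerate(genes):
        if u[i] < config.unmapped_fraction:
            continue
        if u[i] < config.unmapped_fraction + config.many_to_one_fraction and i > 0:
            mapping[g] = humans[i - 1]  # collapses onto the previous symbol
        else:
            mapping[g] = humans[i]
    return mapping


def build_annotation(human_genes: list[str], config: SimConfig) -> pd.DataFrame:
    """Lay human gene spans on chromosomes.

    Genes are placed sequentially; most neighbours sit 0.8-2 Mb apart
    but a minority form sub-0.5 Mb clusters, so the proximity-collapsing
    step sees both isolated genes and chained loci.
    """
    rng = _rng(config, 3)
    per_chrom = math.ceil(len(human_genes) / config.n_chromosomes)
    rows = []
    gid = 1
    for ci in range(config.n_chromosomes):
        chunk = human_genes[ci * per_chrom: (ci + 1) * per_chrom]
        pos = 1_000_000
        for sym in chunk:
            length = int(rng.uniform(5_000, 100_000))
            rows.append(
                {"chrom": str(ci + 1), "start": pos, "end": pos + length,
                 "symbol": sym, "gene_id": gid}
            )
            gid += 1
            if rng.random() < 0.15:
                gap = int(rng.uniform(100_000, 400_000))
            else:
                gap = int(rng.uniform(800_000, 2_000_000))
            pos += length + gap
    return pd.DataFrame(rows)


def _exchangeable_block(rng, n_hap: int, k: int, target_r: float) -> np.ndarray:
    """Binary haplotype block with exchangeable pairwise correlation.

    Each haplotype carries a block 'ancestral' allele; every SNP copies
    it with probability sqrt(r) and draws fresh otherwise, giving
    pairwise correlation r between SNP columns.
    """
    f = rng.uniform(0.15, 0.85)
    w = math.sqrt(target_r)
    master = (rng.random(n_hap) < f).astype(np.int8)
    fresh = (rng.random((n_hap, k)) < f).astype(np.int8)
    copy = rng.random((n_hap, k)) < w
    return np.where(copy, master[:, None], fresh)


def simulate_panel_and_gwas(
    config: SimConfig,
    annotation: pd.DataFrame,
    causal_genes: list[str] | None = None,
) -> tuple[ReferencePanel, GwasSummary, SimTruth]:
    """Reference panel plus GWAS summary statistics on that panel.

    One LD block per annotated gene, nested inside the gene span.
    z-scores are drawn per block from MVN(mu, R_hat) where R_hat is the
    realized LD correlation of the generated haplotypes and mu is
    non-zero (+-causal_effect) only at planted causal SNPs.
    """
    rng = _rng(config, 4)
    if causal_genes is None:
        n_causal = int(round(config.causal_gene_fraction * len(annotation)))
        causal_genes = list(
            rng.choice(annotation["symbol"], size=n_causal, replace=False)
        )
    causal_set = set(causal_genes)
    unknown = causal_set - set(annotation["symbol"])
    if unknown:
        raise ValueError(f"causal genes not in annotation: {sorted(unknown)[:5]}")

    blocks, snp_rows = [], []
    z_all = []
    causal_snps: dict[str, list[str]] = {}
    for _, gene in annotation.sort_values(["chrom", "start"]).iterrows():
        k = int(rng.choice(config.ld_block_sizes))
        span = gene["end"] - gene["start"]
        if k > span:
            raise ValueError(
                f"LD block of {k} SNPs exceeds gene span of {span} bp "
                f"({gene['symbol']})"
            )
        offsets = np.sort(rng.choice(span, size=k, replace=False))
        hap = _exchangeable_block(rng, config.n_haplotypes, k, config.within_block_r)
        # fix monomorphic columns (possible at extreme frequency draws)
        for j in range(k):
            while hap[:, j].min() == hap[:, j].max():
                hap[:, j] = (rng.random(config.n_haplotypes) < 0.5).astype(np.int8)
        names = [f"rs{gene['gene_id']:05d}_{j}" for j in range(k)]
        for j in range(k):
            snp_rows.append(
                {"snp": names[j], "chr": gene["chrom"],
                 "bp": int(gene["start"] + offsets[j]),
                 "a1": "A", "a2": "G"}
            )
        blocks.append(hap)

        dos = hap[0::2].astype(float) + hap[1::2].astype(float)
        r_hat = np.corrcoef(dos, rowvar=False) if k > 1 else np.ones((1, 1))
        mu = np.zeros(k)
        if gene["symbol"] in causal_set:
            n_c = min(config.causal_snps_per_gene, k)
            which = rng.choice(k, size=n_c, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_c)
            mu[which] = signs * config.causal_effect
            causal_snps[gene["symbol"]] = [names[j] for j in which]
        cov = r_hat + 1e-8 * np.eye(k)
        z = mu + np.linalg.cholesky(cov) @ rng.standard_normal(k)
        z_all.append(z)

    hap_all = np.concatenate(blocks, axis=1)
    snps = pd.DataFrame(snp_rows)
    panel = ReferencePanel(hap_all, snps)

    z = np.concatenate(z_all)
    freq = panel.frequencies()
    se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * config.gwas_sample_size)
    from scipy.stats import norm

    table = snps.copy()
    table["beta"] = z * se
    table["se"] = se
    table["p"] = np.maximum(2.0 * norm.sf(np.abs(z)), 1e-300)
    table["freq"] = freq
    gwas = GwasSummary(table, trait="disease")
    truth = SimTruth(causal_genes=causal_set, causal_snps=causal_snps)
    return panel, gwas, truth


def simulate_eqtl(
    panel: ReferencePanel,
    region_snps: list[str],
    condition: str,
    shared_with: str | None = None,
    causal_snp: str | None = None,
    effect_z: float = 8.0,
    eqtl_sample_size: int = 500,
    seed: int = 0,
) -> GwasSummary:
    """eQTL summary statistics for one gene region and condition.

    If ``shared_with`` is given the eQTL signal is centred at that SNP
    (the colocalized case); if ``causal_snp`` is given it is centred
    there instead (distinct causal variants); with neither, the region
    is null.
    """
    if shared_with is not None and shared_with not in region_snps:
        raise ValueError(f"shared SNP {shared_with!r} absent from region")
    if causal_snp is not None and causal_snp not in region_snps:
        raise ValueError(f"causal SNP {causal_snp!r} absent from region")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    dos = panel.dosages(region_snps)
    k = len(region_snps)
    r_hat = np.corrcoef(dos, rowvar=False) if k > 1 else np.ones((1, 1))
    mu = np.zeros(k)
    target = shared_with if shared_with is not None else causal_snp
    if target is not None:
        mu[region_snps.index(target)] = effect_z
    cov = r_hat + 1e-8 * np.eye(k)
    z = mu + np.linalg.cholesky(cov) @ rng.standard_normal(k)

    sub = panel.snps.set_index("snp").loc[region_snps].reset_index()
    freq = panel.frequencies(region_snps)
    se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * eqtl_sample_size)
    from scipy.stats import norm

    table = sub.copy()
    table["beta"] = z * se
    table["se"] = se
    table["p"] = np.maximum(2.0 * norm.sf(np.abs(z)), 1e-300)
    table["freq"] = freq
    return GwasSummary(table, trait=condition)


def write_fixture_bundle(outdir, config: SimConfig) -> dict[str, Path]:
    """Write the complete coupled fixture set to ``outdir``.

    Produces expression + metadata TSV, orthologue map TSV, annotation
    TSV, panel VCF, GWAS TSV, two eQTL TSVs (one colocalized with a
    causal disease SNP, one not) and the truth JSON sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {"seed": config.seed, "n_genes": config.n_genes}

    ds, truth = simulate_expression(config)
    mapping = generate_orthologue_map(config)
    truth.orthologue_map = mapping
    module_orth = sorted(
        {mapping[g] for g in truth.module_genes() if g in mapping}
    )
    human_genes = sorted(set(mapping.values()))
    annotation = build_annotation(human_genes, config)

    rng = _rng(config, 6)
    n_causal = int(round(config.causal_gene_fraction * len(module_orth)))
    causal = list(rng.choice(module_orth, size=n_causal, replace=False))
    panel, gwas, gtruth = simulate_panel_and_gwas(config, annotation, causal)
    truth.causal_genes = gtruth.causal_genes
    truth.causal_snps = gtruth.causal_snps

    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "orthologues": outdir / "orthologues.tsv",
        "annotation": outdir / "annotation.tsv",
        "panel": outdir / "panel.vcf",
        "gwas": outdir / "gwas.tsv",
        "truth": outdir / "truth.json",
    }
    io.write_expression(ds, paths["expression"], paths["metadata"], params)
    io.write_orthologue_map(mapping, paths["orthologues"], params)
    io.write_annotation(annotation, paths["annotation"], params)
    io.write_vcf(panel, paths["panel"])
    io.write_gwas(gwas, paths["gwas"], params)

    # eQTL pair: one sharing a causal disease variant, one independent
    snps_by_gene = {
        sym: [s for s in panel.snp_ids if s.startswith(f"rs{gid:05d}_")]
        for sym, gid in zip(annotation["symbol"], annotation["gene_id"])
    }
    if truth.causal_snps:
        shared_gene = sorted(truth.causal_snps)[0]
        region = snps_by_gene[shared_gene]
        shared_snp = truth.causal_snps[shared_gene][0]
        eq_shared = simulate_eqtl(panel, region, "stimulated",
                                  shared_with=shared_snp, seed=config.seed)
        other = region[-1] if region[-1] != shared_snp else region[0]
        eq_distinct = simulate_eqtl(panel, region, "baseline",
                                    causal_snp=other, seed=config.seed + 1)
        paths["eqtl_stimulated"] = outdir / "eqtl_stimulated.tsv"
        paths["eqtl_baseline"] = outdir / "eqtl_baseline.tsv"
        io.write_gwas(eq_shared, paths["eqtl_stimulated"], params)
        io.write_gwas(eq_distinct, paths["eqtl_baseline"], params)
        truth.shared_eqtl_genes = {shared_gene: "stimulated"}

    io.write_truth(truth, paths["truth"])
    return paths
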