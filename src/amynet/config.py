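"""Simulation and pipeline configuration.

The defaults encode the emulated study design: wild-type, hemizygous and
homozygous transgenic animals sampled at five ages with four replicates
per cell (60 samples), a planted amyloid-responsive microglial module of
150 genes among 5000, a plaque load rising from 4 months of age in
homozygotes and later in hemizygotes, and a microglial cell-number
factor plateauing at 3.7-fold at 18 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class PlaqueCurve:
    """Saturating plaque-load curve: plateau * (1 - exp(-rate*(age-onset)))."""

    onset_months: float
    rate: float
    plateau: float

    def load(self, age: float) -> float:
        import math

        if self.plateau == 0 or age <= self.onset_months:
            return 0.0
        return self.plateau * (1.0 - math.exp(-self.rate * (age - self.onset_months)))


DEFAULT_PLAQUE_CURVES = {
    "WT": PlaqueCurve(onset_months=0.0, rate=0.0, plateau=0.0),
    "HET": PlaqueCurve(onset_months=6.0, rate=0.18, plateau=0.7),
    "HOM": PlaqueCurve(onset_months=4.0, rate=0.25, plateau=1.0),
}


@dataclass
class SimConfig:
    """Parameters of the coupled synthetic datasets.

    Expression arm
    --------------
    n_genes, n_module_genes : genome size and planted module size.
    genotypes, ages_months, replicates_per_cell : the sampling design.
    plaque_curves : per-genotype plaque trajectory (zero for wild-type).
    microglia_fold_max : multiplicative microglial cell-number factor at
        full plaque load (3.7 at 18 months in homozygotes).
    n_direct_responders / direct_beta : module genes with extra
        amyloid-driven amplitude beyond the cell-number increase.
    n_early_transient / early_amp / early_peak_age / early_width :
        module genes elevated only around the onset of heavy plaque.
    n_background_factors : latent co-expression factors among background
        genes (one of them drives the tau_load covariate).
    noise_sd : log-scale multiplicative dispersion.

    Genetics arm
    ------------
    ld_block_sizes : SNPs per gene-level LD block (drawn uniformly).
    within_block_r : target pairwise haplotype correlation in a block.
    n_haplotypes : haplotypes in the reference panel.
    causal_gene_fraction : fraction of module orthologues that carry
        association signal.
    causal_effect : mean non-centrality of causal SNP z-scores.
    causal_snps_per_gene : causal SNPs planted per causal gene.
    unmapped_fraction / many_to_one_fraction : orthologue-map defects.
    """

    n_genes: int = 5000
    n_module_genes: int = 150
    genotypes: tuple[str, ...] = ("WT", "HET", "HOM")
    ages_months: tuple[float, ...] = (2.0, 4.0, 8.0, 12.0, 18.0)
    replicates_per_cell: int = 4
    plaque_curves: dict = field(default_factory=lambda: dict(DEFAULT_PLAQUE_CURVES))
    microglia_fold_max: float = 3.7
    microglia_jitter_sd: float = 0.1
    n_direct_responders: int = 10
    direct_beta: float = 1.8
    n_early_transient: int = 10
    early_amp: float = 0.5
    early_peak_age: float = 8.0
    early_width: float = 3.0
    n_background_factors: int = 150
    background_zipf: float = 1.0
    background_unloaded_fraction: float = 0.35
    background_strength: tuple[float, float] = (0.2, 0.8)
    noise_sd: float = 0.15
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.2

    ld_block_sizes: tuple[int, ...] = (4, 6, 8, 10, 12)
    within_block_r: float = 0.6
    n_haplotypes: int = 500
    gwas_sample_size: int = 60000
    causal_gene_fraction: float = 10.0 / 150.0
    causal_effect: float = 6.0
    causal_snps_per_gene: int = 2
    unmapped_fraction: float = 0.08
    many_to_one_fraction: float = 0.04
    n_chromosomes: int = 20

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_module_genes", "replicates_per_cell",
                     "n_haplotypes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_module_genes > self.n_genes:
            raise ValueError("n_module_genes cannot exceed n_genes")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must lie in [0, 1)")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (diploid panel)")
        if (self.n_direct_responders + self.n_early_transient
                > self.n_module_genes):
            raise ValueError("planted responder classes exceed module size")
        if not 0.0 <= self.causal_gene_fraction <= 1.0:
            raise ValueError("causal_gene_fraction must lie in [0, 1]")
        for g in self.genotypes:
            if g not in self.plaque_curves:
                raise ValueError(f"no plaque curve for genotype {g!r}")
        ages = list(self.ages_months)
        if sorted(ages) != ages or len(set(ages)) != len(ages):
            raise ValueError("ages must be strictly increasing")
        for g, curve in self.plaque_curves.items():
            loads = [curve.load(a) for a in ages]
            if any(b < a for a, b in zip(loads, loads[1:])) or min(loads) < 0:
                raise ValueError(f"plaque load must be non-decreasing ({g})")
        if not any(self.plaque_curves[g].plateau == 0 for g in self.genotypes):
            raise ValueError("at least one genotype must be plaque-free (wild type)")

    @property
    def wild_type(self) -> str:
        for g in self.genotypes:
            if self.plaque_curves[g].plateau == 0:
                return g
        raise ValueError("no plaque-free genotype")

    def plaque(self, genotype: str, age: float) -> float:
        return self.plaque_curves[genotype].load(age)

    def microglia_fold(self, genotype: str, age: float) -> float:
        """Cell-number factor: 1 + (fold_max - 1) * plaque / plateau_hom."""
        ref = max(c.plateau for c in self.plaque_curves.values())
        return 1.0 + (self.microglia_fold_max - 1.0) * self.plaque(genotype, age) / ref

    def replace(self, **kw) -> "SimConfig":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return SimConfig(**d)
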