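"""Core in-memory containers shared across pipeline stages.

Expression matrices and summary-statistic tables are held as pandas
DataFrames with fixed schemas; the reference haplotype panel is a thin
wrapper around an int8 haplotype matrix.  Coordinates are 1-based and
intervals are closed, matching the convention of gene tables that list
inclusive start/end exon spans.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: column order for GWAS / eQTL summary-statistic tables
GWAS_COLUMNS = ["snp", "chr", "bp", "a1", "a2", "beta", "se", "p", "freq"]

#: column order for gene annotation tables (1-based, closed intervals)
ANNOTATION_COLUMNS = ["chrom", "start", "end", "symbol", "gene_id"]


@dataclass
class ExpressionDataset:
    """Gene x sample abundance matrix with per-sample metadata.

    ``values`` is indexed by gene id with one column per sample;
    ``meta`` is indexed by sample id with columns ``genotype``,
    ``age_months``, ``plaque_load`` and ``tau_load``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.meta.index):
            raise ValueError("expression columns and metadata rows must align")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionDataset":
        return ExpressionDataset(self.values.loc[list(genes)], self.meta)


@dataclass
class GwasSummary:
    """Per-SNP association records for one trait or eQTL condition."""

    table: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"GWAS table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        self.table["chr"] = self.table["chr"].astype(str)
        p = self.table["p"].to_numpy()
        if (p <= 0).any() or (p > 1).any():
            raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)


class ReferencePanel:
    """Phased haplotype matrix used only to compute LD correlations.

    ``haplotypes`` has shape (n_haplotypes, n_snps) with 0/1 alleles;
    ``snps`` is a DataFrame with columns snp, chr, bp, a1, a2 aligned to
    the haplotype columns.  Haplotypes pair consecutively into diploid
    genotypes when written to VCF.
    """

    def __init__(self, haplotypes: np.ndarray, snps: pd.DataFrame):
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        if haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if haplotypes.shape[0] % 2:
            raise ValueError("need an even number of haplotypes to form diploids")
        if haplotypes.shape[1] != len(snps):
            raise ValueError("haplotype columns must match SNP table rows")
        self.haplotypes = haplotypes
        self.snps = snps.reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self.snps["snp"])}

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp"])

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def dosages(self, snp_ids) -> np.ndarray:
        """Diploid allele dosages (n_individuals x n_snps), values 0/1/2."""
        try:
            cols = [self._index[s] for s in snp_ids]
        except KeyError as exc:
            raise KeyError(f"SNP absent from reference panel: {exc.args[0]}") from None
        h = self.haplotypes[:, cols].astype(np.float64)
        return h[0::2] + h[1::2]

    def frequencies(self, snp_ids=None) -> np.ndarray:
        h = self.haplotypes if snp_ids is None else self.haplotypes[
            :, [self._index[s] for s in snp_ids]
        ]
        return h.mean(axis=0)


@dataclass
class SimTruth:
    """Planted ground truth recorded by the synthetic-data generators."""

    module_membership: dict[str, str] = field(default_factory=dict)
    direct_responders: set[str] = field(default_factory=set)
    early_transient: set[str] = field(default_factory=set)
    proliferation_tracking: set[str] = field(default_factory=set)
    causal_genes: set[str] = field(default_factory=set)
    causal_snps: dict[str, list[str]] = field(default_factory=dict)
    shared_eqtl_genes: dict[str, str] = field(default_factory=dict)
    orthologue_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        module_genes = {g for g, m in self.module_membership.items() if m == "amyloid"}
        if module_genes and not self.direct_responders <= module_genes:
            raise ValueError("direct responders must be module genes")

    def module_genes(self, label: str = "amyloid") -> set[str]:
        return {g for g, m in self.module_membership.items() if m == label}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, set):
                d[k] = sorted(v)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        for k in ("direct_responders", "early_transient",
                  "proliferation_tracking", "causal_genes"):
            d[k] = set(d.get(k, []))
        return cls(**d)


@dataclass
class GeneScore:
    """Combined gene-level association result (one row of the score table)."""

    gene: str
    chrom: str
    start: int
    end: int
    n_snps: int
    gene_p: float
    best_snp: str
    best_snp_bp: int
    best_snp_p: float
    best_snp_beta: float
    best_snp_freq: float


@dataclass
class EnrichmentResult:
    """Excess of significant genes in a set versus the N*alpha expectation."""

    alpha: float
    n_independent: int
    observed: int
    expected: float
    variance: float
    z: float
    p_one_sided: float
    p_binomial: float
    collapse_window_bp: int
    exclusions_applied: bool

    def __post_init__(self) -> None:
        if self.n_independent >= 1 and not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0,1)")


@dataclass
class ColocResult:
    """Posterior over the five colocalization hypotheses for one region."""

    region: str
    condition: str
    pp: np.ndarray  # PP0..PP4
    priors: tuple[float, float, float]
    n_snps: int

    def __post_init__(self) -> None:
        pp = np.asarray(self.pp, dtype=float)
        if pp.shape != (5,):
            raise ValueError("pp must have five entries (PP0..PP4)")
        if abs(pp.sum() - 1.0) > 1e-12:
            raise ValueError("posteriors must sum to 1")
        self.pp = pp

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


@dataclass
class OverlapResult:
    """Hypergeometric gene-list overlap test with Bonferroni correction."""

    overlap: int
    size_a: int
    size_b: int
    universe: int
    odds_ratio: float
    p: float
    p_bonferroni: float
    n_tests: int


@dataclass
class TrajectoryProfile:
    """Fold-change trajectory of one gene in one transgenic genotype."""

    gene: str
    genotype: str
    ages: np.ndarray
    fc: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        if not (np.diff(ages) > 0).all():
            raise ValueError("ages must be strictly increasing")
        if (np.asarray(self.fc) <= 0).any():
            raise ValueError("fold changes must be positive")
        self.ages = ages


def orthologue_classes(mapping: Mapping[str, str]) -> pd.DataFrame:
    """Tabulate a mouse->human map with its mapping class per entry."""
    items = pd.DataFrame(
        {"mouse": list(mapping.keys()), "human": list(mapping.values())}
    )
    counts = items["human"].value_counts()
    items["mapping_class"] = np.where(
        items["human"].map(counts) > 1, "many-to-one", "one-to-one"
    )
    return items
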