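"""Gene-level association p-values from SNP summary statistics.

The pipeline is: correct all SNP p-values genome-wide for the genomic
inflation factor lambda, assign SNPs to gene spans (1-based closed
intervals, optional flank), compute the LD correlation matrix of each
gene's SNPs from a reference panel, and combine the SNP p-values with
Fisher's statistic referred to an LD-aware null (see
:mod:`amynet._null`).  The best (smallest-p) SNP per gene is reported
for completeness but never feeds the gene-level p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._null import CombinedNull, combined_pvalue
from .datatypes import GwasSummary, ReferencePanel

logger = logging.getLogger(__name__)

#: median of the 1-df chi-square distribution
CHI2_MEDIAN_1DF = 0.45494


def genomic_control(pvals) -> tuple[float, np.ndarray]:
    """Genomic-control correction of a vector of p-values.

    Converts p to 1-df chi-square quantiles, estimates
    lambda = median(chi2) / 0.45494, and if lambda > 1 divides the
    chi-squares by lambda before transforming back.  Deflation
    (lambda <= 1) is reported but not corrected.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / CHI2_MEDIAN_1DF)
    if lam <= 1.0:
        return lam, p.copy()
    corrected = stats.chi2.sf(chi2 / lam, df=1)
    return lam, corrected


def assign_snps_to_genes(gwas: GwasSummary, genes: pd.DataFrame,
                         flank_bp: int = 0) -> dict[str, list[int]]:
    """Map gene symbol -> row indices of SNPs inside the (flanked) span.

    A SNP belongs to a gene iff it lies on the same chromosome and
    start - flank <= bp <= end + flank (closed interval, 1-based).
    SNPs may belong to several overlapping genes; genes without SNPs
    are reported with an empty list.
    """
    if flank_bp < 0:
        raise ValueError("flank must be non-negative")
    table = gwas.table
    out: dict[str, list[int]] = {}
    by_chrom = {
        str(c): sub.sort_values("bp")
        for c, sub in table.groupby(table["chr"].astype(str))
    }
    for _, g in genes.iterrows():
        sub = by_chrom.get(str(g["chrom"]))
        if sub is None:
            out[g["symbol"]] = []
            continue
        bp = sub["bp"].to_numpy()
        lo = np.searchsorted(bp, g["start"] - flank_bp, side="left")
        hi = np.searchsorted(bp, g["end"] + flank_bp, side="right")
        out[g["symbol"]] = sub.index[lo:hi].tolist()
    return out


def ld_matrix(panel: ReferencePanel, snp_ids) -> np.ndarray:
    """Pearson correlation matrix of allele dosages for the given SNPs."""
    snp_ids = list(snp_ids)
    dos = panel.dosages(snp_ids)
    sd = dos.std(axis=0)
    if (sd == 0).any():
        bad = [s for s, v in zip(snp_ids, sd) if v == 0]
        raise ValueError(f"monomorphic SNPs in panel: {bad[:5]}")
    if len(snp_ids) == 1:
        return np.ones((1, 1))
    return np.corrcoef(dos, rowvar=False)


def brown_gene_p(snp_pvals, ld, method: str = "conv",
                 rho_transform: str = "abs") -> float:
    """Combine SNP p-values into one gene p-value under an LD matrix.

    ``method='conv'`` uses the conditional-convolution null (essentially
    exact); ``method='kost'`` the classical two-moment scaled chi-square
    with the Kost covariance polynomial on |r| (``rho_transform='abs'``)
    or r^2 (``'squared'``).
    """
    return combined_pvalue(snp_pvals, ld, method=method,
                           rho_transform=rho_transform)


@dataclass
class _GeneContext:
    symbol: str
    chrom: str
    start: int
    end: int
    snp_rows: list[int]
    ld: np.ndarray
    null: CombinedNull


class GeneScorer:
    """Precomputed per-gene LD and null distributions for repeated scoring.

    The LD matrices and combined-statistic null grids depend only on the
    panel and annotation, so when many GWAS replicates are scored
    against the same panel (calibration and power simulations) they are
    computed once here and reused by :meth:`score`.
    """

    def __init__(self, panel: ReferencePanel, genes: pd.DataFrame,
                 gwas: GwasSummary, flank_bp: int = 0,
                 method: str = "conv", rho_transform: str = "abs"):
        self.method = method
        self.rho_transform = rho_transform
        assignment = assign_snps_to_genes(gwas, genes, flank_bp)
        self.contexts: list[_GeneContext] = []
        self.unscored: list[str] = []
        n_dropped = 0
        table = gwas.table
        for _, g in genes.sort_values(["chrom", "start"]).iterrows():
            rows = assignment[g["symbol"]]
            in_panel = [r for r in rows if table.at[r, "snp"] in panel]
            n_dropped += len(rows) - len(in_panel)
            if not in_panel:
                self.unscored.append(g["symbol"])
                continue
            ids = [table.at[r, "snp"] for r in in_panel]
            try:
                R = ld_matrix(panel, ids)
            except ValueError:
                poly = [s for s in ids
                        if panel.dosages([s]).std() > 0]
                if not poly:
                    logger.info("gene %s skipped: all SNPs monomorphic",
                                g["symbol"])
                    self.unscored.append(g["symbol"])
                    continue
                in_panel = [r for r in in_panel
                            if table.at[r, "snp"] in set(poly)]
                R = ld_matrix(panel, poly)
            self.contexts.append(
                _GeneContext(g["symbol"], str(g["chrom"]), int(g["start"]),
                             int(g["end"]), in_panel,
                             R, CombinedNull(R, method=method,
                                             rho_transform=rho_transform))
            )
        if n_dropped:
            logger.info("dropped %d SNPs absent from the reference panel",
                        n_dropped)

    def score(self, gwas: GwasSummary,
              genomic_control_correction: bool = True) -> pd.DataFrame:
        """Score one set of summary statistics; returns the gene table."""
        table = gwas.table
        pvals = table["p"].to_numpy(dtype=float)
        lam = float("nan")
        if genomic_control_correction:
            lam, pvals = genomic_control(pvals)
        rows = []
        for ctx in self.contexts:
            p_snp = pvals[ctx.snp_rows]
            if len(p_snp) == 1:
                gene_p = float(p_snp[0])
            else:
                x = -2.0 * float(np.sum(np.log(np.maximum(p_snp, 1e-300))))
                gene_p = float(ctx.null.sf(x))
            best = int(np.argmin(p_snp))
            r = ctx.snp_rows[best]
            rows.append(
                {"gene": ctx.symbol, "chrom": ctx.chrom, "start": ctx.start,
                 "end": ctx.end, "n_snps": len(ctx.snp_rows),
                 "gene_p": gene_p, "best_snp": table.at[r, "snp"],
                 "best_snp_bp": int(table.at[r, "bp"]),
                 "best_snp_p": float(p_snp[best]),
                 "best_snp_beta": float(table.at[r, "beta"]),
                 "best_snp_freq": float(table.at[r, "freq"]),
                 "lambda_gc": lam}
            )
        return pd.DataFrame(rows)


def gene_scores(gwas: GwasSummary, genes: pd.DataFrame,
                panel: ReferencePanel, flank_bp: int = 0,
                method: str = "conv", rho_transform: str = "abs",
                genomic_control_correction: bool = True) -> pd.DataFrame:
    """One-shot gene scoring: GC correction, assignment, LD, combination.

    Columns mirror a per-gene association table: gene span, number of
    SNPs, combined gene p-value (on GC-adjusted input), and the best
    SNP with its position, p-value, effect size and frequency.
    """
    scorer = GeneScorer(panel, genes, gwas, flank_bp=flank_bp,
                        method=method, rho_transform=rho_transform)
    return scorer.score(gwas, genomic_control_correction)
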