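"""Bayesian colocalization of disease and eQTL association signals.

Per-SNP evidence is the Wakefield approximate Bayes factor computed
from the effect estimate and its standard error; the five-hypothesis
posterior (no signal / trait-1 only / trait-2 only / two distinct
causal variants / one shared causal variant) follows by enumerating
single-causal-variant configurations with priors p1, p2, p12, in log
space throughout.  A hypergeometric gene-list overlap test used for
cross-species module conservation lives here too.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .datatypes import ColocResult, GwasSummary, OverlapResult

#: default prior standard deviations of true effects
PRIOR_SD_CASE_CONTROL = 0.15
PRIOR_SD_QUANTITATIVE = 0.20


def wakefield_abf(beta, se, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for association at one SNP.

    With V = se^2, W = prior_sd^2, z = beta/se and r = W/(V+W):
    log ABF = 0.5*log(1-r) + 0.5*z^2*r.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior standard deviation must be positive")
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z * z * r


def se_from_p(beta, p) -> np.ndarray:
    """Back-derive standard errors from effects and two-sided p-values."""
    z = stats.norm.isf(np.asarray(p, dtype=float) / 2.0)
    z = np.maximum(z, 1e-8)
    return np.abs(np.asarray(beta, dtype=float)) / z


def coloc_pp(labf1, labf2, p1: float = 1e-4, p2: float = 1e-4,
             p12: float = 1e-5, region: str = "region",
             condition: str = "condition") -> ColocResult:
    """Posterior over colocalization hypotheses from per-SNP log ABFs.

    H0: no association; H1/H2: only trait 1/2; H3: both, distinct
    causal SNPs; H4: both, shared causal SNP.  Computed with
    log-sum-exp so |z| up to 40 cannot overflow.
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("ABF vectors must be 1-D and aligned over SNPs")
    n = l1.size
    if n < 1:
        raise ValueError("need at least one SNP")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + s1
    lh[2] = np.log(p2) + s2
    # sum over ordered distinct pairs = S1*S2 - S12
    if n == 1:
        lh[3] = -np.inf
    else:
        diff = s12 - (s1 + s2)
        lh[3] = (np.log(p1) + np.log(p2) + s1 + s2
                 + np.log1p(-np.exp(diff)) if diff < 0 else -np.inf)
    lh[4] = np.log(p12) + s12
    post = np.exp(lh - logsumexp(lh))
    post = post / post.sum()
    return ColocResult(region, condition, post, (p1, p2, p12), n)


def colocalize(gwas: GwasSummary, eqtl: GwasSummary,
               p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
               prior_sd_gwas: float = PRIOR_SD_CASE_CONTROL,
               prior_sd_eqtl: float = PRIOR_SD_QUANTITATIVE,
               region: str = "region") -> ColocResult:
    """Colocalize two summary-statistic tables over their shared SNPs."""
    merged = gwas.table.merge(eqtl.table, on="snp", suffixes=("_g", "_e"))
    if merged.empty:
        raise ValueError("no shared SNPs between the two tables")
    se_g = merged["se_g"].to_numpy()
    if not np.all(se_g > 0):
        se_g = se_from_p(merged["beta_g"], merged["p_g"])
    se_e = merged["se_e"].to_numpy()
    if not np.all(se_e > 0):
        se_e = se_from_p(merged["beta_e"], merged["p_e"])
    l1 = wakefield_abf(merged["beta_g"], se_g, prior_sd_gwas)
    l2 = wakefield_abf(merged["beta_e"], se_e, prior_sd_eqtl)
    return coloc_pp(l1, l2, p1, p2, p12, region=region, condition=eqtl.trait)


def overlap_fisher(list_a, list_b, universe, n_tests: int = 1) -> OverlapResult:
    """One-sided hypergeometric enrichment test for two gene lists.

    Both lists must be subsets of the universe; the Bonferroni
    correction multiplies by ``n_tests`` and caps at 1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(list_a)
    b = set(list_b)
    if not a <= universe or not b <= universe:
        raise ValueError("gene lists must be subsets of the universe")
    m = len(universe)
    overlap = len(a & b)
    p = float(stats.hypergeom.sf(overlap - 1, m, len(a), len(b)))
    table = np.array(
        [[overlap, len(a) - overlap],
         [len(b) - overlap, m - len(a) - len(b) + overlap]]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = float(table[0, 0] * table[1, 1]) / max(table[0, 1] * table[1, 0], 1) \
            if table[0, 1] * table[1, 0] else np.inf
    return OverlapResult(overlap=overlap, size_a=len(a), size_b=len(b),
                         universe=m, odds_ratio=odds, p=p,
                         p_bonferroni=min(1.0, p * n_tests), n_tests=n_tests)


def coloc_table(results: list[ColocResult]) -> pd.DataFrame:
    rows = [
        {"region": r.region, "condition": r.condition, "n_snps": r.n_snps,
         **{f"pp{i}": r.pp[i] for i in range(5)}}
        for r in results
    ]
    return pd.DataFrame(rows)
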