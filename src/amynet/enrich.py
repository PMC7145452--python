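"""Enrichment of a mouse network's human orthologues for GWAS association.

The observed number of significant genes in the set is compared with
the chance expectation N*alpha using a one-sided Z-test with variance
N*alpha*(1-alpha), where N counts *independent* genes: genes within
0.5 Mb of each other are conservatively collapsed into one group whose
representative carries the smallest gene p-value.  Established GWAS
loci (windows around their top SNPs, plus fixed APOE and HLA windows)
can be excluded before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EnrichmentResult

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 500_000

#: fixed exclusion windows for the two long-range-LD loci
APOE_WINDOW = ("19", 44_500_000, 46_500_000, "APOE")
HLA_WINDOW = ("6", 32_200_000, 32_800_000, "HLA")


@dataclass
class ExclusionRegions:
    """Genomic windows removed before the enrichment test."""

    windows: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, _ in self.windows:
            if start >= end:
                raise ValueError(f"empty window on chr{chrom}: {start}-{end}")

    @classmethod
    def around_loci(cls, loci: pd.DataFrame, half_window: int = DEFAULT_WINDOW_BP,
                    include_fixed: bool = True) -> "ExclusionRegions":
        """Windows +-half_window around established loci's top SNPs.

        ``loci`` needs columns chrom, bp and optionally label.
        """
        wins = [
            (str(r["chrom"]), max(1, int(r["bp"]) - half_window),
             int(r["bp"]) + half_window, str(r.get("label", r["chrom"])))
            for _, r in loci.iterrows()
        ]
        if include_fixed:
            wins += [APOE_WINDOW, HLA_WINDOW]
        return cls(wins)


def map_orthologues(mouse_genes, mapping: dict[str, str]) -> tuple[list[str], dict]:
    """Convert mouse symbols to deduplicated human symbols.

    Returns (human list in stable order, report) where the report
    counts unmapped and many-to-one entries.
    """
    seen: set[str] = set()
    human: list[str] = []
    unmapped: list[str] = []
    collapsed = 0
    for g in mouse_genes:
        h = mapping.get(g)
        if h is None:
            unmapped.append(g)
        elif h in seen:
            collapsed += 1
        else:
            seen.add(h)
            human.append(h)
    if not human:
        raise ValueError("no mouse gene could be mapped to a human symbol")
    report = {"n_input": len(list(mouse_genes)), "n_mapped": len(human),
              "n_unmapped": len(unmapped), "n_many_to_one": collapsed,
              "unmapped": unmapped}
    return human, report


def collapse_proximal(scores: pd.DataFrame,
                      window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Collapse genes within ``window_bp`` of each other into one group.

    Distance is measured between gene-span midpoints with transitive
    chaining per chromosome.  Each group's representative carries the
    minimum member gene p-value.  Input needs columns gene, chrom,
    start, end, gene_p; output adds group and is one row per group.
    """
    df = scores.copy()
    df["midpoint"] = (df["start"] + df["end"]) / 2.0
    group_ids = np.empty(len(df), dtype=int)
    gid = 0
    order = df.sort_values(["chrom", "midpoint"], kind="stable")
    prev_chrom, prev_mid = None, None
    for idx, row in order.iterrows():
        if row["chrom"] != prev_chrom or row["midpoint"] - prev_mid > window_bp:
            gid += 1
        group_ids[df.index.get_loc(idx)] = gid
        prev_chrom, prev_mid = row["chrom"], row["midpoint"]
    df["group"] = group_ids
    reps = (
        df.sort_values("gene_p", kind="stable")
        .groupby("group", as_index=False)
        .first()
        .sort_values(["chrom", "midpoint"], kind="stable")
        .reset_index(drop=True)
    )
    return reps


def apply_exclusions(scores: pd.DataFrame,
                     regions: ExclusionRegions) -> pd.DataFrame:
    """Remove genes whose span intersects any exclusion window."""
    if not regions.windows:
        return scores.copy()
    keep = np.ones(len(scores), dtype=bool)
    for i, (_, row) in enumerate(scores.iterrows()):
        for chrom, start, end, label in regions.windows:
            if (str(row["chrom"]) == chrom and row["start"] <= end
                    and row["end"] >= start):
                keep[i] = False
                logger.info("gene %s removed (overlaps %s window)",
                            row["gene"], label)
                break
    return scores.loc[keep].copy()


def enrichment_test(scores: pd.DataFrame,
                    alphas=(0.05, 0.01, 0.001),
                    window_bp: int = DEFAULT_WINDOW_BP,
                    exclusions: ExclusionRegions | None = None
                    ) -> list[EnrichmentResult]:
    """Z-test for excess of significant genes at each alpha threshold.

    ``scores`` holds the gene-level p-values of the network's mapped
    orthologues (columns gene, chrom, start, end, gene_p).  An exact
    binomial p-value is reported alongside the normal approximation.
    """
    working = scores
    applied = False
    if exclusions is not None:
        working = apply_exclusions(working, exclusions)
        applied = True
    groups = collapse_proximal(working, window_bp)
    n = len(groups)
    if n == 0:
        raise ValueError("no genes left after exclusions")
    results = []
    for alpha in alphas:
        k = int((groups["gene_p"] < alpha).sum())
        expected = n * alpha
        variance = n * alpha * (1.0 - alpha)
        z = (k - expected) / np.sqrt(variance)
        p = float(stats.norm.sf(z))
        p_binom = float(stats.binom.sf(k - 1, n, alpha)) if k > 0 else 1.0
        results.append(
            EnrichmentResult(alpha=alpha, n_independent=n, observed=k,
                             expected=expected, variance=variance, z=float(z),
                             p_one_sided=p, p_binomial=p_binom,
                             collapse_window_bp=window_bp,
                             exclusions_applied=applied)
        )
    return results


def candidate_genes(scores: pd.DataFrame, alpha: float = 0.01,
                    established: set[str] | None = None,
                    exclusions: ExclusionRegions | None = None) -> pd.DataFrame:
    """Network genes below the significance threshold, split by novelty.

    A candidate is *established* if it is in the provided list or its
    span overlaps an exclusion window; otherwise it is novel.  Sorted
    by gene p-value.
    """
    established = established or set()
    hits = scores[scores["gene_p"] < alpha].copy()
    inside = set()
    if exclusions is not None:
        kept = apply_exclusions(hits, exclusions)
        inside = set(hits["gene"]) - set(kept["gene"])
    hits["status"] = [
        "established" if (g in established or g in inside) else "novel"
        for g in hits["gene"]
    ]
    return hits.sort_values("gene_p", kind="stable").reset_index(drop=True)
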