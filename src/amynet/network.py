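"""Weighted co-expression network construction and module detection.

Adjacency is |cor|^beta (unsigned, default) or a signed-hybrid variant;
similarity between genes is the topological overlap measure (TOM),
which credits shared neighbourhoods as well as direct adjacency.
Modules come from average-linkage hierarchical clustering of 1 - TOM
with a static height cut, followed by iterative merging of modules
whose eigengenes correlate strongly.  The module eigengene (first
principal component of the standardized module submatrix) summarizes a
module per sample and is correlated against traits such as plaque load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ExpressionDataset

UNASSIGNED = 0


@dataclass
class AdjacencyConfig:
    power: float = 6.0
    network_type: str = "unsigned"  # or "signed-hybrid"
    candidate_powers: tuple = tuple(range(1, 21))
    scale_free_r2_target: float = 0.85

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("soft-threshold power must be >= 1")
        if not self.candidate_powers:
            raise ValueError("candidate power list must be non-empty")
        if self.network_type not in ("unsigned", "signed-hybrid"):
            raise ValueError(f"unknown network type {self.network_type!r}")


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> int module label, 0 = unassigned
    min_module_size: int
    merge_threshold: float

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    @property
    def modules(self) -> list[int]:
        return sorted(set(self.labels) - {UNASSIGNED})


@dataclass
class ModuleTraitResult:
    module: int
    trait: str
    r: float
    p: float
    n: int


@dataclass
class SoftThresholdResult:
    power: float
    fit_table: pd.DataFrame
    reached_target: bool


def filter_expression(dataset: ExpressionDataset, min_mean: float = 0.0,
                      top_variance: int | None = None) -> ExpressionDataset:
    """Drop low-abundance genes, then keep the most variable ones.

    ``top_variance`` retains that many genes ranked by variance of
    log-expression (None keeps all).  Gene order is preserved.
    """
    values = dataset.values
    keep = values.mean(axis=1) >= min_mean
    if not keep.any():
        raise ValueError("all genes removed by the mean filter")
    values = values.loc[keep]
    if top_variance is not None and top_variance < len(values):
        var = np.log1p(values).var(axis=1)
        chosen = var.sort_values(ascending=False).index[:top_variance]
        values = values.loc[values.index.isin(set(chosen))]
    return ExpressionDataset(values, dataset.meta)


def _correlation(matrix: np.ndarray) -> np.ndarray:
    sd = matrix.std(axis=1)
    if (sd == 0).any():
        raise ValueError("zero-variance gene: filter before building adjacency")
    return np.corrcoef(matrix)


def adjacency(matrix: np.ndarray, config: AdjacencyConfig) -> np.ndarray:
    """Gene x gene adjacency from expression (genes in rows)."""
    cor = _correlation(np.asarray(matrix, dtype=float))
    if config.network_type == "unsigned":
        adj = np.abs(cor) ** config.power
    else:  # signed-hybrid: negative correlations carry no edge
        adj = np.where(cor > 0, cor, 0.0) ** config.power
    np.fill_diagonal(adj, 1.0)
    return np.clip(adj, 0.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index of a connectivity vector.

    Bins the connectivities, regresses log10 frequency on log10 mean
    connectivity, and returns (signed R^2, slope); the R^2 is negated
    when the slope is positive.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.array([k[idx == b].mean() if counts[b] else np.nan
                      for b in range(n_bins)])
    occupied = counts > 0
    if occupied.sum() < 2:
        raise ValueError("fewer than 2 occupied connectivity bins")
    x = np.log10(means[occupied])
    y = np.log10(counts[occupied] / counts.sum())
    slope, _, r, *_ = stats.linregress(x, y)
    r2 = r * r
    return (-r2 if slope > 0 else r2), slope


def pick_soft_threshold(matrix: np.ndarray,
                        config: AdjacencyConfig) -> SoftThresholdResult:
    """Choose the smallest candidate power reaching the scale-free target.

    Falls back to the argmax power (flagged) when no candidate reaches
    the target, as happens for pure-noise input.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] < 10:
        raise ValueError("need at least 10 samples to pick a soft threshold")
    cor = _correlation(matrix)
    base = (np.abs(cor) if config.network_type == "unsigned"
            else np.where(cor > 0, cor, 0.0))
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in config.candidate_powers:
        k = (base ** beta).sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"power": beta, "sft_r2": r2, "slope": slope,
                     "mean_connectivity": k.mean()})
    fit = pd.DataFrame(rows)
    ok = fit[fit["sft_r2"] >= config.scale_free_r2_target]
    if len(ok):
        return SoftThresholdResult(float(ok["power"].iloc[0]), fit, True)
    best = fit.loc[fit["sft_r2"].idxmax(), "power"]
    warnings.warn("no candidate power reached the scale-free R2 target; "
                  "falling back to the best-fitting power", stacklevel=2)
    return SoftThresholdResult(float(best), fit, False)


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with unit diagonal.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j and k_i the connectivity.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    k = a.sum(axis=1) - np.diag(a)
    l = a @ a - a * (np.diag(a)[:, None] + np.diag(a)[None, :])
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (l + a) / denom
    t = np.clip(np.nan_to_num(t), 0.0, 1.0)
    t = (t + t.T) / 2.0
    np.fill_diagonal(t, 1.0)
    return t


def module_eigengene(matrix: np.ndarray, genes_idx=None) -> tuple[np.ndarray, float]:
    """First principal component of the gene-standardized submatrix.

    Returns (unit-norm per-sample eigengene, fraction of variance
    explained).  The sign is oriented so the mean correlation with
    member genes is positive.
    """
    sub = np.asarray(matrix, dtype=float)
    if genes_idx is not None:
        sub = sub[genes_idx]
    if sub.shape[0] < 2:
        raise ValueError("a module needs at least 2 genes for an eigengene")
    z = (sub - sub.mean(axis=1, keepdims=True))
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    cors = z @ eig / (np.linalg.norm(eig) * np.linalg.norm(z, axis=1))
    if cors.mean() < 0:
        eig = -eig
    return eig / np.linalg.norm(eig), var_explained


def detect_modules(tom_matrix: np.ndarray, genes, expression: np.ndarray,
                   min_module_size: int = 30, cut_height: float = 0.995,
                   merge_threshold: float = 0.75) -> ModuleAssignment:
    """Static-cut average-linkage clustering of 1 - TOM into modules.

    Clusters smaller than ``min_module_size`` are set to the unassigned
    label 0.  Modules whose eigengenes correlate above
    ``merge_threshold`` are merged iteratively until stable.  The
    all-equal-TOM degenerate case yields a single module.
    """
    if not 0.0 < cut_height <= 1.0:
        raise ValueError("cut height must lie in (0, 1]")
    d = 1.0 - np.asarray(tom_matrix, dtype=float)
    np.fill_diagonal(d, 0.0)
    lk = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(lk, t=cut_height, criterion="distance")

    labels = pd.Series(raw, index=pd.Index(genes, name="gene"))
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(set(small))] = UNASSIGNED
    # compact labels to 1..m by decreasing size
    kept = [m for m in labels.value_counts().index if m != UNASSIGNED]
    relabel = {m: i + 1 for i, m in enumerate(kept)}
    labels = labels.map(lambda m: relabel.get(m, UNASSIGNED))

    expression = np.asarray(expression, dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}

    def eigengenes(lb: pd.Series) -> dict[int, np.ndarray]:
        return {
            m: module_eigengene(
                expression, [gene_pos[g] for g in lb.index[lb == m]]
            )[0]
            for m in sorted(set(lb) - {UNASSIGNED})
        }

    while True:
        eigs = eigengenes(labels)
        mods = sorted(eigs)
        merged = False
        best = (merge_threshold, None)
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1:]:
                c = float(np.corrcoef(eigs[m1], eigs[m2])[0, 1])
                if c > best[0]:
                    best = (c, (m1, m2))
        if best[1] is not None:
            m1, m2 = best[1]
            labels[labels == m2] = m1
            merged = True
        if not merged:
            break
    kept = [m for m in labels.value_counts().index if m != UNASSIGNED]
    relabel = {m: i + 1 for i, m in enumerate(kept)}
    labels = labels.map(lambda m: relabel.get(m, UNASSIGNED))
    return ModuleAssignment(labels, min_module_size, merge_threshold)


def module_trait_correlation(eigengene: np.ndarray, trait: np.ndarray,
                             module: int = 0,
                             trait_name: str = "trait") -> ModuleTraitResult:
    """Pearson correlation of a module eigengene with a sample trait."""
    e = np.asarray(eigengene, dtype=float)
    t = np.asarray(trait, dtype=float)
    if e.shape != t.shape:
        raise ValueError("eigengene and trait lengths differ")
    n = e.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if t.std() == 0:
        raise ValueError("zero-variance trait")
    r = float(np.corrcoef(e, t)[0, 1])
    if abs(r) >= 1.0:
        p = float(np.nextafter(0, 1))
    else:
        tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
    return ModuleTraitResult(module, trait_name, r, max(p, np.nextafter(0, 1)), n)


@dataclass
class SubnetworkResult:
    genes: pd.DataFrame  # gene, k_within, hub
    edges: pd.DataFrame  # gene_a, gene_b, tom_weight


def top_subnetwork(tom_matrix: np.ndarray, genes, assignment: ModuleAssignment,
                   module: int, n_top: int) -> SubnetworkResult:
    """Top-connectivity members of a module plus their TOM edge table.

    Genes are ranked by intramodular connectivity (row sum of TOM over
    co-members); hubs are the top decile.
    """
    members = assignment.genes_in(module)
    if not members:
        raise ValueError(f"module {module} is empty")
    if n_top > len(members):
        raise ValueError("n_top exceeds module size")
    pos = {g: i for i, g in enumerate(genes)}
    idx = np.array([pos[g] for g in members])
    sub = np.asarray(tom_matrix)[np.ix_(idx, idx)]
    k_within = sub.sum(axis=1) - 1.0
    order = np.argsort(-k_within, kind="stable")[:n_top]
    chosen = [members[i] for i in order]
    kw = k_within[order]
    n_hub = max(1, int(np.ceil(len(members) / 10)))
    hub_cut = np.sort(k_within)[::-1][n_hub - 1]
    table = pd.DataFrame(
        {"gene": chosen, "k_within": kw, "hub": kw >= hub_cut}
    )
    rows = []
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            rows.append((chosen[i], chosen[j], sub[order[i], order[j]]))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "tom_weight"])
    return SubnetworkResult(table, edges)
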