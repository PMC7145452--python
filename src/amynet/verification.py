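"""Calibration and recovery experiments on synthetic data with known truth.

Each function runs one self-contained experiment — type-I error of the
combined gene test, agreement with a Monte-Carlo oracle, enrichment
calibration and power, proximity-collapse correctness, module recovery,
colocalization discrimination, trajectory-label accuracy, and pipeline
determinism — and returns plain numbers.  They are exercised by the
test suite and by ``scripts/acceptance.py``.

All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._null import CombinedNull
from .config import SimConfig
from . import enrich as enr
from . import network as net
from . import trajectory as traj
from . import coloc
from .simulate import _exchangeable_block, simulate_expression


def _realized_block_ld(rng, k: int, r: float, n_hap: int = 500) -> np.ndarray:
    hap = _exchangeable_block(rng, n_hap, k, r)
    for j in range(k):
        while hap[:, j].min() == hap[:, j].max():
            hap[:, j] = (rng.random(n_hap) < 0.5).astype(np.int8)
    dos = hap[0::2].astype(float) + hap[1::2]
    return np.corrcoef(dos, rowvar=False) if k > 1 else np.ones((1, 1))


# -- combined gene-test calibration -------------------------------------

def combined_test_calibration(seed: int, n_structures: int = 20,
                              n_draws: int = 100_000,
                              alphas=(0.05, 0.01)) -> pd.DataFrame:
    """Empirical type-I error of the combined test on realized block LD.

    For each structure, null z-scores are drawn from MVN(0, R) with R
    the realized LD of a simulated haplotype block (k <= 10 SNPs), and
    the rejection rate of the gene p-value at each alpha is recorded
    together with the binomial 99% CI half-width.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_structures):
        k = int(rng.integers(2, 11))
        r = float(rng.uniform(0.1, 0.9))
        R = _realized_block_ld(rng, k, r)
        null = CombinedNull(R)
        z = rng.multivariate_normal(np.zeros(k), R + 1e-10 * np.eye(k),
                                    size=n_draws, method="cholesky")
        p = np.maximum(2 * stats.norm.sf(np.abs(z)), 1e-300)
        gp = null.sf(-2 * np.sum(np.log(p), axis=1))
        row = {"structure": i, "k": k, "target_r": r}
        for a in alphas:
            rate = float((gp < a).mean())
            half = 2.576 * np.sqrt(a * (1 - a) / n_draws)
            row[f"rate_{a}"] = rate
            row[f"ok_{a}"] = abs(rate - a) <= half
        rows.append(row)
    return pd.DataFrame(rows)


def combined_test_vs_oracle(seed: int, n_cases: int = 20,
                            n_draws: int = 200_000) -> pd.DataFrame:
    """Gene p-value versus the empirical MVN Monte-Carlo p for non-null z.

    Each case draws a realized LD structure, plants moderate causal
    means, observes one z-vector, and compares the analytic p with the
    fraction of null draws exceeding the observed statistic.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cases):
        k = int(rng.integers(2, 11))
        r = float(rng.uniform(0.1, 0.9))
        R = _realized_block_ld(rng, k, r)
        mu = np.zeros(k)
        n_causal = int(rng.integers(1, min(3, k) + 1))
        mu[rng.choice(k, n_causal, replace=False)] = rng.uniform(1.5, 2.5,
                                                                 n_causal)
        cov = R + 1e-10 * np.eye(k)
        z_obs = rng.multivariate_normal(mu, cov, method="cholesky")
        x_obs = float(-2 * np.sum(np.log(
            np.maximum(2 * stats.norm.sf(np.abs(z_obs)), 1e-300))))
        p_impl = float(CombinedNull(R).sf(x_obs))
        z0 = rng.multivariate_normal(np.zeros(k), cov, size=n_draws,
                                     method="cholesky")
        x0 = -2 * np.sum(np.log(
            np.maximum(2 * stats.norm.sf(np.abs(z0)), 1e-300)), axis=1)
        p_mc = float((x0 >= x_obs).mean())
        se = np.sqrt(max(p_mc * (1 - p_mc), 1.0 / n_draws) / n_draws)
        rows.append({"case": i, "k": k, "p_impl": p_impl, "p_mc": p_mc,
                     "se_mc": se, "within_3se": abs(p_impl - p_mc) <= 3 * se})
    return pd.DataFrame(rows)


# -- enrichment ----------------------------------------------------------

class _ScaledGwasWorld:
    """A small genome with cached per-gene LD and null grids.

    Used by the enrichment calibration and power experiments: the panel
    and annotation are built once; GWAS replicates re-draw only the
    z-scores.  Network membership covers half the genes; gene spacing
    exceeds the collapse window so each gene is its own group (the
    collapse operation itself is validated separately against its
    oracle).
    """

    def __init__(self, seed: int, n_genes: int = 300,
                 n_network: int = 150):
        cfg = SimConfig(seed=seed, n_genes=n_genes,
                        n_module_genes=n_network)
        rng = np.random.default_rng(seed)
        self.rng = rng
        self.n_genes = n_genes
        self.genes = [f"GENE{i:04d}" for i in range(n_genes)]
        self.network = self.genes[:n_network]
        self.chols, self.nulls, self.ks = [], [], []
        for _ in range(n_genes):
            k = int(rng.choice(cfg.ld_block_sizes))
            r = float(cfg.within_block_r)
            R = _realized_block_ld(rng, k, r, cfg.n_haplotypes)
            self.ks.append(k)
            self.chols.append(np.linalg.cholesky(R + 1e-10 * np.eye(k)))
            self.nulls.append(CombinedNull(R))

    def gene_p_replicates(self, n_reps: int, causal: dict[int, float]
                          ) -> np.ndarray:
        """(n_genes, n_reps) matrix of gene p-values.

        ``causal`` maps gene index -> per-SNP non-centrality (applied to
        the first two SNPs of the gene's block, random signs).
        """
        out = np.empty((self.n_genes, n_reps))
        for g in range(self.n_genes):
            k = self.ks[g]
            mu = np.zeros(k)
            if g in causal:
                n_c = min(2, k)
                mu[:n_c] = self.rng.choice([-1, 1], n_c) * causal[g]
            z = mu + (self.chols[g] @
                      self.rng.standard_normal((k, n_reps))).T
            p = np.maximum(2 * stats.norm.sf(np.abs(z)), 1e-300)
            out[g] = self.nulls[g].sf(-2 * np.sum(np.log(p), axis=1))
        return out


def enrichment_calibration(seed: int, n_reps: int = 1000,
                           alpha: float = 0.05) -> float:
    """Type-I error of the enrichment Z-test under a null GWAS.

    No gene carries association, so network membership is independent
    of causal status by construction; returns the fraction of
    replicates rejected at the nominal level.  The network holds 300
    genes: for much smaller sets the discreteness of the observed count
    makes the exact rejection probability of the normal-approximation
    Z-test deviate from the nominal level no matter how well the
    gene-level p-values are calibrated (at N=150 it is 0.074 exactly).
    """
    world = _ScaledGwasWorld(seed, n_genes=600, n_network=300)
    gp = world.gene_p_replicates(n_reps, causal={})
    net_p = gp[:len(world.network)]
    n = net_p.shape[0]
    k = (net_p < alpha).sum(axis=0)
    z = (k - n * alpha) / np.sqrt(n * alpha * (1 - alpha))
    rejections = stats.norm.sf(z) < alpha
    return float(rejections.mean())


def enrichment_power(seed: int, n_reps: int = 100, n_causal: int = 10,
                     effect: float = 6.0) -> dict:
    """Power and candidate recovery with planted causal network genes.

    Per replicate, ``n_causal`` of the network orthologues carry
    association; success requires enrichment p < 1e-3 and >= 90% of the
    causal genes in the candidate table at alpha = 0.01.
    """
    world = _ScaledGwasWorld(seed)
    n_net = len(world.network)
    successes_p = 0
    successes_recovery = 0
    both = 0
    for rep in range(n_reps):
        causal_idx = world.rng.choice(n_net, n_causal, replace=False)
        gp = world.gene_p_replicates(1, {int(i): effect
                                         for i in causal_idx})[:, 0]
        net_p = gp[:n_net]
        alpha = 0.01
        k = int((net_p < alpha).sum())
        z = (k - n_net * alpha) / np.sqrt(n_net * alpha * (1 - alpha))
        p_enr = float(stats.norm.sf(z))
        recovered = (net_p[causal_idx] < alpha).mean()
        ok_p = p_enr < 1e-3
        ok_r = recovered >= 0.9
        successes_p += ok_p
        successes_recovery += ok_r
        both += ok_p and ok_r
    return {"enrichment_success_rate": successes_p / n_reps,
            "recovery_success_rate": successes_recovery / n_reps,
            "joint_success_rate": both / n_reps}


def collapse_vs_oracle(seed: int, n_layouts: int = 1000,
                       window_bp: int = 500_000) -> int:
    """Mismatches between proximity collapsing and a union-find oracle."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_layouts):
        n = int(rng.integers(2, 40))
        chrom = rng.integers(1, 5, n).astype(str)
        mid = rng.integers(1, 20_000_000, n).astype(float)
        df = pd.DataFrame({"gene": [f"g{i}" for i in range(n)],
                           "chrom": chrom, "start": mid - 100,
                           "end": mid + 100,
                           "gene_p": rng.uniform(0, 1, n)})
        out = enr.collapse_proximal(df, window_bp)

        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if chrom[i] == chrom[j] and abs(mid[i] - mid[j]) <= window_bp:
                    parent[find(i)] = find(j)
        groups: dict[int, list[float]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(df["gene_p"][i])
        want = sorted(min(v) for v in groups.values())
        got = sorted(out["gene_p"])
        if len(out) != len(groups) or not np.allclose(got, want):
            mismatches += 1
    return mismatches


# -- network -------------------------------------------------------------

def module_recovery(seed: int, config: SimConfig | None = None) -> dict:
    """Detect the amyloid module on the default bundle and score it.

    Returns the binary adjusted Rand index of detected-vs-planted
    membership and the eigengene-plaque correlation.
    """
    cfg = config or SimConfig(seed=seed)
    ds, truth = simulate_expression(cfg)
    filtered = net.filter_expression(ds, min_mean=1.0, top_variance=2000)
    matrix = np.log1p(filtered.values.to_numpy())
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sft = net.pick_soft_threshold(matrix, net.AdjacencyConfig())
    tom_m = net.tom(net.adjacency(matrix,
                                  net.AdjacencyConfig(power=sft.power)))
    assignment = net.detect_modules(tom_m, list(filtered.genes), matrix)
    plaque = filtered.meta["plaque_load"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(filtered.genes)}
    best = (0.0, None)
    for m in assignment.modules:
        idx = [gene_pos[g] for g in assignment.genes_in(m)]
        eig, _ = net.module_eigengene(matrix, idx)
        r = net.module_trait_correlation(eig, plaque, m, "plaque_load").r
        if abs(r) > abs(best[0]):
            best = (r, m)
    planted = truth.module_genes()
    detected = {g for g in filtered.genes if assignment.labels[g] == best[1]}
    ari = _binary_ari(list(filtered.genes), planted, detected)
    return {"ari": ari, "eigengene_plaque_r": abs(best[0]),
            "module_size": len(detected),
            "soft_power": sft.power,
            "sft_reached_target": bool(sft.reached_target)}


def _binary_ari(genes, set_a, set_b) -> float:
    """Adjusted Rand index of two binary partitions (no sklearn needed)."""
    a = np.array([g in set_a for g in genes])
    b = np.array([g in set_b for g in genes])
    n = len(genes)
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    n00 = n - n11 - n10 - n01

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(n11) + comb2(n10) + comb2(n01) + comb2(n00)
    sum_a = comb2(n11 + n10) + comb2(n01 + n00)
    sum_b = comb2(n11 + n01) + comb2(n10 + n00)
    expected = sum_a * sum_b / comb2(n)
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        return 1.0
    return float((sum_ij - expected) / (maximum - expected))


def tom_oracle_max_error(seed: int, n_matrices: int = 50,
                         max_nodes: int = 8) -> float:
    """Largest |TOM - brute force| over random small adjacencies."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(2, max_nodes + 1))
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        t = net.tom(a)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l_ij = sum(a[i, u] * a[u, j] for u in range(n)
                           if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                want = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                worst = max(worst, abs(t[i, j] - want))
    return worst


# -- colocalization ------------------------------------------------------

def coloc_discrimination(seed: int, n_runs: int = 200,
                         n_blocks: int = 5, block_size: int = 10,
                         z_causal: float = 8.0) -> dict:
    """PP4 / PP3 success rates for shared and distinct causal variants.

    The region holds ``n_blocks`` LD blocks of ``block_size`` SNPs; the
    shared scenario puts z ~ 8 at one SNP in both traits, the distinct
    scenario at two SNPs in different blocks (hence low LD).
    """
    rng = np.random.default_rng(seed)
    k = n_blocks * block_size
    blocks = []
    for _ in range(n_blocks):
        blocks.append(_realized_block_ld(rng, block_size, 0.6))
    R = np.zeros((k, k))
    for b, Rb in enumerate(blocks):
        s = b * block_size
        R[s:s + block_size, s:s + block_size] = Rb
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(k))
    se1 = np.full(k, 0.03)
    se2 = np.full(k, 0.07)

    def run(shared: bool):
        i = int(rng.integers(0, k))
        if shared:
            j = i
        else:
            other_blocks = [b for b in range(n_blocks)
                            if b != i // block_size]
            b = int(rng.choice(other_blocks))
            j = int(b * block_size + rng.integers(0, block_size))
        mu1 = np.zeros(k)
        mu2 = np.zeros(k)
        mu1[i] = z_causal * rng.choice([-1, 1])
        mu2[j] = z_causal * rng.choice([-1, 1])
        z1 = mu1 + chol @ rng.standard_normal(k)
        z2 = mu2 + chol @ rng.standard_normal(k)
        l1 = coloc.wakefield_abf(z1 * se1, se1, coloc.PRIOR_SD_CASE_CONTROL)
        l2 = coloc.wakefield_abf(z2 * se2, se2, coloc.PRIOR_SD_QUANTITATIVE)
        return coloc.coloc_pp(l1, l2).pp

    pp4_ok = sum(run(True)[4] > 0.9 for _ in range(n_runs))
    pp3_ok = sum(run(False)[3] > 0.9 for _ in range(n_runs))
    return {"pp4_rate": pp4_ok / n_runs, "pp3_rate": pp3_ok / n_runs}


# -- trajectory ----------------------------------------------------------

def trajectory_accuracy(seed: int, config: SimConfig | None = None,
                        n_boot: int = 2000) -> dict:
    """Fraction of planted genes receiving their true response label."""
    cfg = config or SimConfig(seed=seed)
    ds, truth = simulate_expression(cfg)
    genotype = max(cfg.genotypes,
                   key=lambda g: cfg.plaque_curves[g].plateau)
    result = traj.fold_change_table(ds, sorted(truth.module_genes()),
                                    genotype, n_boot=n_boot, seed=seed)
    classes = traj.classify_response(result)
    label = dict(zip(classes["gene"], classes["label"]))
    wanted = {}
    wanted.update({g: "direct_amyloid" for g in truth.direct_responders})
    wanted.update({g: "early_transient" for g in truth.early_transient})
    wanted.update({g: "proliferation_tracking"
                   for g in truth.proliferation_tracking})
    correct = sum(label[g] == w for g, w in wanted.items())
    per_class = {}
    for cls in ("direct_amyloid", "early_transient",
                "proliferation_tracking"):
        members = [g for g, w in wanted.items() if w == cls]
        per_class[cls] = sum(label[g] == cls for g in members) / len(members)
    return {"accuracy": correct / len(wanted), "per_class": per_class,
            "n_planted": len(wanted)}


# -- pipeline ------------------------------------------------------------

def pipeline_determinism(seed: int, workdir: Path,
                         n_genes: int = 600, n_module: int = 100) -> dict:
    """Run the full pipeline twice; compare artifact checksums.

    Also reports the enrichment p-value of the detected module so the
    end-to-end integration (planted causal orthologues flagged) is
    checked on the same run.
    """
    from .pipeline import RunConfig, run_pipeline

    workdir = Path(workdir)
    sums = []
    for tag in ("a", "b"):
        cfg = RunConfig(
            seed=seed, out_dir=workdir / tag,
            simulate={"n_genes": n_genes, "n_module_genes": n_module,
                      "n_direct_responders": 8, "n_early_transient": 8},
            network={"top_variance": min(2000, n_genes)},
            trajectory={"n_boot": 500},
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(cfg)
        digest = {}
        for f in sorted((workdir / tag).rglob("*")):
            if f.is_file() and not f.name.endswith("provenance.json"):
                digest[str(f.relative_to(workdir / tag))] = hashlib.md5(
                    f.read_bytes()).hexdigest()
        sums.append(digest)
    identical = sums[0] == sums[1]
    enrichment = pd.read_csv(workdir / "a" / "enrichment.tsv", sep="\t",
                             comment="#")
    row = enrichment[(enrichment["alpha"] == 0.01)
                     & (~enrichment["exclusions_applied"])].iloc[0]
    return {"identical": identical,
            "enrichment_p_alpha01": float(row["p_one_sided"]),
            "n_artifacts": len(sums[0])}
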