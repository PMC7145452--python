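"""Stage orchestration shared by the command-line interface.

Each stage reads its inputs from, and writes its outputs to, one
artifact directory, so stages can run individually or as a dependency-
ordered batch.  Every output table carries a provenance sidecar with
the parameters, seed and input checksums that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .config import SimConfig
from .datatypes import GwasSummary
from . import network as net
from . import genestats
from . import enrich as enr
from . import trajectory as traj
from . import coloc as col
from .simulate import write_fixture_bundle

logger = logging.getLogger("amynet")

STAGES = ("simulate", "network", "genescores", "enrich", "trajectory", "coloc")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: Path = Path("amynet_run")
    simulate: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    genescores: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    coloc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.out_dir = Path(cfg.out_dir)
        return cfg

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.simulate)


class MissingArtifactError(FileNotFoundError):
    pass


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path.name}: run the '{producer}' stage first"
        )
    return path


def _data_dir(cfg: RunConfig) -> Path:
    return cfg.out_dir / "data"


def stage_simulate(cfg: RunConfig) -> dict:
    paths = write_fixture_bundle(_data_dir(cfg), cfg.sim_config())
    io.write_provenance(cfg.out_dir / "simulate.provenance.json", "simulate",
                        cfg.simulate, cfg.seed)
    logger.info("simulate: wrote %d artifacts", len(paths))
    return paths


def stage_network(cfg: RunConfig) -> pd.DataFrame:
    d = _data_dir(cfg)
    ds = io.read_expression(_require(d / "expression.tsv", "simulate"),
                            d / "metadata.tsv")
    p = cfg.network
    filtered = net.filter_expression(ds, min_mean=p.get("min_mean", 1.0),
                                     top_variance=p.get("top_variance", 2000))
    matrix = np.log1p(filtered.values.to_numpy())
    acfg = net.AdjacencyConfig(
        network_type=p.get("network_type", "unsigned"),
        scale_free_r2_target=p.get("scale_free_r2_target", 0.85),
    )
    sft = net.pick_soft_threshold(matrix, acfg)
    acfg.power = p.get("power") or sft.power
    adj = net.adjacency(matrix, acfg)
    tom_m = net.tom(adj)
    assignment = net.detect_modules(
        tom_m, filtered.genes, matrix,
        min_module_size=p.get("min_module_size", 30),
        cut_height=p.get("cut_height", 0.995),
        merge_threshold=p.get("merge_threshold", 0.75),
    )
    plaque = filtered.meta["plaque_load"].to_numpy()
    trait_rows = []
    best = (0.0, None)
    for m in assignment.modules:
        idx = [list(filtered.genes).index(g) for g in assignment.genes_in(m)]
        eig, _ = net.module_eigengene(matrix, idx)
        for trait in ("plaque_load", "tau_load"):
            res = net.module_trait_correlation(
                eig, filtered.meta[trait].to_numpy(), m, trait
            )
            trait_rows.append(res.__dict__)
            if trait == "plaque_load" and abs(res.r) > abs(best[0]):
                best = (res.r, m)
    amyloid_module = best[1]
    if amyloid_module is None:
        raise RuntimeError("no modules detected")
    members = assignment.genes_in(amyloid_module)
    sub = net.top_subnetwork(tom_m, list(filtered.genes), assignment,
                             amyloid_module,
                             min(p.get("n_top", 147), len(members)))
    membership = pd.DataFrame(
        {"gene": assignment.labels.index,
         "module": assignment.labels.to_numpy()}
    )
    membership["amyloid_module"] = membership["module"] == amyloid_module
    params = {"power": acfg.power, "amyloid_module": amyloid_module,
              "sft_reached_target": sft.reached_target, "seed": cfg.seed}
    io.write_table(membership, cfg.out_dir / "module_membership.tsv", params)
    io.write_table(pd.DataFrame(trait_rows),
                   cfg.out_dir / "module_trait.tsv", params)
    io.write_table(sub.genes, cfg.out_dir / "subnetwork_genes.tsv", params)
    io.write_table(sub.edges, cfg.out_dir / "subnetwork_edges.tsv", params)
    io.write_provenance(cfg.out_dir / "network.provenance.json", "network",
                        params, cfg.seed, [d / "expression.tsv"])
    logger.info("network: amyloid module %s with %d genes (r=%.3f)",
                amyloid_module, len(members), best[0])
    return membership


def stage_genescores(cfg: RunConfig) -> pd.DataFrame:
    d = _data_dir(cfg)
    gwas = io.read_gwas(_require(d / "gwas.tsv", "simulate"), trait="disease")
    genes = io.read_annotation(_require(d / "annotation.tsv", "simulate"))
    panel = io.read_vcf(_require(d / "panel.vcf", "simulate"))
    p = cfg.genescores
    scores = genestats.gene_scores(
        gwas, genes, panel,
        flank_bp=p.get("flank_bp", 0),
        method=p.get("method", "conv"),
        rho_transform=p.get("rho_transform", "abs"),
    )
    params = {"flank_bp": p.get("flank_bp", 0),
              "method": p.get("method", "conv"), "seed": cfg.seed}
    io.write_table(scores, cfg.out_dir / "gene_scores.tsv", params)
    io.write_provenance(cfg.out_dir / "genescores.provenance.json",
                        "genescores", params, cfg.seed,
                        [d / "gwas.tsv", d / "annotation.tsv"])
    logger.info("genescores: scored %d genes (lambda=%.3f)", len(scores),
                scores["lambda_gc"].iloc[0] if len(scores) else float("nan"))
    return scores


def stage_enrich(cfg: RunConfig) -> pd.DataFrame:
    d = _data_dir(cfg)
    scores = io.read_table(_require(cfg.out_dir / "gene_scores.tsv",
                                    "genescores"))
    scores["chrom"] = scores["chrom"].astype(str)
    membership = io.read_table(_require(cfg.out_dir / "module_membership.tsv",
                                        "network"))
    mapping = io.read_orthologue_map(_require(d / "orthologues.tsv",
                                              "simulate"))
    p = cfg.enrich
    module_mouse = membership.loc[membership["amyloid_module"], "gene"]
    human, report = enr.map_orthologues(module_mouse, mapping)
    net_scores = scores[scores["gene"].isin(set(human))].copy()
    if net_scores.empty:
        raise RuntimeError("no scored orthologues of the detected module")
    alphas = tuple(p.get("alphas", (0.05, 0.01, 0.001)))
    window = p.get("window_bp", enr.DEFAULT_WINDOW_BP)
    results = [r.__dict__ for r in
               enr.enrichment_test(net_scores, alphas, window)]
    exclusions = enr.ExclusionRegions([enr.APOE_WINDOW, enr.HLA_WINDOW])
    if p.get("exclude_file"):
        loci = io.read_table(p["exclude_file"])
        exclusions = enr.ExclusionRegions.around_loci(loci, window)
    try:
        results += [r.__dict__ for r in
                    enr.enrichment_test(net_scores, alphas, window, exclusions)]
    except ValueError:
        logger.warning("enrich: exclusion windows removed every gene")
    cands = enr.candidate_genes(net_scores, p.get("candidate_alpha", 0.01),
                                set(p.get("established", [])), exclusions)
    params = {"window_bp": window, "alphas": alphas,
              "n_mapped": report["n_mapped"], "seed": cfg.seed}
    io.write_table(pd.DataFrame(results), cfg.out_dir / "enrichment.tsv",
                   params)
    io.write_table(cands, cfg.out_dir / "candidates.tsv", params)
    io.write_provenance(cfg.out_dir / "enrich.provenance.json", "enrich",
                        params, cfg.seed,
                        [cfg.out_dir / "gene_scores.tsv"])
    logger.info("enrich: N=%d, %d candidates", results[0]["n_independent"],
                len(cands))
    return pd.DataFrame(results)


def stage_trajectory(cfg: RunConfig) -> pd.DataFrame:
    d = _data_dir(cfg)
    ds = io.read_expression(_require(d / "expression.tsv", "simulate"),
                            d / "metadata.tsv")
    membership = io.read_table(_require(cfg.out_dir / "module_membership.tsv",
                                        "network"))
    p = cfg.trajectory
    genes = membership.loc[membership["amyloid_module"], "gene"]
    genotype = p.get("genotype")
    if genotype is None:
        tg = ds.meta[ds.meta["plaque_load"] > 0]
        genotype = tg.groupby("genotype")["plaque_load"].max().idxmax()
    result = traj.fold_change_table(
        ds, genes, genotype,
        n_boot=p.get("n_boot", 2000), seed=cfg.seed,
    )
    classes = traj.classify_response(
        result,
        microglia_reference=p.get("microglia_reference",
                                  traj.MICROGLIA_FOLD_REFERENCE),
        onset_age=p.get("onset_age", 8.0),
    )
    table = traj.trajectory_table(result, classes)
    params = {"genotype": genotype, "n_boot": p.get("n_boot", 2000),
              "seed": cfg.seed}
    io.write_table(table, cfg.out_dir / "trajectories.tsv", params)
    io.write_provenance(cfg.out_dir / "trajectory.provenance.json",
                        "trajectory", params, cfg.seed,
                        [d / "expression.tsv"])
    logger.info("trajectory: %s", classes["label"].value_counts().to_dict())
    return table


def stage_coloc(cfg: RunConfig) -> pd.DataFrame:
    d = _data_dir(cfg)
    gwas = io.read_gwas(_require(d / "gwas.tsv", "simulate"), trait="disease")
    p = cfg.coloc
    eqtl_files = p.get("eqtl_files")
    if eqtl_files is None:
        eqtl_files = sorted(d.glob("eqtl_*.tsv"))
    results = []
    for f in map(Path, eqtl_files):
        condition = f.stem.replace("eqtl_", "")
        eqtl = io.read_gwas(f, trait=condition)
        region_snps = set(eqtl.table["snp"])
        sub = GwasSummary(gwas.table[gwas.table["snp"].isin(region_snps)],
                          trait="disease")
        results.append(
            col.colocalize(sub, eqtl,
                           p1=p.get("p1", 1e-4), p2=p.get("p2", 1e-4),
                           p12=p.get("p12", 1e-5), region=f.stem)
        )
    table = col.coloc_table(results)
    params = {"p1": p.get("p1", 1e-4), "p2": p.get("p2", 1e-4),
              "p12": p.get("p12", 1e-5), "seed": cfg.seed}
    io.write_table(table, cfg.out_dir / "coloc.tsv", params)
    io.write_provenance(cfg.out_dir / "coloc.provenance.json", "coloc",
                        params, cfg.seed, list(map(Path, eqtl_files)))
    logger.info("coloc: %d regions", len(table))
    return table


_STAGE_FN = {
    "simulate": stage_simulate,
    "network": stage_network,
    "genescores": stage_genescores,
    "enrich": stage_enrich,
    "trajectory": stage_trajectory,
    "coloc": stage_coloc,
}


def run_pipeline(cfg: RunConfig, stages=STAGES) -> Path:
    """Execute the requested stages in dependency order."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in set(stages)]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for s in ordered:
        logger.info("-- stage %s --", s)
        _STAGE_FN[s](cfg)
    return cfg.out_dir
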