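"""Readers and writers for the plain-text interchange formats.

Expression matrices, summary statistics, annotations and orthologue maps
travel as TSV; the reference panel as VCF v4.2 with phased genotypes;
planted truth as JSON.  Writers emit a ``#`` comment header carrying the
tool version and the parameters that produced the table so every
artifact records its provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (
    ANNOTATION_COLUMNS,
    GWAS_COLUMNS,
    ExpressionDataset,
    GwasSummary,
    ReferencePanel,
    SimTruth,
)


def _header_lines(params: dict | None) -> str:
    lines = [f"# amynet {__version__}"]
    if params:
        kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        lines.append(f"# {kv}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, params: dict | None = None,
                index: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# -- expression ---------------------------------------------------------

def write_expression(ds: ExpressionDataset, values_path, meta_path,
                     params: dict | None = None) -> None:
    values = ds.values.copy()
    values.index.name = "gene"
    write_table(values, values_path, params, index=True)
    meta = ds.meta.copy()
    meta.index.name = "sample"
    write_table(meta, meta_path, params, index=True)


def read_expression(values_path, meta_path) -> ExpressionDataset:
    values = read_table(values_path, index_col="gene")
    meta = read_table(meta_path, index_col="sample")
    return ExpressionDataset(values, meta.loc[values.columns])


# -- summary statistics -------------------------------------------------

def write_gwas(gwas: GwasSummary, path, params: dict | None = None) -> None:
    write_table(gwas.table[GWAS_COLUMNS], path,
                {**(params or {}), "trait": gwas.trait})


def read_gwas(path, trait: str = "trait") -> GwasSummary:
    return GwasSummary(read_table(path), trait=trait)


# -- gene annotation ----------------------------------------------------

def write_annotation(annotation: pd.DataFrame, path,
                     params: dict | None = None) -> None:
    note = {**(params or {}), "coordinates": "1-based-closed"}
    write_table(annotation[ANNOTATION_COLUMNS], path, note)


def read_annotation(path) -> pd.DataFrame:
    ann = read_table(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    ann["chrom"] = ann["chrom"].astype(str)
    return ann


# -- orthologue map -----------------------------------------------------

def write_orthologue_map(mapping: dict[str, str], path,
                         params: dict | None = None) -> None:
    df = pd.DataFrame(
        {"mouse": list(mapping.keys()), "human": list(mapping.values())}
    )
    write_table(df, path, params)


def read_orthologue_map(path) -> dict[str, str]:
    df = read_table(path)
    return dict(zip(df["mouse"], df["human"]))


# -- reference panel (VCF) ----------------------------------------------

def write_vcf(panel: ReferencePanel, path) -> None:
    """Write the panel as VCF v4.2 with phased GT fields."""
    hap = panel.haplotypes
    n_ind = hap.shape[0] // 2
    sample_names = [f"HG{i:04d}" for i in range(n_ind)]
    chroms = sorted(panel.snps["chr"].astype(str).unique(), key=str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=amynet {__version__}\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        order = panel.snps.sort_values(["chr", "bp"], kind="stable").index
        for i in order:
            row = panel.snps.iloc[i]
            gts = "\t".join(
                f"{hap[2 * j, i]}|{hap[2 * j + 1, i]}" for j in range(n_ind)
            )
            fh.write(f"{row['chr']}\t{row['bp']}\t{row['snp']}\t{row['a2']}\t"
                     f"{row['a1']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> ReferencePanel:
    """Read a phased VCF back into a panel (alt allele is the a1/effect allele)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, haps = [], []
    for var in vcf:
        rows.append(
            {"snp": var.ID, "chr": var.CHROM, "bp": var.POS,
             "a1": var.ALT[0], "a2": var.REF}
        )
        gt = np.asarray(var.genotype.array())[:, :2]  # (n_ind, 2)
        haps.append(gt.reshape(-1))
    vcf.close()
    hap = np.array(haps, dtype=np.int8).T  # (n_hap, n_snp)
    return ReferencePanel(hap, pd.DataFrame(rows))


# -- truth sidecar ------------------------------------------------------

def write_truth(truth: SimTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path) -> SimTruth:
    return SimTruth.from_json(Path(path).read_text())


# -- provenance ---------------------------------------------------------

def file_checksum(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def write_provenance(path, stage: str, params: dict, seed: int | None,
                     inputs: list[str | Path] = ()) -> None:
    record = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "params": {k: repr(v) for k, v in sorted(params.items())},
        "inputs": {str(p): file_checksum(p) for p in inputs},
    }
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True))
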