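"""Readers and writers for the on-disk formats.

Genotypes travel as VCF v4.2 with a GT-only FORMAT field (1-based
positions); gene intervals as 4-column BED (0-based half-open);
phenotypes as a long-format TSV (subject_id, visit, sbp, age, sex,
smoke, bpmed); ground truth and posterior summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_vcf", "read_vcf", "write_bed", "read_bed",
    "write_phenotypes", "read_phenotypes", "write_json", "read_json",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(path, variants: pd.DataFrame, X: np.ndarray,
              sample_ids=None) -> None:
    """Write dosages {0,1,2,NaN} as an uncompressed VCF v4.2, GT only."""
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if p != len(variants):
        raise ValueError("X columns and variant rows differ")
    if sample_ids is None:
        sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    chroms = list(dict.fromkeys(variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j, row in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(
                "./." if np.isnan(X[i, j]) else _GT[int(X[i, j])]
                for i in range(n))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\tA\tG\t.\tPASS"
                     f"\t.\tGT\t{gts}\n")


def read_vcf(path):
    """Read a VCF into ``(variants, X, sample_ids)`` with NaN for missing.

    Dosages count ALT alleles; multiallelic records are flagged via
    ``n_alleles`` rather than dropped, and FILTER!=PASS clears
    ``qc_pass`` so the QC filter downstream can act on them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for v in vcf:
        n_alleles = 1 + len(v.ALT)
        rows.append({
            "variant_id": v.ID or f"{v.CHROM}:{v.POS}",
            "chrom": v.CHROM, "pos": v.POS,
            "qc_pass": v.FILTER is None,  # cyvcf2: None means PASS
            "n_alleles": n_alleles,
        })
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = v.gt_types.astype(np.float64)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        cols.append(dos)
    vcf.close()
    variants = pd.DataFrame(rows)
    X = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return variants, X, samples


def write_bed(path, genes: pd.DataFrame) -> None:
    genes.loc[:, ["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"])
    if (df["end"] <= df["start"]).any():
        raise ValueError("malformed BED interval: end <= start")
    return df


def write_phenotypes(path, long_df: pd.DataFrame) -> None:
    long_df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
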