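"""Variant QC filtering, MAF computation and genic/flanking classification.

Variants are binned on two axes:

* minor allele frequency — ``very_rare`` (MAF < 1%), ``rare``
  (1% <= MAF <= 5%, both boundaries inclusive), ``common`` (MAF > 5%);
* region — ``genic`` if the position falls inside a gene's transcribed
  interval (introns included), ``flanking`` if within a fixed window
  (default 50 kb) outside one, ``outside`` otherwise.  Genic takes
  precedence over flanking when both apply.

Crossing the two axes (plus an ``all`` margin on each) yields the twelve
marker sets on which the whole-genome regression is run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "MAF_CLASSES",
    "REGION_CLASSES",
    "MarkerSet",
    "filter_variants",
    "compute_maf",
    "classify_maf",
    "annotate_region",
    "annotate_variants",
    "build_marker_sets",
    "cross_tab",
]

logger = logging.getLogger(__name__)

MAF_CLASSES = ("very_rare", "rare", "common")
REGION_CLASSES = ("genic", "flanking", "outside")
SET_REGIONS = ("all", "genic", "flanking")
SET_MAFS = ("all", "common", "rare", "very_rare")


@dataclass(frozen=True)
class MarkerSet:
    name: str
    region: str
    maf: str
    indices: tuple
    @property
    def size(self) -> int:
        return len(self.indices)


def filter_variants(variants: pd.DataFrame):
    """Keep QC-passing biallelic variants.

    Expects boolean columns ``qc_pass`` and ``biallelic`` (or an integer
    ``n_alleles``).  Returns ``(retained, n_excluded)``.
    """
    df = variants
    biallelic = df["biallelic"].astype(bool) if "biallelic" in df \
        else (df["n_alleles"] == 2)
    keep = df["qc_pass"].astype(bool) & biallelic
    n_excluded = int((~keep).sum())
    retained = df.loc[keep].reset_index(drop=True)
    logger.info("variant filter: %d in, %d retained, %d excluded",
                len(df), len(retained), n_excluded)
    return retained, n_excluded


def compute_maf(dosages) -> float:
    """Folded minor-allele frequency from a dosage column {0,1,2,NaN}."""
    d = np.asarray(dosages, dtype=np.float64)
    obs = d[~np.isnan(d)]
    if obs.size == 0:
        raise ValueError("cannot compute MAF: all genotypes missing")
    f = obs.sum() / (2.0 * obs.size)
    return float(min(f, 1.0 - f))


def classify_maf(maf: float) -> str:
    """Bin a folded MAF: <1% very rare, 1-5% (inclusive) rare, >5% common."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF {maf} outside [0, 0.5]; fold it first")
    if maf < 0.01:
        return "very_rare"
    if maf <= 0.05:
        return "rare"
    return "common"


def _build_trees(genes: pd.DataFrame, flank_bp: int):
    """Per-chromosome interval trees over genic and flank windows.

    Gene intervals are 0-based half-open [start, end).
    """
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("malformed gene interval: end <= start")
    genic, flank = {}, {}
    for row in genes.itertuples(index=False):
        g = genic.setdefault(row.chrom, IntervalTree())
        g[row.start:row.end] = row.name
        f = flank.setdefault(row.chrom, IntervalTree())
        lo = max(0, row.start - flank_bp)
        if lo < row.start:
            f[lo:row.start] = row.name
        f[row.end:row.end + flank_bp] = row.name
    return genic, flank


def annotate_region(chrom, pos, genes: pd.DataFrame, flank_bp: int = 50_000):
    """Classify positions as genic / flanking / outside against gene intervals.

    Parameters
    ----------
    chrom, pos : variant chromosome(s) and 1-based position(s); scalars
        or equal-length sequences.
    genes : DataFrame with ``chrom, start, end, name`` (0-based half-open).
    flank_bp : window outside each interval counted as flanking.

    Returns
    -------
    (region_class, gene_names) — arrays, ``gene_names`` a comma-joined
    string of every matching gene (genic matches when genic, flank
    matches when flanking, empty when outside).
    """
    scalar = np.isscalar(pos)
    chroms = np.atleast_1d(np.asarray(chrom, dtype=object))
    positions = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    if scalar and chroms.size == 1 and positions.size > 1:
        chroms = np.repeat(chroms, positions.size)
    if chroms.size == 1 and positions.size > 1:
        chroms = np.repeat(chroms, positions.size)
    genic_trees, flank_trees = _build_trees(genes, flank_bp)
    regions = np.empty(positions.size, dtype=object)
    names = np.empty(positions.size, dtype=object)
    for i, (c, p) in enumerate(zip(chroms, positions)):
        p0 = p - 1  # to 0-based
        hits = genic_trees[c][p0] if c in genic_trees else set()
        if hits:
            regions[i] = "genic"
            names[i] = ",".join(sorted(h.data for h in hits))
            continue
        fhits = flank_trees[c][p0] if c in flank_trees else set()
        if fhits:
            regions[i] = "flanking"
            names[i] = ",".join(sorted(h.data for h in fhits))
        else:
            regions[i] = "outside"
            names[i] = ""
    if np.isscalar(pos):
        return regions[0], names[0]
    return regions, names


def annotate_variants(variants: pd.DataFrame, X, genes: pd.DataFrame,
                      flank_bp: int = 50_000) -> pd.DataFrame:
    """Full per-variant annotation table: MAF, MAF class, region, genes.

    ``variants`` needs ``variant_id, chrom, pos`` (1-based); ``X`` is the
    dosage matrix aligned column-wise with ``variants``.
    """
    X = np.asarray(X, dtype=np.float64)
    maf = np.array([compute_maf(X[:, j]) for j in range(X.shape[1])])
    maf_class = np.array([classify_maf(m) for m in maf], dtype=object)
    region, gene_names = annotate_region(
        variants["chrom"].to_numpy(), variants["pos"].to_numpy(), genes, flank_bp)
    return pd.DataFrame({
        "variant_id": variants["variant_id"].to_numpy(),
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "maf": maf,
        "maf_class": maf_class,
        "region_class": region,
        "genes": gene_names,
    })


def build_marker_sets(annotations: pd.DataFrame) -> dict:
    """The 12 marker sets: {all, genic, flanking} x {all, common, rare, very_rare}.

    Variants classified ``outside`` are excluded from every set,
    including the ``all`` margins.
    """
    region = annotations["region_class"].to_numpy()
    maf_class = annotations["maf_class"].to_numpy()
    inside = region != "outside"
    sets = {}
    for r in SET_REGIONS:
        r_mask = inside if r == "all" else (region == r)
        for m in SET_MAFS:
            mask = r_mask if m == "all" else (r_mask & (maf_class == m))
            idx = tuple(int(i) for i in np.flatnonzero(mask))
            name = f"{r}_{m}"
            sets[name] = MarkerSet(name=name, region=r, maf=m, indices=idx)
    return sets


def cross_tab(annotations: pd.DataFrame, counts: pd.DataFrame | None = None):
    """Counts grid with integer percents of the grand total.

    Rows all/genic/flanking, columns all/common/rare/very_rare.  If
    ``counts`` is given (a 3x4 count grid) it is formatted directly;
    otherwise counts are tallied from ``annotations``.  Returns
    ``(counts_df, formatted_df)`` where formatted cells look like
    ``"31814 (64%)"``.
    """
    if counts is None:
        sets = build_marker_sets(annotations)
        counts = pd.DataFrame(
            [[sets[f"{r}_{m}"].size for m in SET_MAFS] for r in SET_REGIONS],
            index=SET_REGIONS, columns=SET_MAFS, dtype=int)
    grand = int(counts.loc["all", "all"])
    def fmt(c):
        pct = int(round(100.0 * c / grand)) if grand else 0
        return f"{int(c)} ({pct}%)"
    formatted = counts.map(fmt)
    return counts, formatted
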