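"""Core in-memory containers shared across the pipeline.

A genotype panel is a plain individuals × variants dosage matrix (0/1/2,
-1 for missing) optionally backed by phased haplotypes, aligned row-for-row
with a variant table.  The variant table is an ordinary :class:`pandas.DataFrame`
with a documented column contract rather than a bespoke class, in the spirit of
how most genomics toolkits pass variant metadata around.

Variant table columns
---------------------
chrom : str
    Chromosome label.
pos_bp : int
    1-based physical coordinate, non-decreasing within a chromosome.
variant_id : str
    Unique identifier.
ancestry : {"NIM", "MH"}
    Introgressed (Neanderthal-informative mutation) vs modern-human class.
allele_freq : float
    Frequency of the counted allele in the panel.
maf : float
    min(p, 1-p), in [0, 0.5].
ld_score : float, optional
    Windowed sum of squared dosage correlations (self term included).
b_value : float, optional
    Background-selection score; any extra matching annotation is supported.
qc_pass : bool, optional
    Set by :func:`nimkit.annotate.qc_filter`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_COLUMNS = ("chrom", "pos_bp", "variant_id", "ancestry", "allele_freq", "maf")


@dataclass
class GenotypePanel:
    """Dosage matrix (n_individuals × n_variants) with optional phased haplotypes.

    ``dosages`` holds 0/1/2 counted-allele dosages (−1 = missing).  When
    ``haplotypes`` (2n × m, 0/1) is present, each individual's dosage equals the
    sum of its two haplotype rows.
    """

    dosages: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals × variants matrix")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")
        if self.haplotypes is not None:
            hap = np.asarray(self.haplotypes)
            if hap.shape != (2 * self.n_individuals, self.n_variants):
                raise ValueError("haplotypes must have shape (2n, m)")
            dos = hap[0::2] + hap[1::2]
            obs = self.dosages != MISSING
            if not np.array_equal(dos[obs], self.dosages[obs]):
                raise ValueError("dosages disagree with haplotype sums")
            self.haplotypes = hap

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Counted-allele frequency per variant, ignoring missing entries."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        return np.asarray(d.mean(axis=0) / 2.0)

    def subset_variants(self, index: np.ndarray) -> "GenotypePanel":
        hap = None if self.haplotypes is None else self.haplotypes[:, index]
        return GenotypePanel(self.dosages[:, index], hap)


def validate_variant_table(variants: pd.DataFrame) -> None:
    """Raise ``ValueError`` if the variant-table column contract is violated."""
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if not variants["ancestry"].isin(["NIM", "MH"]).all():
        raise ValueError("ancestry must be 'NIM' or 'MH'")
    maf = variants["maf"].to_numpy(float)
    if np.any((maf < 0) | (maf > 0.5 + 1e-12)):
        raise ValueError("maf must lie in [0, 0.5]")
    for _, grp in variants.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be non-decreasing within chromosome")
    if variants["variant_id"].duplicated().any():
        raise ValueError("variant_id values must be unique")


def standardized_dosages(
    dosages: np.ndarray,
    allele_freq: np.ndarray | None = None,
    scale: str = "freq",
) -> np.ndarray:
    """Center/scale a dosage matrix column-wise.

    ``scale='freq'`` uses the additive-model weights w = (x − 2p)/√(2p(1−p));
    ``scale='sd'`` standardizes by the sample standard deviation (used for
    Pearson-r² LD computations).  Missing entries are mean-imputed first.
    """
    x = np.asarray(dosages, dtype=np.float64)
    miss = x == MISSING
    if miss.any():
        x = x.copy()
        x[miss] = np.nan
        col_mean = np.nanmean(x, axis=0)
        idx = np.where(miss)
        x[idx] = col_mean[idx[1]]
    if scale == "freq":
        p = np.asarray(allele_freq, float) if allele_freq is not None else x.mean(axis=0) / 2.0
        denom = np.sqrt(2.0 * p * (1.0 - p))
        center = 2.0 * p
    elif scale == "sd":
        denom = x.std(axis=0)
        center = x.mean(axis=0)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if np.any(denom == 0):
        raise ValueError("monomorphic variant cannot be standardized")
    return (x - center) / denom
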