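"""Variant QC, LD scores, NIM expansion and annotation partitions.

This module mirrors the upstream bookkeeping of an ancestry-partitioned
heritability analysis: hard genotype QC (MAF, exact Hardy–Weinberg test,
call rate, region exclusion), windowed LD scores, expansion of a confident
introgressed-variant list by tight LD, and the construction of the
ancestry × MAF × LD (× extra) annotation bins used by the variance-component
estimator, including the rule that bins with fewer than ``min_snps`` variants
are dropped in their entirety.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import MISSING, GenotypePanel, standardized_dosages

__all__ = [
    "AnnotationPartition",
    "qc_filter",
    "hwe_exact_pvalue",
    "compute_ld_scores",
    "expand_nims",
    "build_partition",
]


def hwe_exact_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than that of the observed
    configuration (Wigginton-style enumeration, evaluated in closed form via
    log-factorials).
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    # P(het | allele counts) ∝ n! / (maj! het! min!) · 2^het  (conditional law)
    logp = (hets * np.log(2.0) - gammaln(hom_maj + 1) - gammaln(hets + 1)
            - gammaln(hom_min + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het]
    if len(p_obs) == 0:  # observed het count incompatible (defensive)
        return 1.0
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


def qc_filter(panel: GenotypePanel, variants: pd.DataFrame, *,
              maf_min: float = 0.001, hwe_p_min: float = 1e-7,
              call_rate_min: float = 0.99,
              exclude_regions: pd.DataFrame | None = None) -> np.ndarray:
    """Boolean QC mask over variants.

    A variant passes iff MAF > ``maf_min``, the exact Hardy–Weinberg p-value
    exceeds ``hwe_p_min``, its non-missing fraction is ≥ ``call_rate_min`` and
    it lies outside every exclusion region.  ``exclude_regions`` uses BED
    conventions: columns (chrom, start, end), 0-based half-open.
    """
    d = panel.dosages
    n = d.shape[0]
    obs = d != MISSING
    call_rate = obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(obs.sum(axis=0) > 0,
                     np.where(d == MISSING, 0, d).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1),
                     0.0)
    maf = np.minimum(p, 1 - p)
    mask = (maf > maf_min) & (call_rate >= call_rate_min)

    for j in np.flatnonzero(mask):
        col = d[:, j]
        het = int(np.sum(col == 1))
        hom1 = int(np.sum(col == 2))
        hom0 = int(np.sum(col == 0))
        if hwe_exact_pvalue(hom0, het, hom1) <= hwe_p_min:
            mask[j] = False

    if exclude_regions is not None and len(exclude_regions):
        pos = variants["pos_bp"].to_numpy()
        chrom = variants["chrom"].to_numpy()
        for _, row in exclude_regions.iterrows():
            inside = (chrom == str(row["chrom"])) & (pos - 1 >= int(row["start"])) & (pos - 1 < int(row["end"]))
            mask &= ~inside
    return mask


def _window_bounds(pos: np.ndarray, window_bp: int) -> tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(pos, pos - window_bp, side="left")
    hi = np.searchsorted(pos, pos + window_bp, side="right")
    return lo, hi


def compute_ld_scores(panel: GenotypePanel, variants: pd.DataFrame,
                      window_bp: int = 10_000_000, chunk: int = 512) -> np.ndarray:
    """Per-variant LD score: Σ_j r²(i, j) over same-chromosome variants within
    ``window_bp`` of variant i, including the self term (hence ≥ 1).

    r² is the squared Pearson correlation of (mean-imputed) dosages.  Raises
    on zero-variance variants — exclude them with :func:`qc_filter` first.
    """
    w = standardized_dosages(panel.dosages, scale="sd")  # raises on zero variance
    n = w.shape[0]
    scores = np.zeros(w.shape[1])
    for chrom, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos_bp"].to_numpy()
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        wc = w[:, idx]
        lo, hi = _window_bounds(pos, window_bp)
        for start in range(0, len(idx), chunk):
            stop = min(start + chunk, len(idx))
            r2 = (wc[:, start:stop].T @ wc) / n
            np.square(r2, out=r2)
            cs = np.concatenate([np.zeros((stop - start, 1)), np.cumsum(r2, axis=1)], axis=1)
            rows = np.arange(stop - start)
            scores[idx[start:stop]] = cs[rows, hi[start:stop]] - cs[rows, lo[start:stop]]
    return scores


def expand_nims(confident_nims: set[str] | Sequence[str], panel: GenotypePanel,
                variants: pd.DataFrame, r2_min: float = 0.99,
                window_bp: int = 200_000) -> set[str]:
    """Expand a confident NIM id set by tight LD.

    A variant joins the expanded set iff it has r² ≥ ``r2_min`` with some
    confident NIM on the same chromosome within ``window_bp``.  The returned
    set always contains the confident set itself.
    """
    confident = set(confident_nims)
    ids = variants["variant_id"].to_numpy()
    conf_mask = np.isin(ids, list(confident))
    if not conf_mask.any():
        return confident
    w = standardized_dosages(panel.dosages, scale="sd")
    n = w.shape[0]
    expanded = set(confident)
    for chrom, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos_bp"].to_numpy()
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        conf_local = np.flatnonzero(conf_mask[idx])
        if len(conf_local) == 0:
            continue
        lo, hi = _window_bounds(pos, window_bp)
        for ci in conf_local:
            cols = np.arange(lo[ci], hi[ci])
            r2 = (w[:, idx[cols]].T @ w[:, idx[ci]]) / n
            hit = cols[r2 ** 2 >= r2_min]
            expanded.update(ids[idx[hit]])
    return expanded


@dataclass
class AnnotationPartition:
    """Disjoint annotation bins over retained variants.

    ``bin_of_variant`` maps each variant-table row to a bin index (−1 for
    variants outside the partition: QC failures or members of dropped bins).
    ``labels`` holds one tuple per bin, always starting with the ancestry
    class followed by the quantile index of each extra annotation.
    """

    bin_of_variant: np.ndarray
    labels: list[tuple]
    sizes: np.ndarray
    dropped: list[tuple[tuple, int]] = field(default_factory=list)
    scheme: tuple[str, ...] = ("ancestry",)

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    def bins_with_ancestry(self, ancestry: str) -> np.ndarray:
        return np.array([k for k, lab in enumerate(self.labels) if lab[0] == ancestry], int)

    def matched_pairs(self) -> list[tuple[int, int]]:
        """(NIM bin, MH bin) pairs sharing the same non-ancestry label."""
        by_label = {lab: k for k, lab in enumerate(self.labels)}
        pairs = []
        orphans = []
        for k, lab in enumerate(self.labels):
            if lab[0] != "NIM":
                continue
            partner = by_label.get(("MH",) + lab[1:])
            if partner is None:
                orphans.append(lab)
            else:
                pairs.append((k, partner))
        if orphans:
            raise ValueError(f"NIM bins without a matched MH bin: {orphans}")
        return pairs


def _quantile_bins(values: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                   n_bins: int) -> np.ndarray:
    """Equal-sized quantile bins with (value, chrom, pos) lexicographic tie-break."""
    if len(np.unique(values)) < n_bins:
        raise ValueError(f"{n_bins} bins requested but only "
                         f"{len(np.unique(values))} distinct values")
    order = np.lexsort((pos, chrom, values))
    rank = np.empty(len(values), dtype=np.int64)
    rank[order] = np.arange(len(values))
    return (rank * n_bins) // len(values)


def build_partition(variants: pd.DataFrame,
                    schemes: Sequence[tuple[str, int]] = (),
                    min_snps: int = 30,
                    require_matched: bool = False) -> AnnotationPartition:
    """Intersect ancestry with quantile annotations into estimation bins.

    Quantile edges are computed over ALL QC-passing variants jointly (not per
    ancestry class) and then intersected with ancestry and with each other.
    Bins smaller than ``min_snps`` are dropped with their variants.  With
    ``require_matched=True`` a bin whose ancestry partner was dropped is also
    retired (iterated to a fixed point) so the matched-background statistic
    stays well defined.
    """
    qc = variants["qc_pass"].to_numpy(bool) if "qc_pass" in variants else np.ones(len(variants), bool)
    idx = np.flatnonzero(qc)
    chrom = variants["chrom"].to_numpy()[idx]
    pos = variants["pos_bp"].to_numpy()[idx]

    keys = [variants["ancestry"].to_numpy()[idx]]
    for ann, n_bins in schemes:
        if ann not in variants.columns:
            raise ValueError(f"annotation column {ann!r} missing from variant table")
        vals = variants[ann].to_numpy(float)[idx]
        if np.isnan(vals).any():
            raise ValueError(f"annotation {ann!r} undefined for some QC variants")
        keys.append(_quantile_bins(vals, chrom, pos, n_bins))

    label_of = [tuple(k[i] for k in keys) for i in range(len(idx))]
    uniq = sorted(set(label_of), key=lambda t: (t[0],) + tuple(t[1:]))
    code = {lab: k for k, lab in enumerate(uniq)}
    assign = np.array([code[lab] for lab in label_of])
    sizes = np.bincount(assign, minlength=len(uniq))

    keep = sizes >= min_snps
    if require_matched:
        # retire NIM bins whose matched MH partner was dropped; MH bins are
        # kept regardless (they still absorb variance even when unmatched)
        kept = {lab for k, lab in enumerate(uniq) if keep[k]}
        for k, lab in enumerate(uniq):
            if keep[k] and lab[0] == "NIM" and ("MH",) + lab[1:] not in kept:
                keep[k] = False

    dropped = [(uniq[k], int(sizes[k])) for k in range(len(uniq)) if not keep[k]]
    new_code = {}
    labels = []
    for k, lab in enumerate(uniq):
        if keep[k]:
            new_code[k] = len(labels)
            labels.append(lab)
    bin_of = np.full(len(variants), -1, dtype=np.int64)
    for i, k in zip(idx, assign):
        if keep[k]:
            bin_of[i] = new_code[k]
    kept_sizes = np.array([int(sizes[k]) for k in range(len(uniq)) if keep[k]], int)
    scheme_names = ("ancestry",) + tuple(ann for ann, _ in schemes)
    return AnnotationPartition(bin_of_variant=bin_of, labels=labels, sizes=kept_sizes,
                               dropped=dropped, scheme=scheme_names)
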