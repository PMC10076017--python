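"""Synthetic genotype panels with introgressed-block structure and phenotype simulation.

The generator emulates the population-genetic signature of archaic
introgression at desk scale.  Introgressed haplotype blocks ("segments")
entered the population as single haplotypes, so the Neanderthal-informative
mutations (NIMs) they carry are rare on average, travel together (high LD
score), and their frequency is decoupled from local LD — in contrast to
modern-human (MH) background variants.

Model
-----
* Each of ``n_segments`` non-overlapping segments has a carrier haplotype set
  at frequency drawn from ``intro_freq_dist`` (a Beta law concentrated at low
  frequency, sampled by stratified inverse-CDF so the panel-level mean is
  stable at small segment counts).
* Marginal recombination erodes segment edges: NIM positions are split into a
  few contiguous sub-blocks, each losing a random fraction of carriers
  (``block_decay`` controls the mean loss).  Within a sub-block NIMs are exact
  haplotype copies (pairwise r² = 1); across sub-blocks r² is slightly below 1.
* Introgressed haplotypes also carry pre-existing modern-human alleles:
  "linked MH" variants inside each segment are correlated with the carrier set
  at a graded target r² (drawn from ``linked_r2_range``), with allele
  frequency solved from r² = f(1−p)/(p(1−f)).  These variants generate the
  cross-ancestry LD that confounds single-variant association at NIMs.
* Background MH variants are drawn independently per site with minor allele
  frequency from ``mh_maf_dist``.

Phenotypes follow the standard additive model on standardized genotypes,
y_j = Σ_i w_ij β_i + ε_j with w_ij = (x_ij − 2p_i)/√(2p_i(1−p_i)), β_i i.i.d.
standard normal and the residual variance chosen to realize a target
heritability in-sample.  Causal variants are selected under MAF/LD-coupled
architectures (BASELINE, COMMON, RARE, LOW, HIGH, ULTRA_RARE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel, standardized_dosages, validate_variant_table

__all__ = [
    "PanelConfig",
    "ArchitectureSpec",
    "PhenotypeTruth",
    "architecture",
    "simulate_genotypes",
    "select_causal_variants",
    "simulate_phenotype",
    "true_nim_h2",
    "ARCHITECTURE_NAMES",
]

ARCHITECTURE_NAMES = ("BASELINE", "COMMON", "RARE", "LOW", "HIGH", "ULTRA_RARE")


@dataclass
class PanelConfig:
    """Free parameters of the synthetic-panel generator.

    The defaults are the package's calibrated study conditions: with
    ``n_individuals=2000`` they produce ≈20,000 variants whose NIM class has
    mean MAF ≈ 0.039 and mean 10-Mb LD score ≈ 170, with MH mean MAF ≈ 0.099.
    """

    n_individuals: int = 2000
    n_mh_snps: int = 15200
    n_segments: int = 20
    segment_length_bp: int = 50_000
    nims_per_segment: int = 115
    intro_freq_dist: tuple[float, float] = (1.2, 28.0)
    mh_maf_dist: tuple[float, float] = (0.55, 5.0)
    genome_length_bp: int = 100_000_000
    block_decay: float = 0.05
    seed: int = 0
    # introgressed-haplotype fine structure
    linked_mh_per_segment: int | None = None  # default: same density as NIMs
    linked_r2_range: tuple[float, float] = (0.10, 0.98)
    subblocks_mean: float = 3.0
    min_segment_freq: float = 0.004
    chrom: str = "1"

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_mh_snps", "n_segments", "segment_length_bp",
                     "nims_per_segment", "genome_length_bp"):
            if getattr(self, name) < 0 or (name not in ("n_segments", "n_mh_snps")
                                           and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.block_decay < 0.5):
            raise ValueError("block_decay must lie in [0, 0.5)")
        for a, b in (self.intro_freq_dist, self.mh_maf_dist):
            if a <= 0 or b <= 0:
                raise ValueError("Beta distribution parameters must be positive")
        mean_intro = self.intro_freq_dist[0] / sum(self.intro_freq_dist)
        if not (0.0 < mean_intro <= 0.5):
            raise ValueError("introgression frequency distribution mean must be in (0, 0.5]")
        lo, hi = self.linked_r2_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("linked_r2_range must satisfy 0 < lo <= hi <= 1")
        # worst-case segment draw must fit its placement slot
        if self.n_segments > 0:
            slot = self.genome_length_bp // self.n_segments
            if 1.5 * self.segment_length_bp > slot:
                raise ValueError(
                    "segment placement overflows the genome: "
                    f"1.5×segment_length_bp={1.5 * self.segment_length_bp:.0f} exceeds the "
                    f"per-segment span {slot} bp"
                )


@dataclass
class ArchitectureSpec:
    """A MAF/LD-coupled causal architecture.

    ``class_rule`` maps (maf, ld_score) arrays to a boolean membership of the
    enriched class; ``None`` (BASELINE) selects causal variants uniformly.
    """

    name: str
    n_causal: int
    h2: float
    enriched_fraction: float = 0.9
    class_rule: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.enriched_fraction <= 1.0):
            raise ValueError("enriched_fraction must lie in [0, 1]")
        if not (0.0 <= self.h2 < 1.0 or self.h2 == 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_causal <= 0:
            raise ValueError("n_causal must be positive")


_CLASS_RULES: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray] | None] = {
    "BASELINE": None,
    "COMMON": lambda maf, ld: maf > 0.05,
    "RARE": lambda maf, ld: maf <= 0.05,
    "LOW": lambda maf, ld: ld <= 10.0,
    "HIGH": lambda maf, ld: ld > 10.0,
    "ULTRA_RARE": lambda maf, ld: maf < 0.01,
}


def architecture(name: str, n_causal: int, h2: float,
                 enriched_fraction: float = 0.9) -> ArchitectureSpec:
    """Build the standard architecture specs by name.

    COMMON/RARE split at MAF 0.05, LOW/HIGH at LD score 10, ULTRA_RARE at
    MAF 0.01; in each the enriched class contributes 90% of causal variants.
    """
    key = name.upper()
    if key not in _CLASS_RULES:
        raise ValueError(f"unknown architecture {name!r}; expected one of {ARCHITECTURE_NAMES}")
    return ArchitectureSpec(name=key, n_causal=n_causal, h2=h2,
                            enriched_fraction=enriched_fraction,
                            class_rule=_CLASS_RULES[key])


@dataclass
class PhenotypeTruth:
    """A simulated phenotype with its generating effects and heritabilities."""

    y: np.ndarray
    causal_ids: np.ndarray
    beta: np.ndarray
    true_h2: float
    true_h2_nim: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.causal_ids) != len(self.beta):
            raise ValueError("causal_ids and beta must have equal length")
        if self.true_h2_nim > self.true_h2 + 1e-6:
            raise ValueError("true_h2_nim cannot exceed true_h2")


def _unique_ints(rng: np.random.Generator, low: int, high: int, k: int) -> np.ndarray:
    """k distinct integers in [low, high); redraw collisions (k << high-low)."""
    if high - low < k:
        raise ValueError("range too small for distinct positions")
    pos = rng.integers(low, high, size=k)
    while True:
        uniq, counts = np.unique(pos, return_counts=True)
        if len(uniq) == k:
            return pos
        dup = k - len(uniq)
        pos = np.concatenate([uniq, rng.integers(low, high, size=dup)])


def simulate_genotypes(config: PanelConfig) -> tuple[GenotypePanel, pd.DataFrame]:
    """Generate a phased genotype panel and its variant table.

    Deterministic for a fixed ``config.seed``.  Returns the panel and a
    variant table sorted by position with ancestry labels, realized allele
    frequencies and a diagnostic ``segment`` column (−1 for background MH).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    n_hap = 2 * n
    linked_per_seg = (config.linked_mh_per_segment
                      if config.linked_mh_per_segment is not None
                      else config.nims_per_segment)

    hap_cols: list[np.ndarray] = []
    pos_list: list[np.ndarray] = []
    ancestry: list[str] = []
    segment_of: list[int] = []

    # --- introgressed segments -------------------------------------------------
    if config.n_segments > 0:
        slot = config.genome_length_bp // config.n_segments
        a, b = config.intro_freq_dist
        # stratified inverse-CDF sampling of segment frequencies
        strata = (rng.permutation(config.n_segments) + rng.uniform(0, 1, config.n_segments))
        freqs = stats.beta.ppf(strata / config.n_segments, a, b)
        freqs = np.clip(freqs, config.min_segment_freq, 0.5)

        for s in range(config.n_segments):
            seg_len = int(rng.uniform(0.5, 1.5) * config.segment_length_bp)
            start = int(rng.integers(s * slot + 1, (s + 1) * slot - seg_len))
            f = freqs[s]
            n_core = max(2, rng.binomial(n_hap, f))
            core = rng.choice(n_hap, size=n_core, replace=False)

            # sub-block carrier erosion (recombination at segment edges)
            n_sub = 1 + rng.poisson(config.subblocks_mean)
            decays = np.concatenate([[0.0], rng.uniform(0, 2 * config.block_decay, n_sub - 1)])
            sub_carriers = []
            for d in decays:
                keep = core[rng.random(n_core) >= d]
                sub_carriers.append(keep if len(keep) else core[:1])

            k = max(1, rng.poisson(config.nims_per_segment))
            nim_pos = np.sort(_unique_ints(rng, start, start + seg_len, k))
            blocks = np.array_split(np.arange(k), n_sub)
            for bi, block in enumerate(blocks):
                col = np.zeros(n_hap, dtype=np.int8)
                col[sub_carriers[bi]] = 1
                for _ in block:
                    hap_cols.append(col)
            pos_list.append(nim_pos)
            ancestry.extend(["NIM"] * k)
            segment_of.extend([s] * k)

            # linked MH riding the introgressed haplotype at graded r²
            m = rng.poisson(linked_per_seg)
            if m:
                mh_pos = _unique_ints(rng, start, start + seg_len, m)
                f_core = n_core / n_hap
                r2 = rng.uniform(*config.linked_r2_range, size=m)
                p_target = f_core / (r2 * (1 - f_core) + f_core)
                non_core = np.setdiff1d(np.arange(n_hap), core, assume_unique=False)
                for j in range(m):
                    n_tot = int(round(p_target[j] * n_hap))
                    n_extra = min(max(n_tot - n_core, 0), len(non_core))
                    col = np.zeros(n_hap, dtype=np.int8)
                    col[core] = 1
                    if n_extra:
                        col[rng.choice(non_core, size=n_extra, replace=False)] = 1
                    hap_cols.append(col)
                pos_list.append(mh_pos)
                ancestry.extend(["MH"] * m)
                segment_of.extend([s] * m)

    # --- independent background MH --------------------------------------------
    if config.n_mh_snps:
        a, b = config.mh_maf_dist
        p = stats.beta.ppf(rng.uniform(0, 1, config.n_mh_snps), a, b)
        maf = np.clip(np.minimum(p, 1 - p), 0.0015, 0.5)
        bg = (rng.uniform(0, 1, (n_hap, config.n_mh_snps)) < maf).astype(np.int8)
        bg_pos = _unique_ints(rng, 1, config.genome_length_bp, config.n_mh_snps)
        hap_cols.extend(bg.T)
        pos_list.append(bg_pos)
        ancestry.extend(["MH"] * config.n_mh_snps)
        segment_of.extend([-1] * config.n_mh_snps)

    if not hap_cols:
        raise ValueError("configuration generates no variants")

    hap = np.column_stack(hap_cols)
    pos = np.concatenate(pos_list)
    ancestry_arr = np.array(ancestry)
    segment_arr = np.array(segment_of)

    # resolve cross-group position collisions, then sort genome-wide
    uniq, counts = np.unique(pos, return_counts=True)
    while np.any(counts > 1):
        for p_dup in uniq[counts > 1]:
            idx = np.flatnonzero(pos == p_dup)[1:]
            pos[idx] += rng.integers(1, 7, size=len(idx))
        uniq, counts = np.unique(pos, return_counts=True)
    order = np.argsort(pos, kind="stable")
    hap = hap[:, order]

    freqs = hap.mean(axis=0)
    variants = pd.DataFrame({
        "chrom": config.chrom,
        "pos_bp": pos[order],
        "variant_id": [f"{config.chrom}:{p}" for p in pos[order]],
        "ancestry": ancestry_arr[order],
        "allele_freq": freqs,
        "maf": np.minimum(freqs, 1 - freqs),
        "segment": segment_arr[order],
    })
    validate_variant_table(variants)
    dosages = (hap[0::2] + hap[1::2]).astype(np.int8)
    return GenotypePanel(dosages, hap), variants


def select_causal_variants(variants: pd.DataFrame, spec: ArchitectureSpec,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """Select causal variant ids under an architecture.

    BASELINE draws a uniform ``n_causal``-subset of QC-passing variants;
    otherwise round-half-up(enriched_fraction · n_causal) variants come from
    the enriched class and the remainder from its complement.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qc = variants["qc_pass"].to_numpy(bool) if "qc_pass" in variants else np.ones(len(variants), bool)
    pool = variants.loc[qc]
    if spec.n_causal > len(pool):
        raise ValueError("n_causal exceeds the number of QC-passing variants")
    if spec.class_rule is None:
        pick = rng.choice(pool.index.to_numpy(), size=spec.n_causal, replace=False)
        return variants.loc[np.sort(pick), "variant_id"].to_numpy()
    maf = pool["maf"].to_numpy(float)
    if "ld_score" not in pool:
        raise ValueError("architecture class rule needs an ld_score column")
    ld = pool["ld_score"].to_numpy(float)
    in_class = np.asarray(spec.class_rule(maf, ld), bool)
    quota = int(np.floor(spec.enriched_fraction * spec.n_causal + 0.5))
    rest = spec.n_causal - quota
    for label, mask, need in ((f"{spec.name} enriched class", in_class, quota),
                              (f"{spec.name} complement class", ~in_class, rest)):
        if mask.sum() < need:
            raise ValueError(f"{label} has {int(mask.sum())} variants, fewer than its quota {need}")
    chosen = []
    if quota:
        chosen.append(rng.choice(pool.index.to_numpy()[in_class], size=quota, replace=False))
    if rest:
        chosen.append(rng.choice(pool.index.to_numpy()[~in_class], size=rest, replace=False))
    pick = np.sort(np.concatenate(chosen))
    return variants.loc[pick, "variant_id"].to_numpy()


def simulate_phenotype(panel: GenotypePanel, variants: pd.DataFrame,
                       causal: Sequence[str], h2: float,
                       seed: int | np.random.Generator = 0) -> PhenotypeTruth:
    """Simulate y = Σ w β + ε on standardized causal genotypes.

    β_i are i.i.d. standard normal; ε has variance Var(Σ w β)·(1/h² − 1)
    computed from the in-sample variance of the genetic values, so the
    realized genetic variance share matches ``h2`` up to the sampling noise of
    the residual draw.  ``h2 = 1`` suppresses the residual entirely.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    causal = np.asarray(causal)
    loc = variants.set_index("variant_id").index.get_indexer(causal)
    if np.any(loc < 0):
        raise KeyError("causal ids missing from the variant table")
    freqs = variants["allele_freq"].to_numpy(float)[loc]
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("monomorphic causal variant")
    w = standardized_dosages(panel.dosages[:, loc], allele_freq=freqs, scale="freq")
    beta = rng.standard_normal(len(causal))
    g = w @ beta
    if h2 == 1.0:
        eps = np.zeros_like(g)
    else:
        var_e = g.var() * (1.0 / h2 - 1.0)
        eps = rng.normal(0.0, np.sqrt(var_e), size=len(g))
    y = g + eps
    nim = variants["ancestry"].to_numpy()[loc] == "NIM"
    h2_nim = float(np.sum(beta[nim] ** 2) / y.var()) if nim.any() else 0.0
    if h2_nim > h2:  # finite-sample excess of the per-variant accounting
        warnings.warn("realized NIM heritability accounting exceeds target h2; clipping",
                      stacklevel=2)
        h2_nim = h2
    return PhenotypeTruth(y=y, causal_ids=causal, beta=beta, true_h2=float(h2),
                          true_h2_nim=h2_nim,
                          seed=None if isinstance(seed, np.random.Generator) else int(seed))


def true_nim_h2(truth: PhenotypeTruth, variants: pd.DataFrame) -> float:
    """Σ β²_NIM / Var(y): the per-variant accounting of NIM heritability."""
    anc = variants.set_index("variant_id")["ancestry"]
    missing = [v for v in truth.causal_ids if v not in anc.index]
    if missing:
        raise KeyError(f"causal ids missing from variant table: {missing[:3]}...")
    nim = anc.loc[truth.causal_ids].to_numpy() == "NIM"
    if not nim.any():
        return 0.0
    return float(np.sum(truth.beta[nim] ** 2) / np.var(truth.y))
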