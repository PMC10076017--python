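"""Orchestrated simulation studies: estimator calibration and FDP evaluation.

Two studies exercise the pipeline end to end on the calibrated synthetic
panel:

* The **calibration study** simulates phenotypes with ancestry-blind causal
  selection under the five MAF/LD-coupled architectures (so the matched
  per-NIM vs per-MH heritability difference is zero by construction) and asks
  whether the variance-component estimator's test of Δh² = 0 is calibrated
  under each annotation scheme.  Accounting for ancestry alone is badly
  miscalibrated; intersecting ancestry with MAF and LD quintiles restores
  calibration.

* The **FDP study** runs the association arm (per-NIM regression, Bonferroni
  threshold scaled to the number of tested NIMs, clumping) and the
  fine-mapping arm (LD pruning, ±100 kb windows, sum-of-single-effects fit,
  majority-NIM filter, region merging) on the same simulations and compares
  their false discovery proportions against the known causal variants.

Simulation counts and panel size follow the package defaults: 5 architectures
× 2 heritabilities × 2 polygenicities × 3 replicates = 60 simulations on a
2,000-individual, ≈20,000-variant panel, with causal counts scaled in
proportion to the panel's share of a 7,774,235-SNP genome (minimum 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate, assoc, finemap
from .panel import GenotypePanel
from .synthio import (PanelConfig, architecture, select_causal_variants,
                      simulate_phenotype)
from .vc import MomentEngine

logger = logging.getLogger("nimkit")

__all__ = ["StudyConfig", "PreparedPanel", "prepare_panel", "scaled_causal_counts",
           "run_calibration_study", "run_fdp_study", "SCHEMES"]

#: annotation schemes by name: extra (annotation, n_bins) pairs intersected with ancestry
SCHEMES: dict[str, tuple[tuple[str, int], ...]] = {
    "ancestry": (),
    "ancestry_maf": (("maf", 5),),
    "ancestry_ld": (("ld_score", 5),),
    "ancestry_maf_ld": (("maf", 5), ("ld_score", 5)),
}

_REFERENCE_SNP_COUNT = 7_774_235  # genome-wide QC-ed SNP count being scaled down
_REFERENCE_CAUSAL = {"low": 10_000, "high": 100_000}


def scaled_causal_counts(m_qc: int) -> dict[str, int]:
    """Causal-variant counts proportional to panel size, minimum 10."""
    return {k: max(10, round(v * m_qc / _REFERENCE_SNP_COUNT))
            for k, v in _REFERENCE_CAUSAL.items()}


@dataclass
class StudyConfig:
    """Configuration of the simulation grid and estimation settings."""

    panel: PanelConfig = field(default_factory=PanelConfig)
    architectures: tuple[str, ...] = ("BASELINE", "COMMON", "RARE", "LOW", "HIGH")
    h2_values: tuple[float, ...] = (0.2, 0.5)
    polygenicity: tuple[str, ...] = ("low", "high")
    replicates: int = 3
    schemes: tuple[str, ...] = ("ancestry", "ancestry_maf_ld")
    n_blocks: int = 100
    min_snps: int = 30
    alpha: float = 0.05
    sig_threshold: float | None = None   # None → alpha / number of tested NIMs
    susie_L: int = 10
    susie_coverage: float = 0.95
    susie_purity: float = 0.5
    seed: int = 0

    def n_simulations(self) -> int:
        return (len(self.architectures) * len(self.h2_values)
                * len(self.polygenicity) * self.replicates)

    def grid(self):
        for arch in self.architectures:
            for h2 in self.h2_values:
                for poly in self.polygenicity:
                    for rep in range(self.replicates):
                        yield arch, h2, poly, rep


@dataclass
class PreparedPanel:
    """A generated panel with QC mask, LD scores and annotation partitions."""

    panel: GenotypePanel
    variants: pd.DataFrame
    partitions: dict[str, annotate.AnnotationPartition]
    causal_counts: dict[str, int]


def prepare_panel(cfg: StudyConfig) -> PreparedPanel:
    """Generate the panel, run QC, compute LD scores and build partitions."""
    from .synthio import simulate_genotypes

    panel, variants = simulate_genotypes(cfg.panel)
    qc = annotate.qc_filter(panel, variants)
    variants["qc_pass"] = qc
    logger.info("QC: %d of %d variants retained", int(qc.sum()), len(variants))
    keep = np.flatnonzero(qc)
    sub = panel.subset_variants(keep)
    vsub = variants.iloc[keep].reset_index(drop=True)
    variants["ld_score"] = np.nan
    variants.loc[keep, "ld_score"] = annotate.compute_ld_scores(sub, vsub)

    partitions = {}
    for name in cfg.schemes:
        part = annotate.build_partition(variants, schemes=SCHEMES[name],
                                        min_snps=cfg.min_snps, require_matched=True)
        logger.info("partition %s: %d bins, %d dropped", name, part.n_bins,
                    len(part.dropped))
        partitions[name] = part
    return PreparedPanel(panel=panel, variants=variants, partitions=partitions,
                         causal_counts=scaled_causal_counts(int(qc.sum())))


def _sim_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_calibration_study(cfg: StudyConfig,
                          prepared: PreparedPanel | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the Δh²-calibration suite.

    Returns (per-simulation table, per-scheme summary).  The per-simulation
    table has one row per (simulation, scheme) with the estimated NIM
    heritability, the matched-background difference, their jackknife Z-scores
    and the p < alpha rejection indicator for Δh² = 0.
    """
    prep = prepared or prepare_panel(cfg)
    engine = MomentEngine(prep.panel, prep.variants, prep.partitions,
                          n_blocks=cfg.n_blocks)
    rows = []
    rngs = _sim_seeds(cfg.seed, cfg.n_simulations())
    for i, (arch, h2, poly, rep) in enumerate(cfg.grid()):
        rng = rngs[i]
        spec = architecture(arch, prep.causal_counts[poly], h2)
        causal = select_causal_variants(prep.variants, spec, rng)
        truth = simulate_phenotype(prep.panel, prep.variants, causal, h2, rng)
        for scheme in cfg.schemes:
            est = engine.estimate(truth.y, scheme, truth_h2_nim=truth.true_h2_nim)
            rows.append({
                "architecture": arch, "h2": h2, "polygenicity": poly, "rep": rep,
                "scheme": scheme, "n_causal": len(causal),
                "h2_total": est.h2_total, "h2_nim": est.h2_nim,
                "se_h2_nim": est.se_h2_nim, "true_h2_nim": truth.true_h2_nim,
                "z_h2nim_vs_truth": est.z_h2nim_vs_truth,
                "delta_h2": est.delta_h2, "se_delta": est.se_delta,
                "z_delta": est.z_delta_vs_zero, "p_delta": est.p_delta_two_sided,
                "reject_delta": est.p_delta_two_sided < cfg.alpha,
            })
        logger.info("calibration sim %d/%d done", i + 1, cfg.n_simulations())
    table = pd.DataFrame(rows)
    summary = (table.groupby("scheme")
               .agg(rejection_rate=("reject_delta", "mean"),
                    frac_abs_z_delta_le2=("z_delta", lambda z: float(np.mean(np.abs(z) <= 2))),
                    frac_abs_z_truth_le2=("z_h2nim_vs_truth",
                                          lambda z: float(np.mean(np.abs(z) <= 2))),
                    n=("reject_delta", "size"))
               .reset_index())
    return table, summary


def _fdp_one(prep: PreparedPanel, cfg: StudyConfig, truth) -> dict:
    variants = prep.variants
    nim_idx = np.flatnonzero((variants["ancestry"] == "NIM").to_numpy()
                             & variants["qc_pass"].to_numpy())
    res = assoc.gwas_linear(truth.y, prep.panel, variants, test_idx=nim_idx)
    thr = cfg.sig_threshold if cfg.sig_threshold is not None else cfg.alpha / len(nim_idx)
    clumps = assoc.clump(res, prep.panel, p_index=thr)
    a_fdp, a_tp, a_fp = assoc.association_fdp(clumps, variants,
                                              truth.causal_ids, truth.beta)
    sig_idx = res.significant(thr)["index"].to_numpy()
    out = {"n_sig": len(sig_idx), "n_clumps": len(clumps),
           "assoc_fdp": a_fdp, "assoc_tp": a_tp, "assoc_fp": a_fp,
           "n_regions": 0, "finemap_fdp": None, "finemap_tp": 0, "finemap_fp": 0,
           "n_credible_nims": 0, "n_tested_nims": 0}
    if len(sig_idx) == 0:
        return out
    pruned = assoc.ld_prune(sig_idx, prep.panel, variants)
    windows = finemap.make_windows(pruned, variants)
    y_resid = finemap.residualize(truth.y, None)
    window_sets = []
    tested: set[int] = set()
    anc = variants["ancestry"].to_numpy()
    for widx in windows:
        tested.update(widx[anc[widx] == "NIM"])
        fit = finemap.susie_fit(prep.panel.dosages[:, widx].astype(float), y_resid,
                                L=cfg.susie_L, coverage=cfg.susie_coverage,
                                purity_min=cfg.susie_purity)
        window_sets.append((widx, [cs.variants for cs in fit.sets]))
    regions = finemap.credible_nim_postprocess(window_sets, variants)
    f_fdp, f_tp, f_fp = finemap.evaluate_fdp(regions, truth, variants)
    out.update({"n_regions": len(regions), "finemap_fdp": f_fdp,
                "finemap_tp": f_tp, "finemap_fp": f_fp,
                "n_credible_nims": len({v for r in regions for v in r.credible_nims}),
                "n_tested_nims": len(tested)})
    return out


def run_fdp_study(cfg: StudyConfig,
                  prepared: PreparedPanel | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the association-vs-fine-mapping FDP suite.

    Returns (per-simulation table, summary).  The summary reports, per
    architecture and overall, the mean FDP of each arm over simulations with
    at least one discovery by that arm.
    """
    prep = prepared or prepare_panel(cfg)
    rows = []
    rngs = _sim_seeds(cfg.seed, cfg.n_simulations())
    for i, (arch, h2, poly, rep) in enumerate(cfg.grid()):
        rng = rngs[i]
        spec = architecture(arch, prep.causal_counts[poly], h2)
        causal = select_causal_variants(prep.variants, spec, rng)
        truth = simulate_phenotype(prep.panel, prep.variants, causal, h2, rng)
        row = {"architecture": arch, "h2": h2, "polygenicity": poly, "rep": rep,
               "n_causal": len(causal)}
        row.update(_fdp_one(prep, cfg, truth))
        rows.append(row)
        logger.info("fdp sim %d/%d: clumps=%d regions=%d", i + 1,
                    cfg.n_simulations(), row["n_clumps"], row["n_regions"])
    table = pd.DataFrame(rows)

    def _mean_fdp(sub: pd.DataFrame, col: str) -> float:
        vals = sub[col].dropna()
        return float(vals.mean()) if len(vals) else np.nan

    groups = []
    for arch, sub in table.groupby("architecture"):
        groups.append({"architecture": arch,
                       "assoc_fdp": _mean_fdp(sub, "assoc_fdp"),
                       "finemap_fdp": _mean_fdp(sub, "finemap_fdp"),
                       "n_with_assoc": int(sub["assoc_fdp"].notna().sum()),
                       "n_with_regions": int(sub["finemap_fdp"].notna().sum())})
    groups.append({"architecture": "ALL",
                   "assoc_fdp": _mean_fdp(table, "assoc_fdp"),
                   "finemap_fdp": _mean_fdp(table, "finemap_fdp"),
                   "n_with_assoc": int(table["assoc_fdp"].notna().sum()),
                   "n_with_regions": int(table["finemap_fdp"].notna().sum())})
    return table, pd.DataFrame(groups)
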