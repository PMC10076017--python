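"""Single-variant association testing, clumping and LD pruning for NIMs.

Implements the association arm of the pipeline: principal components computed
from the introgressed variants themselves (to absorb stratification specific
to rare introgressed alleles), vectorized per-variant linear regression with
covariates, greedy p-value clumping, and window LD pruning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel, standardized_dosages

__all__ = ["AssocResult", "compute_nim_pcs", "gwas_linear", "clump", "ld_prune",
           "association_fdp"]


@dataclass
class AssocResult:
    """Per-variant association statistics over a tested variant subset.

    ``table`` has one row per tested variant: variant_id, chrom, pos_bp, beta
    (per standardized allele), se, t, p, tested (False for variants collinear
    with the covariates, which are flagged rather than tested).
    """

    table: pd.DataFrame
    n: int
    n_covariates: int
    clumps: pd.DataFrame | None = None

    def significant(self, threshold: float) -> pd.DataFrame:
        t = self.table
        return t[t["tested"] & (t["p"] < threshold)]


def compute_nim_pcs(panel: GenotypePanel, variants: pd.DataFrame, k: int = 5) -> np.ndarray:
    """Top-k principal-component scores of the column-standardized NIM dosages.

    Returned columns are orthogonal and ordered by decreasing variance;
    deterministic up to sign.  ``k = 0`` returns an empty block.
    """
    n = panel.n_individuals
    if k == 0:
        return np.zeros((n, 0))
    nim_idx = np.flatnonzero(variants["ancestry"].to_numpy() == "NIM")
    if len(nim_idx) < k:
        raise ValueError(f"need at least k={k} NIM variants")
    x = standardized_dosages(panel.dosages[:, nim_idx], scale="sd")
    gram = x @ x.T
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    if np.any(vals <= 1e-8 * max(vals[0], 1.0)):
        raise ValueError(f"k={k} exceeds the rank of the NIM dosage matrix")
    return vecs * np.sqrt(vals)


def gwas_linear(y: np.ndarray, panel: GenotypePanel, variants: pd.DataFrame,
                test_idx: np.ndarray | None = None,
                covariates: np.ndarray | None = None) -> AssocResult:
    """Per-variant least-squares association of y on [dosage, covariates].

    Each variant is regressed jointly with the covariates (equivalently, via
    Frisch–Waugh projection of both y and the standardized dosage onto the
    covariate complement).  Two-sided t-test p-values with n − q − 1 degrees
    of freedom.  Variants whose residual variance vanishes (constant, or
    collinear with covariates) are flagged untested.
    """
    n = panel.n_individuals
    y = np.asarray(y, float)
    if test_idx is None:
        test_idx = np.arange(panel.n_variants)
    test_idx = np.asarray(test_idx)
    covar = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, float)])
    if np.linalg.matrix_rank(covar) < covar.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    q, _ = np.linalg.qr(covar)
    yr = y - q @ (q.T @ y)

    x = panel.dosages[:, test_idx].astype(float)
    miss = x < 0
    if miss.any():
        x[miss] = np.nan
        mean = np.nanmean(x, axis=0)
        ind = np.where(miss)
        x[ind] = mean[ind[1]]
    sd = x.std(axis=0)
    tested = sd > 0
    xs = np.where(sd > 0, 1.0, np.nan) * (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    xs = np.nan_to_num(xs)
    xr = xs - q @ (q.T @ xs)

    xtx = np.einsum("ij,ij->j", xr, xr)
    tested &= xtx > 1e-8 * n
    xty = xr.T @ yr
    dof = n - covar.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(tested, xty / xtx, np.nan)
        rss = yr @ yr - np.where(tested, beta * xty, 0.0)
        se = np.sqrt(rss / dof / xtx)
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    table = pd.DataFrame({
        "variant_id": variants["variant_id"].to_numpy()[test_idx],
        "chrom": variants["chrom"].to_numpy()[test_idx],
        "pos_bp": variants["pos_bp"].to_numpy()[test_idx],
        "beta": beta, "se": np.where(tested, se, np.nan),
        "t": np.where(tested, tstat, np.nan),
        "p": np.where(tested, p, np.nan),
        "tested": tested,
        "index": test_idx,
    })
    return AssocResult(table=table, n=n, n_covariates=covar.shape[1])


def _pairwise_r2(panel: GenotypePanel, idx: np.ndarray) -> np.ndarray:
    w = standardized_dosages(panel.dosages[:, idx], scale="sd")
    r = (w.T @ w) / w.shape[0]
    return r ** 2


def clump(assoc: AssocResult, panel: GenotypePanel,
          window_bp: int = 250_000, r2: float = 0.5,
          p_index: float = 1e-10) -> pd.DataFrame:
    """Greedy LD clumping of significant variants.

    Repeatedly promotes the smallest-p unassigned significant variant to clump
    index and absorbs significant variants within ``window_bp`` on the same
    chromosome with r² ≥ ``r2``.  Returns one row per clump: index_id, chrom,
    pos_bp, p, member_ids.
    """
    sig = assoc.significant(p_index).sort_values("p", kind="stable")
    rows = []
    if len(sig):
        idx = sig["index"].to_numpy()
        r2m = _pairwise_r2(panel, idx)
        pos = sig["pos_bp"].to_numpy()
        chrom = sig["chrom"].to_numpy()
        assigned = np.zeros(len(sig), bool)
        for i in range(len(sig)):
            if assigned[i]:
                continue
            near = (~assigned & (chrom == chrom[i])
                    & (np.abs(pos - pos[i]) <= window_bp) & (r2m[i] >= r2))
            near[i] = True
            assigned |= near
            members = sig.iloc[np.flatnonzero(near)]
            rows.append({
                "index_id": sig.iloc[i]["variant_id"], "chrom": chrom[i],
                "pos_bp": int(pos[i]), "p": float(sig.iloc[i]["p"]),
                "n_members": int(near.sum()),
                "member_ids": ",".join(members["variant_id"]),
            })
    clumps = pd.DataFrame(rows, columns=["index_id", "chrom", "pos_bp", "p",
                                         "n_members", "member_ids"])
    assoc.clumps = clumps
    return clumps


def ld_prune(variant_idx: np.ndarray, panel: GenotypePanel, variants: pd.DataFrame,
             window_bp: int = 100_000, r2: float = 0.99) -> np.ndarray:
    """Sliding-window LD pruning; keeps the earlier-position member of any
    within-window pair with r² > ``r2``.  Input must be position-sorted."""
    variant_idx = np.asarray(variant_idx)
    if len(variant_idx) == 0:
        return variant_idx
    pos = variants["pos_bp"].to_numpy()[variant_idx]
    chrom = variants["chrom"].to_numpy()[variant_idx]
    order = np.lexsort((pos, chrom))
    variant_idx, pos, chrom = variant_idx[order], pos[order], chrom[order]
    w = standardized_dosages(panel.dosages[:, variant_idx], scale="sd")
    n = w.shape[0]
    kept: list[int] = []
    for j in range(len(variant_idx)):
        drop = False
        for i in reversed(kept):
            if chrom[i] != chrom[j] or pos[j] - pos[i] > window_bp:
                break
            r = (w[:, i] @ w[:, j]) / n
            if r * r > r2:
                drop = True
                break
        if not drop:
            kept.append(j)
    return variant_idx[np.array(kept, int)]


def association_fdp(clumps: pd.DataFrame, variants: pd.DataFrame,
                    causal_ids: np.ndarray, beta: np.ndarray,
                    region_bp: int = 200_000) -> tuple[float | None, int, int]:
    """Label clumped significant NIMs and compute the false discovery proportion.

    A clump index is a true positive iff the ``region_bp`` region surrounding
    it (index ± region_bp/2) contains any NIM with non-zero causal effect.
    Returns (fdp, tp, fp); fdp is None when there are no discoveries.
    """
    if clumps is None or len(clumps) == 0:
        return None, 0, 0
    vt = variants.set_index("variant_id")
    causal_ids = np.asarray(causal_ids)
    nz = np.asarray(beta) != 0
    causal_nim = [v for v in causal_ids[nz] if vt.loc[v, "ancestry"] == "NIM"]
    cpos = np.array([vt.loc[v, "pos_bp"] for v in causal_nim])
    cchrom = np.array([vt.loc[v, "chrom"] for v in causal_nim])
    half = region_bp // 2
    tp = fp = 0
    for _, row in clumps.iterrows():
        hit = np.any((cchrom == row["chrom"]) & (np.abs(cpos - row["pos_bp"]) <= half)) \
            if len(cpos) else False
        tp += int(hit)
        fp += int(not hit)
    return fp / (tp + fp), tp, fp
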