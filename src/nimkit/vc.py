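"""Multi-component method-of-moments heritability partitioning.

Fits the variance-component model

    y = Σ_k g_k + ε,   g_k ~ (0, σ²_k K_k),   K_k = W_k W_kᵀ / M_k,

where ``W_k`` stacks the standardized genotypes of annotation bin ``k``, by
solving the method-of-moments normal equations

    E[yᵀ K_k y] = Σ_l σ²_l tr(K_k K_l) + σ²_e tr(K_k),
    E[yᵀ y]     = Σ_l σ²_l tr(K_l)     + σ²_e (n − q),

jointly over all bins plus the identity component (q = number of covariate
columns projected out of y and the genotypes).

Uncertainty comes from a delete-one-block jackknife over ``n_blocks``
contiguous SNP blocks: every replicate re-solves the normal equations with
the block's SNPs removed from their bins, and the covariance across bins (and
any linear functional of them — total, NIM aggregate, the matched-background
difference Δh²) is taken over the replicates.

Two trace back-ends are provided.  The exact mode streams the Gram matrix
WᵀW one SNP block at a time and caches, per (block, bin-pair), the sums of
squared entries needed to reconstruct every jackknife replicate exactly.  The
randomized mode estimates the same quantities with Rademacher probe vectors
(Hutchinson estimator) and converges to the exact mode as the probe count
grows; it exists for very large panels and for validating the exact path.

The matched-background statistic follows the ancestry-partitioned analysis:
ĥ²_NIM = Σ_i ĥ²_NIM,i over NIM bins, ĥ²_MH = Σ_i (M_NIM,i/M_MH,i)·ĥ²_MH,i over
MAF/LD-matched bin pairs, and Δĥ² = ĥ²_NIM − ĥ²_MH, negative values meaning
depletion of introgressed heritability relative to the matched background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import AnnotationPartition
from .panel import GenotypePanel, standardized_dosages

__all__ = ["ComponentEstimates", "MomentEngine", "estimate_components",
           "aggregate_h2_nim", "delta_h2", "matched_background_h2"]


def matched_background_h2(h2_per_bin: np.ndarray, labels: Sequence[tuple],
                          sizes: np.ndarray) -> float:
    """ĥ²_MH = Σ_i (M_NIM,i / M_MH,i) · ĥ²_MH,i over matched bin pairs.

    ``labels`` carry (ancestry, …) tuples; each NIM bin must have an MH bin
    with the identical non-ancestry label, else ValueError lists the orphans.
    """
    by_label = {tuple(lab): k for k, lab in enumerate(labels)}
    total = 0.0
    orphans = []
    for k, lab in enumerate(labels):
        if lab[0] != "NIM":
            continue
        partner = by_label.get(("MH",) + tuple(lab[1:]))
        if partner is None:
            orphans.append(lab)
            continue
        total += (sizes[k] / sizes[partner]) * h2_per_bin[partner]
    if orphans:
        raise ValueError(f"NIM bins without a matched MH bin: {orphans}")
    return float(total)


@dataclass
class ComponentEstimates:
    """Per-bin variance components with jackknife uncertainty."""

    labels: list[tuple]
    sizes: np.ndarray
    sigma2_per_bin: np.ndarray
    sigma2_noise: float
    h2_per_bin: np.ndarray
    h2_total: float
    h2_nim: float
    h2_mh_matched: float | None
    delta_h2: float | None
    jackknife_cov: np.ndarray
    se_h2_per_bin: np.ndarray
    se_h2_total: float
    se_h2_nim: float
    se_h2_mh_matched: float | None
    se_delta: float | None
    z_h2nim_vs_zero: float
    z_h2nim_vs_truth: float | None
    z_delta_vs_zero: float | None
    p_h2nim_one_sided: float
    p_delta_two_sided: float | None
    truth_h2_nim: float | None
    n_blocks: int
    var_y: float
    # jackknife replicates of the derived statistics, for downstream re-use
    jack_h2_per_bin: np.ndarray = field(repr=False, default=None)
    jack_h2_nim: np.ndarray = field(repr=False, default=None)
    jack_h2_mh: np.ndarray | None = field(repr=False, default=None)
    jack_delta: np.ndarray | None = field(repr=False, default=None)
    orphan_bins: list[tuple] = field(default_factory=list)


def _jack_cov(reps: np.ndarray) -> np.ndarray:
    """Delete-one jackknife covariance of a (B, d) replicate matrix."""
    b = reps.shape[0]
    dev = reps - reps.mean(axis=0)
    return (b - 1) / b * (dev.T @ dev)


class MomentEngine:
    """Precomputed trace tables for one genotype panel and ≥1 partitions.

    Building the engine performs the expensive genotype pass once; each call
    to :meth:`estimate` then costs a single matrix–vector product, so many
    simulated phenotypes can be analyzed against the same panel cheaply.
    """

    def __init__(self, panel: GenotypePanel, variants: pd.DataFrame,
                 partitions: dict[str, AnnotationPartition],
                 covariates: np.ndarray | None = None,
                 n_blocks: int = 100, mode: str = "exact",
                 n_probes: int = 32, seed: int = 0):
        if mode not in ("exact", "randomized"):
            raise ValueError("mode must be 'exact' or 'randomized'")
        self.mode = mode
        self.partitions = dict(partitions)
        self.n_blocks = n_blocks

        union = np.zeros(len(variants), dtype=bool)
        for part in self.partitions.values():
            union |= part.bin_of_variant >= 0
        self.cols = np.flatnonzero(union)  # variant-table rows, position order
        if len(self.cols) == 0:
            raise ValueError("no retained variants in any partition")

        n = panel.n_individuals
        covar = np.ones((n, 1)) if covariates is None else np.column_stack(
            [np.ones(n), np.asarray(covariates, float)])
        self._q, _ = np.linalg.qr(covar)
        self.n_eff = n - covar.shape[1]
        if np.linalg.matrix_rank(covar) < covar.shape[1]:
            raise ValueError("covariate matrix is rank deficient")

        w = standardized_dosages(panel.dosages[:, self.cols], scale="freq")
        w -= self._q @ (self._q.T @ w)
        self._w = w
        self.col_norm2 = np.einsum("ij,ij->j", w, w)

        m_union = len(self.cols)
        if n_blocks > m_union:
            raise ValueError("more jackknife blocks than retained SNPs")
        edges = np.linspace(0, m_union, n_blocks + 1).astype(int)
        self.block_of = np.repeat(np.arange(n_blocks), np.diff(edges))
        self._block_slices = [slice(edges[b], edges[b + 1]) for b in range(n_blocks)]

        # per-partition bin assignment over union columns and block-wise size/norm sums
        self._cb: dict[str, np.ndarray] = {}
        self._msize: dict[str, np.ndarray] = {}
        self._norm: dict[str, np.ndarray] = {}
        for name, part in self.partitions.items():
            cb = part.bin_of_variant[self.cols]
            k = part.n_bins
            self._cb[name] = cb
            msize = np.zeros((n_blocks, k))
            norm = np.zeros((n_blocks, k))
            ok = cb >= 0
            np.add.at(msize, (self.block_of[ok], cb[ok]), 1.0)
            np.add.at(norm, (self.block_of[ok], cb[ok]), self.col_norm2[ok])
            self._msize[name] = msize
            self._norm[name] = norm

        if mode == "exact":
            self._compute_exact_traces()
        else:
            self._compute_probe_traces(n_probes, seed)

    # ------------------------------------------------------------------ traces
    def _compute_exact_traces(self) -> None:
        nb = self.n_blocks
        self._tb: dict[str, np.ndarray] = {}
        self._tbb: dict[str, np.ndarray] = {}
        orders, starts = {}, {}
        for name, cb in self._cb.items():
            k = self.partitions[name].n_bins
            self._tb[name] = np.zeros((nb, k, k))
            self._tbb[name] = np.zeros((nb, k, k))
            ok = np.flatnonzero(cb >= 0)
            order = ok[np.argsort(cb[ok], kind="stable")]
            counts = np.bincount(cb[ok], minlength=k)
            orders[name] = order
            starts[name] = np.concatenate([[0], np.cumsum(counts)[:-1]])

        for b in range(nb):
            sl = self._block_slices[b]
            s = self._w[:, sl].T @ self._w
            np.square(s, out=s)
            rows_local = np.arange(sl.start, sl.stop)
            for name, cb in self._cb.items():
                rb = cb[rows_local]
                rmask = rb >= 0
                if not rmask.any():
                    continue
                order = orders[name]
                counts = np.diff(np.concatenate([starts[name], [len(order)]]))
                if len(order):
                    seg = np.add.reduceat(s[:, order],
                                          np.minimum(starts[name], len(order) - 1), axis=1)
                    seg[:, counts == 0] = 0.0  # reduceat artifacts on empty bins
                else:
                    seg = np.zeros((s.shape[0], self.partitions[name].n_bins))
                np.add.at(self._tb[name], (b, rb[rmask]), seg[rmask])
                # within-block squared sums
                local = cb[rows_local]
                lmask = np.flatnonzero(local >= 0)
                if len(lmask):
                    lorder = lmask[np.argsort(local[lmask], kind="stable")]
                    lcounts = np.bincount(local[lmask], minlength=self.partitions[name].n_bins)
                    lstarts = np.concatenate([[0], np.cumsum(lcounts)[:-1]])
                    seg2 = np.add.reduceat(s[:, sl.start + lorder],
                                           np.minimum(lstarts, len(lorder) - 1), axis=1)
                    seg2[:, lcounts == 0] = 0.0
                    np.add.at(self._tbb[name], (b, rb[rmask]), seg2[rmask])
        self._t = {name: tb.sum(axis=0) for name, tb in self._tb.items()}

    def _compute_probe_traces(self, n_probes: int, seed: int) -> None:
        rng = np.random.default_rng(seed)
        n = self._w.shape[0]
        nb = self.n_blocks
        self._probe: dict[str, np.ndarray] = {}
        for name in self.partitions:
            k = self.partitions[name].n_bins
            need = nb * k * n * n_probes * 8
            if need > 4e9:
                raise MemoryError(
                    "randomized-trace block vectors would need "
                    f"{need/1e9:.1f} GB; use mode='exact' or fewer probes")
            self._probe[name] = np.zeros((nb, k, n, n_probes))
        z = rng.choice((-1.0, 1.0), size=(n, n_probes))
        v = self._w.T @ z  # (M, P)
        for b in range(nb):
            sl = self._block_slices[b]
            wb = self._w[:, sl]
            for name, cb in self._cb.items():
                local = cb[sl]
                for k in np.unique(local[local >= 0]):
                    cols = np.flatnonzero(local == k)
                    self._probe[name][b, k] += wb[:, cols] @ v[sl, :][cols]
        self._n_probes = n_probes

    # ---------------------------------------------------------------- estimate
    def _trace_system(self, name: str, delete_block: int | None):
        """(tr(K_kK_l), tr(K_k), adjusted sizes, active mask) for one replicate."""
        part = self.partitions[name]
        k = part.n_bins
        msize = self._msize[name]
        norm = self._norm[name]
        m_full = msize.sum(axis=0)
        n_full = norm.sum(axis=0)
        if delete_block is None:
            m_adj, n_adj = m_full, n_full
        else:
            m_adj = m_full - msize[delete_block]
            n_adj = n_full - norm[delete_block]
        active = m_adj > 0

        if self.mode == "exact":
            t = self._t[name]
            if delete_block is None:
                num = t
            else:
                tb = self._tb[name][delete_block]
                num = t - tb - tb.T + self._tbb[name][delete_block]
        else:
            pv = self._probe[name]
            tot = pv.sum(axis=0)  # (k, n, P)
            if delete_block is not None:
                tot = tot - pv[delete_block]
            num = np.einsum("knp,lnp->kl", tot, tot) / self._n_probes

        denom = np.outer(np.where(active, m_adj, 1.0), np.where(active, m_adj, 1.0))
        tr_kk = num / denom
        tr_k = np.where(active, n_adj / np.where(active, m_adj, 1.0), 0.0)
        return tr_kk, tr_k, m_adj, active

    def _solve(self, name: str, yky_num: np.ndarray, yy: float,
               delete_block: int | None):
        tr_kk, tr_k, m_adj, active = self._trace_system(name, delete_block)
        idx = np.flatnonzero(active)
        ka = len(idx)
        a = np.zeros((ka + 1, ka + 1))
        a[:ka, :ka] = tr_kk[np.ix_(idx, idx)]
        a[:ka, ka] = tr_k[idx]
        a[ka, :ka] = tr_k[idx]
        a[ka, ka] = self.n_eff
        rhs = np.concatenate([yky_num[idx] / m_adj[idx], [yy]])
        cond = np.linalg.cond(a)
        if not np.isfinite(cond) or cond > 1e12:
            labels = [self.partitions[name].labels[i] for i in idx]
            raise np.linalg.LinAlgError(
                f"singular moment matrix (cond={cond:.2e}); collinear bins among {labels}")
        sol = np.linalg.solve(a, rhs)
        sigma2 = np.zeros(self.partitions[name].n_bins)
        sigma2[idx] = sol[:ka]
        return sigma2, float(sol[ka]), m_adj, active

    def estimate(self, y: np.ndarray, partition: str,
                 truth_h2_nim: float | None = None) -> ComponentEstimates:
        """Estimate all components and derived statistics for one phenotype."""
        part = self.partitions[partition]
        y = np.asarray(y, float)
        y_res = y - self._q @ (self._q.T @ y)
        yy = float(y_res @ y_res)
        var_y = yy / self.n_eff
        c = self._w.T @ y_res
        c2 = c ** 2
        cb = self._cb[partition]
        k = part.n_bins
        u = np.zeros((self.n_blocks, k))
        ok = cb >= 0
        np.add.at(u, (self.block_of[ok], cb[ok]), c2[ok])
        u_full = u.sum(axis=0)

        nim_bins = part.bins_with_ancestry("NIM")
        if len(nim_bins) == 0:
            raise ValueError("partition retains no NIM bins")
        try:
            pairs = part.matched_pairs()
            orphans: list[tuple] = []
        except ValueError as exc:
            pairs, orphans = None, [lab for lab in part.labels
                                    if lab[0] == "NIM"
                                    and ("MH",) + lab[1:] not in part.labels]

        def derived(sigma2, sigma2_e, m_adj):
            h2 = sigma2 / var_y
            h2_nim = float(h2[nim_bins].sum())
            if pairs is None:
                return h2, h2_nim, None, None
            h2_mh = matched_background_h2(h2, part.labels, m_adj)
            return h2, h2_nim, h2_mh, h2_nim - h2_mh

        sigma2, sigma2_e, m_adj, _ = self._solve(partition, u_full, yy, None)
        h2, h2_nim, h2_mh, delta = derived(sigma2, sigma2_e, m_adj)

        jack_h2 = np.zeros((self.n_blocks, k))
        jack_nim = np.zeros(self.n_blocks)
        jack_mh = np.zeros(self.n_blocks) if pairs is not None else None
        for b in range(self.n_blocks):
            s_b, se_b, m_b, _ = self._solve(partition, u_full - u[b], yy, b)
            h2_b, nim_b, mh_b, _ = derived(s_b, se_b, m_b)
            jack_h2[b] = h2_b
            jack_nim[b] = nim_b
            if jack_mh is not None:
                jack_mh[b] = mh_b
        jack_delta = jack_nim - jack_mh if jack_mh is not None else None

        cov = _jack_cov(jack_h2)
        se_bins = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se_total = float(np.sqrt(max(np.ones(k) @ cov @ np.ones(k), 0.0)))
        se_nim = float(np.sqrt(max(_jack_cov(jack_nim[:, None])[0, 0], 0.0)))
        se_mh = (float(np.sqrt(max(_jack_cov(jack_mh[:, None])[0, 0], 0.0)))
                 if jack_mh is not None else None)
        se_delta = (float(np.sqrt(max(_jack_cov(jack_delta[:, None])[0, 0], 0.0)))
                    if jack_delta is not None else None)

        z_nim0 = h2_nim / se_nim if se_nim > 0 else np.nan
        z_nimt = ((h2_nim - truth_h2_nim) / se_nim
                  if truth_h2_nim is not None and se_nim > 0 else None)
        z_delta = (delta / se_delta if se_delta not in (None, 0) else None)
        return ComponentEstimates(
            labels=list(part.labels), sizes=part.sizes.copy(),
            sigma2_per_bin=sigma2, sigma2_noise=sigma2_e,
            h2_per_bin=h2, h2_total=float(h2.sum()), h2_nim=h2_nim,
            h2_mh_matched=h2_mh, delta_h2=delta,
            jackknife_cov=cov, se_h2_per_bin=se_bins, se_h2_total=se_total,
            se_h2_nim=se_nim, se_h2_mh_matched=se_mh, se_delta=se_delta,
            z_h2nim_vs_zero=float(z_nim0), z_h2nim_vs_truth=z_nimt,
            z_delta_vs_zero=float(z_delta) if z_delta is not None else None,
            p_h2nim_one_sided=float(stats.norm.sf(z_nim0)),
            p_delta_two_sided=(float(2 * stats.norm.sf(abs(z_delta)))
                               if z_delta is not None else None),
            truth_h2_nim=truth_h2_nim, n_blocks=self.n_blocks, var_y=var_y,
            jack_h2_per_bin=jack_h2, jack_h2_nim=jack_nim,
            jack_h2_mh=jack_mh, jack_delta=jack_delta, orphan_bins=orphans)


def estimate_components(y: np.ndarray, panel: GenotypePanel, variants: pd.DataFrame,
                        partition: AnnotationPartition,
                        covariates: np.ndarray | None = None,
                        mode: str = "exact", n_blocks: int = 100,
                        n_probes: int = 32, seed: int = 0,
                        truth_h2_nim: float | None = None) -> ComponentEstimates:
    """One-shot wrapper around :class:`MomentEngine` for a single phenotype."""
    engine = MomentEngine(panel, variants, {"p": partition}, covariates=covariates,
                          n_blocks=n_blocks, mode=mode, n_probes=n_probes, seed=seed)
    return engine.estimate(y, "p", truth_h2_nim=truth_h2_nim)


def aggregate_h2_nim(est: ComponentEstimates,
                     truth: float | None = None) -> tuple[float, float, float, float | None]:
    """(ĥ²_NIM, jackknife SE of the sum, Z vs 0, Z vs supplied truth)."""
    nim_bins = [k for k, lab in enumerate(est.labels) if lab[0] == "NIM"]
    if not nim_bins:
        raise ValueError("no NIM bins retained in the estimates")
    h2_nim = float(est.h2_per_bin[nim_bins].sum())
    se = float(np.sqrt(max(_jack_cov(est.jack_h2_per_bin[:, nim_bins]
                                     .sum(axis=1, keepdims=True))[0, 0], 0.0)))
    z0 = h2_nim / se if se > 0 else np.nan
    zt = (h2_nim - truth) / se if truth is not None and se > 0 else None
    return h2_nim, se, z0, zt


def delta_h2(est: ComponentEstimates) -> tuple[float, float, float]:
    """(Δĥ², jackknife SE, Z) for the matched-background difference."""
    if est.orphan_bins:
        raise ValueError(f"NIM bins without a matched MH bin: {est.orphan_bins}")
    if est.delta_h2 is None or est.jack_delta is None:
        raise ValueError("matched-background statistics unavailable")
    se = float(np.sqrt(max(_jack_cov(est.jack_delta[:, None])[0, 0], 0.0)))
    return float(est.delta_h2), se, float(est.delta_h2 / se) if se > 0 else np.nan
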