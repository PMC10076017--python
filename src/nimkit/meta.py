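"""Random-effects meta-analysis across phenotypes.

Pools per-phenotype estimates (e.g. introgressed-variant heritability or the
matched-background difference) under a DerSimonian–Laird random-effects
model, and selects a low-correlation phenotype subset for the across-category
meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MetaResult", "random_effects_meta", "select_low_correlation_subset",
           "MIN_CATEGORY_SIZE"]

MIN_CATEGORY_SIZE = 4  # categories below this size are not meta-analyzed


@dataclass
class MetaResult:
    mean: float
    tau2: float
    se: float
    z: float
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("meta-analysis needs at least one phenotype")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


def random_effects_meta(estimates: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) with fixed-effect weights
    w = 1/se²; the pooled mean uses weights 1/(se² + τ²).
    """
    est = np.asarray(estimates, float)
    se = np.asarray(ses, float)
    if est.size == 0:
        raise ValueError("no estimates supplied")
    if est.shape != se.shape or np.any(se <= 0):
        raise ValueError("estimates and positive ses of equal length required")
    k = est.size
    w = 1.0 / se ** 2
    mean_fe = np.sum(w * est) / np.sum(w)
    q = float(np.sum(w * (est - mean_fe) ** 2))
    if k > 1:
        denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    w_re = 1.0 / (se ** 2 + tau2)
    mean = float(np.sum(w_re * est) / np.sum(w_re))
    se_mean = float(np.sqrt(1.0 / np.sum(w_re)))
    return MetaResult(mean=mean, tau2=float(tau2), se=se_mean,
                      z=mean / se_mean, k=int(k))


def select_low_correlation_subset(pheno: np.ndarray, r2_max: float = 0.25,
                                  ids: Sequence | None = None) -> list:
    """Greedy low-correlation phenotype subset.

    Phenotypes are visited in input (column) order; one is kept iff its
    squared Pearson correlation with every already-kept phenotype is
    ≤ ``r2_max``.  Every kept pair therefore certifiably satisfies the bound.
    """
    x = np.asarray(pheno, float)
    if x.ndim != 2:
        raise ValueError("pheno must be an n × k matrix of phenotype columns")
    ids = list(ids) if ids is not None else list(range(x.shape[1]))
    kept: list[int] = []
    for j in range(x.shape[1]):
        ok = True
        for i in kept:
            r = np.corrcoef(x[:, i], x[:, j])[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return [ids[j] for j in kept]
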