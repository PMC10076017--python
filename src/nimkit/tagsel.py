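"""Greedy tag-SNP selection for array design.

Selects variants that tag a candidate set (e.g. introgressed variants not
already tagged by an existing array) under a probe-feature budget.  At each
step the score of candidate j is

    Score_j = Σ_i δ(r²(i, j) > 0.80) · freq_i / cost_j

summed over currently untagged candidates i (including j itself), where
``freq`` is the derived-allele frequency and ``cost`` the number of array
features needed to genotype j.  The highest-scoring candidate is selected,
every candidate it tags at r² > the threshold is marked tagged, and its cost
is charged to the budget.  Scores are recomputed from scratch each iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import GenotypePanel, standardized_dosages

__all__ = ["TagSelection", "greedy_tag_selection"]


@dataclass
class TagSelection:
    selected_ids: list[str]
    step_scores: list[float]
    features_used: int
    untagged_ids: list[str] = field(default_factory=list)


def greedy_tag_selection(candidates: pd.DataFrame, panel: GenotypePanel,
                         variants: pd.DataFrame,
                         existing_tags: Sequence[str] = (),
                         r2_tag: float = 0.8,
                         budget: int | None = None) -> TagSelection:
    """Greedy maximum-score tag selection.

    ``candidates`` must carry variant_id, freq and cost columns (costs ≥ 1);
    candidates already tagged at r² > ``r2_tag`` by ``existing_tags`` are
    removed before selection.  Ties are broken by lowest (chrom, pos).
    """
    if (candidates["cost"] < 1).any():
        raise ValueError("feature costs must be ≥ 1")
    if budget is not None and budget < 0:
        raise ValueError("budget must be ≥ 0")
    ids_all = variants["variant_id"].to_numpy()
    cand_ids = candidates["variant_id"].to_numpy()
    idx = variants.set_index("variant_id").index.get_indexer(cand_ids)
    if np.any(idx < 0):
        raise KeyError("candidate ids missing from the variant table")
    w = standardized_dosages(panel.dosages[:, idx], scale="sd")
    n = w.shape[0]
    r2 = (w.T @ w / n) ** 2

    freq = candidates["freq"].to_numpy(float)
    cost = candidates["cost"].to_numpy(float)
    chrom = variants["chrom"].to_numpy()[idx]
    pos = variants["pos_bp"].to_numpy()[idx]

    untagged = np.ones(len(cand_ids), bool)
    existing = [e for e in existing_tags if e in set(ids_all)]
    if existing:
        eidx = variants.set_index("variant_id").index.get_indexer(existing)
        we = standardized_dosages(panel.dosages[:, eidx], scale="sd")
        r2e = (we.T @ w / n) ** 2
        untagged &= ~(r2e > r2_tag).any(axis=0)

    selected: list[str] = []
    scores: list[float] = []
    used = 0
    order = np.lexsort((pos, chrom))  # tie-break rank
    rank = np.empty(len(cand_ids), int)
    rank[order] = np.arange(len(cand_ids))
    while untagged.any():
        gain = ((r2 > r2_tag) & untagged[None, :]).astype(float) @ freq
        score = np.where(untagged, gain, 0.0) / cost
        # candidates may tag untagged peers even if themselves tagged; the
        # selection pool is the untagged set, as selected SNPs must be informative
        score[~untagged] = -np.inf
        best = np.lexsort((rank, -score))[0]
        if budget is not None and used + cost[best] > budget:
            break
        selected.append(str(cand_ids[best]))
        scores.append(float(score[best]))
        used += int(cost[best])
        untagged &= ~(r2[best] > r2_tag)
        untagged[best] = False
    return TagSelection(selected_ids=selected, step_scores=scores,
                        features_used=used,
                        untagged_ids=list(cand_ids[untagged]))
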