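import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from nimkit.panel import GenotypePanel, standardized_dosages
from nimkit.annotate import (build_partition, compute_ld_scores, expand_nims,
                             hwe_exact_pvalue, qc_filter)


# ---------------------------------------------------------------- HWE exact test
def hwe_oracle(hom_major, het, hom_minor):
    """Independent enumeration oracle: conditional probability of every het
    count from the closed-form factorial expression, two-sided tail."""
    n = hom_major + het + hom_minor
    na = 2 * hom_minor + het
    na = min(na, 2 * n - na)
    probs = {}
    for h in range(na % 2, na + 1, 2):
        hm = (na - h) // 2
        hM = n - h - hm
        logp = (gammaln(n + 1) - gammaln(hM + 1) - gammaln(h + 1) - gammaln(hm + 1)
                + h * np.log(2) + gammaln(na + 1) + gammaln(2 * n - na + 1)
                - gammaln(2 * n + 1))
        probs[h] = np.exp(logp)
    p_obs = probs[het]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize("counts", [(5, 0, 5), (57, 14, 50), (0, 10, 0),
                                    (20, 20, 20), (100, 1, 0), (3, 4, 3)])
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert hwe_exact_pvalue(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-10)


def test_hwe_extreme_homozygote_excess_is_significant():
    # (AA, Aa, aa) = (50, 0, 50): maximal heterozygote deficit
    assert hwe_exact_pvalue(50, 0, 50) < 1e-7


# ---------------------------------------------------------------------- QC filter
def _mini_panel():
    rng = np.random.default_rng(0)
    n = 200
    cols = {
        "mono": np.zeros(n, int),
        "ok": rng.binomial(2, 0.3, n),
        "hwe_bad": np.concatenate([np.full(n // 2, 0), np.full(n // 2, 2)]),
        "low_call": np.where(rng.random(n) < 0.05, -1, rng.binomial(2, 0.3, n)),
        "in_region": rng.binomial(2, 0.4, n),
    }
    dos = np.column_stack(list(cols.values())).astype(np.int8)
    var = pd.DataFrame({
        "chrom": "1", "pos_bp": [100, 200, 300, 400, 5000],
        "variant_id": list(cols), "ancestry": "MH",
        "allele_freq": dos.clip(0).mean(0) / 2, "maf": 0.0,
    })
    var["maf"] = np.minimum(var["allele_freq"], 1 - var["allele_freq"])
    return GenotypePanel(dos), var


def test_qc_filter_rules():
    panel, var = _mini_panel()
    regions = pd.DataFrame({"chrom": ["1"], "start": [4990], "end": [5010]})
    mask = qc_filter(panel, var, exclude_regions=regions)
    got = dict(zip(var["variant_id"], mask))
    assert not got["mono"]          # MAF 0
    assert got["ok"]
    assert not got["hwe_bad"]       # exact p far below 1e-7
    assert not got["low_call"]      # call rate < 0.99
    assert not got["in_region"]     # inside exclusion interval


# ---------------------------------------------------------------------- LD scores
def test_ld_score_isolated_variant_is_one():
    rng = np.random.default_rng(1)
    dos = rng.binomial(2, 0.4, size=(100, 2)).astype(np.int8)
    var = pd.DataFrame({"chrom": "1", "pos_bp": [1, 50_000_000],
                        "variant_id": ["a", "b"], "ancestry": "MH",
                        "allele_freq": 0.4, "maf": 0.4})
    scores = compute_ld_scores(GenotypePanel(dos), var, window_bp=1_000_000)
    np.testing.assert_allclose(scores, 1.0, atol=1e-12)


def test_ld_score_duplicated_pair_is_two():
    rng = np.random.default_rng(2)
    col = rng.binomial(2, 0.4, 100).astype(np.int8)
    dos = np.column_stack([col, col])
    var = pd.DataFrame({"chrom": "1", "pos_bp": [1000, 2000],
                        "variant_id": ["a", "b"], "ancestry": "MH",
                        "allele_freq": 0.4, "maf": 0.4})
    scores = compute_ld_scores(GenotypePanel(dos), var, window_bp=10_000)
    np.testing.assert_allclose(scores, 2.0, atol=1e-12)


def test_ld_scores_match_bruteforce_all_pairs(small_panel):
    panel, var = small_panel
    keep = np.flatnonzero(var["maf"].to_numpy() > 0.01)[:50]
    sub = panel.subset_variants(keep)
    vs = var.iloc[keep].reset_index(drop=True)
    window = 500_000
    scores = compute_ld_scores(sub, vs, window_bp=window)
    w = standardized_dosages(sub.dosages, scale="sd")
    n = w.shape[0]
    pos = vs["pos_bp"].to_numpy()
    expected = np.zeros(len(keep))
    for i, j in itertools.product(range(len(keep)), repeat=2):
        if abs(pos[i] - pos[j]) <= window:
            expected[i] += ((w[:, i] @ w[:, j]) / n) ** 2
    np.testing.assert_allclose(scores, expected, rtol=1e-10)


def test_ld_score_zero_variance_errors():
    dos = np.zeros((50, 1), np.int8)
    var = pd.DataFrame({"chrom": "1", "pos_bp": [1], "variant_id": ["a"],
                        "ancestry": "MH", "allele_freq": 0.0, "maf": 0.0})
    with pytest.raises(ValueError, match="monomorphic"):
        compute_ld_scores(GenotypePanel(dos), var)


# -------------------------------------------------------------------- expand NIMs
def test_expand_nims_matches_bruteforce(small_panel):
    panel, var = small_panel
    nim_ids = var.loc[var["ancestry"] == "NIM", "variant_id"]
    confident = set(nim_ids.iloc[::7])
    got = expand_nims(confident, panel, var, r2_min=0.9, window_bp=100_000)
    assert confident <= got  # self-inclusion
    # brute force over all pairs
    w = standardized_dosages(panel.dosages, scale="sd")
    n = w.shape[0]
    pos = var["pos_bp"].to_numpy()
    ids = var["variant_id"].to_numpy()
    conf_idx = np.flatnonzero(var["variant_id"].isin(confident))
    expected = set(confident)
    for j in range(panel.n_variants):
        for i in conf_idx:
            if abs(pos[i] - pos[j]) <= 100_000 and \
                    ((w[:, i] @ w[:, j]) / n) ** 2 >= 0.9:
                expected.add(ids[j])
                break
    assert got == expected


def test_expand_nims_distance_rule():
    rng = np.random.default_rng(3)
    col = rng.binomial(2, 0.3, 200).astype(np.int8)
    dos = np.column_stack([col, col])  # r² = 1 but 300 kb apart
    var = pd.DataFrame({"chrom": "1", "pos_bp": [1000, 301_000],
                        "variant_id": ["a", "b"], "ancestry": ["NIM", "MH"],
                        "allele_freq": 0.3, "maf": 0.3})
    got = expand_nims({"a"}, GenotypePanel(dos), var, window_bp=200_000)
    assert got == {"a"}


# --------------------------------------------------------------------- partitions
def test_partition_ancestry_only_two_bins(toy_variants):
    part = build_partition(toy_variants, schemes=(), min_snps=1)
    assert part.labels == [("MH",), ("NIM",)]
    assert part.sizes.sum() == len(toy_variants)


def test_partition_equal_quintiles_before_intersection():
    rng = np.random.default_rng(4)
    var = pd.DataFrame({
        "chrom": "1", "pos_bp": np.arange(1, 101) * 10,
        "variant_id": [f"v{i}" for i in range(100)],
        "ancestry": "MH", "allele_freq": 0.2, "maf": rng.uniform(0.01, 0.5, 100),
    })
    part = build_partition(var, schemes=(("maf", 5),), min_snps=1)
    assert sorted(part.sizes) == [20] * 5


def test_partition_drop_rule_retires_variants(toy_variants):
    part = build_partition(toy_variants, schemes=(), min_snps=4)
    # 3 NIMs < 4 → NIM bin dropped entirely, its variants retired
    assert part.labels == [("MH",)]
    assert part.dropped == [(("NIM",), 3)]
    dropped_rows = np.flatnonzero(part.bin_of_variant < 0)
    assert set(toy_variants.iloc[dropped_rows]["ancestry"]) == {"NIM"}


def test_partition_quantiles_permutation_invariant(toy_variants):
    part1 = build_partition(toy_variants, schemes=(("maf", 2),), min_snps=1)
    perm = np.random.default_rng(0).permutation(len(toy_variants))
    shuffled = toy_variants.iloc[perm].reset_index(drop=True)
    part2 = build_partition(shuffled, schemes=(("maf", 2),), min_snps=1)
    lab1 = {toy_variants.iloc[i]["variant_id"]: part1.labels[part1.bin_of_variant[i]]
            for i in range(len(toy_variants))}
    lab2 = {shuffled.iloc[i]["variant_id"]: part2.labels[part2.bin_of_variant[i]]
            for i in range(len(shuffled))}
    assert lab1 == lab2


def test_partition_sizes_account_for_everything(small_panel):
    _, var = small_panel
    var = var.copy()
    var["qc_pass"] = var["maf"] > 0.01
    part = build_partition(var, schemes=(("maf", 3),), min_snps=10)
    retained = int((part.bin_of_variant >= 0).sum())
    dropped = sum(size for _, size in part.dropped)
    assert retained == part.sizes.sum()
    assert retained + dropped == int(var["qc_pass"].sum())


def test_partition_too_many_bins_errors(toy_variants):
    var = toy_variants.copy()
    var["b_value"] = 1.0
    with pytest.raises(ValueError, match="distinct"):
        build_partition(var, schemes=(("b_value", 3),), min_snps=1)
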