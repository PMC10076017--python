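import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nimkit.panel import GenotypePanel, standardized_dosages
from nimkit.assoc import (association_fdp, clump, compute_nim_pcs, gwas_linear,
                          ld_prune)


def _table(dos, pos=None, ancestry="MH"):
    m = dos.shape[1]
    pos = pos if pos is not None else np.arange(1, m + 1) * 1000
    p = dos.clip(0).mean(0) / 2
    anc = [ancestry] * m if isinstance(ancestry, str) else ancestry
    return pd.DataFrame({"chrom": "1", "pos_bp": pos,
                         "variant_id": [f"v{i}" for i in range(m)],
                         "ancestry": anc, "allele_freq": p,
                         "maf": np.minimum(p, 1 - p)})


# ------------------------------------------------------------------------- PCs
def test_rank_one_matrix_pc1_captures_everything():
    base = np.tile(np.array([0, 1, 2, 1, 0], np.int8), (1, 1)).T
    dos = np.repeat(base, 6, axis=1)
    var = _table(dos, ancestry="NIM")
    scores = compute_nim_pcs(GenotypePanel(dos), var, k=1)
    x = standardized_dosages(dos, scale="sd")
    explained = np.var(scores[:, 0]) / np.sum(np.var(x, axis=0) / x.shape[1]) \
        if False else None
    # rank 1: the single PC reconstructs the matrix direction exactly
    corr = np.corrcoef(scores[:, 0], x[:, 0])[0, 1]
    assert abs(corr) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="rank"):
        compute_nim_pcs(GenotypePanel(dos), var, k=2)


def test_pc_scores_match_dense_svd_oracle():
    rng = np.random.default_rng(0)
    dos = rng.binomial(2, 0.3, (200, 500)).astype(np.int8)
    var = _table(dos, ancestry="NIM")
    scores = compute_nim_pcs(GenotypePanel(dos), var, k=5)
    x = standardized_dosages(dos, scale="sd")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    oracle = u[:, :5] * s[:5]
    for j in range(5):
        sign = np.sign(oracle[0, j] * scores[0, j])
        np.testing.assert_allclose(scores[:, j], sign * oracle[:, j], atol=1e-6)


def test_k_zero_is_a_no_op(small_panel):
    panel, var = small_panel
    assert compute_nim_pcs(panel, var, k=0).shape == (panel.n_individuals, 0)


# ------------------------------------------------------------------------ GWAS
def test_single_variant_matches_closed_form_ols():
    dos = np.array([[0], [1], [2], [1], [0], [2]], np.int8)
    y = np.array([1.0, 2.0, 4.0, 2.5, 0.5, 3.0])
    var = _table(dos)
    res = gwas_linear(y, GenotypePanel(dos), var)
    x = (dos[:, 0] - dos.mean()) / dos.std()
    xc = x - x.mean()
    yc = y - y.mean()
    beta = (xc @ yc) / (xc @ xc)
    resid = yc - beta * xc
    se = np.sqrt((resid @ resid) / (6 - 2) / (xc @ xc))
    assert res.table["beta"][0] == pytest.approx(beta)
    assert res.table["se"][0] == pytest.approx(se)
    t = beta / se
    assert res.table["p"][0] == pytest.approx(2 * stats.t.sf(abs(t), 4))


def test_gwas_matches_statsmodels_joint_fit():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(1)
    n = 150
    dos = rng.binomial(2, 0.3, (n, 3)).astype(np.int8)
    covar = rng.standard_normal((n, 2))
    y = dos[:, 1] * 0.4 + covar @ [0.3, -0.2] + rng.standard_normal(n)
    res = gwas_linear(y, GenotypePanel(dos), _table(dos), covariates=covar)
    for j in range(3):
        x = (dos[:, j] - dos[:, j].mean()) / dos[:, j].std()
        design = sm.add_constant(np.column_stack([x, covar]))
        fit = sm.OLS(y, design).fit()
        assert res.table["beta"][j] == pytest.approx(fit.params[1])
        assert res.table["p"][j] == pytest.approx(fit.pvalues[1])


def test_null_p_values_uniform():
    rng = np.random.default_rng(2)
    dos = rng.binomial(2, 0.3, (200, 5000)).astype(np.int8)
    keep = dos.std(axis=0) > 0
    dos = dos[:, keep]
    y = rng.standard_normal(200)
    res = gwas_linear(y, GenotypePanel(dos), _table(dos))
    p = res.table.loc[res.table["tested"], "p"]
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_constant_variant_flagged_untested():
    dos = np.column_stack([np.full(50, 1, np.int8),
                           np.random.default_rng(3).binomial(2, 0.4, 50).astype(np.int8)])
    res = gwas_linear(np.random.default_rng(4).standard_normal(50),
                      GenotypePanel(dos), _table(dos))
    assert not res.table["tested"][0]
    assert np.isnan(res.table["p"][0])
    assert res.table["tested"][1]


def test_rank_deficient_covariates_error():
    dos = np.random.default_rng(5).binomial(2, 0.4, (30, 2)).astype(np.int8)
    covar = np.ones((30, 1))  # duplicates intercept
    with pytest.raises(ValueError, match="rank"):
        gwas_linear(np.zeros(30), GenotypePanel(dos), _table(dos), covariates=covar)


# -------------------------------------------------------------------- clumping
def _assoc_with(dos, p_values, pos):
    var = _table(dos, pos=pos)
    res = gwas_linear(np.random.default_rng(0).standard_normal(dos.shape[0]),
                      GenotypePanel(dos), var)
    res.table["p"] = p_values
    res.table["tested"] = True
    return res, var


def test_clump_singleton():
    dos = np.random.default_rng(6).binomial(2, 0.4, (100, 3)).astype(np.int8)
    res, _ = _assoc_with(dos, [1e-12, 0.5, 0.9], [1000, 2000, 3000])
    clumps = clump(res, GenotypePanel(dos), p_index=1e-10)
    assert len(clumps) == 1 and clumps.iloc[0]["index_id"] == "v0"
    assert clumps.iloc[0]["n_members"] == 1


def test_clump_joins_by_window_and_r2():
    rng = np.random.default_rng(7)
    a = rng.binomial(2, 0.4, 400)
    noisy = np.where(rng.random(400) < 0.1, rng.binomial(2, 0.4, 400), a)
    r2 = np.corrcoef(a, noisy)[0, 1] ** 2
    assert r2 > 0.5
    dos = np.column_stack([a, noisy]).astype(np.int8)
    res, _ = _assoc_with(dos, [1e-12, 1e-11], [1000, 101_000])
    clumps = clump(res, GenotypePanel(dos), p_index=1e-10)
    assert len(clumps) == 1
    assert clumps.iloc[0]["index_id"] == "v0"  # smaller p is the index

    # same pair 300 kb apart → two clumps regardless of r²
    res2, _ = _assoc_with(dos, [1e-12, 1e-11], [1000, 301_000])
    clumps2 = clump(res2, GenotypePanel(dos), p_index=1e-10)
    assert len(clumps2) == 2


def test_clump_membership_partitions_significant_set(small_panel):
    panel, var = small_panel
    rng = np.random.default_rng(8)
    nim_idx = np.flatnonzero(var["ancestry"] == "NIM")
    w = standardized_dosages(panel.dosages[:, nim_idx], scale="sd")
    y = w[:, 0] + 0.5 * rng.standard_normal(panel.n_individuals)
    res = gwas_linear(y, panel, var, test_idx=nim_idx)
    clumps = clump(res, panel, p_index=1e-4)
    sig = set(res.significant(1e-4)["variant_id"])
    members = [m for _, row in clumps.iterrows() for m in row["member_ids"].split(",")]
    assert sorted(members) == sorted(sig)  # each significant NIM in exactly one clump


# -------------------------------------------------------------------- pruning
def test_prune_removes_exact_duplicates():
    rng = np.random.default_rng(9)
    a = rng.binomial(2, 0.4, 200).astype(np.int8)
    b = rng.binomial(2, 0.4, 200).astype(np.int8)
    dos = np.column_stack([a, a, b])
    var = _table(dos, pos=[1000, 2000, 3000])
    kept = ld_prune(np.arange(3), GenotypePanel(dos), var)
    assert list(kept) == [0, 2]  # later duplicate dropped


def test_prune_no_op_below_threshold():
    rng = np.random.default_rng(10)
    dos = rng.binomial(2, 0.4, (300, 10)).astype(np.int8)
    var = _table(dos)
    kept = ld_prune(np.arange(10), GenotypePanel(dos), var)
    assert list(kept) == list(range(10))


def test_prune_certificate_on_blocky_panel(small_panel):
    panel, var = small_panel
    nim_idx = np.flatnonzero((var["ancestry"] == "NIM").to_numpy()
                             & (var["maf"] > 0.01).to_numpy())[:30]
    kept = ld_prune(nim_idx, panel, var, window_bp=100_000, r2=0.99)
    assert len(kept) < len(nim_idx)  # exact sub-block copies collapse
    w = standardized_dosages(panel.dosages[:, kept], scale="sd")
    n = w.shape[0]
    pos = var["pos_bp"].to_numpy()[kept]
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            if pos[j] - pos[i] <= 100_000:
                assert ((w[:, i] @ w[:, j]) / n) ** 2 <= 0.99 + 1e-12


# ------------------------------------------------------------------ FDP labels
def test_association_fdp_counting(toy_variants):
    clumps = pd.DataFrame({
        "index_id": ["1:100", "2:5000"], "chrom": ["1", "2"],
        "pos_bp": [100, 5000], "p": [1e-12, 1e-12], "n_members": [1, 1],
        "member_ids": ["1:100", "2:5000"]})
    # causal NIM at 1:200 (within 100 kb of clump 1); none near clump 2
    fdp, tp, fp = association_fdp(clumps, toy_variants,
                                  np.array(["1:200"]), np.array([1.0]))
    assert (tp, fp) == (1, 1) and fdp == pytest.approx(0.5)
    fdp_none, tp0, fp0 = association_fdp(clumps.iloc[:0], toy_variants,
                                         np.array(["1:200"]), np.array([1.0]))
    assert fdp_none is None and tp0 == fp0 == 0
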