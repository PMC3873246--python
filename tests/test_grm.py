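"""GRM constructions and LD adjustments."""

import numpy as np
import pytest

from herloc import grm, sim
from herloc.grm import (
    GRM,
    LDParams,
    effective_snp_fraction,
    grm_from_residuals,
    ld_prune,
    ld_residual,
    ld_shrink_grm,
    ld_shrink_weights,
    local_grm,
    standard_grm,
)

from conftest import make_geno


# --------------------------------------------------------------- standard GRM


def test_standard_grm_single_snp_hand_oracle():
    """One SNP [0,1,2]: z = (x-1)/sd with sd = sqrt(2/3), A = z z^T / 1."""
    geno = make_geno([[0], [1], [2]])
    a = standard_grm(geno).A
    z = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
    np.testing.assert_allclose(a, np.outer(z, z), atol=1e-12)
    np.testing.assert_allclose(np.diag(a), [1.5, 0.0, 1.5])


def test_standard_grm_duplicating_all_snps_is_invariant(free_panel):
    a1 = standard_grm(free_panel).A
    doubled = make_geno(
        np.concatenate([free_panel.dosage, free_panel.dosage], axis=1)
    )
    a2 = standard_grm(doubled).A
    np.testing.assert_allclose(a1, a2, atol=1e-10)


def test_standard_grm_independent_snps_off_diagonal_scale():
    n = 500
    g = sim.simulate_genotypes(
        sim.GenoSimConfig(n_samples=n, n_snps=10_000, ld_rho=0.0, seed=9)
    )
    fit = standard_grm(g)
    a, m = fit.A, fit.norm_constant
    off = a[np.triu_indices_from(a, k=1)]
    # column centering pins the off-diagonal mean at -trace/(n(n-1)) ~ -1/(n-1)
    assert off.mean() == pytest.approx(-1.0 / (n - 1), rel=0.05)
    assert off.std() == pytest.approx(1.0 / m**0.5, rel=0.15)


def test_standard_grm_diag_mean_near_one(ld_panel):
    assert np.diag(standard_grm(ld_panel).A).mean() == pytest.approx(1.0, abs=0.05)


def test_grm_invariant_to_allele_flip(free_panel):
    a1 = standard_grm(free_panel).A
    flipped = free_panel.dosage.copy()
    flipped[:, ::3] = 2 - flipped[:, ::3]
    a2 = standard_grm(make_geno(flipped)).A
    np.testing.assert_allclose(a1, a2, atol=1e-10)


# ------------------------------------------------------------------ LD prune


def _corr_pair(rng, n, r):
    """Two unit-variance columns with approximate correlation r."""
    x = rng.standard_normal(n)
    y = r * x + np.sqrt(1 - r**2) * rng.standard_normal(n)
    return x, y


def test_ld_prune_perfect_proxy_drops_one(free_panel):
    d = free_panel.dosage[:, :10].copy()
    d[:, 1] = d[:, 0]
    kept = ld_prune(make_geno(d), prune_r2=0.3)
    assert ("s0" in kept) != ("s1" in kept)


def test_ld_prune_no_high_ld_keeps_all(free_panel):
    kept = ld_prune(free_panel, prune_r2=0.3)
    assert len(kept) == free_panel.n_snps


def test_ld_prune_chain_removes_hub():
    """A-B r2=.5, B-C r2=.5, A-C r2=.1: B has degree 2 and is removed."""
    rng = np.random.default_rng(11)
    n = 4000
    b = rng.integers(0, 3, n)
    mask_a = rng.random(n) < 0.32
    mask_c = rng.random(n) < 0.32
    a = np.where(mask_a, rng.integers(0, 3, n), b)
    c = np.where(mask_c, rng.integers(0, 3, n), b)
    geno = make_geno(np.column_stack([a, b, c]))
    z, _ = grm.normalize_dosage(geno.dosage)
    r2 = (z.T @ z / n) ** 2
    assert r2[0, 1] > 0.3 and r2[1, 2] > 0.3 and r2[0, 2] < 0.3
    kept = ld_prune(geno, prune_r2=0.3)
    assert kept == ["s0", "s2"]


# --------------------------------------------------------------- LD residual


def test_ld_residual_perfect_copy_gives_zero_variance():
    rng = np.random.default_rng(0)
    d = rng.integers(0, 3, (100, 2)).astype(np.int8)
    d[:, 1] = d[:, 0]
    resid, var = ld_residual(make_geno(d))
    np.testing.assert_allclose(resid[:, 1], 0.0, atol=1e-10)
    assert var[1] == pytest.approx(0.0, abs=1e-12)
    assert var[0] == pytest.approx(1.0)


def test_ld_residual_first_snp_untouched(ld_panel):
    resid, _ = ld_residual(ld_panel)
    z, _ = grm.normalize_dosage(ld_panel.dosage)
    np.testing.assert_allclose(resid[:, 0], z[:, 0], atol=1e-12)


def test_ld_residual_independent_snps_keep_unit_variance(free_panel):
    _, var = ld_residual(free_panel)
    # residual variance 1 - R^2 of a regression on ~k noise predictors
    assert var.mean() > 0.8
    assert (var <= 1.0 + 1e-9).all()


def test_ld_residual_window_respects_bp_distance():
    """A perfect proxy outside the window must not be regressed out."""
    rng = np.random.default_rng(1)
    d = rng.integers(0, 3, (200, 2)).astype(np.int8)
    d[:, 1] = d[:, 0]
    geno = make_geno(d, pos=[1000, 500_000])
    _, var = ld_residual(geno, LDParams(residual_window_bp=100_000))
    assert var[1] == pytest.approx(1.0)


def test_ld_residual_reverse_sweep_runs(ld_panel):
    fwd, var_f = ld_residual(ld_panel)
    rev, var_r = ld_residual(ld_panel, reverse=True)
    # last SNP is first in the reverse sweep: untouched there
    z, _ = grm.normalize_dosage(ld_panel.dosage)
    np.testing.assert_allclose(rev[:, -1], z[:, -1], atol=1e-12)
    assert var_f.sum() == pytest.approx(var_r.sum(), rel=0.1)


def _sparse_independent_panel():
    # inter-SNP spacing 50 kb >> the 100 kb window holds ~2 predictors, so
    # incidental-regression noise is O(2/n) and the constructions must agree
    return sim.simulate_genotypes(
        sim.GenoSimConfig(n_samples=600, n_snps=800, ld_rho=0.0,
                          bp_spacing=50_000, seed=33)
    )


def test_grm_from_residuals_matches_standard_when_independent():
    panel = _sparse_independent_panel()
    resid, var = ld_residual(panel)
    a_res = grm_from_residuals(resid, var).A
    a_std = standard_grm(panel).A
    off = np.triu_indices_from(a_std, k=1)
    # same matrix up to the sampling effect of small incidental correlations
    assert np.corrcoef(a_res[off], a_std[off])[0, 1] > 0.95


def test_ld_residual_grm_ignores_duplicated_snps(ld_panel):
    """Appending exact copies changes the standard GRM's normalization but
    leaves the LD-residual GRM untouched (copies have zero residual)."""
    base = ld_panel.take_snps(np.arange(200))
    dup_dosage = np.concatenate([base.dosage, base.dosage[:, 100:]], axis=1)
    pos = base.snp_meta["pos_bp"].values
    dup_pos = np.concatenate([pos, pos[100:] + 1])
    order = np.argsort(dup_pos, kind="stable")
    dup = make_geno(dup_dosage[:, order], pos=dup_pos[order])

    r1, v1 = ld_residual(base)
    r2, v2 = ld_residual(dup)
    a1 = grm_from_residuals(r1, v1).A
    a2 = grm_from_residuals(r2, v2).A
    np.testing.assert_allclose(a1, a2, atol=1e-8)

    s1 = standard_grm(base).A
    s2 = standard_grm(dup).A
    assert np.abs(s1 - s2).max() > 0.01


def test_ld_residual_norm_constant_bounded_by_snp_count(ld_panel):
    _, var = ld_residual(ld_panel)
    assert var.sum() <= ld_panel.n_snps + 1e-9


def test_single_residual_outer_product():
    resid = np.zeros((4, 3))
    resid[:, 1] = [1.0, -1.0, 1.0, -1.0]
    a = grm_from_residuals(resid, resid.var(axis=0)).A
    np.testing.assert_allclose(a, np.outer(resid[:, 1], resid[:, 1]) / 1.0)


# ----------------------------------------------------------------- LD shrink


def test_ld_shrink_isolated_snp_weight_one(free_panel):
    w = ld_shrink_weights(free_panel)
    assert (w > 0.45).all()  # independent SNPs: almost no high-r2 neighbors
    assert w.max() == 1.0


def test_ld_shrink_proxy_pair_shares_unit_weight():
    rng = np.random.default_rng(2)
    d = rng.integers(0, 3, (150, 5)).astype(np.int8)
    d[:, 3] = d[:, 2]  # perfect proxy pair
    w = ld_shrink_weights(make_geno(d))
    assert w[2] == pytest.approx(0.5) and w[3] == pytest.approx(0.5)
    assert w[2] + w[3] == pytest.approx(1.0)


def test_ld_shrink_proxy_triple():
    rng = np.random.default_rng(3)
    d = rng.integers(0, 3, (150, 6)).astype(np.int8)
    d[:, 2] = d[:, 1]
    d[:, 3] = d[:, 1]
    w = ld_shrink_weights(make_geno(d))
    np.testing.assert_allclose(w[1:4], 1.0 / 3.0)
    assert w[1:4].sum() == pytest.approx(1.0)


def test_ld_shrink_grm_well_formed(ld_panel):
    g = ld_shrink_grm(ld_panel)
    assert g.method == "ld_shrink"
    assert g.norm_constant == pytest.approx(g.snp_variances.sum())
    np.testing.assert_allclose(g.A, g.A.T)


# ----------------------------------------------------------------- local GRM


def _whole_genome_locus(geno):
    from herloc.localh2 import LocusSet

    c = geno.snp_meta["chrom"].iloc[0]
    return LocusSet(intervals=[(c, 0, int(geno.snp_meta["pos_bp"].max()) + 1)])


def test_local_grm_whole_genome_equals_global(ld_panel):
    ls = _whole_genome_locus(ld_panel)
    for method, global_a in [
        ("standard", standard_grm(ld_panel).A),
        ("ld_residual", grm_from_residuals(*ld_residual(ld_panel)).A),
    ]:
        local = local_grm(ld_panel, ls, method=method)
        np.testing.assert_allclose(local.A, global_a, atol=1e-9)


def test_local_grm_locus_order_invariance(ld_panel):
    from herloc.localh2 import LocusSet

    pos = ld_panel.snp_meta["pos_bp"].values
    cut = int(pos[len(pos) // 2])
    iv = [(1, 0, cut), (1, cut, int(pos.max()) + 1)]
    a1 = local_grm(ld_panel, [np.flatnonzero(pos < cut),
                              np.flatnonzero(pos >= cut)], "ld_residual").A
    a2 = local_grm(ld_panel, [np.flatnonzero(pos >= cut),
                              np.flatnonzero(pos < cut)], "ld_residual").A
    np.testing.assert_allclose(a1, a2, atol=1e-10)
    ls = LocusSet(intervals=iv)
    a3 = local_grm(ld_panel, ls, "ld_residual").A
    np.testing.assert_allclose(a1, a3, atol=1e-10)


def test_local_grm_identical_loci_contribute_equally(free_panel):
    idx1 = np.arange(100)
    idx2 = np.arange(100)  # same internal structure: literally the same block
    g = local_grm(free_panel, [idx1, idx2], "standard")
    v = g.snp_variances
    assert v[:100].sum() == pytest.approx(v[100:].sum())


def test_local_grm_empty_locus_dropped(free_panel):
    with pytest.warns(UserWarning, match="zero SNPs"):
        g = local_grm(free_panel, [np.arange(50), np.array([], dtype=int)],
                      "standard")
    assert g.norm_constant == pytest.approx(50)


def test_effective_snp_fraction_bounds(free_panel):
    _, var = ld_residual(free_panel)
    assert effective_snp_fraction(var, var) == pytest.approx(1.0)
    assert effective_snp_fraction(var[:0], var) == 0.0
    frac = effective_snp_fraction(var[:20], var)
    assert 0 < frac < 0.02


def test_effective_snp_fraction_random_one_percent():
    g = sim.simulate_genotypes(
        sim.GenoSimConfig(n_samples=300, n_snps=3000, ld_rho=0.0, seed=21)
    )
    _, var = ld_residual(g)
    rng = np.random.default_rng(0)
    pick = rng.choice(3000, size=30, replace=False)
    assert effective_snp_fraction(var[pick], var) == pytest.approx(0.01, rel=0.3)


def test_ld_adjustments_converge_to_standard_without_ld():
    """Carrier permutation removes LD; all constructions then agree."""
    structured = sim.simulate_genotypes(
        sim.GenoSimConfig(n_samples=600, n_snps=800, ld_rho=0.9,
                          bp_spacing=50_000, seed=34)
    )
    free = sim.permute_carriers(structured, seed=4)
    a_std = standard_grm(free).A
    a_res = grm_from_residuals(*ld_residual(free)).A
    a_shr = ld_shrink_grm(free).A
    off = np.triu_indices_from(a_std, k=1)
    assert np.corrcoef(a_res[off], a_std[off])[0, 1] > 0.95
    assert np.corrcoef(a_shr[off], a_std[off])[0, 1] > 0.99
    # before permutation the LD-residual construction genuinely differs
    a_std_ld = standard_grm(structured).A
    a_res_ld = grm_from_residuals(*ld_residual(structured)).A
    assert np.corrcoef(a_res_ld[off], a_std_ld[off])[0, 1] < 0.999
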