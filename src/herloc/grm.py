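"""Genetic relatedness matrices with LD adjustment.

Four constructions are provided.  ``standard`` is the usual cross-product of
column-normalized genotypes divided by the SNP count.  ``pruned`` drops one
of every high-r2 pair before the standard construction.  ``ld_residual``
replaces each SNP by the least-squares residual of its regression on the
markers in the preceding window, so that redundant (correlated) markers stop
being double-counted; the resulting GRM must be normalized by the summed
empirical residual variances instead of the SNP count.  ``ld_shrink``
down-weights each SNP by one plus its count of high-r2 neighbors.

All constructions mean-impute missing dosages per SNP at normalization time
and are invariant to allele-orientation flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geno_io import MISSING, GenotypeMatrix


@dataclass
class LDParams:
    """Tuning knobs of the LD adjustments.

    residual_window_bp: span of the preceding-marker window used by the
        LD-residual regression (100 kbp for array-density panels; 500 kbp
        is the conventional choice for imputed-density panels).
    residual_r2_cap: one of any predictor pair above this r2 is dropped
        before the regression so the normal equations stay solvable.
    prune_r2: pruning threshold.
    shrink_neighbors: number of nearest markers examined by LD-shrink.
    shrink_r2_threshold: r2 above which a neighbor counts toward the shrink
        weight.
    """

    residual_window_bp: int = 100_000
    residual_r2_cap: float = 0.95
    prune_r2: float = 0.3
    prune_window_snps: int = 50
    prune_step_snps: int = 5
    shrink_neighbors: int = 150
    shrink_r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        for name in ("residual_r2_cap", "prune_r2", "shrink_r2_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.residual_window_bp <= 0:
            raise ValueError("residual_window_bp must be positive")


@dataclass
class GRM:
    """n x n relatedness matrix plus per-SNP post-adjustment variances.

    ``norm_constant`` is the sum of ``snp_variances`` and plays the role of
    the SNP count m in the standard construction; for LD-adjusted matrices
    it is the effective number of SNPs.
    """

    A: np.ndarray
    sample_ids: Sequence
    snp_variances: np.ndarray
    norm_constant: float
    method: str
    snp_ids: Sequence = field(default=None)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape[0] != self.A.shape[1]:
            raise ValueError("GRM must be square")
        if self.norm_constant <= 0:
            raise ValueError("norm_constant must be positive")

    @property
    def n_samples(self) -> int:
        return self.A.shape[0]


def normalize_dosage(dosage: np.ndarray, drop_monomorphic: bool = False):
    """Mean-impute missing calls, center and scale columns to unit variance.

    Returns ``(Z, kept)`` where ``kept`` indexes the columns with non-zero
    variance after imputation.  With ``drop_monomorphic=False`` zero-variance
    columns are kept as all-zero columns (and still reported absent from
    ``kept``).
    """
    x = np.asarray(dosage, dtype=float)
    x = np.where(x == MISSING, np.nan, x)
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mean, x)
    x = x - mean
    sd = x.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    z = np.zeros_like(x)
    z[:, kept] = x[:, kept] / sd[kept]
    if drop_monomorphic:
        z = z[:, kept]
    return z, kept


def standard_grm(geno: GenotypeMatrix) -> GRM:
    """A = Z Z^T / m over unit-variance normalized SNPs."""
    z, kept = normalize_dosage(geno.dosage, drop_monomorphic=True)
    if kept.size < geno.n_snps:
        warnings.warn(
            f"excluded {geno.n_snps - kept.size} zero-variance SNP(s) from GRM"
        )
    if kept.size == 0:
        raise ValueError("no polymorphic SNPs left to build a GRM")
    m = z.shape[1]
    a = z @ z.T / m
    return GRM(
        A=a,
        sample_ids=list(geno.sample_ids),
        snp_variances=np.ones(m),
        norm_constant=float(m),
        method="standard",
        snp_ids=list(geno.snp_meta["id"].iloc[kept]),
    )


def _pairwise_r2(z: np.ndarray) -> np.ndarray:
    """Squared Pearson correlations between unit-variance columns."""
    n = z.shape[0]
    r = z.T @ z / n
    return r**2


def ld_prune(geno: GenotypeMatrix, prune_r2: float = 0.3,
             window_snps: int = 50, step_snps: int = 5) -> list:
    """Greedy max-degree pruning within a sliding window; returns kept ids.

    In every window placement the marker participating in the most
    over-threshold pairs is removed first, ties broken toward the leftmost
    position, until no retained pair inside the window exceeds ``prune_r2``.
    """
    order = np.lexsort((geno.snp_meta["pos_bp"].values, geno.snp_meta["chrom"].values))
    z, kept_cols = normalize_dosage(geno.dosage, drop_monomorphic=False)
    retained = np.ones(geno.n_snps, dtype=bool)

    chroms = geno.snp_meta["chrom"].values
    for chrom in np.unique(chroms):
        idx = order[chroms[order] == chrom]
        for start in range(0, len(idx), step_snps):
            win = idx[start : start + window_snps]
            win = win[retained[win]]
            if len(win) < 2:
                if start + window_snps >= len(idx):
                    break
                continue
            r2 = _pairwise_r2(z[:, win])
            np.fill_diagonal(r2, 0.0)
            over = r2 > prune_r2
            while over.any():
                degree = over.sum(axis=1)
                worst = int(np.argmax(degree))  # argmax takes first = leftmost
                retained[win[worst]] = False
                over[worst, :] = False
                over[:, worst] = False
            if start + window_snps >= len(idx):
                break
    return list(geno.snp_meta["id"].values[retained])


def ld_residual(geno: GenotypeMatrix, params: LDParams | None = None,
                reverse: bool = False):
    """Regress each normalized SNP on its preceding-window markers.

    Returns ``(residual_matrix, snp_variances)`` with one column per SNP in
    the input order.  The predictor set for SNP j is every SNP of the same
    chromosome with position in ``(pos_j - residual_window_bp, pos_j)``;
    one of any predictor pair with r2 >= ``residual_r2_cap`` is dropped
    (leftmost kept) before the least-squares fit.  ``reverse=True`` runs the
    sweep right-to-left (an order-robustness check).
    """
    if params is None:
        params = LDParams()
    meta = geno.snp_meta
    if reverse:
        geno_idx = np.arange(geno.n_snps)[::-1]
        flipped = GenotypeMatrix(
            dosage=geno.dosage[:, geno_idx],
            snp_meta=meta.iloc[geno_idx].assign(
                pos_bp=lambda df: -df["pos_bp"].values
            ),
            sample_meta=geno.sample_meta,
        )
        resid, var = ld_residual(flipped, params, reverse=False)
        return resid[:, ::-1], var[::-1]

    order = np.lexsort((meta["pos_bp"].values, meta["chrom"].values))
    if not (order == np.arange(len(order))).all():
        raise ValueError("SNPs must be sorted by (chrom, pos) for LD-residual")

    z, _ = normalize_dosage(geno.dosage, drop_monomorphic=False)
    n, m = z.shape
    resid = np.empty_like(z)
    chroms = meta["chrom"].values
    pos = meta["pos_bp"].values

    for chrom in np.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        _residualize_chrom(z, cols, pos, params, resid)

    variances = resid.var(axis=0)
    return resid, variances


def _residualize_chrom(z, cols, pos, params: LDParams, out) -> None:
    """Left-to-right residual sweep over one chromosome's columns.

    Overlapping regression windows share their correlation entries, so the
    Gram matrix is computed once per block of consecutive SNPs (covering
    the maximal lookback) instead of once per SNP.
    """
    n = z.shape[0]
    mc = len(cols)
    cpos = pos[cols]
    window_start = np.searchsorted(
        cpos, cpos - params.residual_window_bp, side="right"
    )
    block = 256
    for a in range(0, mc, block):
        b = min(a + block, mc)
        lo = int(window_start[a:b].min())
        sub = cols[lo:b]
        c_gram = z[:, sub].T @ z[:, sub] / n
        for j in range(a, b):
            lj = window_start[j] - lo  # window start within sub
            jj = j - lo  # target within sub
            w = jj - lj
            if w <= 0:
                out[:, cols[j]] = z[:, cols[j]]
                continue
            cw = c_gram[lj:jj, lj:jj]
            cj = c_gram[lj:jj, jj]
            # drop near-duplicate predictors, keeping the leftmost of a pair
            keep: list[int] = []
            for c in range(w):
                if keep and np.max(cw[c, keep] ** 2) >= params.residual_r2_cap:
                    continue
                keep.append(c)
            ck, cjk = cw[np.ix_(keep, keep)], cj[keep]
            try:
                beta = np.linalg.solve(ck, cjk)
            except np.linalg.LinAlgError:
                warnings.warn(
                    f"singular window at column {cols[j]}; using ridge fallback"
                )
                lam = 1e-6 * len(keep)
                beta = np.linalg.solve(ck + lam * np.eye(len(keep)), cjk)
            win_cols = sub[lj:jj][keep]
            out[:, cols[j]] = z[:, cols[j]] - z[:, win_cols] @ beta


def grm_from_residuals(residual_matrix: np.ndarray,
                       snp_variances: np.ndarray,
                       sample_ids=None, snp_ids=None) -> GRM:
    """A = R R^T / sum_j var(r_j) — the LD-residual GRM."""
    total = float(np.sum(snp_variances))
    if total <= 0:
        raise ValueError("all residual variances are zero")
    a = residual_matrix @ residual_matrix.T / total
    n = residual_matrix.shape[0]
    return GRM(
        A=a,
        sample_ids=sample_ids if sample_ids is not None else list(range(n)),
        snp_variances=np.asarray(snp_variances, dtype=float),
        norm_constant=total,
        method="ld_residual",
        snp_ids=snp_ids,
    )


def ld_shrink_weights(geno: GenotypeMatrix, params: LDParams | None = None) -> np.ndarray:
    """w_j = 1 / (1 + #{neighbors with r2 > threshold}) over the K nearest.

    Neighbors are the ``shrink_neighbors`` markers nearest by SNP index on
    the same chromosome, split evenly around j (clipped at chromosome ends).
    """
    if params is None:
        params = LDParams()
    z, _ = normalize_dosage(geno.dosage, drop_monomorphic=False)
    n, m = z.shape
    half = params.shrink_neighbors // 2
    chroms = geno.snp_meta["chrom"].values
    w = np.empty(m)
    for j in range(m):
        lo, hi = max(0, j - half), min(m, j + half + 1)
        nbr = [k for k in range(lo, hi) if k != j and chroms[k] == chroms[j]]
        if not nbr:
            w[j] = 1.0
            continue
        r = z[:, nbr].T @ z[:, j] / n
        w[j] = 1.0 / (1.0 + int(np.sum(r**2 > params.shrink_r2_threshold)))
    return w


def ld_shrink_grm(geno: GenotypeMatrix, params: LDParams | None = None) -> GRM:
    """GRM of sqrt(w)-reweighted normalized genotypes, normalized by sum w."""
    if params is None:
        params = LDParams()
    w = ld_shrink_weights(geno, params)
    z, _ = normalize_dosage(geno.dosage, drop_monomorphic=False)
    zw = z * np.sqrt(w)
    a = zw @ zw.T / w.sum()
    return GRM(
        A=a,
        sample_ids=list(geno.sample_ids),
        snp_variances=w.copy(),
        norm_constant=float(w.sum()),
        method="ld_shrink",
        snp_ids=list(geno.snp_meta["id"]),
    )


def _adjusted_block(geno: GenotypeMatrix, method: str, params: LDParams):
    """Adjusted (column-transformed) genotype block and its SNP variances."""
    if method == "standard":
        z, kept = normalize_dosage(geno.dosage, drop_monomorphic=True)
        return z, np.ones(z.shape[1])
    if method == "pruned":
        kept_ids = ld_prune(geno, params.prune_r2, params.prune_window_snps,
                            params.prune_step_snps)
        idx = np.flatnonzero(geno.snp_meta["id"].isin(kept_ids).values)
        z, _ = normalize_dosage(geno.take_snps(idx).dosage, drop_monomorphic=True)
        return z, np.ones(z.shape[1])
    if method == "ld_residual":
        resid, var = ld_residual(geno, params)
        return resid, var
    if method == "ld_shrink":
        w = ld_shrink_weights(geno, params)
        z, _ = normalize_dosage(geno.dosage, drop_monomorphic=False)
        return z * np.sqrt(w), w
    raise ValueError(f"unknown GRM method: {method}")


def local_grm(geno: GenotypeMatrix, locus_set, method: str = "standard",
              params: LDParams | None = None) -> GRM:
    """Per-locus adjusted GRM: each locus is adjusted independently
    (regression windows never cross locus boundaries), blocks concatenated,
    and the combined matrix normalized by the summed post-adjustment
    variances across all loci.

    ``locus_set`` is anything with ``member_snp_indices(geno)`` (a
    ``localh2.LocusSet``) or a plain list of column-index arrays.
    """
    if params is None:
        params = LDParams()
    if hasattr(locus_set, "member_snp_indices"):
        blocks_idx = locus_set.member_snp_indices(geno)
    else:
        blocks_idx = [np.asarray(b) for b in locus_set]

    blocks, variances = [], []
    for k, idx in enumerate(blocks_idx):
        if len(idx) == 0:
            warnings.warn(f"locus {k} contains zero SNPs; dropped")
            continue
        sub = geno.take_snps(idx)
        b, v = _adjusted_block(sub, method, params)
        blocks.append(b)
        variances.append(v)
    if not blocks:
        raise ValueError("no locus contains any SNPs")
    big = np.concatenate(blocks, axis=1)
    var = np.concatenate(variances)
    total = float(var.sum())
    if total <= 0:
        raise ValueError("all adjusted SNP variances are zero across loci")
    a = big @ big.T / total
    return GRM(
        A=a,
        sample_ids=list(geno.sample_ids),
        snp_variances=var,
        norm_constant=total,
        method=method,
    )


def effective_snp_fraction(snp_variances_local, snp_variances_global) -> float:
    """Share of genome-wide post-adjustment SNP variance inside the loci."""
    num = float(np.sum(snp_variances_local))
    den = float(np.sum(snp_variances_global))
    if den <= 0:
        raise ValueError("genome-wide SNP variance total must be positive")
    return num / den
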