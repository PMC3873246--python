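"""Local heritability at known GWAS loci.

Pipeline: merge windows around catalog SNPs into a locus set (``define_loci``),
measure the variance explained by the index SNPs alone (``h2_gwas``) and by a
stepwise conditional model (``h2_joint``), estimate the locus set's
variance-component heritability (``h2_local``), compare it with the share the
loci would explain by chance (``local_expectation``), and attach analytic and
empirical significance (``ztest_increase`` in :mod:`herloc.reml`,
``empirical_null`` here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import grm as grm_mod
from . import reml as reml_mod
from .geno_io import GenotypeMatrix

MHC_REGION = (6, 26_000_000, 34_000_000)


@dataclass
class LocusSet:
    """Disjoint half-open genomic intervals with SNP membership.

    Three genome-fraction metrics quantify the share of the genome the loci
    occupy: physical base pairs (``rho_physical``), SNP count (``rho_snp``)
    and post-LD-residual SNP variance (``rho_ldvar``, filled by
    :func:`attach_rho_ldvar`).
    """

    intervals: list  # [(chrom, start_bp, end_bp)] half-open, disjoint, sorted
    index_snp_ids: list = field(default_factory=list)
    rho_physical: float | None = None
    rho_snp: float | None = None
    rho_ldvar: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            (int(c), int(s), int(e)) for c, s, e in self.intervals
        )
        prev = None
        for c, s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty interval {(c, s, e)}")
            if prev and prev[0] == c and s < prev[2]:
                raise ValueError("intervals overlap after merging")
            prev = (c, s, e)

    @property
    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def member_snp_indices(self, geno: GenotypeMatrix) -> list:
        """Per-interval arrays of genotype column indices inside it."""
        chrom = geno.snp_meta["chrom"].values
        pos = geno.snp_meta["pos_bp"].values
        out = []
        for c, s, e in self.intervals:
            out.append(np.flatnonzero((chrom == c) & (pos >= s) & (pos < e)))
        return out

    def member_mask(self, geno: GenotypeMatrix) -> np.ndarray:
        mask = np.zeros(geno.n_snps, dtype=bool)
        for idx in self.member_snp_indices(geno):
            mask[idx] = True
        return mask

    def overlaps(self, chrom: int, start: int, end: int) -> bool:
        return any(c == chrom and s < end and start < e for c, s, e in self.intervals)

    def to_bed(self, path) -> None:
        pd.DataFrame(
            [(f"chr{c}", s, e) for c, s, e in self.intervals]
        ).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class LocalResult:
    """Collected outputs of the locus pipeline for one trait."""

    h2_gwas: float
    h2_joint: float
    h2_local: float
    se_local: float
    expected_local: float
    gain: float
    z: float
    p_analytic: float
    p_empirical: float | None = None
    diagnostics: dict = field(default_factory=dict)


def _merge(intervals):
    intervals = sorted(intervals)
    merged = []
    for c, s, e in intervals:
        if merged and merged[-1][0] == c and s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([c, s, e])
    return [tuple(t) for t in merged]


def _subtract(intervals, exclusions):
    out = []
    for c, s, e in intervals:
        pieces = [(s, e)]
        for xc, xs, xe in exclusions:
            if xc != c:
                continue
            nxt = []
            for ps, pe in pieces:
                if xe <= ps or pe <= xs:
                    nxt.append((ps, pe))
                    continue
                if ps < xs:
                    nxt.append((ps, xs))
                if xe < pe:
                    nxt.append((xe, pe))
            pieces = nxt
        out.extend((c, ps, pe) for ps, pe in pieces)
    return sorted(out)


def genome_span_bp(geno: GenotypeMatrix) -> int:
    """Total physical span of the panel (per-chromosome min..max position)."""
    g = geno.snp_meta.groupby("chrom")["pos_bp"]
    return int((g.max() - g.min() + 1).sum())


def define_loci(
    catalog: pd.DataFrame,
    geno: GenotypeMatrix,
    window_bp: int = 1_000_000,
    exclude=(MHC_REGION,),
) -> LocusSet:
    """Build the locus set for a catalog of associated SNPs.

    ``catalog`` needs columns ``snp_id`` plus optionally ``chrom``/``pos``
    used only when the id is absent from the panel; unresolvable entries are
    dropped with a warning.  A ``window_bp`` interval is centered on each
    index SNP, overlapping intervals merged, exclusion regions (MHC by
    default) subtracted.  For merged multi-hit regions only the leading
    (first-listed) SNP enters the index list used by ``h2_gwas``.
    """
    meta = geno.snp_meta.set_index("id")
    records = []
    for _, row in catalog.iterrows():
        sid = str(row["snp_id"])
        if sid in meta.index:
            records.append((sid, int(meta.loc[sid, "chrom"]), int(meta.loc[sid, "pos_bp"])))
        elif "chrom" in row and "pos" in row and not pd.isna(row.get("pos")):
            records.append((sid, int(row["chrom"]), int(row["pos"])))
        else:
            warnings.warn(f"catalog SNP {sid} not resolvable; dropped")
    if not records:
        raise ValueError("no catalog SNP could be resolved against the panel")

    half = window_bp // 2
    raw = [(c, max(0, p - half), p - half + window_bp) for _, c, p in records]
    merged = _merge(raw)
    final = _subtract(merged, exclude)
    if not final:
        raise ValueError("all loci fell inside exclusion regions")

    # leading SNP per final interval = first catalog entry inside it
    index_ids = []
    for c, s, e in final:
        for sid, rc, rp in records:
            if rc == c and s <= rp < e:
                index_ids.append(sid)
                break

    ls = LocusSet(
        intervals=final,
        index_snp_ids=index_ids,
        provenance={"window_bp": window_bp, "n_catalog": len(records)},
    )
    span = genome_span_bp(geno)
    covered = 0
    chrom = geno.snp_meta["chrom"].values
    pos = geno.snp_meta["pos_bp"].values
    for c, s, e in final:
        on = chrom == c
        if not on.any():
            continue
        lo, hi = pos[on].min(), pos[on].max()
        covered += max(0, min(e, hi + 1) - max(s, lo))
    ls.rho_physical = covered / span
    ls.rho_snp = ls.member_mask(geno).mean()
    return ls


def attach_rho_ldvar(locus_set: LocusSet, geno: GenotypeMatrix,
                     snp_variances_global: np.ndarray) -> LocusSet:
    """Fill ``rho_ldvar`` from genome-wide LD-residual SNP variances."""
    mask = locus_set.member_mask(geno)
    locus_set.rho_ldvar = grm_mod.effective_snp_fraction(
        snp_variances_global[mask], snp_variances_global
    )
    return locus_set


def _r2_of_model(y, design) -> float:
    """R^2 of an OLS fit (design includes whatever intercept it includes)."""
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / tss


def h2_gwas(geno: GenotypeMatrix, y, covariates, index_snp_ids):
    """Shrunk variance explained by the index SNPs jointly.

    R^2 beyond the covariates-only model, minus 1/N per fitted SNP (the
    winner's-curse-agnostic shrinkage), floored at zero.  Returns
    (estimate, number of index SNPs used).
    """
    y = np.asarray(y, dtype=float)
    x_cov = np.asarray(covariates, dtype=float)
    ids = [s for s in index_snp_ids if (geno.snp_meta["id"] == s).any()]
    if not ids:
        return 0.0, 0
    cols = [int(np.flatnonzero(geno.snp_meta["id"].values == s)[0]) for s in ids]
    z, _ = grm_mod.normalize_dosage(geno.dosage[:, cols])
    r2_cov = _r2_of_model(y, x_cov)
    r2_full = _r2_of_model(y, np.column_stack([x_cov, z]))
    est = (r2_full - r2_cov) - len(cols) / len(y)
    return max(est, 0.0), len(cols)


def _coef_pvalue(y, design, col) -> float:
    """Two-sided t-test p-value for one coefficient of an OLS fit."""
    n, p = design.shape
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p:
        return np.nan  # collinear: caller skips
    resid = y - design @ beta
    dof = n - p
    s2 = float((resid**2).sum()) / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(s2 * xtx_inv[col, col])
    if se == 0:
        return np.nan
    t = beta[col] / se
    return 2.0 * float(stats.t.sf(abs(t), dof))


def h2_joint(geno: GenotypeMatrix, y, covariates, index_snp_ids,
             locus_set: LocusSet, alpha: float = 0.05):
    """Stepwise conditional model of index plus significant locus SNPs.

    Candidates are the locus member SNPs (index SNPs excluded), pre-screened
    univariately at alpha/m; the conditionally most associated candidate is
    added while its conditional p-value stays below alpha/m.  The final R^2
    is shrunk by 1/N per SNP predictor.  Returns (estimate, model snp ids).
    """
    y = np.asarray(y, dtype=float)
    x_cov = np.asarray(covariates, dtype=float)
    n = len(y)

    mask = locus_set.member_mask(geno)
    all_ids = geno.snp_meta["id"].values
    index_set = set(index_snp_ids)
    cand_cols = [j for j in np.flatnonzero(mask) if all_ids[j] not in index_set]
    m = len(cand_cols)
    index_cols = [int(np.flatnonzero(all_ids == s)[0]) for s in index_snp_ids
                  if (all_ids == s).any()]

    z_all, _ = grm_mod.normalize_dosage(geno.dosage)
    forced = z_all[:, index_cols] if index_cols else np.empty((n, 0))
    thresh = alpha / m if m else 0.0

    # univariate Bonferroni screen (covariates adjusted)
    screened = []
    for j in cand_cols:
        design = np.column_stack([x_cov, z_all[:, j]])
        p = _coef_pvalue(y, design, design.shape[1] - 1)
        if np.isfinite(p) and p < thresh:
            screened.append(j)

    chosen: list[int] = []
    while screened:
        best_j, best_p = None, np.inf
        base = np.column_stack([x_cov, forced] + [z_all[:, [c]] for c in chosen])
        for j in screened:
            design = np.column_stack([base, z_all[:, j]])
            p = _coef_pvalue(y, design, design.shape[1] - 1)
            if not np.isfinite(p):
                continue  # collinear with current model
            if p < best_p:
                best_j, best_p = j, p
        if best_j is None or best_p >= thresh:
            break
        chosen.append(best_j)
        screened.remove(best_j)

    model_cols = index_cols + chosen
    design = np.column_stack([x_cov] + [z_all[:, [c]] for c in model_cols]) \
        if model_cols else x_cov
    r2_cov = _r2_of_model(y, x_cov)
    r2_full = _r2_of_model(y, design)
    est = (r2_full - r2_cov) - len(model_cols) / n
    return max(est, 0.0), [all_ids[c] for c in model_cols]


def h2_local(geno: GenotypeMatrix, y, covariates, locus_set: LocusSet,
             adjustment: str = "ld_residual",
             params: grm_mod.LDParams | None = None) -> reml_mod.VCFit:
    """Single-component AI-REML fit of the per-locus adjusted GRM."""
    local = grm_mod.local_grm(geno, locus_set, method=adjustment, params=params)
    return reml_mod.ai_reml(np.asarray(y, float), covariates, [local])


def local_expectation(h2_global: float, h2_gwas_est: float,
                      locus_set: LocusSet, metric: str = "physical",
                      genic_adjust: dict | None = None,
                      composition: str = "additive") -> float:
    """Heritability the loci would capture under a uniform (or genic-aware)
    genome: the known index-SNP contribution plus the chance share of the
    remaining genome-wide heritability landing inside the loci.

    ``metric`` selects rho: 'physical' (bp), 'snp' (SNP count) or 'ldvar'
    (LD-residual variance).  ``genic_adjust`` replaces the uniform chance
    term rho*h2_global with a genic/non-genic weighted average; it needs
    keys rho_genic, rho_nongenic (fractions of genome covered-and-genic /
    covered-and-non-genic, summing to rho), h2_genic, h2_nongenic (joint
    two-component genome-wide estimates) and genic_genome_fraction.
    ``composition='rho-only'`` drops the index-SNP term (the cross-trait
    form, where h2_gwas is zero by definition).
    """
    rho = {
        "physical": locus_set.rho_physical,
        "snp": locus_set.rho_snp,
        "ldvar": locus_set.rho_ldvar,
    }[metric]
    if rho is None:
        raise ValueError(f"rho metric '{metric}' has not been computed")

    if genic_adjust is None:
        chance = rho * h2_global
    else:
        ga = genic_adjust
        pi = ga["genic_genome_fraction"]
        chance = (
            ga["rho_genic"] * ga["h2_genic"] / pi
            + ga["rho_nongenic"] * ga["h2_nongenic"] / (1.0 - pi)
        )
    if composition == "rho-only":
        return chance
    if h2_global <= 0:
        return h2_gwas_est
    return h2_gwas_est + (1.0 - h2_gwas_est / h2_global) * chance


def sample_random_loci(geno: GenotypeMatrix, n_loci: int, locus_span_bp: int,
                       rng: np.random.Generator,
                       exclusions: LocusSet | None = None) -> LocusSet:
    """Union of ``n_loci`` random windows (drawn with replacement, merged),
    avoiding ``exclusions``."""
    chroms = geno.snp_meta["chrom"].values
    pos = geno.snp_meta["pos_bp"].values
    uniq = np.unique(chroms)
    spans = {c: (pos[chroms == c].min(), pos[chroms == c].max()) for c in uniq}
    weights = np.array([max(spans[c][1] - spans[c][0], 1) for c in uniq], float)
    weights /= weights.sum()
    raw = []
    attempts = 0
    while len(raw) < n_loci:
        attempts += 1
        if attempts > 100 * n_loci:
            raise RuntimeError("could not place random loci outside exclusions")
        c = int(rng.choice(uniq, p=weights))
        lo, hi = spans[c]
        if hi - lo <= locus_span_bp:
            start = lo
        else:
            start = int(rng.integers(lo, hi - locus_span_bp))
        if exclusions is not None and exclusions.overlaps(c, start, start + locus_span_bp):
            continue
        raw.append((c, start, start + locus_span_bp))
    ls = LocusSet(intervals=_merge(raw))
    ls.rho_physical = ls.total_bp / genome_span_bp(geno)
    ls.rho_snp = ls.member_mask(geno).mean()
    return ls


def empirical_null(geno: GenotypeMatrix, y, covariates, h2_global: float,
                   n_loci: int, locus_span_bp: int, observed_excess: float,
                   n_draws: int = 1000, exclusions: LocusSet | None = None,
                   adjustment: str = "standard", metric: str = "physical",
                   seed: int = 0):
    """Empirical p-value for an observed local-heritability excess.

    Each draw samples ``n_loci`` random windows, fits the local
    variance component and measures its excess over the draw's own chance
    expectation (conservatively taking the drawn loci's h2_gwas as zero).
    p = (#draws with excess >= observed + 1) / (n_draws + 1).
    """
    if n_draws < 100:
        warnings.warn(
            f"only {n_draws} draws: empirical p resolution floor is "
            f"{1.0 / (n_draws + 1):.3g}"
        )
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    excesses = np.empty(n_draws)
    for r in range(n_draws):
        ls = sample_random_loci(geno, n_loci, locus_span_bp, rng, exclusions)
        fit = h2_local(geno, y, covariates, ls, adjustment=adjustment)
        expected = local_expectation(h2_global, 0.0, ls, metric=metric)
        excesses[r] = fit.h2_total - expected
    p = (float((excesses >= observed_excess).sum()) + 1.0) / (n_draws + 1.0)
    return p, excesses


def power_curve(sim_generator, n_reps: int = 100, alpha: float = 0.05) -> float:
    """Fraction of replicates whose local estimate significantly exceeds its
    expectation by one-sided z-test.

    ``sim_generator(rep)`` must return ``(h2_est, se_est, expected)`` for
    replicate ``rep``.
    """
    hits = 0
    for rep in range(n_reps):
        h2_est, se_est, expected = sim_generator(rep)
        _, _, p = reml_mod.ztest_increase(h2_est, se_est, expected)
        if p < alpha:
            hits += 1
    return hits / n_reps
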