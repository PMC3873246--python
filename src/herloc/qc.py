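"""Cohort quality control: SNP filters, relatedness pruning, PCA outlier
removal and PCA-based case-control matching.

The SNP filter chain applies, in order: minor-allele frequency, call-rate,
Hardy-Weinberg equilibrium (an exact test, evaluated in controls only when
case-control status is supplied) and case/control differential missingness.
Each dropped SNP is reported with the first rule it failed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .geno_io import MISSING, GenotypeMatrix
from .grm import normalize_dosage, standard_grm


@dataclass
class QCThresholds:
    """Defaults follow conservative array-cohort practice: MAF >= 0.01,
    missingness <= 0.002, HWE p >= 0.01, differential missingness p >= 0.05,
    six-SD outliers on the top 20 eigenvectors over five removal rounds."""

    maf_min: float = 0.01
    miss_max: float = 0.002
    hwe_p_min: float = 0.01
    diffmiss_p_min: float = 0.05
    relatedness_cov_max: float = 0.05
    pca_sd: float = 6.0
    pca_rounds: int = 5
    n_evec: int = 20

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "diffmiss_p_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")
        if self.pca_rounds < 1 or self.n_evec < 1:
            raise ValueError("pca_rounds and n_evec must be >= 1")


def hwe_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact Hardy-Weinberg equilibrium test (no mid-p correction).

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all configurations no
    more probable than the observed one.
    """
    counts = (int(n_aa_hom), int(n_het), int(n_bb_hom))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("total genotype count is zero")
    n_a = 2 * counts[0] + counts[1]
    n_b = 2 * counts[2] + counts[1]
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    logp = (
        hets * np.log(2.0)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_b - hets) / 2 + 1)
    )
    logp -= logsumexp(logp)
    obs = np.flatnonzero(hets == counts[1])[0]
    p = float(np.exp(logp)[np.exp(logp) <= np.exp(logp[obs]) * (1 + 1e-12)].sum())
    return min(p, 1.0)


def diff_missingness_test(miss_case: int, n_case: int,
                          miss_ctrl: int, n_ctrl: int) -> float:
    """Two-sided test of (missing vs typed) x (case vs control).

    Fisher's exact test when any expected cell count is below 5, otherwise
    the chi-square test without continuity correction.
    """
    table = np.array(
        [
            [miss_case, n_case - miss_case],
            [miss_ctrl, n_ctrl - miss_ctrl],
        ],
        dtype=float,
    )
    if table.min() < 0:
        raise ValueError("negative cell count")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0  # degenerate margin carries no information
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if expected.min() < 5:
        return float(stats.fisher_exact(table.astype(int))[1])
    return float(stats.chi2_contingency(table, correction=False)[1])


def filter_snps(geno: GenotypeMatrix, pheno_status=None,
                thresholds: QCThresholds | None = None):
    """Apply the SNP filter chain; returns (filtered panel, drop report).

    ``pheno_status`` is 0/1 per sample; when given, HWE is evaluated in
    controls only and the differential-missingness test is run.  The drop
    report lists each removed SNP with the first failing rule.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    maf = geno.maf()
    miss = geno.missing_rate()
    d = geno.dosage
    rows = []
    keep = np.ones(geno.n_snps, dtype=bool)

    status = None
    if pheno_status is not None:
        status = np.asarray(pheno_status).astype(int)
        ctrl_mask = status == 0
        case_mask = status == 1
    for j in range(geno.n_snps):
        sid = geno.snp_meta["id"].iloc[j]
        if not maf[j] >= thresholds.maf_min:  # NaN maf (all missing) also drops
            rows.append((sid, "maf", maf[j], np.nan))
            keep[j] = False
            continue
        if miss[j] > thresholds.miss_max:
            rows.append((sid, "missingness", miss[j], np.nan))
            keep[j] = False
            continue
        col = d[:, j]
        hwe_col = col[ctrl_mask] if status is not None else col
        obs = hwe_col[hwe_col != MISSING]
        p_hwe = hwe_test(int((obs == 0).sum()), int((obs == 1).sum()),
                         int((obs == 2).sum())) if obs.size else 1.0
        if p_hwe < thresholds.hwe_p_min:
            rows.append((sid, "hwe", np.nan, p_hwe))
            keep[j] = False
            continue
        if status is not None:
            p_dm = diff_missingness_test(
                int((col[case_mask] == MISSING).sum()), int(case_mask.sum()),
                int((col[ctrl_mask] == MISSING).sum()), int(ctrl_mask.sum()),
            )
            if p_dm < thresholds.diffmiss_p_min:
                rows.append((sid, "diff_missingness", np.nan, p_dm))
                keep[j] = False
                continue

    report = pd.DataFrame(rows, columns=["snp_id", "rule", "statistic", "p"])
    if not keep.any():
        raise ValueError("QC removed every SNP in the panel")
    return geno.take_snps(np.flatnonzero(keep)), report


def prune_related(geno: GenotypeMatrix, cov_max: float = 0.05) -> list:
    """Drop samples until no pair has GRM covariance above ``cov_max``.

    Greedy: at each step the sample participating in the most offending
    pairs is removed, ties broken by input order.  Returns retained iids.
    """
    a = standard_grm(geno).A
    n = a.shape[0]
    over = a > cov_max
    np.fill_diagonal(over, False)
    active = np.ones(n, dtype=bool)
    while True:
        degree = (over & active[None, :] & active[:, None]).sum(axis=1)
        degree[~active] = 0
        if degree.max() == 0:
            break
        active[int(np.argmax(degree))] = False
    return list(geno.sample_ids[active])


def pca_eigenvectors(geno: GenotypeMatrix, n_evec: int) -> np.ndarray:
    """Top sample-space eigenvectors of the normalized genotype matrix."""
    z, _ = normalize_dosage(geno.dosage, drop_monomorphic=True)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, :n_evec]


def pca_outlier_loop(geno: GenotypeMatrix, n_evec: int = 20,
                     sd_limit: float = 6.0, rounds: int = 5):
    """Iterative eigenvector outlier removal.

    Each round recomputes the top ``n_evec`` eigenvectors of the retained
    samples and removes anyone further than ``sd_limit`` standard deviations
    from the mean along any axis; the loop stops early once a round removes
    no one.  Returns (eigenvectors of the final panel, retained iids).
    """
    if n_evec >= geno.n_samples:
        raise ValueError("n_evec must be smaller than the sample count")
    retained = np.arange(geno.n_samples)
    sub = geno
    evecs = pca_eigenvectors(sub, n_evec)
    for _ in range(rounds):
        sd = evecs.std(axis=0)
        sd[sd == 0] = 1.0
        dev = np.abs(evecs - evecs.mean(axis=0)) / sd
        bad = (dev > sd_limit).any(axis=1)
        if not bad.any():
            break
        retained = retained[~bad]
        if n_evec >= retained.size:
            raise ValueError("outlier removal left fewer samples than n_evec")
        sub = geno.take_samples(retained)
        evecs = pca_eigenvectors(sub, n_evec)
    return evecs, list(geno.sample_ids.iloc[retained])


def pc_match(evecs: np.ndarray, pheno_status, sample_ids=None) -> list:
    """Greedy phenotype-weighted pair matching of cases to controls.

    Each eigenvector is scaled by its squared correlation with the
    phenotype; controls are visited in input order and paired with the
    nearest unused case in the reweighted Euclidean metric (ties to the
    earlier case).  Returns (case_id, control_id) pairs; pairing stops when
    either pool is exhausted.
    """
    evecs = np.asarray(evecs, dtype=float)
    status = np.asarray(pheno_status).astype(int)
    if sample_ids is None:
        sample_ids = np.arange(len(status))
    sample_ids = np.asarray(sample_ids)
    cases = np.flatnonzero(status == 1)
    controls = np.flatnonzero(status == 0)
    if len(cases) == 0 or len(controls) == 0:
        import warnings

        warnings.warn("no cases or no controls; empty pairing")
        return []

    weights = np.empty(evecs.shape[1])
    for k in range(evecs.shape[1]):
        col = evecs[:, k]
        if col.std() == 0 or status.std() == 0:
            weights[k] = 0.0
        else:
            weights[k] = np.corrcoef(col, status)[0, 1] ** 2
    scaled = evecs * np.sqrt(weights)

    used = np.zeros(len(cases), dtype=bool)
    pairs = []
    for ctrl in controls:
        if used.all():
            break
        d2 = ((scaled[cases] - scaled[ctrl]) ** 2).sum(axis=1)
        d2[used] = np.inf
        best = int(np.argmin(d2))  # argmin takes the first minimum: input order
        used[best] = True
        pairs.append((sample_ids[cases[best]], sample_ids[ctrl]))
    return pairs
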