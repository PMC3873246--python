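"""Synthetic genotypes and simulated polygenic traits.

The genotype generator is a stand-in for controlled-access cohort data:
haplotypes follow a first-order Markov (latent Gaussian AR(1)) process along
each chromosome, thresholded so every SNP hits its drawn allele frequency,
and two haplotypes are summed per sample.  ``ld_rho`` controls the
adjacent-site latent correlation and hence the LD decay; carrier permutation
destroys that LD while preserving each SNP's frequency exactly.

Two trait architectures are provided: a genome-wide polygenic model with a
tunable fraction of low-frequency causal variants, and a local model that
scatters a fixed number of 1-Mbp loci each centered on a handful of causal
variants.  Residual noise is rescaled (after removing its sample covariance
with the genetic value) so the realized heritability equals the target
exactly in the simulated sample.

All randomness flows from a single seed through named substreams, so the
genotype draw, causal-SNP choice, effect sizes and noise can be re-rolled
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import GenotypeMatrix
from .grm import normalize_dosage
from .localh2 import LocusSet, genome_span_bp

LOWFREQ_MAX = 0.05   # low-frequency class: MAF in [0.01, 0.05)
COMMON_MIN = 0.10    # common class: MAF > 0.10

_STREAMS = {"genotypes": 11, "causals": 12, "effects": 13, "noise": 14,
            "permute": 15, "positions": 16, "loci": 17, "ascertain": 18}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class GenoSimConfig:
    """Genotype substrate: sample size, SNP count, MAF spectrum,
    adjacent-haplotype latent correlation and mean inter-SNP spacing in bp.

    The default spectrum is uniform over ``maf_range``.  Setting
    ``low_freq_fraction`` switches to a two-class mixture in which that
    fraction of SNPs draws its frequency from a band safely inside the
    low-frequency class (0.02-0.045) and the rest from a band safely
    inside the common class (0.12-0.5), so class-restricted causal
    architectures can always be satisfied.
    """

    n_samples: int = 500
    n_snps: int = 1000
    maf_range: tuple = (0.01, 0.5)
    low_freq_fraction: float | None = None
    ld_rho: float = 0.0
    bp_spacing: int = 5_000
    n_chromosomes: int = 1
    seed: int = 0


@dataclass
class TraitSimConfig:
    """Trait architecture.

    Genome-wide mode uses ``n_causal`` total causal SNPs of which a fraction
    ``frac_lowfreq_F`` comes from the low-frequency class (the rest from the
    common class).  Local mode places ``n_loci`` disjoint windows of
    ``locus_span_bp`` centered on ``n_causal`` causal variants each, all
    drawn from ``causal_maf_class`` ('low' or 'common').  ``effect_model``:
    'equal_variance' draws effects as standard normal on normalized
    genotypes (every causal explains equal variance in expectation, i.e.
    allelic variance 1/(2p(1-p))); 'allelic_normal' draws the allelic
    effect itself as standard normal.
    """

    n_causal: int = 5000
    frac_lowfreq_F: float = 0.0
    effect_model: str = "equal_variance"
    target_h2: float = 0.8
    n_loci: int = 180
    locus_span_bp: int = 1_000_000
    causal_maf_class: str = "common"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_h2 < 1.0:
            raise ValueError("target_h2 must be in (0,1)")
        if not 0.0 <= self.frac_lowfreq_F <= 1.0:
            raise ValueError("frac_lowfreq_F must be in [0,1]")
        if self.effect_model not in ("equal_variance", "allelic_normal"):
            raise ValueError(f"unknown effect_model {self.effect_model!r}")


@dataclass
class TraitTruth:
    """Simulated phenotype with full generative ground truth."""

    y: np.ndarray
    g: np.ndarray
    causal_ids: list
    beta_allelic: np.ndarray
    beta_normalized: np.ndarray
    realized_h2: float
    target_h2: float
    loci: LocusSet | None = None
    ideal_gwas: list = field(default_factory=list)  # per-locus (snp_id, effect)
    locus_true_var: np.ndarray | None = None  # per-locus genetic variance
    causal_ids_per_locus: list = field(default_factory=list)

    @property
    def h2_gwas_true(self) -> float:
        """Idealized per-locus best-tag variance, as a fraction of Var(y)."""
        alpha2 = sum(e**2 for _, e in self.ideal_gwas)
        return float(alpha2 / self.y.var())

    @property
    def h2_local_true(self) -> float:
        """Summed per-locus genetic variance, as a fraction of Var(y)."""
        return float(self.locus_true_var.sum() / self.y.var())


def simulate_genotypes(config: GenoSimConfig) -> GenotypeMatrix:
    """Draw an LD-structured diploid genotype panel.

    Per chromosome, each haplotype is a latent AR(1) Gaussian with lag-one
    correlation ``ld_rho``; site j carries the alternate allele when the
    latent value exceeds the normal quantile of its drawn frequency, and
    dosages sum two independent haplotypes.  Positions accumulate
    exponential gaps with mean ``bp_spacing``.  Fully reproducible from
    ``config.seed``.
    """
    rho = float(config.ld_rho)
    if not 0.0 <= rho < 1.0:
        import warnings

        clipped = min(max(rho, 0.0), 0.999)
        warnings.warn(f"ld_rho {rho} outside [0,1); clipped to {clipped}")
        rho = clipped
    rng_g = _rng(config.seed, "genotypes")
    rng_p = _rng(config.seed, "positions")

    n, m = config.n_samples, config.n_snps
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1

    if config.low_freq_fraction is None:
        freqs = rng_g.uniform(config.maf_range[0], config.maf_range[1], size=m)
    else:
        n_low = int(round(config.low_freq_fraction * m))
        freqs = np.concatenate(
            [
                rng_g.uniform(0.02, 0.045, size=n_low),
                rng_g.uniform(0.12, 0.5, size=m - n_low),
            ]
        )
        rng_g.shuffle(freqs)
    thresholds = stats.norm.isf(freqs)

    dosage = np.empty((n, m), dtype=np.int8)
    chrom_col = np.empty(m, dtype=int)
    pos_col = np.empty(m, dtype=int)
    offset = 0
    for c, mc in enumerate(per_chrom, start=1):
        if mc == 0:
            continue
        sl = slice(offset, offset + mc)
        latent = np.empty((2 * n, mc))
        latent[:, 0] = rng_g.standard_normal(2 * n)
        innov = rng_g.standard_normal((2 * n, mc - 1)) if mc > 1 else None
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, mc):
            latent[:, j] = rho * latent[:, j - 1] + scale * innov[:, j - 1]
        carriers = latent > thresholds[sl][None, :]
        dosage[:, sl] = (carriers[:n] + carriers[n:]).astype(np.int8)
        gaps = np.maximum(
            1, rng_p.exponential(config.bp_spacing, size=mc).round().astype(int)
        )
        pos_col[sl] = np.cumsum(gaps)
        chrom_col[sl] = c
        offset += mc

    snp_meta = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos_bp": pos_col,
            "id": [f"snp{c}_{p}" for c, p in zip(chrom_col, pos_col)],
            "allele1": "A",
            "allele2": "B",
        }
    )
    sample_meta = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "sex": 0,
            "phenotype": -9,
        }
    )
    return GenotypeMatrix(dosage=dosage, snp_meta=snp_meta, sample_meta=sample_meta)


def permute_carriers(geno: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Independently permute each SNP's dosages across samples.

    Destroys all cross-SNP correlation (LD) while preserving every SNP's
    genotype counts, hence its allele frequency, exactly.
    """
    rng = _rng(seed, "permute")
    dosage = geno.dosage.copy()
    n = geno.n_samples
    for j in range(geno.n_snps):
        dosage[:, j] = dosage[rng.permutation(n), j]
    return GenotypeMatrix(
        dosage=dosage,
        snp_meta=geno.snp_meta.copy(),
        sample_meta=geno.sample_meta.copy(),
    )


def _class_indices(geno: GenotypeMatrix):
    maf = geno.maf()
    low = np.flatnonzero((maf >= 0.01) & (maf < LOWFREQ_MAX))
    common = np.flatnonzero(maf > COMMON_MIN)
    return low, common


def _draw_effects(geno, causal_cols, model, rng):
    """Normalized-scale and allelic-scale effects for the causal columns."""
    z, _ = normalize_dosage(geno.dosage[:, causal_cols], drop_monomorphic=False)
    x = np.where(geno.dosage[:, causal_cols] == -1, np.nan,
                 geno.dosage[:, causal_cols]).astype(float)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0] = 1.0
    if model == "equal_variance":
        beta_norm = rng.standard_normal(len(causal_cols))
        beta_allelic = beta_norm / sd
    else:  # allelic_normal
        beta_allelic = rng.standard_normal(len(causal_cols))
        beta_norm = beta_allelic * sd
    return z, beta_norm, beta_allelic


def _finish_trait(g, target_h2, rng_noise):
    """Add noise rescaled to hit the target heritability exactly in-sample.

    The raw Gaussian noise is centered, its sample covariance with g
    removed, and its variance set to Var(g)(1-h2)/h2, so
    Var(g)/Var(g+e) == target_h2 to machine precision.
    """
    var_g = g.var()
    e = rng_noise.standard_normal(len(g))
    e = e - e.mean()
    gc = g - g.mean()
    e = e - (e @ gc) / (gc @ gc) * gc
    e *= np.sqrt(var_g * (1.0 - target_h2) / target_h2) / e.std()
    y = g + e
    return y, float(g.var() / y.var())


def simulate_trait_genomewide(geno: GenotypeMatrix,
                              config: TraitSimConfig) -> TraitTruth:
    """Polygenic trait with ``n_causal`` causals split between MAF classes.

    A fraction F of the causal set is drawn (without replacement) from the
    low-frequency class, the remainder from the common class; SNPs with MAF
    in [0.05, 0.10] are never causal in this class-restricted design.
    """
    rng_c = _rng(config.seed, "causals")
    rng_e = _rng(config.seed, "effects")
    rng_n = _rng(config.seed, "noise")

    low, common = _class_indices(geno)
    n_low = int(round(config.frac_lowfreq_F * config.n_causal))
    n_com = config.n_causal - n_low
    if n_low > len(low) or n_com > len(common):
        raise ValueError(
            f"not enough SNPs per MAF class: need {n_low} low-frequency "
            f"(have {len(low)}) and {n_com} common (have {len(common)})"
        )
    causal_cols = np.concatenate(
        [
            rng_c.choice(low, size=n_low, replace=False) if n_low else [],
            rng_c.choice(common, size=n_com, replace=False) if n_com else [],
        ]
    ).astype(int)
    causal_cols.sort()

    z, beta_norm, beta_allelic = _draw_effects(
        geno, causal_cols, config.effect_model, rng_e
    )
    g = z @ beta_norm
    y, realized = _finish_trait(g, config.target_h2, rng_n)
    return TraitTruth(
        y=y,
        g=g,
        causal_ids=list(geno.snp_meta["id"].iloc[causal_cols]),
        beta_allelic=beta_allelic,
        beta_normalized=beta_norm,
        realized_h2=realized,
        target_h2=config.target_h2,
    )


def simulate_trait_local(geno: GenotypeMatrix,
                         config: TraitSimConfig) -> TraitTruth:
    """Trait driven by ``n_loci`` disjoint windows of causal variants.

    Each window is centered on its seed causal variant (with uniform jitter
    of 10% of the span) and holds ``n_causal`` causal SNPs drawn from the
    requested MAF class.  The idealized per-locus GWAS SNP (best tag among
    the locus members, causals typed) is recorded alongside the truth.
    """
    rng_l = _rng(config.seed, "loci")
    rng_e = _rng(config.seed, "effects")
    rng_n = _rng(config.seed, "noise")

    low, common = _class_indices(geno)
    pool = low if config.causal_maf_class == "low" else common
    chrom = geno.snp_meta["chrom"].values
    pos = geno.snp_meta["pos_bp"].values
    span = config.locus_span_bp

    pool_mask = np.zeros(geno.n_snps, dtype=bool)
    pool_mask[pool] = True
    seeds = rng_l.permutation(pool)
    intervals: list = []
    causal_per_locus: list = []
    used = np.zeros(geno.n_snps, dtype=bool)
    for s in seeds:
        if len(intervals) == config.n_loci:
            break
        if used[s]:
            continue
        jitter = int(rng_l.uniform(-0.1, 0.1) * span)
        start = max(0, pos[s] - span // 2 + jitter)
        end = start + span
        c = chrom[s]
        if any(cc == c and ss < end and start < ee for cc, ss, ee in intervals):
            continue
        inside = np.flatnonzero((chrom == c) & (pos >= start) & (pos < end))
        class_inside = [j for j in inside if pool_mask[j] and not used[j]]
        if s not in class_inside or len(class_inside) < config.n_causal:
            continue
        others = [j for j in class_inside if j != s]
        extra = rng_l.choice(len(others), size=config.n_causal - 1,
                             replace=False) if config.n_causal > 1 else []
        chosen = sorted([int(s)] + [int(others[k]) for k in extra])
        intervals.append((int(c), int(start), int(end)))
        causal_per_locus.append(chosen)
        used[inside] = True  # keep loci non-overlapping in SNP membership too
    if len(intervals) < config.n_loci:
        raise ValueError(
            f"could only place {len(intervals)} of {config.n_loci} disjoint "
            f"{span}-bp loci with {config.n_causal} "
            f"{config.causal_maf_class}-class causals each"
        )

    order = sorted(range(len(intervals)), key=lambda k: intervals[k])
    intervals = [intervals[k] for k in order]
    causal_per_locus = [causal_per_locus[k] for k in order]

    causal_cols = np.concatenate([np.asarray(c) for c in causal_per_locus])
    z_causal, beta_norm, beta_allelic = _draw_effects(
        geno, causal_cols, config.effect_model, rng_e
    )
    g = z_causal @ beta_norm
    y, realized = _finish_trait(g, config.target_h2, rng_n)

    loci = LocusSet(intervals=intervals,
                    provenance={"simulated": True, "window_bp": span})
    loci.rho_physical = loci.total_bp / genome_span_bp(geno)
    loci.rho_snp = loci.member_mask(geno).mean()

    # per-locus genetic variance and idealized GWAS SNP
    beta_by_col = dict(zip(causal_cols.tolist(), beta_norm))
    ids = geno.snp_meta["id"].values
    locus_var = np.empty(len(intervals))
    ideal = []
    offset = 0
    for k, ccols in enumerate(causal_per_locus):
        nk = len(ccols)
        g_k = z_causal[:, offset : offset + nk] @ beta_norm[offset : offset + nk]
        locus_var[k] = g_k.var()
        offset += nk
        best_id, best_eff = ideal_gwas_snp(
            geno, loci.intervals[k],
            {ids[c]: beta_by_col[c] for c in ccols},
        )
        ideal.append((best_id, best_eff))

    return TraitTruth(
        y=y,
        g=g,
        causal_ids=list(ids[causal_cols]),
        beta_allelic=beta_allelic,
        beta_normalized=beta_norm,
        realized_h2=realized,
        target_h2=config.target_h2,
        loci=loci,
        ideal_gwas=ideal,
        locus_true_var=locus_var,
        causal_ids_per_locus=[list(ids[c] for c in cc) for cc in causal_per_locus],
    )


def ideal_gwas_snp(geno: GenotypeMatrix, locus, causal_effects: dict,
                   tag_panel=None):
    """Best single tag of a locus's causal set, free of sampling noise.

    For each candidate tag t (normalized genotype), the marginal effect is
    sum_c beta_c * r(t, c) with r the in-sample correlation; the tag
    maximizing the squared marginal effect is returned as
    ``(snp_id, marginal_effect)``.  ``tag_panel`` restricts candidates to a
    subset of locus SNP ids (e.g. a sparser array, or causals hidden).
    """
    c, s, e = locus
    chrom = geno.snp_meta["chrom"].values
    pos = geno.snp_meta["pos_bp"].values
    ids = geno.snp_meta["id"].values
    inside = np.flatnonzero((chrom == c) & (pos >= s) & (pos < e))
    if tag_panel is not None:
        panel = set(tag_panel)
        inside = np.array([j for j in inside if ids[j] in panel], dtype=int)
    if inside.size == 0:
        raise ValueError("empty tag panel for locus")

    causal_cols = np.array(
        [int(np.flatnonzero(ids == sid)[0]) for sid in causal_effects], dtype=int
    )
    beta = np.array(list(causal_effects.values()), dtype=float)
    z_tags, _ = normalize_dosage(geno.dosage[:, inside])
    z_cau, _ = normalize_dosage(geno.dosage[:, causal_cols])
    n = geno.n_samples
    r = z_tags.T @ z_cau / n  # (tags, causals)
    marginal = r @ beta
    best = int(np.argmax(marginal**2))
    return ids[inside[best]], float(marginal[best])


def ascertain_case_control(g: np.ndarray, noise_var: float, prevalence_k: float,
                           sample_p: float, n_target: int, seed: int = 0):
    """Liability-threshold case-control sampling.

    Liability = g + e with e ~ N(0, noise_var); the top K of the empirical
    liability distribution are cases.  A sample of ``n_target`` is drawn so
    its case fraction equals P (rounded).  Returns (status over the full
    panel, sampled indices).
    """
    if not (0 < prevalence_k < 1 and 0 < sample_p < 1):
        raise ValueError("K and P must be in (0,1)")
    rng = _rng(seed, "ascertain")
    g = np.asarray(g, float)
    liab = g + rng.normal(0.0, np.sqrt(noise_var), size=len(g))
    thresh = np.quantile(liab, 1.0 - prevalence_k)
    status = (liab > thresh).astype(int)

    n_case = int(round(sample_p * n_target))
    n_ctrl = n_target - n_case
    cases = np.flatnonzero(status == 1)
    ctrls = np.flatnonzero(status == 0)
    if n_case > len(cases) or n_ctrl > len(ctrls):
        raise ValueError("panel too small for the requested case/control split")
    sampled = np.concatenate(
        [
            rng.choice(cases, size=n_case, replace=False),
            rng.choice(ctrls, size=n_ctrl, replace=False),
        ]
    )
    return status, np.sort(sampled)
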