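"""PLINK BED/BIM/FAM, PLINK text phenotype/covariate and GCTA GRM I/O.

Genotypes are stored as hard-call dosages counting the BIM allele2 (PLINK
A2), with ``-1`` marking missing calls.  BIM positions stay 1-based as read;
interval arithmetic elsewhere in the package uses half-open ``[start, end)``
base-pair coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# PLINK 2-bit code -> dosage of allele2 (00=hom A1, 01=missing, 10=het, 11=hom A2)
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


class PlinkFormatError(ValueError):
    """Malformed or unsupported PLINK/GCTA binary content."""


class AlignmentError(ValueError):
    """Sample identifiers failed to resolve between files."""


@dataclass
class GenotypeMatrix:
    """n samples x m SNPs of {0,1,2,missing} allele2 counts plus metadata.

    ``snp_meta`` columns: chrom, pos_bp (1-based), id, allele1, allele2.
    ``sample_meta`` columns: fid, iid, sex, phenotype.
    """

    dosage: np.ndarray  # (n, m) int8, MISSING = -1
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x SNPs)")
        n, m = self.dosage.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one sample and one SNP")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length does not match dosage columns")
        if len(self.sample_meta) != n:
            raise ValueError("sample_meta length does not match dosage rows")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.sample_meta = self.sample_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def sample_ids(self) -> pd.Series:
        return self.sample_meta["iid"]

    def allele2_freq(self) -> np.ndarray:
        """Per-SNP frequency of allele2 among non-missing calls."""
        d = self.dosage
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        total = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = total / (2.0 * n_obs)
        return np.where(n_obs > 0, freq, np.nan)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency, in [0, 0.5]."""
        f = self.allele2_freq()
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def take_snps(self, index) -> "GenotypeMatrix":
        """Column subset (by positional index), preserving order given."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            snp_meta=self.snp_meta.iloc[index].reset_index(drop=True),
            sample_meta=self.sample_meta.copy(),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosage=self.dosage[index, :],
            snp_meta=self.snp_meta.copy(),
            sample_meta=self.sample_meta.iloc[index].reset_index(drop=True),
        )


@dataclass
class PhenoCovar:
    """Phenotype vector and fixed-effect design aligned to a sample panel."""

    y: np.ndarray  # (n,), NaN = missing
    covariates: np.ndarray  # (n, p) including leading affine column of 1s
    sample_ids: pd.Series = field(default=None)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.y)


def decode_bed_byte(byte: int) -> np.ndarray:
    """Dosages of the four genotypes packed in one SNP-major BED byte."""
    codes = np.array([(byte >> (2 * k)) & 0b11 for k in range(4)])
    return _CODE_TO_DOSAGE[codes]


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK binary triple (SNP-major mode only)."""
    bed_path = Path(bed_path)
    if bim_path is None:
        bim_path = bed_path.with_suffix(".bim")
    if fam_path is None:
        fam_path = bed_path.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos_bp", "allele1", "allele2"],
        dtype={"chrom": int, "id": str, "pos_bp": int, "allele1": str, "allele2": str},
    ).drop(columns="cm")
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    ).drop(columns=["father", "mother"])

    n, m = len(fam), len(bim)
    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad BED magic bytes")
    if raw[2] != _BED_SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: only SNP-major BED (mode 0x01) is supported, got mode {raw[2]:#04x}"
        )
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bytes_per_snp * m} genotype bytes for "
            f"{n} samples x {m} SNPs, found {body.size}"
        )

    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, low bits first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    dosage = _CODE_TO_DOSAGE[codes].T  # (n, m)

    snp_meta = bim[["chrom", "pos_bp", "id", "allele1", "allele2"]]
    return GenotypeMatrix(dosage=dosage, snp_meta=snp_meta, sample_meta=fam)


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """Write a SNP-major PLINK binary triple ``prefix``.bed/.bim/.fam."""
    prefix = Path(prefix)
    n, m = geno.dosage.shape
    bytes_per_snp = (n + 3) // 4

    pad = bytes_per_snp * 4 - n
    dosage = geno.dosage.T  # (m, n)
    if pad:
        dosage = np.concatenate(
            [dosage, np.zeros((m, pad), dtype=np.int8)], axis=1
        )
    code = np.zeros(dosage.shape, dtype=np.uint8)
    for dos, c in _DOSAGE_TO_CODE.items():
        code[dosage == dos] = c
    blocks = code.reshape(m, bytes_per_snp, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (blocks << shifts[None, None, :]).sum(axis=2).astype(np.uint8)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())

    bim = geno.snp_meta.copy()
    bim_out = pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "id": bim["id"],
            "cm": 0,
            "pos_bp": bim["pos_bp"],
            "allele1": bim["allele1"],
            "allele2": bim["allele2"],
        }
    )
    bim_out.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = geno.sample_meta
    fam_out = pd.DataFrame(
        {
            "fid": fam["fid"],
            "iid": fam["iid"],
            "father": 0,
            "mother": 0,
            "sex": fam.get("sex", pd.Series([0] * len(fam))),
            "phenotype": fam.get("phenotype", pd.Series([-9] * len(fam))),
        }
    )
    fam_out.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_pheno_covar(
    pheno_path, sample_meta: pd.DataFrame, covar_path=None
) -> PhenoCovar:
    """Read PLINK-dialect phenotype (FID IID value) and optional covariates.

    Output rows follow ``sample_meta`` (FAM) order.  The missing code ``-9``
    becomes NaN.  Covariate columns get a leading affine column of ones
    prepended, so a 20-eigenvector file yields a 21-column fixed-effect
    design.
    """
    key = sample_meta["fid"].astype(str) + "\t" + sample_meta["iid"].astype(str)
    order = pd.Series(np.arange(len(key)), index=key)

    def _align(df: pd.DataFrame, what: str) -> pd.DataFrame:
        k = df.iloc[:, 0].astype(str) + "\t" + df.iloc[:, 1].astype(str)
        unknown = k[~k.isin(order.index)]
        if len(unknown):
            raise AlignmentError(
                f"{what}: ids not present in the sample panel: "
                + ", ".join(unknown.head(10).str.replace("\t", ":"))
            )
        if k.duplicated().any():
            raise AlignmentError(f"{what}: duplicated sample ids")
        return df.set_index(order[k.values].values).sort_index()

    pheno = pd.read_csv(pheno_path, sep=r"\s+", header=None)
    pheno = _align(pheno, str(pheno_path))
    if not (pheno.index.values == np.arange(len(sample_meta))).all():
        missing = set(range(len(sample_meta))) - set(pheno.index)
        ids = sample_meta["iid"].iloc[sorted(missing)[:10]]
        raise AlignmentError(f"phenotype file lacks samples: {', '.join(map(str, ids))}")
    y = pheno.iloc[:, 2].astype(float).values
    y = np.where(y == -9, np.nan, y)

    n = len(sample_meta)
    if covar_path is not None:
        cov = pd.read_csv(covar_path, sep=r"\s+", header=None)
        cov = _align(cov, str(covar_path))
        if len(cov) != n:
            raise AlignmentError("covariate file does not cover every sample")
        cmat = cov.iloc[:, 2:].astype(float).values
        if np.isnan(cmat).any():
            raise AlignmentError("missing covariate entries after alignment")
        covariates = np.column_stack([np.ones(n), cmat])
    else:
        covariates = np.ones((n, 1))

    return PhenoCovar(y=y, covariates=covariates, sample_ids=sample_meta["iid"])


def read_grm_gcta(prefix):
    """Read a GCTA binary GRM triple -> (A, n_snps_matrix, ids DataFrame).

    ``prefix``.grm.bin holds the row-major lower triangle (diagonal
    included) as little-endian float32; ``prefix``.grm.N.bin the per-pair
    SNP counts in the same layout; ``prefix``.grm.id two columns FID IID.
    """
    prefix = Path(prefix)
    ids = pd.read_csv(
        str(prefix) + ".grm.id", sep=r"\s+", header=None, names=["fid", "iid"],
        dtype=str,
    )
    n = len(ids)
    n_tri = n * (n + 1) // 2

    def _unpack(path) -> np.ndarray:
        tri = np.fromfile(path, dtype="<f4")
        if tri.size != n_tri:
            raise PlinkFormatError(
                f"{path}: {tri.size} elements, expected n(n+1)/2 = {n_tri} for n = {n}"
            )
        mat = np.zeros((n, n))
        iu = np.tril_indices(n)
        mat[iu] = tri
        mat = mat + mat.T - np.diag(np.diag(mat))
        return mat

    a = _unpack(str(prefix) + ".grm.bin")
    nmat = _unpack(str(prefix) + ".grm.N.bin")
    return a, nmat, ids


def write_grm_gcta(a: np.ndarray, ids: pd.DataFrame, prefix, n_snps=None) -> None:
    """Write a GCTA binary GRM triple; round-trips to float32 precision."""
    prefix = Path(prefix)
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n):
        raise ValueError("GRM must be square")
    il = np.tril_indices(n)
    a[il].astype("<f4").tofile(str(prefix) + ".grm.bin")
    if n_snps is None:
        n_snps = 1
    nmat = np.full((n, n), float(n_snps))
    nmat[il].astype("<f4").tofile(str(prefix) + ".grm.N.bin")
    ids.iloc[:, :2].to_csv(str(prefix) + ".grm.id", sep="\t", header=False, index=False)
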