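"""PLINK binary genotype I/O and quality control.

Genotypes are held as an individuals x SNPs dosage matrix counting A1
alleles (0/1/2, ``NaN`` for missing), together with marker map columns
(chromosome, base-pair position).  The bed codec implements the PLINK
v1.00 SNP-major 2-bit encoding; QC mirrors the conventional HD-chip
filters for beef-cattle panels: minor allele frequency, per-SNP call
rate, Hardy-Weinberg equilibrium and per-individual missingness, with
analysis restricted to the 29 bovine autosomes.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "allele_freq",
    "hwe_test",
    "qc_filter",
    "AUTOSOMES",
]

#: Bovine autosomes (BTA1-29).
AUTOSOMES = frozenset(range(1, 30))

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 2-bit codes, least-significant pair first within each byte:
# 00 = hom A1 (dosage 2), 01 = missing, 10 = het, 11 = hom A2 (dosage 0)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0], dtype=np.float32)
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


class PlinkFormatError(ValueError):
    """Raised when a bed/bim/fam triplet is malformed."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-dosage matrix with marker map.

    ``dosage[i, j]`` counts A1 alleles of individual *i* at SNP *j*
    (0, 1 or 2); missing calls are ``NaN``.
    """

    ids: np.ndarray        # (n,) individual identifiers
    snp_ids: np.ndarray    # (m,) marker names
    chrom: np.ndarray      # (m,) int chromosome
    bp: np.ndarray         # (m,) int 1-based physical position
    dosage: np.ndarray     # (n, m) float32

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.float32)
        n, m = self.dosage.shape
        if len(self.ids) != n or not (len(self.snp_ids) == len(self.chrom) == len(self.bp) == m):
            raise ValueError("inconsistent genotype dimensions")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-SNP A1 allele frequency from non-missing calls (NaN if all missing)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def missing_rate_snp(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def missing_rate_ind(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def imputed(self, freq: np.ndarray | None = None) -> np.ndarray:
        """float64 dosage with missing calls imputed to the column mean 2p."""
        p = self.allele_freq() if freq is None else np.asarray(freq, dtype=float)
        z = self.dosage.astype(np.float64)
        miss = np.isnan(z)
        if miss.any():
            z[miss] = np.broadcast_to(2.0 * p, z.shape)[miss]
        return z

    def centered(self, freq: np.ndarray | None = None) -> np.ndarray:
        """Imputed dosage centered by twice the allele frequency."""
        p = self.allele_freq() if freq is None else np.asarray(freq, dtype=float)
        return self.imputed(p) - 2.0 * p

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        if snp.dtype == bool:
            snp = np.flatnonzero(snp)
        return GenotypeMatrix(
            ids=self.ids[ind],
            snp_ids=self.snp_ids[snp],
            chrom=self.chrom[snp],
            bp=self.bp[snp],
            dosage=self.dosage[np.ix_(ind, snp)],
        )

    def genotype_counts(self) -> np.ndarray:
        """(m, 3) counts of hom-A1, het, hom-A2 genotypes per SNP."""
        d = self.dosage
        return np.stack(
            [np.nansum(d == 2, axis=0), np.nansum(d == 1, axis=0), np.nansum(d == 0, axis=0)],
            axis=1,
        ).astype(np.int64)


def allele_freq(geno: GenotypeMatrix) -> np.ndarray:
    """A1 allele frequency per SNP: mean non-missing dosage / 2."""
    return geno.allele_freq()


def hwe_test(geno_counts) -> float:
    """Chi-square (1 df) Hardy-Weinberg goodness-of-fit p-value.

    Parameters
    ----------
    geno_counts : (n_AA, n_Aa, n_aa) observed genotype counts.

    Monomorphic SNPs return p = 1 by convention.
    """
    n_aa1, n_het, n_aa2 = (int(c) for c in geno_counts)
    n = n_aa1 + n_het + n_aa2
    if n <= 0:
        raise ValueError("no genotyped individuals")
    p = (2 * n_aa1 + n_het) / (2 * n)
    q = 1.0 - p
    if p <= 0.0 or p >= 1.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa1, n_het, n_aa2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class QCReport:
    """Accounting of a QC pass; removal categories partition the dropped SNPs."""

    n_ind_in: int
    n_ind_out: int
    n_snps_in: int
    n_snps_out: int
    removed_ind_missing: int
    removed_nonautosomal: int
    removed_by_maf: int
    removed_by_callrate: int
    removed_by_hwe: int
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    snp_missing_max: float = 0.05,
    hwe_p_min: float = 1e-6,
    ind_missing_max: float = 0.10,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard HD-panel filters and return the retained matrix.

    Individuals with missing rate above ``ind_missing_max`` are removed
    first; SNP statistics are then computed on the retained sample, and
    SNPs are kept when MAF > ``maf_min``, missing rate < ``snp_missing_max``
    and HWE p > ``hwe_p_min``.  Non-autosomal markers are always dropped.
    A removed SNP is attributed to the first failed filter in the order
    MAF, call rate, HWE.
    """
    for thr in (maf_min, snp_missing_max, hwe_p_min, ind_missing_max):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")

    keep_ind = geno.missing_rate_ind() <= ind_missing_max
    n_ind_removed = int((~keep_ind).sum())
    work = geno.subset(individuals=keep_ind) if n_ind_removed else geno

    autosomal = np.isin(work.chrom, list(AUTOSOMES))
    n_nonauto = int((~autosomal).sum())
    work = work.subset(snps=autosomal) if n_nonauto else work

    p = work.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    miss = work.missing_rate_snp()
    counts = work.genotype_counts()
    hwe_p = np.array([hwe_test(c) if c.sum() > 0 else 1.0 for c in counts])

    maf_fail = maf <= maf_min                    # NaN compares False: all-missing goes to call rate
    call_fail = (miss >= snp_missing_max) | np.isnan(p)
    hwe_fail = hwe_p <= hwe_p_min

    by_maf = maf_fail
    by_call = call_fail & ~maf_fail
    by_hwe = hwe_fail & ~maf_fail & ~call_fail
    keep_snp = ~(maf_fail | call_fail | hwe_fail)

    out = work.subset(snps=keep_snp)
    if out.n_individuals == 0 or out.n_snps == 0:
        raise RuntimeError("QC removed all individuals or all SNPs")

    report = QCReport(
        n_ind_in=geno.n_individuals,
        n_ind_out=out.n_individuals,
        n_snps_in=geno.n_snps,
        n_snps_out=out.n_snps,
        removed_ind_missing=n_ind_removed,
        removed_nonautosomal=n_nonauto,
        removed_by_maf=int(by_maf.sum()),
        removed_by_callrate=int(by_call.sum()),
        removed_by_hwe=int(by_hwe.sum()),
        thresholds={
            "maf_min": maf_min,
            "snp_missing_max": snp_missing_max,
            "hwe_p_min": hwe_p_min,
            "ind_missing_max": ind_missing_max,
        },
    )
    return out, report


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam codec

_DECODE_TABLE = None


def _decode_table() -> np.ndarray:
    """(256, 4) byte -> four dosages lookup, LSB pair = first individual."""
    global _DECODE_TABLE
    if _DECODE_TABLE is None:
        table = np.empty((256, 4), dtype=np.float32)
        for byte in range(256):
            for k in range(4):
                table[byte, k] = _CODE_TO_DOSAGE[(byte >> (2 * k)) & 0b11]
        _DECODE_TABLE = table
    return _DECODE_TABLE


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triplet (SNP-major v1.00 bed)."""
    prefix = Path(prefix)
    bed_path, bim_path, fam_path = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for path in (bed_path, bim_path, fam_path):
        if not path.exists():
            raise FileNotFoundError(path)

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    n, m = len(fam), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not a SNP-major PLINK 1 bed)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes for "
            f"{n} individuals x {m} SNPs, found {body.size}"
        )
    decoded = _decode_table()[body.reshape(m, bytes_per_snp)]  # (m, bytes, 4)
    dosage = decoded.reshape(m, bytes_per_snp * 4)[:, :n].T.copy()

    return GenotypeMatrix(
        ids=fam.iloc[:, 1].to_numpy(dtype=object),
        snp_ids=bim.iloc[:, 1].to_numpy(dtype=object),
        chrom=bim.iloc[:, 0].astype(int).to_numpy(),
        bp=bim.iloc[:, 3].astype(int).to_numpy(),
        dosage=dosage,
    )


def write_plink(geno: GenotypeMatrix, prefix) -> dict[str, Path]:
    """Write bed/bim/fam; inverse of :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.dosage.shape
    bytes_per_snp = (n + 3) // 4

    codes = np.full((m, bytes_per_snp * 4), 0b01, dtype=np.uint8)  # pad = missing code
    d = geno.dosage.T  # (m, n)
    col = codes[:, :n]
    col[d == 2.0] = 0b00
    col[d == 1.0] = 0b10
    col[d == 0.0] = 0b11
    shifted = codes.reshape(m, bytes_per_snp, 4) << (2 * np.arange(4, dtype=np.uint8))
    packed = np.bitwise_or.reduce(shifted, axis=2).astype(np.uint8)

    bed_path = prefix.with_suffix(".bed")
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": geno.chrom,
            "snp": geno.snp_ids,
            "cm": 0,
            "bp": geno.bp,
            "a1": "A",
            "a2": "G",
        }
    )
    bim_path = prefix.with_suffix(".bim")
    bim.to_csv(bim_path, sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {"fid": geno.ids, "iid": geno.ids, "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
    )
    fam_path = prefix.with_suffix(".fam")
    fam.to_csv(fam_path, sep="\t", header=False, index=False)

    return {"bed": bed_path, "bim": bim_path, "fam": fam_path}
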