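"""Genotype matrices: VCF I/O, SNP filtering, imputation, and LD pruning.

Genotypes are biallelic diploid dosages (count of alternate alleles, 0/1/2),
stored as a float matrix with NaN marking missing calls.  The filtering chain
mirrors standard GbS practice: per-SNP missingness, minor allele frequency on
the remaining calls, frequency-based imputation of residual missing
genotypes, and greedy windowed LD pruning on squared Pearson correlation of
dosages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "FilterReport", "read_vcf", "write_vcf",
           "filter_genotypes", "impute_missing", "ld_prune"]

SNP_META_COLS = ["id", "chrom", "pos", "ref", "alt"]
SAMPLE_META_COLS = ["id", "locality", "lon", "lat"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with site and sample metadata.

    ``dosages`` holds alternate-allele counts in {0, 1, 2} with NaN for
    missing calls.  ``snp_meta`` has one row per SNP (id, chrom, pos, ref,
    alt; positions strictly increasing within each chromosome) and
    ``sample_meta`` one row per individual (id, locality, lon, lat).
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs matrix")
        n, l = self.dosages.shape
        if n < 1:
            raise ValueError("at least one individual required")
        if len(self.snp_meta) != l:
            raise ValueError("snp_meta rows must match the number of SNP columns")
        if len(self.sample_meta) != n:
            raise ValueError("sample_meta rows must match the number of individuals")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        for col in ("ref", "alt"):
            if (self.snp_meta[col].astype(str).str.len() == 0).any():
                raise ValueError(f"empty {col} allele label")
        for chrom, grp in self.snp_meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.sample_meta = self.sample_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix with the SNP columns selected by ``index`` (order kept)."""
        return GenotypeMatrix(self.dosages[:, index],
                              self.snp_meta.iloc[index].reset_index(drop=True),
                              self.sample_meta.copy())

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)


@dataclass
class FilterReport:
    """Bookkeeping of a filtering step; counts always reconcile."""

    n_input: int
    n_removed_missing: int = 0
    n_removed_maf: int = 0
    n_removed_ld: int = 0
    n_output: int = 0

    def __post_init__(self):
        removed = self.n_removed_missing + self.n_removed_maf + self.n_removed_ld
        if min(self.n_input, self.n_removed_missing, self.n_removed_maf,
               self.n_removed_ld, self.n_output) < 0:
            raise ValueError("negative count in FilterReport")
        if self.n_output != self.n_input - removed:
            raise ValueError("FilterReport counts do not reconcile")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_vcf(path: str | Path, sample_table: pd.DataFrame | str | Path | None = None
             ) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Multiallelic records and indels are skipped (a count is logged).  Missing
    genotypes ("./.") become NaN.  ``sample_table`` optionally supplies
    locality and coordinates per sample id; otherwise placeholder metadata is
    generated.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows = []
    meta = []
    n_skipped = 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            n_skipped += 1
            continue
        dos = np.empty(len(samples))
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            dos[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append(dos)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        meta.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/indel records", n_skipped)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    dosages = np.column_stack(rows)
    snp_meta = pd.DataFrame(meta, columns=SNP_META_COLS)
    if sample_table is None:
        sample_meta = pd.DataFrame({"id": samples, "locality": "unknown",
                                    "lon": np.nan, "lat": np.nan})
    else:
        if not isinstance(sample_table, pd.DataFrame):
            sample_table = pd.read_csv(sample_table, sep="\t")
        sample_meta = sample_table.set_index("id").loc[samples].reset_index()
    return GenotypeMatrix(dosages, snp_meta, sample_meta)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal VCF v4.2 with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.snp_meta["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        ids = "\t".join(gm.sample_meta["id"].astype(str))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ids}\n")
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in gm.snp_meta.iterrows():
            col = gm.dosages[:, j]
            gts = "\t".join("./." if np.isnan(d) else gt_of[d] for d in col)
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def filter_genotypes(gm: GenotypeMatrix, max_missing: float = 0.2,
                     min_maf: float = 0.01) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove SNPs by missingness then minor allele frequency.

    SNPs with a missing fraction above ``max_missing`` go first; MAF is then
    computed on the survivors' non-missing calls and SNPs below ``min_maf``
    are dropped.  SNP order is preserved.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = gm.missing_fraction()
    keep_miss = miss <= max_missing
    n_removed_missing = int((~keep_miss).sum())
    gm2 = gm.take_snps(np.flatnonzero(keep_miss)) if n_removed_missing else gm
    if gm2.n_snps == 0:
        raise ValueError("all SNPs removed by the missingness filter; "
                         "review max_missing")
    freq = gm2.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    keep_maf = maf >= min_maf
    n_removed_maf = int((~keep_maf).sum())
    out = gm2.take_snps(np.flatnonzero(keep_maf)) if n_removed_maf else gm2
    if out.n_snps == 0:
        raise ValueError("all SNPs removed by the MAF filter; review min_maf")
    report = FilterReport(n_input=gm.n_snps, n_removed_missing=n_removed_missing,
                          n_removed_maf=n_removed_maf, n_output=out.n_snps)
    return out, report


def impute_missing(gm: GenotypeMatrix, mode: str = "per_locality_frequency",
                   seed: int = 0) -> GenotypeMatrix:
    """Fill missing dosages by binomial draws from estimated allele frequency.

    With ``per_locality_frequency`` the alt-allele frequency is estimated per
    sampling locality (falling back to the global frequency when a locality
    has no call at the SNP); ``global_frequency`` always pools all samples.
    Imputed dosages are drawn as Binomial(2, p-hat) with a fixed seed.
    """
    if mode not in ("per_locality_frequency", "global_frequency"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    d = gm.dosages.copy()
    missing = np.isnan(d)
    if not missing.any():
        return GenotypeMatrix(d, gm.snp_meta.copy(), gm.sample_meta.copy())
    if np.any(missing.all(axis=0)):
        bad = gm.snp_meta["id"].iloc[np.flatnonzero(missing.all(axis=0))].tolist()
        raise ValueError(f"SNPs entirely missing, cannot impute: {bad}")
    rng = np.random.default_rng(seed)
    global_p = gm.allele_freq()
    p_hat = np.broadcast_to(global_p, d.shape).copy()
    if mode == "per_locality_frequency":
        localities = gm.sample_meta["locality"].to_numpy()
        for loc in pd.unique(localities):
            rows = localities == loc
            with np.errstate(invalid="ignore"):
                p_loc = np.nanmean(d[rows], axis=0) / 2.0
            p_loc = np.where(np.isnan(p_loc), global_p, p_loc)
            p_hat[rows] = p_loc
    d[missing] = rng.binomial(2, p_hat[missing]).astype(float)
    return GenotypeMatrix(d, gm.snp_meta.copy(), gm.sample_meta.copy())


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed on pairwise-complete calls; zero-variance vectors give 0, never
    NaN.
    """
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok], b[ok]
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 0.0
    c = np.mean((x - x.mean()) * (y - y.mean()))
    return float(c * c / (vx * vy))


def ld_prune(gm: GenotypeMatrix, r2_max: float = 0.5, window_bp: int = 5000
             ) -> tuple[GenotypeMatrix, FilterReport]:
    """Greedy windowed LD pruning, keeping the earlier-position SNP.

    Per chromosome, SNPs are scanned left to right; for every retained SNP,
    any later SNP within ``window_bp`` whose dosage r-squared with it exceeds
    ``r2_max`` is dropped.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not 0 <= r2_max <= 1:
        raise ValueError("r2_max must lie in [0, 1]")
    keep = np.ones(gm.n_snps, bool)
    chroms = gm.snp_meta["chrom"].to_numpy()
    pos = gm.snp_meta["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for a in range(len(idx)):
            i = idx[a]
            if not keep[i]:
                continue
            for b in range(a + 1, len(idx)):
                j = idx[b]
                if pos[j] - pos[i] > window_bp:
                    break
                if not keep[j]:
                    continue
                if _pairwise_r2(gm.dosages[:, i], gm.dosages[:, j]) > r2_max:
                    keep[j] = False
    out = gm.take_snps(np.flatnonzero(keep))
    report = FilterReport(n_input=gm.n_snps, n_removed_ld=int((~keep).sum()),
                          n_output=out.n_snps)
    return out, report
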