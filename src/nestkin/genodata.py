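"""Genotype I/O, site filtering and LD pruning.

The pipeline starts from a VCF of diploid, biallelic SNPs.  Genotypes are
held as alt-allele dosages (0, 1, 2, or NaN for missing) in a sites x
samples array.  Filtering reproduces the conventional ddRAD-seq workflow:
a per-site missingness ceiling, a singleton/minor-allele-frequency floor,
a site quality floor, an optional mean-depth floor, and a two-SNP sliding
window LD prune (the PLINK ``--indep-pairwise 2 1 0.5`` rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a set of samples.

    Attributes
    ----------
    sample_ids:
        Sample names, in column order.
    sites:
        Per-site table with columns ``chrom, pos, ref, alt, qual``
        (positions 1-based, strictly increasing within a chromosome).
    dosages:
        ``(n_sites, n_samples)`` float array of alt-allele counts
        (0, 1 or 2); missing genotypes are ``NaN``.
    depths:
        Optional ``(n_sites, n_samples)`` array of per-genotype depths.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    dosages: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sites), len(self.sample_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sites)} sites x {len(self.sample_ids)} samples"
            )
        with np.errstate(invalid="ignore"):
            bad = np.logical_or(self.dosages < 0, self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must lie in {0, 1, 2} or NaN")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def allele_freqs(self) -> np.ndarray:
        """Per-site alt-allele frequency from called genotypes only."""
        called = ~np.isnan(self.dosages)
        n_called = called.sum(axis=1)
        alt = np.nansum(self.dosages, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n_called)
        return np.where(n_called > 0, p, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def missingness(self) -> np.ndarray:
        """Per-site fraction of samples with a missing genotype."""
        return np.isnan(self.dosages).mean(axis=1)

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(
            sample_ids=list(ids),
            sites=self.sites.copy(),
            dosages=self.dosages[:, idx].copy(),
            depths=None if self.depths is None else self.depths[:, idx].copy(),
        )

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[idx],
            depths=None if self.depths is None else self.depths[idx],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        if self.sample_ids != other.sample_ids:
            return False
        if not self.sites[SITE_COLUMNS[:4]].equals(other.sites[SITE_COLUMNS[:4]]):
            return False
        a, b = self.dosages, other.dosages
        return a.shape == b.shape and bool(
            np.all((a == b) | (np.isnan(a) & np.isnan(b)))
        )


@dataclass
class FilterSpec:
    """Site-retention thresholds applied jointly by :func:`filter_sites`."""

    max_site_missingness: float = 0.05
    min_maf: float = 0.0056
    min_qual: float = 30.0
    min_site_depth: float = 5.0
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_site_missingness <= 1.0:
            raise ValueError("max_site_missingness must be in [0, 1]")
        for name in ("min_maf", "min_qual", "min_site_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT required) into a :class:`GenotypeMatrix`.

    Multiallelic records are dropped with a logged count; non-diploid
    genotypes raise an error naming the record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dosage_rows, depth_rows = [], [], []
    n_multi = 0
    any_depth = False
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotype.array()
        if gts.shape[1] - 1 != 2:  # last column is the phase flag
            raise ValueError(
                f"non-diploid genotype at {var.CHROM}:{var.POS}"
            )
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        dos = alleles.sum(axis=1)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0],
                     float(var.QUAL) if var.QUAL is not None else np.nan))
        dosage_rows.append(dos)
        try:
            fmt_depth = var.format("DP")
        except KeyError:
            fmt_depth = None
        if fmt_depth is not None:
            any_depth = True
            d = fmt_depth.astype(float).reshape(-1)
            d[d < 0] = np.nan
            depth_rows.append(d)
        else:
            depth_rows.append(np.full(len(samples), np.nan))
    if n_multi:
        log.warning("dropped %d multiallelic record(s)", n_multi)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosages = (np.vstack(dosage_rows) if dosage_rows
               else np.empty((0, len(samples))))
    depths = np.vstack(depth_rows) if (depth_rows and any_depth) else None
    return GenotypeMatrix(samples, sites, dosages, depths)


def write_vcf(M: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 with GT (and DP when depths are present)."""
    has_dp = M.depths is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(M.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(M.sample_ids) + "\n")
        gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i, site in M.sites.iterrows():
            qual = "." if np.isnan(site["qual"]) else f"{site['qual']:g}"
            cells = []
            for j in range(M.n_samples):
                d = M.dosages[i, j]
                gt = "./." if np.isnan(d) else gt_code[d]
                if has_dp:
                    dp = M.depths[i, j]
                    gt += ":" + ("." if np.isnan(dp) else str(int(dp)))
                cells.append(gt)
            fmt = "GT:DP" if has_dp else "GT"
            fh.write(f"{site['chrom']}\t{int(site['pos'])}\t.\t{site['ref']}\t"
                     f"{site['alt']}\t{qual}\tPASS\t.\t{fmt}\t"
                     + "\t".join(cells) + "\n")


def filter_sites(
    M: GenotypeMatrix, spec: FilterSpec | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply all site filters jointly; return the matrix and a removal report.

    The report counts, per criterion, how many sites failed it (a site may
    fail several).  MAF is computed from called genotypes only; the depth
    floor is skipped with a warning when the input carries no DP.
    """
    spec = spec or FilterSpec()
    keep = np.ones(M.n_sites, dtype=bool)
    report = []

    miss = M.missingness()
    fail = miss > spec.max_site_missingness
    report.append(("max_site_missingness", int(fail.sum())))
    keep &= ~fail

    maf = M.maf()
    # thresholds are printed to limited precision (0.0056 means "at least
    # a doubleton in a 180-sample set"), so compare with a 1e-4 tolerance
    fail = ~(maf >= spec.min_maf - 1e-4)  # NaN maf (no calls) also fails
    report.append(("min_maf", int(fail.sum())))
    keep &= ~fail

    qual = M.sites["qual"].to_numpy(dtype=float)
    fail = qual < spec.min_qual  # NaN qual passes (QUAL absent)
    report.append(("min_qual", int(np.nansum(fail))))
    keep &= ~np.where(np.isnan(qual), False, fail)

    if spec.min_site_depth > 0:
        if M.depths is None:
            log.warning("no per-genotype DP in input; depth filter skipped")
            report.append(("min_site_depth", 0))
        else:
            mean_depth = np.nanmean(M.depths, axis=1)
            fail = ~(mean_depth >= spec.min_site_depth)
            report.append(("min_site_depth", int(fail.sum())))
            keep &= ~fail

    if not keep.any():
        log.warning("all %d sites removed by filtering", M.n_sites)
    out = M.take_sites(keep)
    return out, pd.DataFrame(report, columns=["criterion", "sites_removed"])


def ld_prune(
    M: GenotypeMatrix,
    r2_threshold: float = 0.5,
    window: int = 2,
    step: int = 1,
    seed: int = 0,
) -> GenotypeMatrix:
    """Two-SNP sliding-window LD prune (PLINK ``--indep-pairwise 2 1 0.5``).

    Within each window of ``window`` consecutive retained sites (advancing
    by ``step``), if the squared Pearson correlation of dosages over
    pairwise-complete samples exceeds ``r2_threshold``, one member of the
    pair is removed, chosen by a seeded uniform draw.  A pair in which
    either site has zero variance over the shared samples is kept (r^2
    undefined, logged).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    rng = np.random.default_rng(seed)
    alive = np.ones(M.n_sites, dtype=bool)
    X = M.dosages
    for start in range(0, M.n_sites - 1, step):
        idx = [i for i in range(start, min(start + window, M.n_sites))
               if alive[i]]
        for a_pos in range(len(idx)):
            for b_pos in range(a_pos + 1, len(idx)):
                a, b = idx[a_pos], idx[b_pos]
                if not (alive[a] and alive[b]):
                    continue
                shared = ~np.isnan(X[a]) & ~np.isnan(X[b])
                if shared.sum() < 2:
                    continue
                xa, xb = X[a, shared], X[b, shared]
                va, vb = xa.var(), xb.var()
                if va == 0.0 or vb == 0.0:
                    log.debug("zero-variance pair (%d, %d); kept", a, b)
                    continue
                r = np.corrcoef(xa, xb)[0, 1]
                if r * r > r2_threshold:
                    victim = a if rng.random() < 0.5 else b
                    alive[victim] = False
    return M.take_sites(alive)


def select_parentage_sites(
    M: GenotypeMatrix,
    min_maf: float = 0.45,
    max_site_missingness: float = 0.05,
) -> GenotypeMatrix:
    """High-information site subset for parentage and sibship analyses.

    Keeps sites with low missingness whose minor-allele frequency is near
    its 0.5 ceiling — the most informative markers for discriminating
    full-sib, half-sib and unrelated dyads.
    """
    if min_maf > 0.5:
        raise ValueError("min_maf cannot exceed 0.5")
    log.info("parentage site selection: maf >= %.3f, missingness <= %.3f",
             min_maf, max_site_missingness)
    keep = (M.maf() >= min_maf) & (M.missingness() <= max_site_missingness)
    return M.take_sites(keep)
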