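"""Genotype matrix I/O and the SNP filtering cascade.

Reads biallelic SNP genotypes (with per-genotype depth) from VCF into a
samples x sites dosage matrix, and applies the standard reduced-representation
filtering cascade: per-genotype depth masking, site-level call-rate /
missingness / MAF / biallelic filters, and sample-level call-rate filtering
with re-removal of sites left monomorphic by dropped samples.

Dosages are ALT-allele counts in {0, 1, 2}; missing genotypes are coded -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1

SITE_COLUMNS = ["contig", "pos", "ref", "alt", "biallelic_snp"]


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid dosage matrix with site metadata.

    Attributes
    ----------
    sample_ids : list of str
    sites : pandas.DataFrame
        One row per site with columns ``contig``, ``pos`` (1-based),
        ``ref``, ``alt`` and ``biallelic_snp`` (False for multi-allelic
        or indel records, which are retained on read but flagged so the
        site filter can drop them).
    calls : ndarray of int8, shape (n_samples, n_sites)
        ALT dosage 0/1/2, or -1 for missing.
    depth : ndarray of int32 or None
        Per-genotype read depth, same shape as ``calls``.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth shape does not match calls shape")
        self.sites = self.sites.reset_index(drop=True)
        for contig, grp in self.sites.groupby("contig", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {contig}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Per-site ALT allele frequency over non-missing genotypes (NaN if none)."""
        called = self.calls != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def site_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            sites=self.sites.copy(),
            calls=self.calls[idx],
            depth=None if self.depth is None else self.depth[idx],
        )


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering cascade.

    ``min_genotype_depth`` is an exclusive bound: genotypes with depth <= 7
    are masked, keeping DP > 7. ``maf_min`` is likewise exclusive (MAF > 0.05
    kept). Call-rate thresholds are inclusive ("at least 80%").
    """

    min_genotype_depth: int = 7
    max_site_missing_frac: float = 0.30
    min_site_call_rate: float = 0.80
    min_sample_call_rate: float = 0.80
    maf_min: float = 0.05
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        for name in ("max_site_missing_frac", "min_site_call_rate",
                     "min_sample_call_rate", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


_SINGLE_BASES = frozenset("ACGT")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Dosage is the ALT-allele count of the GT field; any genotype containing
    a missing allele (``./.``, ``0/.``) is coded missing. Multi-allelic and
    indel records are kept but flagged ``biallelic_snp=False`` so that
    :func:`filter_sites` can remove them. DP is captured when present.
    """
    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows = []
    calls_rows = []
    depth_rows = []
    has_depth = False
    for var in vcf:
        alts = var.ALT
        biallelic = (
            len(alts) == 1
            and var.REF in _SINGLE_BASES
            and alts[0] in _SINGLE_BASES
        )
        # gts012: 0/1/2 dosage, 3 = unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        calls_rows.append(g)
        dp = var.format("DP")
        if dp is not None:
            has_depth = True
            d = np.asarray(dp, dtype=np.int32).reshape(-1)
            d[d < 0] = 0
            depth_rows.append(d)
        else:
            depth_rows.append(np.zeros(len(sample_ids), dtype=np.int32))
        rows.append(
            (var.CHROM, var.POS, var.REF, alts[0] if alts else ".", biallelic)
        )
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    calls = np.vstack(calls_rows).T
    depth = np.vstack(depth_rows).T if has_depth else None
    return GenotypeMatrix(sample_ids, sites, calls, depth)


def write_vcf(gm: GenotypeMatrix, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write the matrix as a minimal VCF 4.2 with GT:DP genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radpop\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(gm.sites["contig"]):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        has_depth = gm.depth is not None
        for j in range(gm.n_sites):
            s = gm.sites.iloc[j]
            fields = [str(s.contig), str(int(s.pos)), ".", s.ref, s.alt, ".", ".", ".",
                      "GT:DP" if has_depth else "GT"]
            for i in range(gm.n_samples):
                g = gt_str[int(gm.calls[i, j])]
                if has_depth:
                    g = f"{g}:{int(gm.depth[i, j])}"
                fields.append(g)
            fh.write("\t".join(fields) + "\n")


def mask_low_depth(gm: GenotypeMatrix, min_genotype_depth: int = 7) -> GenotypeMatrix:
    """Set genotypes with depth <= ``min_genotype_depth`` to missing (DP > 7 kept)."""
    if gm.depth is None:
        raise ValueError("mask_low_depth requires per-genotype depth (DP)")
    calls = gm.calls.copy()
    calls[gm.depth <= min_genotype_depth] = MISSING
    return replace(gm, sample_ids=list(gm.sample_ids), sites=gm.sites.copy(),
                   calls=calls, depth=gm.depth.copy())


def filter_sites(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Drop sites failing the biallelic / call-rate / missingness / MAF filters.

    A site passes iff it is a biallelic SNP (when ``biallelic_only``), its
    call rate is >= ``min_site_call_rate``, its missing fraction is
    < ``max_site_missing_frac``, and its MAF (over non-missing calls) is
    strictly > ``maf_min``. Site order is preserved.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    cfg = cfg or FilterConfig()
    call_rate = gm.site_call_rates()
    maf = gm.minor_allele_frequencies()
    keep = (call_rate >= cfg.min_site_call_rate) & ((1.0 - call_rate) < cfg.max_site_missing_frac)
    with np.errstate(invalid="ignore"):
        keep &= np.nan_to_num(maf, nan=-1.0) > cfg.maf_min
    if cfg.biallelic_only:
        keep &= gm.sites["biallelic_snp"].to_numpy()
    if not keep.any():
        warnings.warn("all sites removed by site filters", stacklevel=2)
    return gm.take_sites(np.flatnonzero(keep))


def filter_samples(gm: GenotypeMatrix, min_sample_call_rate: float = 0.80) -> GenotypeMatrix:
    """Drop samples with call rate below threshold, then re-drop dead sites.

    After removing low-call-rate samples, any site that is no longer
    polymorphic among the kept samples (it was polymorphic only in the
    removed individuals, or has no remaining calls) is dropped as well.
    """
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    keep_samples = np.flatnonzero(gm.sample_call_rates() >= min_sample_call_rate)
    if len(keep_samples) == gm.n_samples:
        return gm
    out = gm.take_samples(keep_samples)
    maf = out.minor_allele_frequencies()
    alive = np.nan_to_num(maf, nan=0.0) > 0.0
    return out.take_sites(np.flatnonzero(alive))


def filter_cascade(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Full cascade: depth mask -> site filters -> sample filter -> site re-drop."""
    cfg = cfg or FilterConfig()
    if gm.depth is not None:
        gm = mask_low_depth(gm, cfg.min_genotype_depth)
    gm = filter_sites(gm, cfg)
    return filter_samples(gm, cfg.min_sample_call_rate)


def read_popmap(path: str) -> pd.DataFrame:
    """Read a 2- or 3-column TSV mapping sample -> population [-> phenotype]."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("population map needs >= 2 tab-separated columns")
    df = df.iloc[:, :3]
    df.columns = ["sample_id", "population", "phenotype"][: df.shape[1]]
    if "phenotype" not in df.columns:
        df["phenotype"] = pd.NA
    return df
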