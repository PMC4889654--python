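"""Diversity and differentiation statistics.

Observed heterozygosity, windowed nucleotide diversity (pi), windowed
Tajima's D, Hardy–Weinberg exact tests with Bonferroni / Benjamini–Hochberg
correction, Weir–Cockerham Fst (mean-of-ratios and ratio-of-sums forms), and
per-window SNP density.

All statistics operate on the dosage matrix of :class:`~radpop.variant_io.
GenotypeMatrix`; per-site sample sizes use non-missing calls only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .variant_io import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# heterozygosity

def observed_heterozygosity(
    gm: GenotypeMatrix, popmap: pd.DataFrame | None = None
) -> tuple[pd.Series, pd.Series | None]:
    """Per-individual and per-population observed heterozygosity.

    Ho of an individual is the fraction of its non-missing genotypes that are
    heterozygous; the population value is the mean over member individuals.
    Individuals with zero calls get NaN.
    """
    called = gm.calls != MISSING
    n_called = called.sum(axis=1)
    n_het = (gm.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    per_ind = pd.Series(ho, index=gm.sample_ids, name="Ho")
    if popmap is None:
        return per_ind, None
    pops = popmap.set_index("sample_id")["population"].reindex(gm.sample_ids)
    per_pop = per_ind.groupby(pops.to_numpy()).mean()
    per_pop.name = "Ho"
    return per_ind, per_pop


# ---------------------------------------------------------------------------
# windows

def _window_edges(contig_len: int, window_bp: int) -> np.ndarray:
    n = int(np.ceil(contig_len / window_bp))
    return np.arange(n + 1) * window_bp


def _contig_lengths(gm: GenotypeMatrix, contig_lengths: dict[str, int] | None) -> dict[str, int]:
    if contig_lengths is not None:
        return contig_lengths
    return {c: int(g["pos"].max()) for c, g in gm.sites.groupby("contig", sort=False)}


def _site_stats(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ALT frequency, non-missing allele count)."""
    called = gm.calls != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, gm.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return p, n_alleles


def nucleotide_diversity(
    gm: GenotypeMatrix,
    window_bp: int = 5000,
    contig_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Windowed pi and its genome-wide average (total pairwise diversity / bp).

    Per window, pi = sum over SNPs of ``2 p (1-p) n/(n-1)`` divided by the
    window length, with n the non-missing allele count at the site — the
    standard unbiased per-site estimator aggregated over the window.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    p, n = _site_stats(gm)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(n > 1, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1), 0.0)
    lengths = _contig_lengths(gm, contig_lengths)
    rows = []
    pos_all = gm.sites["pos"].to_numpy()
    contig_all = gm.sites["contig"].to_numpy()
    for contig, clen in lengths.items():
        edges = _window_edges(clen, window_bp)
        in_contig = contig_all == contig
        idx = np.flatnonzero(in_contig)
        # windows are half-open [start, start+window) on 0-based coordinates
        wbin = (pos_all[idx] - 1) // window_bp
        sums = np.bincount(wbin, weights=per_site[idx], minlength=len(edges) - 1)
        counts = np.bincount(wbin, minlength=len(edges) - 1)
        for w in range(len(edges) - 1):
            rows.append((contig, int(edges[w]), int(edges[w + 1]),
                         int(counts[w]), sums[w] / window_bp, True))
    windows = pd.DataFrame(
        rows, columns=["contig", "start", "end", "n_snps", "value", "defined"]
    )
    total_len = float(sum(lengths.values()))
    genome_avg = float(np.nansum(per_site)) / total_len if total_len else float("nan")
    return windows, genome_avg


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajimas_d_value(pi_sum: float, S: int, n: int) -> float:
    """Tajima's D from the pairwise-diversity sum, segregating-site count and
    the number of sequences; NaN if S == 0 or n < 4."""
    if S == 0 or n < 4:
        return float("nan")
    k = _tajima_constants(n)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return (pi_sum - theta_w) / np.sqrt(var)


def tajimas_d(
    gm: GenotypeMatrix,
    window_bp: int = 1000,
    contig_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Windowed Tajima's D plus two averages.

    Returns ``(windows, avg_all, avg_snp_windows)``: windows with no
    segregating sites are ``defined=False``, contribute 0 to the
    all-windows average and are excluded from the SNP-windows average.
    The number of sequences per window is the median non-missing allele
    count over its segregating sites (exact 2N with complete data).
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    p, n_alleles = _site_stats(gm)
    seg = (p > 0) & (p < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(
            n_alleles > 1, 2.0 * p * (1.0 - p) * n_alleles / np.maximum(n_alleles - 1, 1), 0.0
        )
    lengths = _contig_lengths(gm, contig_lengths)
    pos_all = gm.sites["pos"].to_numpy()
    contig_all = gm.sites["contig"].to_numpy()
    rows = []
    for contig, clen in lengths.items():
        edges = _window_edges(clen, window_bp)
        idx = np.flatnonzero(contig_all == contig)
        wbin = (pos_all[idx] - 1) // window_bp
        for w in range(len(edges) - 1):
            in_w = idx[wbin == w]
            seg_w = in_w[seg[in_w]]
            S = len(seg_w)
            if S == 0:
                rows.append((contig, int(edges[w]), int(edges[w + 1]), 0, np.nan, False))
                continue
            n_seq = int(np.median(n_alleles[seg_w]))
            d = tajimas_d_value(float(pi_site[seg_w].sum()), S, n_seq)
            rows.append((contig, int(edges[w]), int(edges[w + 1]), S, d, np.isfinite(d)))
    windows = pd.DataFrame(
        rows, columns=["contig", "start", "end", "n_snps", "value", "defined"]
    )
    defined = windows["defined"].to_numpy()
    vals = windows["value"].to_numpy(dtype=float)
    avg_all = float(np.where(defined, vals, 0.0).sum() / len(windows)) if len(windows) else float("nan")
    avg_snp = float(vals[defined].mean()) if defined.any() else float("nan")
    return windows, avg_all, avg_snp


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test

def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact HWE p-value for one biallelic site (Wigginton-style).

    Sums, over all heterozygote counts compatible with the observed allele
    counts (same parity), the probabilities of configurations no more likely
    than the observed one. Monomorphic sites give p = 1.
    """
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if n == 0 or rare == 0 or rare == 2 * n:
        return 1.0

    def logprob(h: int) -> float:
        # P(h hets | n genotypes, `rare` copies of the rarer allele)
        hr = (rare - h) // 2
        hc = n - h - hr
        return (
            gammaln(n + 1) - gammaln(h + 1) - gammaln(hr + 1) - gammaln(hc + 1)
            + h * np.log(2.0)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
        )

    hets = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    logs = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


def hwe_exact(gm: GenotypeMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-site exact HWE test with Bonferroni and BH flags at ``alpha``."""
    n_het = (gm.calls == 1).sum(axis=0)
    n_hom1 = (gm.calls == 0).sum(axis=0)
    n_hom2 = (gm.calls == 2).sum(axis=0)
    pvals = np.array([
        hwe_exact_pvalue(int(h), int(a), int(b))
        for h, a, b in zip(n_het, n_hom1, n_hom2)
    ])
    bonf = multipletests(pvals, alpha=alpha, method="bonferroni")
    bh = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = gm.sites[["contig", "pos"]].copy()
    out["p_hwe"] = pvals
    out["p_bonferroni"] = bonf[1]
    out["p_bh"] = bh[1]
    out["flag_bonferroni"] = bonf[1] <= alpha
    out["flag_bh"] = bh[1] <= alpha
    return out


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst

@dataclass
class FstResult:
    """Per-site Weir–Cockerham variance components and the two summaries.

    ``mean_fst`` averages per-site a/(a+b+c) over sites with a positive
    denominator; ``weighted_fst`` is the ratio of sums (the sample-size
    corrected form reported below the diagonal of pairwise tables).
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    mean_fst: float
    weighted_fst: float

    @property
    def per_site(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.a / denom, np.nan)


def wc_fst(gm: GenotypeMatrix, popmap: pd.DataFrame, pops: list[str] | None = None) -> FstResult:
    """Weir & Cockerham (1984) Fst over the given populations.

    Computes the per-site among-population (a), among-individual (b) and
    within-individual (c) variance components for diploid data with unequal
    sample sizes, using per-site non-missing counts.
    """
    pop_of = popmap.set_index("sample_id")["population"].reindex(gm.sample_ids)
    if pop_of.isna().any():
        missing = [s for s, v in zip(gm.sample_ids, pop_of.isna()) if v]
        raise ValueError(f"samples missing from population map: {missing[:5]}")
    if pops is None:
        pops = sorted(pop_of.unique())
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    groups = [np.flatnonzero(pop_of.to_numpy() == p) for p in pops]
    r = len(groups)

    n_i = np.empty((r, gm.n_sites))
    p_i = np.empty((r, gm.n_sites))
    h_i = np.empty((r, gm.n_sites))
    for k, idx in enumerate(groups):
        sub = gm.calls[idx]
        called = sub != MISSING
        cnt = called.sum(axis=0)
        if not cnt.any():
            raise ValueError(f"population {pops[k]} has zero calls at every site")
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n_i[k] = cnt
            p_i[k] = np.where(cnt > 0, alt / np.maximum(2 * cnt, 1), np.nan)
            h_i[k] = np.where(cnt > 0, (sub == 1).sum(axis=0) / np.maximum(cnt, 1), np.nan)

    valid = (n_i > 0).all(axis=0)
    n_i, p_i, h_i = n_i[:, valid], p_i[:, valid], h_i[:, valid]

    n_bar = n_i.mean(axis=0)
    n_tot = r * n_bar
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_tot

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2

    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (n_bar > 1) & (n_c > 0)
    a, b, c = a[ok], b[ok], c[ok]
    denom = a + b + c
    pos = denom > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_fst = float(np.mean(a[pos] / denom[pos])) if pos.any() else float("nan")
    weighted = float(a.sum() / denom.sum()) if denom.sum() != 0 else float("nan")
    return FstResult(a=a, b=b, c=c, mean_fst=mean_fst, weighted_fst=weighted)


def pairwise_fst(gm: GenotypeMatrix, popmap: pd.DataFrame, pops: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Fst matrix: mean-of-ratios above the diagonal, weighted below."""
    pop_of = popmap.set_index("sample_id")["population"].reindex(gm.sample_ids)
    if pops is None:
        pops = sorted(pop_of.dropna().unique())
    mat = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            res = wc_fst(gm, popmap, [p1, p2])
            mat.loc[p1, p2] = res.mean_fst
            mat.loc[p2, p1] = res.weighted_fst
    return mat


# ---------------------------------------------------------------------------
# SNP density

def snp_density(
    gm: GenotypeMatrix,
    window_bp: int = 10_000,
    contig_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-window SNP counts over each contig's full length, plus a summary."""
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    lengths = _contig_lengths(gm, contig_lengths)
    pos_all = gm.sites["pos"].to_numpy()
    contig_all = gm.sites["contig"].to_numpy()
    rows = []
    for contig, clen in lengths.items():
        edges = _window_edges(clen, window_bp)
        idx = np.flatnonzero(contig_all == contig)
        wbin = (pos_all[idx] - 1) // window_bp
        counts = np.bincount(wbin, minlength=len(edges) - 1)
        for w, cnt in enumerate(counts):
            rows.append((contig, int(edges[w]), int(edges[w + 1]), int(cnt)))
    windows = pd.DataFrame(rows, columns=["contig", "start", "end", "n_snps"])
    counts = windows["n_snps"].to_numpy()
    summary = {
        "mean": float(counts.mean()) if len(counts) else float("nan"),
        "median": float(np.median(counts)) if len(counts) else float("nan"),
        "max": int(counts.max()) if len(counts) else 0,
    }
    return windows, summary
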