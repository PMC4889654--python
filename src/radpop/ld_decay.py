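"""Within-contig pairwise r^2, distance binning, and decay-curve fitting.

r^2 is the squared Pearson correlation of unphased ALT dosages (genotype
r^2), computed pairwise-complete over samples with both genotypes called.
Pairs are binned by physical distance (default 50-bp bins) and a
count-weighted loess (tricube-kernel local linear regression) of bin mean
r^2 on bin midpoint gives the decay curve, its maximum ``r2_max``, and the
half-decay distance ``d_half`` — the first distance at which the fitted
curve falls to ``r2_max / 2``, located by linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix

PAIR_COLUMNS = ["contig", "pos_a", "pos_b", "distance", "r2", "n_obs"]


def _contig_pair_r2(calls: np.ndarray, min_obs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs pairwise-complete r^2 for one contig's samples x sites dosages.

    Returns (i_idx, j_idx, r2) for pairs with n_obs >= min_obs and positive
    variance in both dosage vectors, plus the n_obs per pair.
    """
    X = calls.astype(np.float64)
    M = (calls != MISSING).astype(np.float64)
    Xm = np.where(calls == MISSING, 0.0, X)
    n = M.T @ M                       # pairwise-complete counts
    sx = Xm.T @ M                     # sum of x over joint support (rows=x site)
    sxx = (Xm * Xm).T @ M
    sxy = Xm.T @ Xm
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        vx = sxx - sx**2 / n          # var of row-site over joint support
        vy = vx.T
        r2 = cov**2 / (vx * vy)
    iu, ju = np.triu_indices(calls.shape[1], k=1)
    r2u = r2[iu, ju]
    nu = n[iu, ju]
    ok = (nu >= min_obs) & np.isfinite(r2u)
    return iu[ok], ju[ok], np.column_stack([r2u[ok], nu[ok]])


def em_haplotype_r2(x: np.ndarray, y: np.ndarray, max_iter: int = 100,
                    tol: float = 1e-10) -> float:
    """r^2 from EM-estimated two-locus haplotype frequencies (unphased data).

    Resolves the double-heterozygote phase ambiguity by expectation-
    maximization on the 3x3 genotype contingency, starting from linkage
    equilibrium. Returns NaN for monomorphic input.
    """
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    n = len(x)
    if n == 0:
        return float("nan")
    table = np.zeros((3, 3))
    np.add.at(table, (x.astype(int), y.astype(int)), 1)
    pA = 1.0 - x.mean() / 2.0          # REF-allele frequencies
    pB = 1.0 - y.mean() / 2.0
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return float("nan")
    n_dh = table[1, 1]                 # double heterozygotes: phase unknown
    # known haplotype counts (AB, Ab, aB, ab) excluding double hets
    base = np.array([
        2 * table[0, 0] + table[0, 1] + table[1, 0],
        2 * table[0, 2] + table[0, 1] + table[1, 2],
        2 * table[2, 0] + table[2, 1] + table[1, 0],
        2 * table[2, 2] + table[2, 1] + table[1, 2],
    ], dtype=float)
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new = counts / counts.sum()
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    D = f[0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    return float(D * D / denom) if denom > 0 else float("nan")


def pairwise_r2(
    gm: GenotypeMatrix,
    max_distance: int | None = None,
    min_obs: int = 5,
    method: str = "genotype",
) -> pd.DataFrame:
    """r^2 for every same-contig site pair (optionally within ``max_distance``).

    ``method="genotype"`` (default) is the squared Pearson correlation of
    dosages; ``method="em"`` re-estimates each retained pair's r^2 from
    EM haplotype frequencies. Pairs where either dosage vector has zero
    variance over the jointly called samples, or with fewer than
    ``min_obs`` joint calls, are omitted.
    """
    if method not in ("genotype", "em"):
        raise ValueError(f"method must be 'genotype' or 'em', got {method!r}")
    rows = []
    contig_all = gm.sites["contig"].to_numpy()
    pos_all = gm.sites["pos"].to_numpy()
    for contig in dict.fromkeys(contig_all):
        idx = np.flatnonzero(contig_all == contig)
        if len(idx) < 2:
            continue
        i, j, stats = _contig_pair_r2(gm.calls[:, idx], min_obs)
        pos = pos_all[idx]
        dist = pos[j] - pos[i]
        keep = np.ones(len(dist), dtype=bool)
        if max_distance is not None:
            keep = dist <= max_distance
        r2 = np.clip(stats[keep, 0], 0.0, 1.0)
        if method == "em":
            sub = gm.calls[:, idx]
            r2 = np.array([
                em_haplotype_r2(sub[:, a], sub[:, b])
                for a, b in zip(i[keep], j[keep])
            ])
        rows.append(pd.DataFrame({
            "contig": contig,
            "pos_a": pos[i][keep],
            "pos_b": pos[j][keep],
            "distance": dist[keep],
            "r2": r2,
            "n_obs": stats[keep, 1].astype(int),
        }))
    if not rows:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(rows, ignore_index=True)


@dataclass
class DistanceBinSet:
    """50-bp (by default) distance bins of SNP pairs.

    ``bins`` has one row per bin index from 0 to the maximum observed
    (empty bins retained with count 0); ``pairs`` is the input pair table
    with a ``bin`` column added.
    """

    width: int
    bins: pd.DataFrame = field(repr=False)   # bin, lo, hi, count, mean_r2
    pairs: pd.DataFrame = field(repr=False)


def bin_by_distance(pairs: pd.DataFrame, width: int = 50) -> DistanceBinSet:
    """Assign each pair to bin ``floor(distance / width)`` and summarize."""
    if width < 1:
        raise ValueError("bin width must be >= 1")
    if len(pairs) == 0:
        raise ValueError("no pairs to bin")
    pairs = pairs.copy()
    pairs["bin"] = (pairs["distance"] // width).astype(int)
    n_bins = int(pairs["bin"].max()) + 1
    counts = np.bincount(pairs["bin"], minlength=n_bins)
    sums = np.bincount(pairs["bin"], weights=pairs["r2"], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    bins = pd.DataFrame({
        "bin": np.arange(n_bins),
        "lo": np.arange(n_bins) * width,
        "hi": (np.arange(n_bins) + 1) * width,
        "count": counts,
        "mean_r2": means,
    })
    return DistanceBinSet(width=width, bins=bins, pairs=pairs)


def weighted_loess(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, span: float = 0.3,
    degree: int = 2,
) -> np.ndarray:
    """Tricube-kernel local polynomial regression with observation weights.

    Fits y(x) at each x using the nearest ``span`` fraction of points,
    kernel-weighted by distance and multiplied by the per-point weights
    (here: pair counts per bin). Degree 2 (local quadratic) is the default:
    on convex decreasing curves like LD decay, local linear smoothing has a
    strong boundary/curvature bias that flattens the maximum, while the
    quadratic tracks it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 2)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.partition(d, min(k - 1, n - 1))[min(k - 1, n - 1)]
        h = max(h, 1e-12)
        tri = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        ww = tri * w
        if ww.sum() <= 0:
            fitted[i] = y[i]
            continue
        # centered design => intercept is the fitted value at x[i]
        X = np.vander(x - x[i], degree + 1, increasing=True)
        XtW = X.T * ww
        beta, *_ = np.linalg.lstsq(XtW @ X, XtW @ y, rcond=None)
        fitted[i] = beta[0]
    return fitted


@dataclass
class DecayCurve:
    """Smoothed r^2-vs-distance curve with its headline summaries.

    ``d_half`` is None when the fitted curve never falls to ``r2_max / 2``
    within the observed distance range.
    """

    grid: np.ndarray
    fitted: np.ndarray
    r2_max: float
    d_half: float | None
    span: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.grid, "fitted_r2": self.fitted})


def fit_decay(
    bins: DistanceBinSet,
    span: float = 0.3,
    use_fitted_max: bool = True,
) -> DecayCurve:
    """Fit the decay curve over non-empty bins and locate the half-decay point.

    Each bin contributes its midpoint distance and mean r^2, weighted by its
    pair count. ``r2_max`` is the maximum of the fitted curve (or of the raw
    bin means with ``use_fitted_max=False``); ``d_half`` is the first
    crossing of ``r2_max / 2`` at or after the argmax, by linear
    interpolation between adjacent grid points.
    """
    nb = bins.bins[bins.bins["count"] > 0]
    if len(nb) < 10:
        raise ValueError(f"need >= 10 non-empty bins, got {len(nb)}")
    x = (nb["lo"].to_numpy() + nb["hi"].to_numpy()) / 2.0
    y = nb["mean_r2"].to_numpy()
    w = nb["count"].to_numpy().astype(float)
    fitted = weighted_loess(x, y, w, span=span)
    r2_max = float(fitted.max()) if use_fitted_max else float(y.max())
    half = r2_max / 2.0
    start = int(np.argmax(fitted))
    d_half: float | None = None
    for i in range(start, len(fitted)):
        if fitted[i] <= half:
            if i == 0:
                d_half = float(x[0])
            else:
                x0, x1 = x[i - 1], x[i]
                y0, y1 = fitted[i - 1], fitted[i]
                if y0 == y1:
                    d_half = float(x1)
                else:
                    d_half = float(x0 + (y0 - half) * (x1 - x0) / (y0 - y1))
            break
    return DecayCurve(grid=x, fitted=fitted, r2_max=r2_max, d_half=d_half, span=span)


def decay_pipeline(
    gm: GenotypeMatrix,
    bin_width: int = 50,
    span: float = 0.3,
    max_distance: int | None = None,
    min_obs: int = 5,
) -> DecayCurve:
    """pairwise_r2 -> bin_by_distance -> fit_decay in one call."""
    pairs = pairwise_r2(gm, max_distance=max_distance, min_obs=min_obs)
    return fit_decay(bin_by_distance(pairs, bin_width), span=span)


def per_population_decay(
    gm: GenotypeMatrix,
    popmap: pd.DataFrame,
    min_samples: int = 5,
    bin_width: int = 50,
    span: float = 0.3,
    max_distance: int | None = None,
) -> dict[str, DecayCurve]:
    """Decay curve per population; populations below ``min_samples`` skipped."""
    pop_of = popmap.set_index("sample_id")["population"].reindex(gm.sample_ids)
    curves: dict[str, DecayCurve] = {}
    for pop in sorted(pop_of.dropna().unique()):
        idx = np.flatnonzero(pop_of.to_numpy() == pop)
        if len(idx) < min_samples:
            warnings.warn(f"population {pop} skipped: {len(idx)} < {min_samples} samples",
                          stacklevel=2)
            continue
        sub = gm.take_samples(idx)
        curves[pop] = decay_pipeline(sub, bin_width=bin_width, span=span,
                                     max_distance=max_distance)
    return curves
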