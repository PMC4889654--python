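"""Beta-distribution outlier test for abnormally high LD within distance bins.

Within each physical-distance bin, r^2 values are symmetrically shrunk into
the open interval (0, 1) via ``((x - 0.5) * theta) + 0.5`` (default theta =
0.999), a Beta distribution is fitted to the scaled values of the bin
(maximum likelihood, method-of-moments initialized), and each pair receives
``p_raw = 1 - CDF(scaled r^2)`` under its own bin's fit — the probability of
observing a more extreme value. Benjamini–Hochberg correction (globally
across all retained pairs by default, or per bin) then flags pairs with
adjusted p <= alpha (default 0.01) as LD outliers.

Bins with fewer than ``min_bin_size`` pairs are merged with the next bin
upward before fitting (Beta MLE is unstable on tiny samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ld_decay import DistanceBinSet

DEFAULT_THETA = 0.999


def scale_r2(values: np.ndarray | float, theta: float = DEFAULT_THETA) -> np.ndarray:
    """Shrink values in [0, 1] symmetrically about 0.5 into (0, 1).

    Elementwise ``((x - 0.5) * theta) + 0.5``; strictly monotone and
    invertible (:func:`unscale_r2`). 0.5 is the fixed point.
    """
    x = np.asarray(values, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("scale_r2 input outside [0, 1]")
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in (0, 1)")
    return (x - 0.5) * theta + 0.5


def unscale_r2(values: np.ndarray | float, theta: float = DEFAULT_THETA) -> np.ndarray:
    """Inverse of :func:`scale_r2`."""
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in (0, 1)")
    return (np.asarray(values, dtype=float) - 0.5) / theta + 0.5


@dataclass
class BetaFit:
    """Beta shapes fitted to one (possibly merged) distance bin."""

    bin: int
    shape_a: float
    shape_b: float
    n: int
    method: str           # "mle" or "moments"
    converged: bool
    merged_bins: tuple[int, ...] = ()


def moments_beta(values: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Beta shape estimates from sample mean and variance."""
    m = float(np.mean(values))
    v = float(np.var(values))
    if v <= 0 or not 0 < m < 1:
        return 1.0, 1.0
    common = m * (1.0 - m) / v - 1.0
    if common <= 0:
        return 1.0, 1.0
    return m * common, (1.0 - m) * common


def fit_beta(values: np.ndarray, bin_index: int = 0,
             merged: tuple[int, ...] = ()) -> BetaFit:
    """Fit Beta shapes to scaled values in (0, 1) by MLE.

    Initialized at the method-of-moments estimate; falls back to the
    moments estimate with ``converged=False`` if the optimizer fails or
    returns non-finite shapes.
    """
    values = np.asarray(values, dtype=float)
    if np.any((values <= 0) | (values >= 1)):
        raise ValueError("fit_beta requires values strictly in (0, 1); scale first")
    a0, b0 = moments_beta(values)
    try:
        a, b, _, _ = stats.beta.fit(values, a0, b0, floc=0.0, fscale=1.0)
        if np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0:
            return BetaFit(bin_index, float(a), float(b), len(values), "mle",
                           True, merged)
    except Exception:
        pass
    return BetaFit(bin_index, a0, b0, len(values), "moments", False, merged)


def _merge_small_bins(bin_sizes: pd.Series, min_bin_size: int) -> dict[int, int]:
    """Map each original bin index to the fit-group index it belongs to.

    Bins with fewer than ``min_bin_size`` pairs are merged with the next
    non-empty bin upward (larger distances); a trailing undersized group is
    merged downward into the last adequate group.
    """
    order = sorted(bin_sizes.index)
    mapping: dict[int, int] = {}
    group: list[int] = []
    total = 0
    last_target: int | None = None
    for b in order:
        group.append(b)
        total += int(bin_sizes[b])
        if total >= min_bin_size:
            target = group[-1]
            for g in group:
                mapping[g] = target
            last_target = target
            group, total = [], 0
    if group:
        target = last_target if last_target is not None else group[-1]
        for g in group:
            mapping[g] = target
    return mapping


def fit_bins(
    binset: DistanceBinSet,
    theta: float = DEFAULT_THETA,
    min_bin_size: int = 10,
) -> tuple[dict[int, BetaFit], pd.Series]:
    """Fit a Beta law to each (merged) distance bin of scaled r^2 values.

    Returns the fits keyed by fit-group index and the per-pair group
    assignment (aligned with ``binset.pairs``).
    """
    pairs = binset.pairs
    sizes = pairs.groupby("bin").size()
    mapping = _merge_small_bins(sizes, min_bin_size)
    groups = pairs["bin"].map(mapping)
    fits: dict[int, BetaFit] = {}
    for g, sub in pairs.groupby(groups):
        scaled = scale_r2(sub["r2"].to_numpy(), theta)
        merged = tuple(sorted(set(sub["bin"])))
        fits[int(g)] = fit_beta(scaled, bin_index=int(g), merged=merged)
    return fits, groups


def pair_probabilities(
    binset: DistanceBinSet,
    fits: dict[int, BetaFit],
    groups: pd.Series,
    theta: float = DEFAULT_THETA,
) -> pd.DataFrame:
    """Per-pair upper-tail probability under its own bin's Beta fit.

    ``p_raw = 1 - CDF(scaled r^2; shape_a, shape_b)`` — the regularized
    incomplete Beta complement. Pairs in bins without a fit are excluded.
    """
    pairs = binset.pairs.copy()
    pairs["fit_group"] = groups.to_numpy()
    pairs = pairs[pairs["fit_group"].isin(fits.keys())].copy()
    scaled = scale_r2(pairs["r2"].to_numpy(), theta)
    a = pairs["fit_group"].map({g: f.shape_a for g, f in fits.items()}).to_numpy()
    b = pairs["fit_group"].map({g: f.shape_b for g, f in fits.items()}).to_numpy()
    pairs["scaled_r2"] = scaled
    pairs["p_raw"] = stats.beta.sf(scaled, a, b)
    return pairs


def flag_outliers(
    probs: pd.DataFrame,
    alpha: float = 0.01,
    scope: str = "global",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """BH-correct the raw tail probabilities and flag pairs at ``alpha``.

    ``scope="global"`` pools all retained pairs into one BH family (the
    default: a single genome-wide flagged count); ``scope="bin"`` corrects
    within each fit group separately.
    """
    out = probs.copy()
    p = out["p_raw"].to_numpy()
    if scope == "global":
        out["p_adj"] = multipletests(p, method="fdr_bh")[1]
    elif scope == "bin":
        adj = np.empty(len(out))
        for _, idx in out.groupby("fit_group").indices.items():
            adj[idx] = multipletests(p[idx], method="fdr_bh")[1]
        out["p_adj"] = adj
    else:
        raise ValueError(f"scope must be 'global' or 'bin', got {scope!r}")
    out["flagged"] = out["p_adj"] <= alpha
    summary = {
        "flagged": int(out["flagged"].sum()),
        "total": int(len(out)),
        "fraction": float(out["flagged"].mean()) if len(out) else float("nan"),
    }
    return out, summary


def outlier_pipeline(
    binset: DistanceBinSet,
    theta: float = DEFAULT_THETA,
    alpha: float = 0.01,
    min_bin_size: int = 10,
    scope: str = "global",
) -> tuple[pd.DataFrame, dict[int, BetaFit], dict[str, float]]:
    """fit_bins -> pair_probabilities -> flag_outliers in one call."""
    fits, groups = fit_bins(binset, theta=theta, min_bin_size=min_bin_size)
    probs = pair_probabilities(binset, fits, groups, theta=theta)
    flagged, summary = flag_outliers(probs, alpha=alpha, scope=scope)
    return flagged, fits, summary
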