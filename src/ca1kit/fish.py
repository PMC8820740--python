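"""smFISH quantification: cell-body-layer boundary estimation, spot
distances, compartment calls and group comparisons.

The cell-body layer edge is estimated from nuclei positions: the image is
cut into vertical slices, a kernel-smoothed nuclei density along y is
computed per slice, and the anchor is where that density first falls below
10% of the slice maximum moving toward the neuropil. Because the 10% point
of a Gaussian-smoothed sharp edge lies z_0.90 x bandwidth beyond the edge,
that known offset is subtracted before fitting. Anchors are fit with a
polynomial in two rounds, removing |residual| > 2 SD outliers between
rounds (an automated stand-in for manual outlier curation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "BoundaryCurve",
    "estimate_boundary",
    "spot_distances",
    "classify_spots",
    "compare_probe_distributions",
    "binned_wt_ko_comparison",
]

NEUROPIL_DISTANCE_UM = 10.0
N_SLICES = 25
POLY_DEGREE = 3
DENSITY_BANDWIDTH_UM = 5.0
DENSITY_CROSSING = 0.10
OUTLIER_SD = 2.0
EDGE_OFFSET_Z = sps.norm.isf(DENSITY_CROSSING)  # 1.2816


@dataclass
class BoundaryCurve:
    """Fitted polynomial cell-body-layer boundary (ascending powers, µm)."""

    coeffs: np.ndarray
    degree: int
    anchors_x: np.ndarray
    anchors_y: np.ndarray
    round1_sd: float
    round2_sd: float
    n_outliers_removed: int
    x_range: tuple[float, float]
    neuropil_above: bool

    def __call__(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float),
                                                self.coeffs)


def _slice_anchor(ys: np.ndarray, bandwidth: float, neuropil_above: bool,
                  crossing: float = DENSITY_CROSSING) -> float:
    """Anchor of one slice: the y where the smoothed nuclei density first
    drops below ``crossing`` of its maximum moving toward the neuropil,
    minus the known smoothing offset of a sharp edge."""
    lo, hi = ys.min() - 4 * bandwidth, ys.max() + 4 * bandwidth
    grid = np.linspace(lo, hi, 400)
    dens = np.exp(-0.5 * ((grid[:, None] - ys[None, :]) / bandwidth) ** 2).sum(axis=1)
    peak = int(np.argmax(dens))
    thr = crossing * dens[peak]
    if neuropil_above:
        after = np.nonzero(dens[peak:] < thr)[0]
        y0 = grid[peak + after[0]] if len(after) else grid[-1]
        return float(y0 - EDGE_OFFSET_Z * bandwidth)
    before = np.nonzero(dens[: peak + 1][::-1] < thr)[0]
    y0 = grid[peak - before[0]] if len(before) else grid[0]
    return float(y0 + EDGE_OFFSET_Z * bandwidth)


def estimate_boundary(nuclei_um: np.ndarray, n_slices: int = N_SLICES,
                      degree: int = POLY_DEGREE,
                      bandwidth: float = DENSITY_BANDWIDTH_UM,
                      neuropil_above: bool = True,
                      outlier_sd: float = OUTLIER_SD) -> BoundaryCurve:
    """Fit the cell-body-layer boundary from nuclei coordinates (µm).

    Two rounds of polynomial least squares; anchors with |residual| >
    ``outlier_sd`` x SD after round 1 are removed before the refit.
    """
    pts = np.asarray(nuclei_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("nuclei_um must be an (n, 2) array of x, y in µm")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) <= 0:
        raise ValueError("degenerate x-range")
    edges = np.linspace(x.min(), x.max() + 1e-9, n_slices + 1)
    ax, ay = [], []
    for i in range(n_slices):
        sel = (x >= edges[i]) & (x < edges[i + 1])
        if sel.sum() < 3:
            continue
        ax.append(0.5 * (edges[i] + edges[i + 1]))
        ay.append(_slice_anchor(y[sel], bandwidth, neuropil_above))
    ax, ay = np.asarray(ax), np.asarray(ay)
    if len(ax) < degree + 2:
        raise ValueError(f"only {len(ax)} valid slices for degree-{degree} fit")
    c1 = np.polynomial.polynomial.polyfit(ax, ay, degree)
    res1 = ay - np.polynomial.polynomial.polyval(ax, c1)
    sd1 = float(res1.std(ddof=1))
    keep = np.abs(res1) <= outlier_sd * sd1 if sd1 > 0 else np.ones(len(ax), bool)
    if keep.sum() < degree + 2:
        keep = np.ones(len(ax), bool)
    c2 = np.polynomial.polynomial.polyfit(ax[keep], ay[keep], degree)
    res2 = ay[keep] - np.polynomial.polynomial.polyval(ax[keep], c2)
    sd2 = float(res2.std(ddof=1))
    return BoundaryCurve(coeffs=c2, degree=degree, anchors_x=ax[keep],
                         anchors_y=ay[keep], round1_sd=sd1, round2_sd=sd2,
                         n_outliers_removed=int((~keep).sum()),
                         x_range=(float(x.min()), float(x.max())),
                         neuropil_above=neuropil_above)


def _min_distance_to_curve(px, py, curve, x_lo, x_hi, step=0.1):
    """Minimum Euclidean distance from points to the densely sampled curve."""
    xs = np.arange(x_lo, x_hi + step, step)
    ys = curve(xs)
    d2 = (xs[None, :] - np.asarray(px)[:, None]) ** 2 + \
         (ys[None, :] - np.asarray(py)[:, None]) ** 2
    return np.sqrt(d2.min(axis=1))


def spot_distances(spots: pd.DataFrame, curve: BoundaryCurve,
                   step_um: float = 0.1) -> pd.DataFrame:
    """Signed minimum Euclidean distance from each spot to the fitted
    curve (positive toward the neuropil), by dense sampling of the curve
    at ``step_um``. Spots outside the curve's x-range get the distance to
    the nearest curve endpoint and are flagged."""
    x_lo, x_hi = curve.x_range
    px = spots["x_um"].to_numpy(dtype=float)
    py = spots["y_um"].to_numpy(dtype=float)
    d = _min_distance_to_curve(px, py, curve, x_lo, x_hi, step_um)
    above = py > curve(px.clip(x_lo, x_hi))
    sign = np.where(above == curve.neuropil_above, 1.0, -1.0)
    out = spots.copy()
    out["distance_um"] = sign * d
    out["outside_x_range"] = (px < x_lo) | (px > x_hi)
    return out


def classify_spots(distances: pd.DataFrame,
                   cutoff_um: float = NEUROPIL_DISTANCE_UM):
    """Compartment call per spot (neuropil iff distance > ``cutoff_um``,
    strict) and the per-table neuropil fraction."""
    out = distances.copy()
    out["compartment"] = np.where(out["distance_um"] > cutoff_um,
                                  "neuropil", "cell-body")
    frac = float((out["compartment"] == "neuropil").mean()) if len(out) else float("nan")
    return out, frac


def compare_probe_distributions(distances_a: np.ndarray, distances_b: np.ndarray,
                                fractions_a: np.ndarray | None = None,
                                fractions_b: np.ndarray | None = None,
                                alternative: str = "two-sided") -> dict:
    """Two-sample KS test on spot distance vectors, plus a Wilcoxon
    rank-sum test on per-image neuropil fractions when given (exact
    enumeration for small samples, normal approximation with tie
    correction otherwise, as implemented in scipy)."""
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need >= 5 observations per group for the KS test")
    ks = sps.ks_2samp(a, b)
    out = {"ks_D": float(ks.statistic), "ks_p": float(ks.pvalue)}
    if fractions_a is not None and fractions_b is not None:
        fa, fb = np.asarray(fractions_a, float), np.asarray(fractions_b, float)
        if len(fa) < 3 or len(fb) < 3:
            raise ValueError("need >= 3 images per group for the rank-sum test")
        method = "exact" if (len(fa) <= 8 and len(fb) <= 8) else "asymptotic"
        mw = sps.mannwhitneyu(fa, fb, alternative=alternative, method=method)
        out["wilcoxon_U"] = float(mw.statistic)
        out["wilcoxon_p"] = float(mw.pvalue)
    return out


def binned_wt_ko_comparison(tables_wt: list[pd.DataFrame],
                            tables_ko: list[pd.DataFrame],
                            n_sample: int = 1000, n_bins: int = 15,
                            bin_range: tuple[float, float] = (0.0, 150.0),
                            seed: int = 0) -> pd.DataFrame:
    """Per-bin t-tests of spot distance distributions between genotypes.

    From each image, ``n_sample`` spots are sampled (with replacement if
    the image has fewer, flagged by the ``resampled`` column), binned into
    ``n_bins`` equal-width distance bins, and converted to percent of
    sampled spots; a two-sample t-test per bin compares per-image percents
    between genotypes, BH-corrected across bins.
    """
    if len(tables_wt) < 2 or len(tables_ko) < 2:
        raise ValueError("need >= 2 images per genotype")
    rng = np.random.default_rng(seed)
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)

    def per_image(tables):
        pcts, resampled = [], False
        for t in tables:
            d = t["distance_um"].to_numpy(dtype=float)
            replace = len(d) < n_sample
            resampled |= replace
            samp = rng.choice(d, size=n_sample, replace=replace)
            hist, _ = np.histogram(samp, bins=edges)
            pcts.append(100.0 * hist / n_sample)
        return np.asarray(pcts), resampled

    wt, rs1 = per_image(tables_wt)
    ko, rs2 = per_image(tables_ko)
    rows = []
    for b in range(n_bins):
        t, p = sps.ttest_ind(wt[:, b], ko[:, b])
        rows.append({"bin": b, "bin_lo_um": edges[b], "bin_hi_um": edges[b + 1],
                     "mean_pct_wt": float(wt[:, b].mean()),
                     "mean_pct_ko": float(ko[:, b].mean()),
                     "t": float(t), "p": float(p),
                     "resampled": bool(rs1 or rs2)})
    out = pd.DataFrame(rows)
    out["FDR"] = bh_fdr(out["p"].to_numpy())
    return out
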