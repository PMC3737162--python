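"""Integer copy-number calling from binned read depth.

The chain mirrors the read-depth CN workflow used for heavily aneuploid
cell lines:

1. bin per-base depth into fixed windows (default 10 kb);
2. divide each bin by its mappable fraction, discarding (NA) bins where
   fewer than half the positions are uniquely mappable;
3. remove GC bias with a local-regression fit of coverage on GC fraction,
   rescaling the fitted curve to a target coverage;
4. take log2 ratios against the median adjusted coverage x0 of a curated
   copy-number-2 calibration region;
5. segment the log2 track (recursive binary segmentation, sd-undo merge);
   each segment mean s yields a CN estimate 2**(s+1);
6. fit a mixture of m normal components with means fixed at 1..m (weights
   and SDs free, EM), and assign each segment the integer CN with maximum
   posterior, requiring posterior >= 0.95; estimates below 0.5 — half the
   expectation for one copy — are called CN 0 before mixture classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .segmentation import segment_indices
from .tracks import BinnedTrack, make_bins

__all__ = [
    "CnSegment",
    "CnMixtureModel",
    "bin_depth",
    "mappability_correct",
    "gc_adjust",
    "log2_ratio",
    "segment_track",
    "fit_cn_mixture",
    "assign_copy_number",
    "cn_histogram",
    "call_copy_number",
]

MIN_MAPPABLE_FRACTION = 0.5  # below this a bin is NA
CN_ZERO_THRESHOLD = 0.5  # estimates below half of CN 1 are called 0
SD_FLOOR = 0.01  # 1% of the unit spacing between CN classes


@dataclass
class CnSegment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    n_bins: int
    cn_estimate: float = field(init=False)
    assigned_cn: Optional[int] = None
    posterior: Optional[float] = None

    def __post_init__(self):
        self.cn_estimate = float(2.0 ** (self.mean_log2 + 1.0))


@dataclass
class CnMixtureModel:
    """Normal mixture with means fixed at the integers 1..m."""

    m: int
    weights: np.ndarray
    sds: np.ndarray
    loglik: float
    calibration_x0: Optional[float] = None
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def means(self) -> np.ndarray:
        return np.arange(1, self.m + 1, dtype=float)

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "means": self.means.tolist(),
            "weights": self.weights.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "calibration_x0": self.calibration_x0,
        }


# --------------------------------------------------------------------- stage 1
def bin_depth(
    per_base_depth: Mapping[str, np.ndarray], bin_size: int = 10_000
) -> BinnedTrack:
    """Mean depth per fixed-width bin; the terminal partial bin is averaged
    over its actual length."""
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    lengths = {c: len(d) for c, d in per_base_depth.items()}
    grid = make_bins(lengths, bin_size)
    values = np.empty(len(grid))
    i = 0
    for chrom, depth in per_base_depth.items():
        depth = np.asarray(depth, dtype=float)
        if (depth < 0).any():
            raise ValueError(f"negative depth on {chrom}")
        n_bins = int(np.ceil(len(depth) / bin_size))
        for b in range(n_bins):
            values[i] = depth[b * bin_size : (b + 1) * bin_size].mean()
            i += 1
    grid["value"] = values
    return BinnedTrack(grid, validate=False)


# --------------------------------------------------------------------- stage 2
def mappability_correct(
    coverage: BinnedTrack, mappable_fraction: BinnedTrack
) -> BinnedTrack:
    """Divide coverage by the bin's mappable fraction; bins with fraction
    below 0.5 are discarded (NA)."""
    coverage.require_same_grid(mappable_fraction, "mappability_correct")
    frac = mappable_fraction.values
    out = coverage.values.copy()
    low = frac < MIN_MAPPABLE_FRACTION
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(low, np.nan, out / frac)
    return coverage.with_values(out)


# --------------------------------------------------------------------- stage 3
def _tricube_local_linear(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float,
    robust_iter: int = 3,
) -> np.ndarray:
    """Local linear regression with tricube weights and bisquare
    robustifying iterations.

    The robust reweighting matters on copy-number data: within a GC window
    bins mix several CN states, and a plain local mean tracks the local CN
    composition rather than the GC effect.  Downweighting residual outliers
    makes the curve follow the dominant (modal) CN state, which is the
    quantity the adjustment should rescale.

    ``span`` is the LOESS convention: the fraction of points in each local
    window (k-nearest-neighbor bandwidth), so sparse tails of the GC
    distribution get wider, stable windows instead of a handful of points.
    """
    n = len(x)
    k = max(int(np.ceil(span * n)), 10)
    if np.ptp(x) <= 0:
        return np.full_like(x_eval, np.median(y))
    rw = np.ones_like(y)

    def _fit_at(x0: float) -> float:
        d = np.abs(x - x0)
        h = np.partition(d, min(k - 1, n - 1))[min(k - 1, n - 1)]
        u = d / max(h, 1e-12)
        w = np.where(u <= 1, (1 - np.minimum(u, 1) ** 3) ** 3, 0.0) * rw
        w[u <= 1e-12] = np.maximum(w[u <= 1e-12], 1e-12)
        if w.sum() <= 0:
            w = np.where(u <= 1, 1.0, 0.0)
        dx = x - x0
        sqw = np.sqrt(w)
        # local quadratic: captures the curvature of a smooth bias without
        # the boundary/peak bias a local line leaves behind
        design = np.column_stack([np.ones_like(dx), dx, dx * dx]) * sqw[:, None]
        coef, *_ = np.linalg.lstsq(design, y * sqw, rcond=None)
        return float(coef[0])

    for _ in range(robust_iter):
        # evaluate on the requested grid and interpolate for residuals
        f_grid = np.array([_fit_at(xi) for xi in x_eval])
        resid = y - np.interp(x, x_eval, f_grid)
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = resid / (6.0 * s)
        rw = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return np.array([_fit_at(xi) for xi in x_eval])


def _running_median(v: np.ndarray, window: int) -> np.ndarray:
    """Centered running median (edges use the available half-window)."""
    n = len(v)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        out[i] = np.median(v[max(0, i - half) : min(n, i + half + 1)])
    return out


def gc_adjust(
    coverage: BinnedTrack,
    gc_fraction: BinnedTrack,
    target_coverage: float = 60.0,
    span: float = 0.3,
    grid_points: int = 101,
    level_window: int = 15,
) -> BinnedTrack:
    """Remove GC bias by a local fit f(gc) of coverage on GC fraction.

    Adjusted value = value / (f(gc) / target_coverage).  NA propagates.

    The curve is estimated on coverage divided by a per-chromosome running
    median (``level_window`` bins): the running median carries the local
    copy-number level, so the remaining ratio depends on GC alone and the
    fit is not confounded by which CN states happen to occupy a GC window.
    ``span`` is the LOESS fraction-of-points bandwidth of the local
    quadratic fit; the fitted shape is rescaled back to coverage units.
    """
    coverage.require_same_grid(gc_fraction, "gc_adjust")
    cov = coverage.values
    gc = gc_fraction.values
    ok = ~np.isnan(cov) & ~np.isnan(gc)
    if ok.sum() < 50:
        raise ValueError(
            f"gc_adjust: only {int(ok.sum())} non-NA bins; at least 50 required"
        )

    # local CN level per bin, computed on the non-NA run of each chromosome
    level = np.full(len(cov), np.nan)
    chrom_arr = coverage.df["chrom"].to_numpy()
    for chrom in coverage.chroms:
        idx = np.where((chrom_arr == chrom) & ok)[0]
        if len(idx):
            level[idx] = _running_median(cov[idx], level_window)

    usable = ok & (level > 0)
    if usable.sum() < 50:
        raise ValueError("gc_adjust: too few bins with positive local level")
    x = gc[usable]
    y = cov[usable] / level[usable]
    grid = np.linspace(gc[ok].min(), gc[ok].max(), grid_points)
    shape_grid = _tricube_local_linear(x, y, grid, span)
    bad = shape_grid <= 0
    if bad.any():
        raise FloatingPointError(
            f"gc_adjust: fitted curve non-positive at GC={grid[bad][0]:.3f}"
        )
    shape_at_bins = np.interp(gc, grid, shape_grid)
    # rescale the dimensionless shape back to coverage units
    scale = float(np.median(cov[usable] / shape_at_bins[usable]))
    f_at_bins = shape_at_bins * scale
    out = np.where(ok, cov / (f_at_bins / target_coverage), np.nan)
    return coverage.with_values(out)


# --------------------------------------------------------------------- stage 4
def log2_ratio(
    adjusted: BinnedTrack,
    calibration_region: tuple[str, int, int],
    region_cn: int = 2,
) -> tuple[BinnedTrack, float]:
    """log2(value / x0) with x0 the median adjusted coverage in the
    user-supplied CN-2 calibration region.

    ``region_cn`` allows calibrating on a curated region of known CN other
    than 2; the median is rescaled by 2/region_cn so the log2 scale keeps
    its meaning (0 = two copies).
    """
    chrom, start, end = calibration_region
    if region_cn < 1:
        raise ValueError("region_cn must be >= 1")
    mask = adjusted.overlap_mask(chrom, start, end)
    region_vals = adjusted.values[mask]
    region_vals = region_vals[~np.isnan(region_vals)]
    if len(region_vals) < 10:
        raise ValueError(
            f"log2_ratio: calibration region {chrom}:{start}-{end} overlaps "
            f"only {len(region_vals)} non-NA bins (need >= 10)"
        )
    x0 = float(np.median(region_vals)) * 2.0 / region_cn
    ratio = adjusted.values / x0
    # zero-coverage bins (true CN-0 territory) are floored, not dropped, so
    # they survive to segmentation and trigger the CN-0 rule downstream
    ratio = np.where(~np.isnan(ratio) & (ratio < 2.0**-8), 2.0**-8, ratio)
    out = np.log2(ratio)
    return adjusted.with_values(out), x0


# --------------------------------------------------------------------- stage 5
def segment_track(
    log2_track: BinnedTrack,
    undo_sd: float = 2.0,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[CnSegment]:
    """Per-chromosome changepoint segmentation of the non-NA bins.

    Segment coordinates span from the start of their first non-NA bin to the
    end of their last; all-NA chromosomes contribute no segments.
    """
    segments: list[CnSegment] = []
    for chrom in log2_track.chroms:
        sub = log2_track.chrom_view(chrom)
        vals = sub["value"].to_numpy()
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        x = vals[ok]
        starts = sub["start"].to_numpy()[ok]
        ends = sub["end"].to_numpy()[ok]
        for i0, i1 in segment_indices(
            x, alpha=alpha, n_perm=n_perm, undo_sd=undo_sd, seed=seed
        ):
            segments.append(
                CnSegment(
                    chrom=chrom,
                    start=int(starts[i0]),
                    end=int(ends[i1 - 1]),
                    mean_log2=float(x[i0:i1].mean()),
                    n_bins=i1 - i0,
                )
            )
    return segments


# --------------------------------------------------------------------- stage 6
def fit_cn_mixture(
    segments: list[CnSegment],
    m: int = 8,
    weight_by_bins: bool = True,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> CnMixtureModel:
    """EM fit of a normal mixture with means fixed at 1..m to segment CN
    estimates, each segment weighted by its bin count (genome-fraction
    interpretation) unless ``weight_by_bins`` is off.

    Component SDs are floored at 0.01 CN units: segment estimates carry at
    least that much fit wobble, and letting an SD collapse to zero makes
    the downstream Bayes classifier assign near-integer estimates to a
    leftover broad component instead of the obvious nearest one.
    """
    x = np.array([s.cn_estimate for s in segments], dtype=float)
    c = (
        np.array([s.n_bins for s in segments], dtype=float)
        if weight_by_bins
        else np.ones(len(segments))
    )
    if c.sum() < m:
        raise ValueError(
            f"fit_cn_mixture: {c.sum():.0f} weighted data points < m={m}"
        )
    means = np.arange(1, m + 1, dtype=float)
    weights = np.full(m, 1.0 / m)
    mu = (c * x).sum() / c.sum()
    sds = np.full(m, max(np.sqrt((c * (x - mu) ** 2).sum() / c.sum()), SD_FLOOR))

    def _loglik(w, s):
        dens = w[None, :] * norm.pdf(x[:, None], means[None, :], s[None, :])
        return float((c * np.log(np.maximum(dens.sum(axis=1), 1e-300))).sum())

    ll = _loglik(weights, sds)
    trace = [ll]
    for _ in range(max_iter):
        dens = weights[None, :] * norm.pdf(x[:, None], means[None, :], sds[None, :])
        total = np.maximum(dens.sum(axis=1, keepdims=True), 1e-300)
        resp = dens / total
        cw = (c[:, None] * resp).sum(axis=0)
        weights = cw / cw.sum()
        sq = (c[:, None] * resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
        sds = np.sqrt(np.where(cw > 0, sq / np.maximum(cw, 1e-300), SD_FLOOR**2))
        sds = np.maximum(sds, SD_FLOOR)
        new_ll = _loglik(weights, sds)
        # EM guarantee, modulo the sd floor
        assert new_ll >= ll - 1e-6, "EM log-likelihood decreased"
        trace.append(new_ll)
        if abs(new_ll - ll) < tol:
            ll = new_ll
            break
        ll = new_ll
    return CnMixtureModel(m=m, weights=weights, sds=sds, loglik=ll, loglik_trace=trace)


def assign_copy_number(
    segments: list[CnSegment],
    model: CnMixtureModel,
    min_posterior: float = 0.95,
) -> list[CnSegment]:
    """Bayes classification of segments to integer CN.

    Mixture weights act as prior probabilities; a segment gets the argmax
    component if its posterior reaches ``min_posterior``, else NA.  Segments
    with CN estimate below 0.5 are called CN 0 before classification (the
    fixed-mean mixture has no zero component).
    """
    means = model.means
    for seg in segments:
        if seg.cn_estimate < CN_ZERO_THRESHOLD:
            seg.assigned_cn = 0
            seg.posterior = None
            continue
        dens = model.weights * norm.pdf(seg.cn_estimate, means, model.sds)
        total = dens.sum()
        if total <= 0:
            seg.assigned_cn = None
            seg.posterior = None
            continue
        post = dens / total
        k = int(np.argmax(post))
        seg.posterior = float(post[k])
        seg.assigned_cn = int(means[k]) if post[k] >= min_posterior else None
    return segments


def cn_histogram(segments: list[CnSegment]) -> dict:
    """Genome fraction per assigned CN class (NA included); sums to 1."""
    total = float(sum(s.end - s.start for s in segments))
    if total == 0:
        return {}
    frac: dict = {}
    for s in segments:
        key = s.assigned_cn if s.assigned_cn is not None else "NA"
        frac[key] = frac.get(key, 0.0) + (s.end - s.start) / total
    return frac


# ------------------------------------------------------------------ pipeline
def call_copy_number(
    coverage: BinnedTrack,
    gc: BinnedTrack,
    mappability: BinnedTrack,
    calibration_region: tuple[str, int, int],
    calibration_cn: int = 2,
    target_coverage: float = 60.0,
    span: float = 0.3,
    m: int = 8,
    min_posterior: float = 0.95,
    undo_sd: float = 2.0,
    seed: int = 0,
) -> tuple[list[CnSegment], CnMixtureModel, BinnedTrack]:
    """Full chain: mappability masking, GC adjustment, log2 calibration,
    segmentation, mixture fit, Bayes assignment.

    Returns (assigned segments, fitted model, log2 track).
    """
    corrected = mappability_correct(coverage, mappability)
    adjusted = gc_adjust(corrected, gc, target_coverage=target_coverage, span=span)
    log2_track, x0 = log2_ratio(adjusted, calibration_region, region_cn=calibration_cn)
    segments = segment_track(log2_track, undo_sd=undo_sd, seed=seed)
    model = fit_cn_mixture(segments, m=m)
    model.calibration_x0 = x0
    segments = assign_copy_number(segments, model, min_posterior=min_posterior)
    return segments, model, log2_track


def segments_to_frame(segments: list[CnSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_bins": [s.n_bins for s in segments],
            "mean_log2": [s.mean_log2 for s in segments],
            "cn_estimate": [s.cn_estimate for s in segments],
            "assigned_cn": [s.assigned_cn for s in segments],
            "posterior": [s.posterior for s in segments],
        }
    )
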