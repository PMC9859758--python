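"""Automatic annotation of microtubule growth and shrinkage phases.

Punctum-to-SPB distance trajectories are annotated in four steps:

1. Savitzky-Golay smoothing (polynomial order 1, window 5 frames by
   default; for a symmetric window and order 1 this is exactly the centred
   moving average).
2. Changepoint detection on the smoothed series: for each candidate number
   of changepoints k the segmentation minimising the total residual sum of
   squares of per-segment least-squares lines is found by exact dynamic
   programming, subject to a minimum segment length; k is selected by BIC.
3. Refinement of each changepoint to the nearest local extremum of the
   *unfiltered* series whose topographic prominence is at least a fraction
   of the trajectory's full length range.
4. Classification of the intervals between boundaries by ordinary least
   squares on the unfiltered data: significantly positive slope -> growth,
   significantly negative -> shrinkage, otherwise indeterminate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from tipbody.trajectory import GROWTH, INDETERMINATE, SHRINKAGE, Trajectory

_PERFECT_FIT_RTOL = 1e-12


@dataclass
class AnnotationConfig:
    """Tunable parameters of the four-step annotation.

    Defaults mirror a standard plus-end tracking analysis: order-1
    Savitzky-Golay filter over 5 frames, at most 5 changepoints at least
    5 frames apart, 25% peak prominence for extremum refinement, and a 5%
    significance level for the per-segment slope t-tests.
    """

    sg_polyorder: int = 1
    sg_window: int = 5
    max_changes: int = 5
    min_distance: int = 5
    prominence_frac: float = 0.25
    alpha: float = 0.05
    min_segment_points: int = 3
    penalty_mult: float = 1.0  # multiplies the BIC parameter penalty

    def __post_init__(self) -> None:
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd and >= 3")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.prominence_frac <= 1):
            raise ValueError("prominence_frac must lie in (0, 1]")
        if self.min_distance < 1 or self.max_changes < 0:
            raise ValueError("min_distance >= 1 and max_changes >= 0 required")
        if self.min_segment_points < 3:
            raise ValueError("min_segment_points must be >= 3 (slope t-test needs >= 1 df)")


@dataclass
class PhaseSegment:
    """A contiguous frame interval with its phase call.

    ``start_frame``/``end_frame`` are inclusive 0-based indices; boundary
    frames are shared between adjacent segments. ``slope`` is in response
    units per second when times are supplied to the classifier, otherwise
    per frame. ``intercept`` is the fitted value at the segment start.
    """

    start_frame: int
    end_frame: int
    kind: str
    slope: float = float("nan")
    intercept: float = float("nan")
    slope_p: float = float("nan")

    @property
    def n_points(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class PhaseAnnotation:
    """Result of the full annotation of one trajectory."""

    changepoints: list[int]
    boundaries: list[int]
    segments: list[PhaseSegment]
    n_frames: int
    warnings: list[str] = field(default_factory=list)

    def frame_labels(self) -> np.ndarray:
        """Per-frame phase label; a shared boundary frame takes the label
        of the earlier segment."""
        labels = np.full(self.n_frames, INDETERMINATE, dtype=object)
        for seg in reversed(self.segments):
            labels[seg.start_frame : seg.end_frame + 1] = seg.kind
        return labels


def smooth_trajectory(series: np.ndarray, config: AnnotationConfig | None = None) -> np.ndarray:
    """Savitzky-Golay smoothing with symmetric window shrinkage at edges.

    At each point a polynomial of ``sg_polyorder`` is least-squares fitted
    over the largest symmetric window not exceeding ``sg_window`` and
    evaluated at the centre. Order 1 over a symmetric window reduces to the
    centred moving average. Series shorter than 3 points are returned
    unchanged with a warning.
    """
    config = config or AnnotationConfig()
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < config.sg_window:
        warnings.warn(
            f"series of length {n} shorter than smoothing window {config.sg_window}; "
            "shrinking window (series < 3 points returned unchanged)",
            stacklevel=2,
        )
    if n < 3:
        return y.copy()
    half = config.sg_window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        lo, hi = i - h, i + h + 1
        if config.sg_polyorder >= 1 and h == 0:
            out[i] = y[i]
            continue
        order = min(config.sg_polyorder, 2 * h)
        x = np.arange(lo, hi) - i
        coeffs = np.polynomial.polynomial.polyfit(x, y[lo:hi], order)
        out[i] = coeffs[0]
    return out


def _segment_cost_factory(y: np.ndarray):
    """O(1) residual sum of squares of a least-squares line on y[i:j]."""
    x = np.arange(len(y), dtype=float)
    c1 = np.concatenate(([0.0], np.cumsum(np.ones_like(x))))
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))

    def cost(i: int, j: int) -> float:
        n = c1[j] - c1[i]
        sx = cx[j] - cx[i]
        sy = cy[j] - cy[i]
        sxx = cxx[j] - cxx[i]
        sxy = cxy[j] - cxy[i]
        syy = cyy[j] - cyy[i]
        sxx_c = sxx - sx * sx / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy * sy / n
        if sxx_c <= 0:
            return max(syy_c, 0.0)
        return max(syy_c - sxy_c * sxy_c / sxx_c, 0.0)

    return cost


def detect_changepoints(series: np.ndarray, config: AnnotationConfig | None = None) -> list[int]:
    """Optimal piecewise-linear changepoints of a series.

    For each k in 0..max_changes, exact dynamic programming finds the
    k-changepoint segmentation minimising the summed per-segment linear-fit
    RSS with every segment at least ``min_distance`` frames long; the
    returned k minimises BIC = n*ln(RSS/n) + m*(3k + 2)*ln(n) with penalty
    multiplier m. Changepoints are 0-based indices of the first frame of
    each new segment.
    """
    config = config or AnnotationConfig()
    y = np.asarray(series, dtype=float)
    n = len(y)
    d = config.min_distance
    if n < 2 * d:
        return []
    cost = _segment_cost_factory(y)
    kmax = min(config.max_changes, n // d - 1)

    # dp[k][j]: best RSS of y[0:j] split into k+1 segments, each >= d frames
    NEG = -1
    dp = np.full((kmax + 1, n + 1), np.inf)
    back = np.full((kmax + 1, n + 1), NEG, dtype=int)
    for j in range(d, n + 1):
        dp[0][j] = cost(0, j)
    for k in range(1, kmax + 1):
        for j in range((k + 1) * d, n + 1):
            best, arg = np.inf, NEG
            for i in range(k * d, j - d + 1):
                c = dp[k - 1][i] + cost(i, j)
                if c < best - 1e-15:
                    best, arg = c, i
            dp[k][j], back[k][j] = best, arg

    logn = np.log(n)
    floor = max(np.var(y), 1.0) * n * 1e-15  # guards log of an exact fit
    best_k, best_bic = 0, np.inf
    for k in range(kmax + 1):
        rss = dp[k][n]
        if not np.isfinite(rss):
            continue
        bic = n * np.log(max(rss, floor) / n) + config.penalty_mult * (3 * k + 2) * logn
        if bic < best_bic - 1e-12:
            best_k, best_bic = k, bic
    cps: list[int] = []
    j, k = n, best_k
    while k > 0:
        i = back[k][j]
        cps.append(int(i))
        j, k = i, k - 1
    return sorted(cps)


def refine_extrema(
    series: np.ndarray, changepoints: list[int], config: AnnotationConfig | None = None
) -> list[int]:
    """Snap changepoints to nearby prominent extrema of the raw series.

    Qualifying extrema are local maxima of the series or of its negation
    with topographic prominence at least ``prominence_frac`` times the full
    range of the series. Each changepoint moves to the nearest qualifying
    extremum (ties broken toward the earlier frame); with no qualifying
    extremum the changepoint itself is kept. Result is sorted and
    de-duplicated.
    """
    config = config or AnnotationConfig()
    if not changepoints:
        return []
    y = np.asarray(series, dtype=float)
    rng_y = float(np.max(y) - np.min(y))
    if rng_y <= 0:
        return sorted(set(int(c) for c in changepoints))
    thr = config.prominence_frac * rng_y
    maxima, _ = signal.find_peaks(y, prominence=thr)
    minima, _ = signal.find_peaks(-y, prominence=thr)
    candidates = np.sort(np.concatenate([maxima, minima]))
    out = []
    for cp in changepoints:
        if len(candidates) == 0:
            out.append(int(cp))
            continue
        dist = np.abs(candidates - cp)
        # argmin returns the first (earlier) index on ties
        out.append(int(candidates[int(np.argmin(dist))]))
    return sorted(set(out))


def _ols_segment(t: np.ndarray, y: np.ndarray, alpha: float) -> tuple[float, float, float]:
    """Slope, intercept-at-start and two-sided slope p-value of an OLS line."""
    t0 = t - t[0]
    n = len(y)
    res = stats.linregress(t0, y)
    slope, intercept = float(res.slope), float(res.intercept)
    fitted = intercept + slope * t0
    rss = float(np.sum((y - fitted) ** 2))
    scale = max(float(np.sum((y - np.mean(y)) ** 2)), 1.0)
    if rss <= _PERFECT_FIT_RTOL * scale:
        slope_zero = abs(slope) * np.ptp(t0) <= 1e-9 * (np.max(np.abs(y)) + 1.0)
        p = 1.0 if slope_zero else 0.0
    else:
        p = float(res.pvalue)
    return slope, intercept, p


def classify_phases(
    series: np.ndarray,
    boundaries: list[int],
    config: AnnotationConfig | None = None,
    times: np.ndarray | None = None,
) -> list[PhaseSegment]:
    """OLS-based phase calls for the intervals between boundaries.

    Segments run between consecutive boundaries (plus the trajectory ends),
    sharing the boundary frames. Each segment with at least
    ``min_segment_points`` frames is fitted by OLS on the unfiltered data;
    a significantly positive slope is growth, significantly negative is
    shrinkage, anything else indeterminate. Shorter segments are
    indeterminate with missing statistics. ``times`` (seconds) puts slopes
    in per-second units; by default slopes are per frame.
    """
    config = config or AnnotationConfig()
    y = np.asarray(series, dtype=float)
    n = len(y)
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, dtype=float)
    edges = sorted(set([0] + [int(b) for b in boundaries if 0 <= b <= n - 1] + [n - 1]))
    segments = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        npts = hi - lo + 1
        if npts < config.min_segment_points:
            segments.append(PhaseSegment(lo, hi, INDETERMINATE))
            continue
        slope, intercept, p = _ols_segment(t[lo : hi + 1], y[lo : hi + 1], config.alpha)
        if p < config.alpha and slope > 0:
            kind = GROWTH
        elif p < config.alpha and slope < 0:
            kind = SHRINKAGE
        else:
            kind = INDETERMINATE
        segments.append(PhaseSegment(lo, hi, kind, slope, intercept, p))
    return segments


def annotate(traj: Trajectory, config: AnnotationConfig | None = None) -> PhaseAnnotation:
    """Full four-step annotation of one trajectory's length series.

    Annotation runs on the longest prefix of non-missing length values.
    Smoothing feeds only the changepoint detector; extremum refinement and
    phase classification use the unfiltered series.
    """
    config = config or AnnotationConfig()
    length = np.asarray(traj.length, dtype=float)
    missing = np.isnan(length)
    n_valid = int(np.argmax(missing)) if missing.any() else len(length)
    warn: list[str] = []
    if n_valid < len(length):
        warn.append(f"annotating first {n_valid} of {len(length)} frames (missing values)")
    y = length[:n_valid]
    t = traj.time[:n_valid]
    if n_valid < config.min_segment_points:
        return PhaseAnnotation(
            [], [], [PhaseSegment(0, max(n_valid - 1, 0), INDETERMINATE)], n_valid, warn
        )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        smoothed = smooth_trajectory(y, config)
    warn.extend(str(w.message) for w in caught)
    cps = detect_changepoints(smoothed, config)
    bounds = refine_extrema(y, cps, config)
    segments = classify_phases(y, bounds, config, times=t)
    return PhaseAnnotation(cps, bounds, segments, n_valid, warn)


def display_smooth(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving-average smoothing for display only (never feeds analysis)."""
    y = np.asarray(series, dtype=float)
    if window < 2 or len(y) < window:
        return y.copy()
    kernel = np.ones(window) / window
    out = np.convolve(y, kernel, mode="same")
    # fix the edges with shrunken symmetric windows
    half = window // 2
    n = len(y)
    for i in range(half):
        out[i] = y[: 2 * i + 1].mean()
        out[n - 1 - i] = y[n - 1 - 2 * i :].mean()
    return out
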