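"""LOWESS smoothing and Chow-test structural-breakpoint detection.

This is the threshold engine: the per-ELN log-effect sequence (log odds
ratio or log hazard ratio against the reference count) is smoothed with
locally weighted scatterplot smoothing (tricube kernel, local linear
fits, bisquare robustification, default bandwidth 2/3), and the
structural breakpoint of the fitted series is located by a Chow-type
sup-F scan: at every admissible split the F statistic compares a pooled
straight-line fit against two segment-wise straight lines, and the split
maximising F is the estimated breakpoint.

Smoothing and testing operate on the log-effect scale; display code
exponentiates.  The naive F reference distribution (the one conventionally
reported alongside such scans) is complemented by an optional permutation
calibration that accounts for the breakpoint being estimated rather than
prespecified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SmoothedSeries",
    "BreakpointResult",
    "lowess_smooth",
    "chow_f",
    "find_breakpoint",
    "sequence_breakpoint",
]

DEFAULT_BANDWIDTH = 2.0 / 3.0


class DomainError(ValueError):
    pass


@dataclass
class SmoothedSeries:
    """A LOWESS fit over the ELN axis, smoothing parameters included."""

    x: np.ndarray
    y_raw: np.ndarray
    y_fit: np.ndarray
    bandwidth: float = DEFAULT_BANDWIDTH
    robustify_iterations: int = 3
    weights: np.ndarray | None = None

    def values(self, use: str = "smoothed") -> np.ndarray:
        if use == "smoothed":
            return self.y_fit
        if use == "raw":
            return self.y_raw
        raise ValueError(f"unknown series choice {use!r}")


@dataclass
class BreakpointResult:
    """Outcome of the sup-F scan over candidate splits."""

    break_x: float
    f_statistic: float
    p_value: float
    left_fit: tuple  # (intercept, slope, rss)
    right_fit: tuple
    pooled_fit: tuple
    n_left: int
    n_right: int
    candidate_scan: dict = field(default_factory=dict)
    no_break: bool = False
    permutation_p: float | None = None


def lowess_smooth(
    x, y, bandwidth: float = DEFAULT_BANDWIDTH, robustify_iterations: int = 3, weights=None
) -> SmoothedSeries:
    """Locally weighted scatterplot smoothing (Cleveland's LOWESS).

    At each point the nearest ``ceil(bandwidth * n)`` neighbours are fit
    by weighted linear regression with tricube distance weights; the fit
    is then robustified ``robustify_iterations`` times with bisquare
    weights of the residuals.  Optional prior ``weights`` (for example,
    per-ELN-level patient counts) multiply the kernel weights.
    Deterministic; requires at least 5 strictly increasing x values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise DomainError("x and y must be one-dimensional and of equal length")
    if len(x) < 5:
        raise DomainError("LOWESS requires at least 5 points")
    if np.any(np.diff(x) <= 0):
        raise DomainError("x must be strictly increasing")
    if not 0 < bandwidth <= 1:
        raise DomainError("bandwidth must lie in (0, 1]")
    n = len(x)
    # neighbourhood size per the canonical LOWESS routine: trunc(f*n + eps)
    k = max(2, min(n, int(bandwidth * n + 1e-7)))
    prior = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if prior.shape != x.shape or np.any(prior < 0):
        raise DomainError("weights must be non-negative and match x in length")

    robust = np.ones(n)
    y_fit = np.empty(n)
    for iteration in range(robustify_iterations + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            h = np.partition(d, k - 1)[k - 1]
            if h <= 0:
                y_fit[i] = y[i]
                continue
            u = np.clip(d / h, 0, 1)
            w = (1 - u**3) ** 3 * robust * prior
            sw = w.sum()
            if sw <= 0:
                y_fit[i] = y[i]
                continue
            xm = (w * x).sum() / sw
            ym = (w * y).sum() / sw
            sxx = (w * (x - xm) ** 2).sum()
            if sxx <= 1e-12 * max(1.0, xm**2):
                y_fit[i] = ym
            else:
                slope = (w * (x - xm) * (y - ym)).sum() / sxx
                y_fit[i] = ym + slope * (x[i] - xm)
        if iteration == robustify_iterations:
            break
        resid = y - y_fit
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        robust = np.clip(1 - (resid / (6.0 * s)) ** 2, 0, 1) ** 2
    return SmoothedSeries(
        x=x,
        y_raw=y,
        y_fit=y_fit,
        bandwidth=bandwidth,
        robustify_iterations=robustify_iterations,
        weights=None if weights is None else prior,
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple:
    """Least-squares straight line; returns (intercept, slope, rss)."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def chow_f(x, y, split_x, min_segment: int = 3) -> tuple:
    """Chow test of a single structural break at a prespecified split.

    Segments are the points with ``x <= split_x`` and ``x > split_x``;
    with k = 2 line parameters per segment,

        F = [(RSS_pooled - RSS1 - RSS2)/k] / [(RSS1 + RSS2)/(n1 + n2 - 2k)]

    and the p-value comes from the F(k, n1+n2-2k) distribution.  A series
    fit perfectly by every line involved (all RSS zero) has F defined as
    0 — no evidence of a break.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    left = x <= split_x
    n1, n2 = int(left.sum()), int((~left).sum())
    if n1 < min_segment or n2 < min_segment:
        raise DomainError(
            f"split at {split_x} leaves segments of {n1} and {n2} points; "
            f"both need at least {min_segment}"
        )
    k = 2
    _, _, rss_pool = _ols_line(x, y)
    l_fit = _ols_line(x[left], y[left])
    r_fit = _ols_line(x[~left], y[~left])
    rss_seg = l_fit[2] + r_fit[2]
    dof = n1 + n2 - 2 * k
    if rss_seg <= 1e-14 and rss_pool <= 1e-14:
        return 0.0, 1.0
    if rss_seg <= 1e-14:
        return float("inf"), 0.0
    f = ((rss_pool - rss_seg) / k) / (rss_seg / dof)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, k, dof))
    return float(f), p


def find_breakpoint(
    series: SmoothedSeries,
    min_segment: int = 3,
    use: str = "smoothed",
    permutations: int = 0,
    rng=None,
) -> BreakpointResult:
    """Sup-F scan: evaluate the Chow test at every admissible split and
    return the split maximising F (exact ties broken toward the larger x,
    which assigns a noiseless hinge point to the left segment).

    ``use`` selects the smoothed fitted values (default — the series the
    breakpoint is defined on) or the raw per-level estimates for
    sensitivity analysis.  ``permutations > 0`` adds a circular-shuffle
    permutation p-value for the sup-F statistic itself.
    """
    x = np.asarray(series.x, dtype=float)
    y = np.asarray(series.values(use), dtype=float)
    n = len(x)
    if n < 2 * min_segment:
        raise DomainError(f"need at least {2 * min_segment} points for a breakpoint scan")
    candidates = x[min_segment - 1 : n - min_segment]
    scan = {}
    for c in candidates:
        f, _ = chow_f(x, y, c, min_segment=min_segment)
        scan[float(c)] = f

    # exact F ties arise only in degenerate (noiseless piecewise) series,
    # where the hinge point lies on both segment lines; assigning it to the
    # left segment means breaking the tie toward the larger split
    best_x = min(scan, key=lambda c: (-scan[c], -c))
    best_f, best_p = chow_f(x, y, best_x, min_segment=min_segment)
    left = x <= best_x
    result = BreakpointResult(
        break_x=float(best_x),
        f_statistic=best_f,
        p_value=best_p,
        left_fit=_ols_line(x[left], y[left]),
        right_fit=_ols_line(x[~left], y[~left]),
        pooled_fit=_ols_line(x, y),
        n_left=int(left.sum()),
        n_right=int((~left).sum()),
        candidate_scan=scan,
        no_break=best_f <= 1e-10,
    )
    if permutations > 0:
        rng = np.random.default_rng(rng)
        hits = 0
        for _ in range(permutations):
            shift = int(rng.integers(1, n))
            y_perm = np.roll(y, shift)
            f_perm = max(
                chow_f(x, y_perm, c, min_segment=min_segment)[0] for c in candidates
            )
            hits += f_perm >= best_f
        result.permutation_p = (hits + 1) / (permutations + 1)
    return result


def sequence_breakpoint(
    sequence,
    bandwidth: float = DEFAULT_BANDWIDTH,
    robustify_iterations: int = 3,
    min_segment: int = 3,
    weighting: str | None = "inverse_variance",
    use: str = "smoothed",
    permutations: int = 0,
    rng=None,
) -> tuple[SmoothedSeries, BreakpointResult]:
    """Smooth a per-ELN effect sequence and locate its structural break.

    Works on the log-effect scale.  ``weighting`` controls the LOWESS
    prior weights: ``"inverse_variance"`` (default — per-level estimates
    are strongly heteroscedastic, sparse tail counts carry much larger
    standard errors), ``"n"`` (per-level patient counts) or ``None``.
    The reference level, whose log effect is exactly 0 by construction,
    is given the largest weight observed among the other levels.
    """
    x = sequence.eln.astype(float)
    y = sequence.log_points
    if weighting in (None, "none"):
        w = None
    elif weighting == "inverse_variance":
        se = sequence.table["se_log"].to_numpy(float)
        pos = se > 0
        w = np.empty_like(se)
        w[pos] = 1.0 / se[pos] ** 2
        if pos.any():
            w[~pos] = w[pos].max()
        else:
            w[:] = 1.0
    elif weighting == "n":
        w = sequence.table["n"].to_numpy(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    series = lowess_smooth(x, y, bandwidth=bandwidth, robustify_iterations=robustify_iterations, weights=w)
    result = find_breakpoint(series, min_segment=min_segment, use=use, permutations=permutations, rng=rng)
    return series, result
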