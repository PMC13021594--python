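"""Stabilogram diffusion analysis.

The stabilogram diffusion function (SDF) is the mean square planar
displacement of the centre point of force as a function of the time lag
between samples,

    msd(kΔ) = ⟨ [x(t+kΔ) − x(t)]² + [y(t+kΔ) − y(t)]² ⟩_t ,

averaged over all overlapping sample pairs. In quiet stance the SDF is
biphasic: a steep short-term (open-loop) regime and a flatter long-term
(closed-loop) regime. The critical point is where ordinary least-squares
lines fitted to the two regimes intersect; its abscissa is the critical time
``cri_t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import FitError, ParameterError

__all__ = ["SDFCurve", "CriticalPoint", "compute_sdf", "fit_critical_point"]


@dataclass
class SDFCurve:
    """Mean-square-displacement curve on a strictly increasing lag grid."""

    lags: np.ndarray  # seconds
    msd: np.ndarray  # cm²
    n_pairs: np.ndarray  # pairs averaged per lag


@dataclass
class CriticalPoint:
    """Two-line fit of an SDF curve.

    ``breakpoint`` is the SSE-optimal split of the lag grid; ``cri_t`` the
    abscissa of the fitted lines' intersection, clamped to (0, max lag].
    ``degenerate`` flags one-regime curves (slopes within 5% of each other) or
    intersections outside the grid; degenerate values are excluded from cohort
    statistics rather than imputed.
    """

    cri_t: float
    short_slope: float
    long_slope: float
    breakpoint: float
    intersection_msd: float
    degenerate: bool


def compute_sdf(cpf_x, cpf_y, fs: float, max_lag: float = 2.5) -> SDFCurve:
    """Exact SDF over every sample lag from 1 sample up to ``max_lag`` seconds.

    No subsampling: each msd value averages all overlapping pairs. 12 s records
    support lags to about a fifth of their duration before the pair count gets
    too small; 2.5 s is the default ceiling.
    """
    x = np.asarray(cpf_x, dtype=float)
    y = np.asarray(cpf_y, dtype=float)
    n = x.shape[0]
    k_max = int(round(max_lag * fs))
    if k_max >= n:
        raise ParameterError(
            f"max_lag {max_lag} s >= record duration {n / fs} s"
        )
    lags = np.arange(1, k_max + 1) / fs
    msd = np.empty(k_max)
    n_pairs = np.empty(k_max, dtype=int)
    for k in range(1, k_max + 1):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        msd[k - 1] = np.mean(dx * dx + dy * dy)
        n_pairs[k - 1] = n - k
    return SDFCurve(lags=lags, msd=msd, n_pairs=n_pairs)


def _ols_line(t, v):
    # slope/intercept and SSE of an OLS line; constant abscissa yields SSE of mean
    tm = t.mean()
    vm = v.mean()
    tt = np.sum((t - tm) ** 2)
    if tt == 0:
        return 0.0, vm, float(np.sum((v - vm) ** 2))
    slope = np.sum((t - tm) * (v - vm)) / tt
    intercept = vm - slope * tm
    resid = v - (slope * t + intercept)
    return float(slope), float(intercept), float(np.sum(resid * resid))


def fit_critical_point(
    sdf: SDFCurve,
    min_segment: int = 4,
    rel_slope_tol: float = 0.05,
) -> CriticalPoint:
    """Two-segment least-squares fit of an SDF curve.

    Scans every breakpoint on the lag grid leaving at least ``min_segment``
    points on each side; the short segment is [min lag, b] and the long
    segment [b, max lag] (the breakpoint belongs to both). The breakpoint
    minimising the pooled squared error wins, ties going to the smaller
    breakpoint. The critical time is the intersection abscissa of the two
    fitted lines; the fit is degenerate when the slopes differ by less than
    ``rel_slope_tol`` relative or the intersection leaves (0, max lag].
    """
    t = np.asarray(sdf.lags, dtype=float)
    v = np.asarray(sdf.msd, dtype=float)
    n = t.shape[0]
    if n < 8:
        raise FitError(f"need >= 8 lag points, got {n}")
    if n < 2 * min_segment - 1:
        raise FitError(
            f"no breakpoint leaves {min_segment} points per segment with {n} lags"
        )
    best = None
    for b in range(min_segment - 1, n - min_segment + 1):
        s1, c1, e1 = _ols_line(t[: b + 1], v[: b + 1])
        s2, c2, e2 = _ols_line(t[b:], v[b:])
        sse = e1 + e2
        if best is None or sse < best[0] - 1e-15:
            best = (sse, b, s1, c1, s2, c2)
    _, b, s1, c1, s2, c2 = best

    max_lag = t[-1]
    scale = max(abs(s1), abs(s2))
    degenerate = scale == 0 or abs(s1 - s2) < rel_slope_tol * scale
    if degenerate or s1 == s2:
        t_star = float("nan")
    else:
        t_star = (c2 - c1) / (s1 - s2)
    if not degenerate and not (0.0 < t_star <= max_lag):
        degenerate = True
    cri_t = float(np.clip(t_star, np.nextafter(0.0, 1.0), max_lag)) if np.isfinite(
        t_star
    ) else float("nan")
    msd_at = float(s1 * t_star + c1) if np.isfinite(t_star) else float("nan")
    return CriticalPoint(
        cri_t=cri_t,
        short_slope=s1,
        long_slope=s2,
        breakpoint=float(t[b]),
        intersection_msd=msd_at,
        degenerate=bool(degenerate),
    )
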