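"""Steady-phase detection from moving variances of the moment channels.

A sample belongs to a steady (low-variation) phase when the 5-point moving
variances of the two moment channels, summed and divided by the square of the
subject's mass, fall at or below a threshold (default 0.002). The moving
variance at index i is the population variance of samples i−2…i+2,

    Var_i = (1/5) Σ_{k=i−2}^{i+2} (x_k − x̄_i)²,  x̄_i = (1/5) Σ x_k,

so the first and last two samples of a record are never steady. ST(N) is the
count of steady samples in the 600-sample analysis window. The default
threshold corresponds to the upper limit of the lowest quartile of the
per-subject mean moving variance of the normalised weight signal;
:func:`calibrate_threshold` reproduces that derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError, ParameterError

__all__ = [
    "SteadyPhaseResult",
    "moving_variance",
    "steady_mask",
    "calibrate_threshold",
]

WINDOW = 5


@dataclass
class SteadyPhaseResult:
    mask: np.ndarray  # per-sample bool; edges always False
    st_n: int
    threshold: float
    summed_norm_variance: np.ndarray  # NaN at the 2-sample edges


def moving_variance(x, window: int = WINDOW) -> np.ndarray:
    """Centred moving population variance (divisor = window).

    Returns a full-length array with NaN at the (window−1)/2 undefined edge
    samples.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < window:
        raise InputError(f"need >= {window} samples, got {x.shape[0]}")
    if window % 2 == 0:
        raise ParameterError("window must be odd")
    views = np.lib.stride_tricks.sliding_window_view(x, window)
    core = views.var(axis=-1)  # population variance
    half = window // 2
    out = np.full(x.shape[0], np.nan)
    out[half : x.shape[0] - half] = core
    return out


def steady_mask(
    moment_x,
    moment_y,
    mass: float,
    threshold: float = 0.002,
    window: int = WINDOW,
) -> SteadyPhaseResult:
    """Classify each sample as steady or not.

    steady_i ⇔ [Var_i(moment_x) + Var_i(moment_y)] / mass² ≤ threshold.
    """
    if not mass > 0:
        raise ParameterError(f"mass must be positive, got {mass}")
    mx = np.asarray(moment_x, dtype=float)
    my = np.asarray(moment_y, dtype=float)
    if mx.shape != my.shape:
        raise InputError("moment channels must have equal length")
    snv = (moving_variance(mx, window) + moving_variance(my, window)) / mass**2
    mask = np.zeros(mx.shape[0], dtype=bool)
    defined = ~np.isnan(snv)
    mask[defined] = snv[defined] <= threshold
    return SteadyPhaseResult(
        mask=mask,
        st_n=int(np.count_nonzero(mask)),
        threshold=float(threshold),
        summed_norm_variance=snv,
    )


def calibrate_threshold(cohort_weight_variances) -> float:
    """Derive the low-variation threshold from a cohort.

    Takes one number per subject — the mean moving variance of that subject's
    normalised weight signal — and returns the upper limit of the lowest
    quartile (25th percentile, linear-interpolation rule).
    """
    v = np.asarray(cohort_weight_variances, dtype=float)
    if v.size == 0:
        raise InputError("empty cohort")
    return float(np.percentile(v, 25))
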