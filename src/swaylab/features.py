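"""Time-domain postural-control features of a preprocessed stabilogram.

The six-parameter set:

* ``cy`` — C(Y): central-95% amplitude range of anteroposterior sway, cm
  (97.5th − 2.5th percentile of the centred samples);
* ``m_my`` — M(MY): mean absolute moment about the anteroposterior axis
  divided by body mass;
* ``zcr_y`` / ``zcr_x`` — sign-change counts of the centred AP / ML position
  over the 12 s measuring period;
* ``zcr_vx`` — direction changes of the mediolateral sway velocity;
* ``cri_t`` — critical time of the open- to closed-loop transition, s
  (stabilogram diffusion analysis, :mod:`swaylab.diffusion`);
* ``st_n`` — steady-phase sample count (:mod:`swaylab.steady_phase`).

Auxiliary quantities for Romberg-quotient analyses: total AP sway path,
mean AP velocity, and full min–max (peak-to-peak) AP range.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .diffusion import compute_sdf, fit_critical_point
from .exceptions import DegenerateInputError, InputError, ParameterError
from .recording import StabilogramRecording
from .steady_phase import steady_mask

__all__ = [
    "FeatureVector",
    "RombergPair",
    "amplitude_range_95",
    "mean_abs_moment",
    "zero_crossing_count",
    "velocity",
    "zcr_vx",
    "ap_sway_path",
    "romberg_quotient",
    "extract_features",
    "SwayFeatureExtractor",
]

#: Canonical column order of feature tables.
FEATURE_COLUMNS = ["cy", "m_my", "zcr_y", "zcr_x", "zcr_vx", "cri_t", "st_n"]
AUX_COLUMNS = ["ap_path", "ap_mean_velocity", "pp_ap_range"]


@dataclass
class FeatureVector:
    """One recording's feature set. ``None`` marks an unavailable/degenerate value."""

    cy: float
    zcr_y: int
    zcr_x: int
    zcr_vx: int
    ap_path: float
    ap_mean_velocity: float
    pp_ap_range: float
    m_my: Optional[float] = None
    cri_t: Optional[float] = None
    st_n: Optional[int] = None
    condition: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RombergPair:
    """A feature measured eyes open and eyes closed, with its Romberg quotient."""

    eo_value: float
    ec_value: float
    rq: float


def amplitude_range_95(y) -> float:
    """Central-95% amplitude range: 97.5th − 2.5th percentile, cm.

    Linear-interpolation percentiles over the sample values; an empirical
    coverage interval, not a parametric confidence interval.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise InputError("empty series")
    lo, hi = np.percentile(y, [2.5, 97.5])
    return float(hi - lo)


def mean_abs_moment(my, mass: float) -> float:
    """Mean absolute AP-axis moment normalised by body mass: mean(|my|)/mass."""
    if not mass > 0:
        raise ParameterError(f"mass must be positive, got {mass}")
    my = np.asarray(my, dtype=float)
    return float(np.mean(np.abs(my)) / mass)


def _filled_signs(x: np.ndarray) -> np.ndarray:
    # Zero samples inherit the most recent nonzero sign; leading zeros take the
    # first nonzero sign so a touch of zero never double-counts as two crossings.
    s = np.sign(x)
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return s
    idx = np.zeros(s.shape[0], dtype=int)
    idx[nz] = nz
    idx = np.maximum.accumulate(idx)
    idx[: nz[0]] = nz[0]
    return s[idx]


def zero_crossing_count(x) -> int:
    """Count strict sign changes between consecutive samples of a centred series.

    Zero-valued samples inherit the previous nonzero sign, so grazing the axis
    counts at most one crossing. An all-zero series yields 0.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise InputError("need at least 2 samples")
    s = _filled_signs(x)
    return int(np.count_nonzero(np.diff(s)))


def velocity(x, fs: float) -> np.ndarray:
    """Velocity by central differences (one-sided at the ends), same length."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise InputError("need at least 3 samples for a velocity estimate")
    return np.gradient(x, 1.0 / fs)


def zcr_vx(cpf_x, fs: float) -> int:
    """Direction changes of the mediolateral sway velocity."""
    return zero_crossing_count(velocity(cpf_x, fs))


def ap_sway_path(y, fs: float):
    """Total anteroposterior sway path Σ|Δy| (cm) and mean velocity (cm/s)."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] < 2:
        raise InputError("need at least 2 samples")
    path = float(np.sum(np.abs(np.diff(y))))
    duration = (y.shape[0] - 1) / fs
    return path, path / duration


def romberg_quotient(ec_value: float, eo_value: float) -> float:
    """Romberg quotient: eyes-closed value over eyes-open value.

    Values above 1 indicate reliance on vision for the measured quantity.
    """
    if not eo_value > 0:
        raise DegenerateInputError(
            f"eyes-open value must be positive, got {eo_value}"
        )
    return float(ec_value / eo_value)


def extract_features(
    recording: StabilogramRecording,
    max_lag: float = 2.5,
    steady_threshold: float = 0.002,
) -> FeatureVector:
    """Compute the full feature vector of a preprocessed 600-sample recording.

    Moment-dependent features (``m_my``, ``st_n``) are ``None`` when the moment
    channels are missing; ``cri_t`` is ``None`` on degenerate (motionless)
    input.
    """
    if not recording.preprocessed:
        raise InputError("recording must be preprocessed (600 centred samples)")
    y = recording.cpf_y
    x = recording.cpf_x
    fs = recording.fs

    cy = amplitude_range_95(y)
    path, mean_vel = ap_sway_path(y, fs)
    fv = FeatureVector(
        cy=cy,
        zcr_y=zero_crossing_count(y),
        zcr_x=zero_crossing_count(x),
        zcr_vx=zcr_vx(x, fs),
        ap_path=path,
        ap_mean_velocity=mean_vel,
        pp_ap_range=float(np.max(y) - np.min(y)),
        condition=None if recording.meta is None else recording.meta.condition,
    )

    if np.ptp(x) == 0 and np.ptp(y) == 0:
        cp = None
    else:
        sdf = compute_sdf(x, y, fs, max_lag=max_lag)
        cp = fit_critical_point(sdf)
    if cp is not None and not cp.degenerate:
        fv.cri_t = cp.cri_t

    if (
        recording.moment_x is not None
        and recording.moment_y is not None
        and recording.meta is not None
    ):
        fv.m_my = mean_abs_moment(recording.moment_y, recording.meta.mass)
        fv.st_n = steady_mask(
            recording.moment_x,
            recording.moment_y,
            recording.meta.mass,
            threshold=steady_threshold,
        ).st_n
    return fv


class SwayFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping preprocessed recordings to a feature DataFrame.

    Parameters
    ----------
    max_lag : float, default 2.5
        Longest lag (s) of the stabilogram diffusion function.
    steady_threshold : float, default 0.002
        Mass-normalised moving-variance threshold of the steady-phase detector.
    log_transform : bool, default False
        Append natural-log columns (``log_<name>``) for strictly positive
        features, as used by the downstream statistical models.
    """

    def __init__(
        self,
        max_lag: float = 2.5,
        steady_threshold: float = 0.002,
        log_transform: bool = False,
    ):
        self.max_lag = max_lag
        self.steady_threshold = steady_threshold
        self.log_transform = log_transform

    def fit(self, X, y=None):
        self.n_features_in_ = 0
        return self

    def transform(self, X) -> pd.DataFrame:
        recs = X if isinstance(X, (list, tuple)) else [X]
        rows = []
        for rec in recs:
            fv = extract_features(
                rec, max_lag=self.max_lag, steady_threshold=self.steady_threshold
            )
            row = fv.to_dict()
            if rec.meta is not None:
                row.update(
                    subject_id=rec.meta.subject_id,
                    sex=rec.meta.sex,
                    age=rec.meta.age,
                    mass=rec.meta.mass,
                )
            rows.append(row)
        df = pd.DataFrame(rows)
        if self.log_transform:
            for col in FEATURE_COLUMNS + AUX_COLUMNS:
                if col in df:
                    vals = pd.to_numeric(df[col], errors="coerce")
                    df[f"log_{col}"] = np.where(vals > 0, np.log(vals), np.nan)
        return df
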