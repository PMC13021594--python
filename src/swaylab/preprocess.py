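"""Signal conditioning for raw stabilograms.

The chain, applied to every channel of a 50 Hz, ≥27 s recording:

1. median filter (default 5-sample kernel) to remove transient spikes,
2. linear-phase equiripple low-pass FIR (17 Hz passband, 21 Hz stopband,
   ≤1 dB passband ripple, ≥80 dB stopband attenuation) with integer
   group-delay compensation,
3. drop the first 15 s (stance transients and filter edge effects), keeping
   exactly 600 samples (12 s),
4. mean-centre the positional channels,
5. z-score the weight channel into ``weight_norm`` while keeping the filtered,
   un-normalised weight for moment-based computations.

Filtering precedes trimming so that edge effects of both the median and FIR
stages fall in the discarded segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateInputError, DesignError, InputError, ParameterError
from .recording import StabilogramRecording

__all__ = [
    "FilterDesign",
    "median_filter",
    "design_lowpass",
    "apply_filter",
    "trim_transient",
    "center_positions",
    "normalize_weight",
    "StabilogramPreprocessor",
]

#: Samples discarded at the start (15 s at 50 Hz) and retained afterwards (12 s).
TRIM_START = 750
N_ANALYSIS = 600


@dataclass
class FilterDesign:
    """A designed linear-phase low-pass FIR filter and its spec."""

    fs: float
    passband_edge: float = 17.0
    stopband_edge: float = 21.0
    max_passband_ripple: float = 1.0  # dB
    min_stopband_attenuation: float = 80.0  # dB
    coefficients: np.ndarray = field(default=None, repr=False)

    @property
    def group_delay(self) -> int:
        """Delay of the symmetric FIR in samples, (n_taps − 1)/2."""
        return (len(self.coefficients) - 1) // 2

    def response(self, n_grid: int = 4096):
        """Magnitude response |H(f)| on a dense frequency grid, f in Hz."""
        w, h = sps.freqz(self.coefficients, worN=n_grid, fs=self.fs)
        return w, np.abs(h)

    def measured_passband_ripple(self, n_grid: int = 4096) -> float:
        """Max deviation from unity gain over [0, passband_edge], in dB."""
        f, mag = self.response(n_grid)
        band = mag[f <= self.passband_edge]
        return float(np.max(np.abs(20.0 * np.log10(band))))

    def measured_stopband_attenuation(self, n_grid: int = 4096) -> float:
        """Min attenuation over [stopband_edge, fs/2], in dB (positive)."""
        f, mag = self.response(n_grid)
        band = mag[f >= self.stopband_edge]
        return float(-np.max(20.0 * np.log10(np.maximum(band, 1e-300))))

    def meets_spec(self, n_grid: int = 4096) -> bool:
        return (
            self.measured_passband_ripple(n_grid) <= self.max_passband_ripple
            and self.measured_stopband_attenuation(n_grid)
            >= self.min_stopband_attenuation
        )


def median_filter(x, kernel: int = 5) -> np.ndarray:
    """Sliding-window median with reflection padding at the edges.

    Parameters
    ----------
    x : array-like
        Sample series.
    kernel : odd int
        Window length in samples; must be odd, ≥3 and ≤ len(x).
    """
    x = np.asarray(x, dtype=float)
    if kernel % 2 == 0 or kernel < 3:
        raise ParameterError(f"median kernel must be odd and >= 3, got {kernel}")
    if kernel > x.shape[0]:
        raise ParameterError(
            f"median kernel {kernel} exceeds signal length {x.shape[0]}"
        )
    half = kernel // 2
    padded = np.pad(x, half, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, kernel)
    return np.median(windows, axis=-1)


def _kaiser_order_estimate(fs, f_pass, f_stop, ripple_db, atten_db) -> int:
    # Herrmann/Kaiser-style estimate used only as a starting point; the design
    # loop below increases the order until the measured response meets spec.
    delta_p = (10 ** (ripple_db / 20.0) - 1) / (10 ** (ripple_db / 20.0) + 1)
    delta_s = 10 ** (-atten_db / 20.0)
    delta_f = (f_stop - f_pass) / fs
    n = (-20.0 * math.log10(math.sqrt(delta_p * delta_s)) - 13.0) / (14.6 * delta_f)
    return max(int(math.ceil(n)), 8)


def design_lowpass(
    fs: float,
    passband_edge: float = 17.0,
    stopband_edge: float = 21.0,
    max_passband_ripple: float = 1.0,
    min_stopband_attenuation: float = 80.0,
    max_taps: int = 2001,
) -> FilterDesign:
    """Design a linear-phase equiripple (Chebyshev-criterion) low-pass FIR.

    The Parks–McClellan exchange algorithm produces the minimax (equiripple)
    approximation; the tap count starts at a Kaiser-type analytic estimate and
    is increased (odd counts only, so the group delay is an integer) until the
    measured response on a 4096-point grid satisfies both the ripple and the
    attenuation spec.
    """
    if not (0 < passband_edge < stopband_edge < fs / 2):
        raise DesignError(
            f"need 0 < passband ({passband_edge}) < stopband ({stopband_edge})"
            f" < Nyquist ({fs / 2})"
        )
    delta_p = (10 ** (max_passband_ripple / 20.0) - 1) / (
        10 ** (max_passband_ripple / 20.0) + 1
    )
    delta_s = 10 ** (-min_stopband_attenuation / 20.0)
    n0 = _kaiser_order_estimate(
        fs, passband_edge, stopband_edge, max_passband_ripple, min_stopband_attenuation
    )
    numtaps = n0 + 1 if (n0 + 1) % 2 == 1 else n0 + 2
    while numtaps <= max_taps:
        taps = sps.remez(
            numtaps,
            [0, passband_edge, stopband_edge, fs / 2],
            [1, 0],
            weight=[1.0 / delta_p, 1.0 / delta_s],
            fs=fs,
        )
        design = FilterDesign(
            fs=fs,
            passband_edge=passband_edge,
            stopband_edge=stopband_edge,
            max_passband_ripple=max_passband_ripple,
            min_stopband_attenuation=min_stopband_attenuation,
            coefficients=taps,
        )
        if design.meets_spec():
            return design
        numtaps += 2
    raise DesignError(
        f"no FIR with <= {max_taps} taps meets the spec at fs={fs} Hz"
    )


def apply_filter(x, design: FilterDesign) -> np.ndarray:
    """Single forward pass of the FIR with integer group-delay compensation.

    The signal is reflection-padded by one group delay at each end so the
    output has the input's length and is time-aligned with it. Edge samples
    carry the usual startup transient, which the downstream 15 s trim discards.
    """
    x = np.asarray(x, dtype=float)
    taps = design.coefficients
    if x.shape[0] <= taps.shape[0]:
        raise InputError(
            f"signal length {x.shape[0]} must exceed filter length {taps.shape[0]}"
        )
    d = design.group_delay
    padded = np.pad(x, d, mode="reflect")
    y = sps.lfilter(taps, 1.0, padded)
    return y[2 * d : 2 * d + x.shape[0]]


def trim_transient(recording: StabilogramRecording) -> StabilogramRecording:
    """Drop the first 15 s of the recording, keeping exactly 600 samples.

    Subjects readjust their stance after stepping onto the platform; the
    retained segment is samples 750–1349 (0-based) of the input at 50 Hz.
    """
    n = len(recording)
    needed = TRIM_START + N_ANALYSIS
    if n < needed:
        raise InputError(
            f"recording too short: need {needed} samples"
            f" ({needed / recording.fs:.1f} s), have {n} ({recording.duration:.1f} s)"
        )
    out = recording.copy()
    for name in recording.CHANNELS:
        arr = getattr(out, name)
        if arr is not None:
            setattr(out, name, arr[TRIM_START : TRIM_START + N_ANALYSIS])
    out.provenance = {
        **recording.provenance,
        "trim": [TRIM_START, TRIM_START + N_ANALYSIS],
    }
    return out


def center_positions(recording: StabilogramRecording) -> StabilogramRecording:
    """Remove the mean of both positional channels; other channels untouched."""
    out = recording.copy()
    out.cpf_x = out.cpf_x - out.cpf_x.mean()
    out.cpf_y = out.cpf_y - out.cpf_y.mean()
    return out


def normalize_weight(weight) -> np.ndarray:
    """Z-score the weight series to mean 0, variance 1 (population variance)."""
    w = np.asarray(weight, dtype=float)
    sd = w.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("weight signal has zero variance")
    return (w - w.mean()) / sd


class StabilogramPreprocessor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer running the full conditioning chain.

    Parameters
    ----------
    median_kernel : odd int, default 5
        Median-filter window (0.1 s at 50 Hz).
    lowpass : bool, default True
        Apply the equiripple FIR stage. Disable for pre-filtered data.
    passband_edge, stopband_edge, max_passband_ripple, min_stopband_attenuation :
        FIR spec; defaults are the platform's acquisition spec.

    Attributes
    ----------
    filter_design_ : FilterDesign
        The designed FIR (set by :meth:`fit`, keyed to the first recording's
        sampling rate).
    """

    def __init__(
        self,
        median_kernel: int = 5,
        lowpass: bool = True,
        passband_edge: float = 17.0,
        stopband_edge: float = 21.0,
        max_passband_ripple: float = 1.0,
        min_stopband_attenuation: float = 80.0,
    ):
        self.median_kernel = median_kernel
        self.lowpass = lowpass
        self.passband_edge = passband_edge
        self.stopband_edge = stopband_edge
        self.max_passband_ripple = max_passband_ripple
        self.min_stopband_attenuation = min_stopband_attenuation

    def fit(self, X, y=None):
        """Design the FIR for the sampling rate of the input recording(s)."""
        rec = X[0] if isinstance(X, (list, tuple)) else X
        if self.lowpass:
            self.filter_design_ = design_lowpass(
                rec.fs,
                self.passband_edge,
                self.stopband_edge,
                self.max_passband_ripple,
                self.min_stopband_attenuation,
            )
        else:
            self.filter_design_ = None
        return self

    def transform(self, X):
        if isinstance(X, (list, tuple)):
            return [self._transform_one(rec) for rec in X]
        return self._transform_one(X)

    def _transform_one(self, rec: StabilogramRecording) -> StabilogramRecording:
        out = rec.copy()
        for name in ("cpf_x", "cpf_y", "moment_x", "moment_y", "weight"):
            arr = getattr(out, name)
            if arr is None:
                continue
            arr = median_filter(arr, self.median_kernel)
            if self.filter_design_ is not None:
                arr = apply_filter(arr, self.filter_design_)
            setattr(out, name, arr)
        out = trim_transient(out)
        out = center_positions(out)
        if out.weight is not None:
            out.weight_norm = normalize_weight(out.weight)
        out.preprocessed = True
        out.provenance.update(
            {
                "median_kernel": self.median_kernel,
                "fir_taps": (
                    0
                    if self.filter_design_ is None
                    else int(len(self.filter_design_.coefficients))
                ),
            }
        )
        return out


def preprocess_recording(
    recording: StabilogramRecording, **kwargs
) -> StabilogramRecording:
    """One-shot functional wrapper over :class:`StabilogramPreprocessor`."""
    return StabilogramPreprocessor(**kwargs).fit(recording).transform(recording)
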