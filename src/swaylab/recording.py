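"""Containers for force-platform stabilogram recordings.

A recording holds the five platform channels sampled at ``fs`` Hz:

* ``cpf_x`` — mediolateral centre-point-of-force position, cm
* ``cpf_y`` — anteroposterior centre-point-of-force position, cm
* ``moment_x`` — moment about the mediolateral axis, N·m
* ``moment_y`` — moment about the anteroposterior axis, N·m
* ``weight`` — vertical reaction force (raw scale)

plus subject metadata. Coordinate convention: X = mediolateral, Y =
anteroposterior. After preprocessing the positional channels are mean-centred,
``weight_norm`` holds the zero-mean unit-variance copy of the weight channel,
and ``weight`` keeps the filtered but un-normalised signal used in moment
computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import InputError

__all__ = ["SubjectMeta", "StabilogramRecording"]

#: Conditions a trial can be recorded under.
CONDITIONS = ("eyes_open", "eyes_closed")
SEXES = ("male", "female")


@dataclass(frozen=True)
class SubjectMeta:
    """Subject-level metadata attached to a recording.

    ``mass`` (kg) is the divisor used by the mass-normalised features
    (mean absolute moment, steady-phase detection).
    """

    subject_id: str
    sex: str
    age: float
    mass: float
    condition: str = "eyes_closed"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not self.mass > 0:
            raise ValueError(f"mass must be positive, got {self.mass}")


@dataclass
class StabilogramRecording:
    """A multichannel stabilogram plus metadata.

    Channels may be ``None`` for feature-limited recordings (missing moment or
    weight columns); all present channels must share one length.
    """

    fs: float
    cpf_x: np.ndarray
    cpf_y: np.ndarray
    moment_x: Optional[np.ndarray] = None
    moment_y: Optional[np.ndarray] = None
    weight: Optional[np.ndarray] = None
    weight_norm: Optional[np.ndarray] = None
    meta: Optional[SubjectMeta] = None
    preprocessed: bool = False
    provenance: dict = field(default_factory=dict)

    CHANNELS = ("cpf_x", "cpf_y", "moment_x", "moment_y", "weight", "weight_norm")

    def __post_init__(self):
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for name in self.CHANNELS:
            arr = getattr(self, name)
            if arr is not None:
                setattr(self, name, np.asarray(arr, dtype=float))
        lengths = {
            getattr(self, name).shape[0]
            for name in self.CHANNELS
            if getattr(self, name) is not None
        }
        if len(lengths) > 1:
            raise InputError(f"channel lengths differ: {sorted(lengths)}")

    def __len__(self) -> int:
        return int(self.cpf_x.shape[0])

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self) / self.fs

    @property
    def feature_limited(self) -> bool:
        """True when moment or weight channels are missing."""
        return self.moment_x is None or self.moment_y is None or self.weight is None

    def copy(self) -> "StabilogramRecording":
        kwargs = {
            name: (None if getattr(self, name) is None else getattr(self, name).copy())
            for name in self.CHANNELS
        }
        return replace(self, provenance=dict(self.provenance), **kwargs)
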