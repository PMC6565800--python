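"""Containers for multi-frequency impedance recordings."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DomainError

__all__ = ["MUSCLES", "SIDES", "GENDERS", "SpectrumMeta", "ImpedanceSpectrum"]

#: The eight skeletal muscles covered by the normative tables.
MUSCLES = (
    "biceps",
    "triceps",
    "abductor_pollicis_brevis",
    "trapezius",
    "rectus_femoris",
    "vastus_lateralis",
    "gastrocnemius",
    "tibialis_anterior",
)

SIDES = ("left", "right", "unspecified")
GENDERS = ("men", "women")

#: Minimum number of frequency points for an identifiable 4-parameter fit.
MIN_POINTS = 8


@dataclass(frozen=True)
class SpectrumMeta:
    """Subject/recording metadata attached to a spectrum."""

    subject_id: str = ""
    muscle: str = ""
    side: str = "unspecified"
    gender: str = ""
    age: float | None = None

    def __post_init__(self) -> None:
        if self.muscle and self.muscle not in MUSCLES:
            raise DomainError(f"unknown muscle {self.muscle!r}; expected one of {MUSCLES}")
        if self.side not in SIDES:
            raise DomainError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.gender and self.gender not in GENDERS:
            raise DomainError(f"gender must be one of {GENDERS}, got {self.gender!r}")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """One recording: a frequency sweep with resistance and reactance.

    frequencies are kHz, strictly increasing, in (0, 1e4]; resistance is Ω,
    strictly positive; reactance is the Ω magnitude (negated imaginary
    part — small negative excursions from measurement noise at the sweep
    extremes are tolerated).
    """

    frequencies: np.ndarray
    resistance: np.ndarray
    reactance: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        r = np.asarray(self.resistance, dtype=float)
        x = np.asarray(self.reactance, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "resistance", r)
        object.__setattr__(self, "reactance", x)
        if not (f.ndim == r.ndim == x.ndim == 1):
            raise DomainError("frequencies, resistance and reactance must be 1-D")
        if not (len(f) == len(r) == len(x)):
            raise DomainError("frequencies, resistance and reactance must have equal length")
        if len(f) < MIN_POINTS:
            raise DomainError(f"need at least {MIN_POINTS} frequency points, got {len(f)}")
        if not np.all(np.isfinite(f)) or np.any(f <= 0.0) or np.any(f > 1e4):
            raise DomainError("frequencies must be finite, positive and at most 1e4 kHz")
        if np.any(np.diff(f) <= 0.0):
            raise DomainError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(r)) or np.any(r <= 0.0):
            raise DomainError("resistance must be finite and strictly positive")
        if not np.all(np.isfinite(x)):
            raise DomainError("reactance must be finite")

    def __len__(self) -> int:
        return len(self.frequencies)

    @property
    def complex_impedance(self) -> np.ndarray:
        """R − jXc at each frequency."""
        return self.resistance - 1j * self.reactance

    def scaled(self, factor: float) -> "ImpedanceSpectrum":
        """Uniformly rescale all impedances (used for scale-invariance checks)."""
        if factor <= 0.0:
            raise DomainError("scale factor must be positive")
        return replace(
            self, resistance=self.resistance * factor, reactance=self.reactance * factor
        )
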