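"""Domain types for overnight beat-by-beat blood-pressure recordings.

The substrate of the whole package is a :class:`BeatSeries` — one systolic
(and optionally diastolic) pressure per cardiac beat with a per-beat quality
flag — plus interval-shaped annotations (:class:`SurgeAnnotation`) that mark
a surge's start, peak, and end beats.  Expert labels, detector output, and
raw candidates all share the annotation shape and differ only in ``source``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "QUALITY_VALID",
    "QUALITY_ARTIFACT",
    "QUALITY_GAP",
    "QUALITIES",
    "FormatError",
    "ValidationError",
    "BeatSeries",
    "SurgeAnnotation",
    "CandidateSurge",
    "PsgEvent",
    "IntermittentSeries",
]

QUALITY_VALID = "valid"
QUALITY_ARTIFACT = "artifact"
QUALITY_GAP = "gap"
QUALITIES = (QUALITY_VALID, QUALITY_ARTIFACT, QUALITY_GAP)

SBP_MIN = 30.0
SBP_MAX = 300.0

SOURCES = ("label", "detection", "candidate")
SA_CLASSES = ("sa", "non_sa", "unassigned")


class FormatError(ValueError):
    """Raised when an input file or record is structurally malformed."""


class ValidationError(ValueError):
    """Raised when a structurally sound record violates a domain invariant."""


@dataclass
class BeatSeries:
    """Per-beat timestamped SBP/DBP sequence with quality flags.

    Parameters
    ----------
    night_id
        Identifier of the overnight recording.
    time_s
        Per-beat timestamps in seconds from recording start, strictly
        increasing.
    sbp_mmHg
        Systolic BP per beat.  Valid beats must lie in [30, 300] mmHg.
    dbp_mmHg
        Diastolic BP per beat; may be wholly absent (``None``).
    quality
        Per-beat flag, one of ``valid``, ``artifact``, ``gap``.  Defaults to
        all-valid.
    """

    night_id: str
    time_s: np.ndarray
    sbp_mmHg: np.ndarray
    dbp_mmHg: Optional[np.ndarray] = None
    quality: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.sbp_mmHg = np.asarray(self.sbp_mmHg, dtype=float)
        n = self.time_s.size
        if n < 2:
            raise ValidationError(
                f"{self.night_id}: a beat series needs at least 2 beats, got {n}"
            )
        if self.sbp_mmHg.size != n:
            raise ValidationError(
                f"{self.night_id}: time_s has {n} beats but sbp_mmHg has "
                f"{self.sbp_mmHg.size}"
            )
        if self.dbp_mmHg is not None:
            self.dbp_mmHg = np.asarray(self.dbp_mmHg, dtype=float)
            if self.dbp_mmHg.size != n:
                raise ValidationError(
                    f"{self.night_id}: dbp_mmHg length {self.dbp_mmHg.size} != {n}"
                )
        if self.quality is None:
            self.quality = np.full(n, QUALITY_VALID, dtype=object)
        else:
            self.quality = np.asarray(self.quality, dtype=object)
            if self.quality.size != n:
                raise ValidationError(
                    f"{self.night_id}: quality length {self.quality.size} != {n}"
                )
            bad = set(np.unique(self.quality)) - set(QUALITIES)
            if bad:
                raise ValidationError(
                    f"{self.night_id}: unknown quality flags {sorted(bad)}"
                )
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise FormatError(
                f"{self.night_id}: time_s not strictly increasing at beat {row} "
                f"(t={self.time_s[row]:.3f} after t={self.time_s[row - 1]:.3f})"
            )
        valid = self.valid_mask
        sv = self.sbp_mmHg[valid]
        out = (sv < SBP_MIN) | (sv > SBP_MAX)
        if np.any(out):
            row = int(np.flatnonzero(valid)[np.argmax(out)])
            raise ValidationError(
                f"{self.night_id}: SBP {self.sbp_mmHg[row]:.1f} mmHg outside "
                f"[{SBP_MIN:.0f}, {SBP_MAX:.0f}] at valid beat {row}"
            )
        if self.dbp_mmHg is not None:
            both = valid & np.isfinite(self.dbp_mmHg)
            if np.any(self.sbp_mmHg[both] <= self.dbp_mmHg[both]):
                row = int(
                    np.flatnonzero(both)[
                        np.argmax(self.sbp_mmHg[both] <= self.dbp_mmHg[both])
                    ]
                )
                raise ValidationError(
                    f"{self.night_id}: SBP <= DBP at valid beat {row}"
                )

    @property
    def n_beats(self) -> int:
        return int(self.time_s.size)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.quality == QUALITY_VALID

    @property
    def valid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.valid_mask)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def equals(self, other: "BeatSeries", atol_time: float = 0.0,
               atol_bp: float = 0.0) -> bool:
        """Field-by-field equality, optionally within absolute tolerances."""
        if self.night_id != other.night_id or self.n_beats != other.n_beats:
            return False
        if not np.allclose(self.time_s, other.time_s, rtol=0, atol=atol_time):
            return False
        if not np.allclose(self.sbp_mmHg, other.sbp_mmHg, rtol=0, atol=atol_bp):
            return False
        if (self.dbp_mmHg is None) != (other.dbp_mmHg is None):
            return False
        if self.dbp_mmHg is not None and not np.allclose(
            self.dbp_mmHg, other.dbp_mmHg, rtol=0, atol=atol_bp
        ):
            return False
        return bool(np.all(self.quality == other.quality))


@dataclass
class SurgeAnnotation:
    """A (start, peak, end) beat-index triple on a :class:`BeatSeries`.

    ``source`` records provenance (expert ``label``, algorithm ``detection``,
    or raw ``candidate``); ``sa_class`` records whether the surge is
    sleep-apnea related.
    """

    night_id: str
    start_idx: int
    peak_idx: int
    end_idx: int
    source: str = "label"
    sa_class: str = "unassigned"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValidationError(f"unknown annotation source {self.source!r}")
        if self.sa_class not in SA_CLASSES:
            raise ValidationError(f"unknown sa_class {self.sa_class!r}")
        if not (self.start_idx < self.peak_idx < self.end_idx):
            raise ValidationError(
                f"{self.night_id}: annotation indices must satisfy "
                f"start < peak < end, got ({self.start_idx}, {self.peak_idx}, "
                f"{self.end_idx})"
            )

    def validate_against(self, series: BeatSeries) -> None:
        """Check index bounds and the peak-above-start invariant."""
        if self.night_id != series.night_id:
            raise ValidationError(
                f"annotation night {self.night_id!r} != series "
                f"{series.night_id!r}"
            )
        if not (0 <= self.start_idx and self.end_idx < series.n_beats):
            raise ValidationError(
                f"{self.night_id}: annotation ({self.start_idx}, "
                f"{self.end_idx}) outside series of {series.n_beats} beats"
            )
        if series.sbp_mmHg[self.peak_idx] < series.sbp_mmHg[self.start_idx]:
            raise ValidationError(
                f"{self.night_id}: peak SBP below start SBP for annotation "
                f"at beat {self.start_idx}"
            )

    def times(self, series: BeatSeries) -> tuple[float, float, float]:
        t = series.time_s
        return (
            float(t[self.start_idx]),
            float(t[self.peak_idx]),
            float(t[self.end_idx]),
        )

    def with_class(self, sa_class: str) -> "SurgeAnnotation":
        return replace(self, sa_class=sa_class)


@dataclass
class CandidateSurge(SurgeAnnotation):
    """Detector candidate: an annotation plus its measured amplitude and
    whether start/end came from the fallback (no-stable-start / no-decay)
    branches."""

    source: str = "candidate"
    amplitude_mmHg: float = 0.0
    start_fallback: bool = False
    end_fallback: bool = False


@dataclass
class PsgEvent:
    """A polysomnography event interval: apnea, hypopnea, or desaturation."""

    night_id: str
    kind: str
    start_s: float
    end_s: float

    KINDS = ("apnea", "hypopnea", "desaturation")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown PSG event kind {self.kind!r}")
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"{self.night_id}: PSG event start {self.start_s} >= end "
                f"{self.end_s}"
            )


@dataclass
class IntermittentSeries:
    """Cuff-oscillometric SBP readings taken every ~30 min overnight."""

    night_id: str
    time_s: np.ndarray
    sbp_mmHg: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.sbp_mmHg = np.asarray(self.sbp_mmHg, dtype=float)
        if self.time_s.size != self.sbp_mmHg.size:
            raise ValidationError(
                f"{self.night_id}: intermittent time/SBP length mismatch"
            )
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise FormatError(
                f"{self.night_id}: intermittent reading times not strictly "
                "increasing"
            )

    @property
    def n_readings(self) -> int:
        return int(self.time_s.size)
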