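"""Encodings, conversions and difference scores for the four visual-function scales.

The battery evaluated here consists of four examinations taken once before
and once after amblyopia treatment:

* **Visual acuity** of the amblyopic eye, recorded in logMAR (lower is
  better). The standard logarithmic chart spans decimal acuity 0.1-2.0 in
  14 steps, i.e. logMAR 1.0 down to -0.3 in 0.1 steps.
* **Binocular rivalry balance point (BRBP)**, per eye, on an 8-level
  signal/noise dot-proportion ladder: level 1 is 100% signal dots, the noise
  share then grows (15%, 30%, then +10% per level) until level 8 is 20%
  signal / 80% noise. A deeper level means that eye tolerates more noise
  before losing the motion-direction signal; the *interocular* level gap
  quantifies suppression imbalance.
* **Perceptual eye position (PEP)**: angular deviation (degrees) between the
  perceived and actual alignment of dichoptic fixation targets, horizontal
  and vertical components. Larger deviation = worse cortical eye-position
  control.
* **Stereoacuity**, from a four-plate random-dot test at 400/300/200/100
  seconds of arc, coded on an ordinal 0-4 scale (0 = no measurable
  stereopsis, 4 = 100").

Per-subject treatment effect is the post-minus-pre difference of each index;
with VA in logMAR an improvement shows up as a *negative* difference for
VA, interocular BRBP gap and horizontal PEP, and a *positive* difference for
the stereo level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError, IncompleteRecordError, PairingError

__all__ = [
    "CHART_LOGMAR_MIN",
    "CHART_LOGMAR_MAX",
    "BRBP_LADDER",
    "STEREO_ARCSEC_TO_LEVEL",
    "STEREO_LEVEL_TO_ARCSEC",
    "VisualAcuity",
    "BrbpLevel",
    "PerceptualEyePosition",
    "StereoLevel",
    "ExamRecord",
    "DifferenceVector",
    "decimal_to_logmar",
    "logmar_to_decimal",
    "brbp_level_to_proportions",
    "encode_stereoacuity",
    "decode_stereoacuity",
    "interocular_brbp_difference",
    "compute_difference_vector",
]

#: logMAR range of the standard logarithmic chart (decimal 2.0 and 0.1).
CHART_LOGMAR_MIN = -0.3
CHART_LOGMAR_MAX = 1.0

#: (signal %, noise %) for BRBP levels 1..8. Levels 1-3 are the anchor
#: proportions of the ladder; 4-8 continue with a 10-point shift per level.
BRBP_LADDER: dict[int, tuple[int, int]] = {
    1: (100, 0),
    2: (85, 15),
    3: (70, 30),
    4: (60, 40),
    5: (50, 50),
    6: (40, 60),
    7: (30, 70),
    8: (20, 80),
}

#: Stereo threshold (arcsec) -> ordinal level; None encodes "no stereopsis".
STEREO_ARCSEC_TO_LEVEL: dict[int | None, int] = {
    100: 4,
    200: 3,
    300: 2,
    400: 1,
    None: 0,
}
STEREO_LEVEL_TO_ARCSEC = {lvl: arc for arc, lvl in STEREO_ARCSEC_TO_LEVEL.items()}


def decimal_to_logmar(decimal_va: float) -> float:
    """Convert decimal visual acuity to logMAR (``-log10``).

    Raises :class:`DomainError` for non-positive input. Values are stored
    at full precision; rounding is a display concern.
    """
    if not decimal_va > 0:
        raise DomainError(f"decimal acuity must be > 0, got {decimal_va!r}")
    return -math.log10(decimal_va)


def logmar_to_decimal(logmar: float) -> float:
    """Inverse of :func:`decimal_to_logmar`."""
    return 10.0 ** (-logmar)


@dataclass(frozen=True)
class VisualAcuity:
    """Visual acuity in logMAR units.

    The chart supports logMAR -0.3..1.0; values outside that window are
    accepted (free-form clinical input) but flagged via :attr:`off_chart`.
    """

    logmar: float

    @property
    def off_chart(self) -> bool:
        return not (CHART_LOGMAR_MIN - 1e-9 <= self.logmar <= CHART_LOGMAR_MAX + 1e-9)

    @property
    def decimal(self) -> float:
        return logmar_to_decimal(self.logmar)

    @classmethod
    def from_decimal(cls, decimal_va: float) -> "VisualAcuity":
        return cls(decimal_to_logmar(decimal_va))


@dataclass(frozen=True)
class BrbpLevel:
    """One eye's binocular-rivalry balance level on the 8-step ladder."""

    level: int

    def __post_init__(self) -> None:
        if self.level not in BRBP_LADDER:
            raise DomainError(f"BRBP level must be in 1..8, got {self.level!r}")

    @property
    def proportions(self) -> tuple[int, int]:
        return BRBP_LADDER[self.level]


def brbp_level_to_proportions(level: int | BrbpLevel) -> tuple[int, int]:
    """Return the ``(signal %, noise %)`` pair for a BRBP level (sums to 100)."""
    if isinstance(level, BrbpLevel):
        level = level.level
    if level not in BRBP_LADDER:
        raise DomainError(f"BRBP level must be in 1..8, got {level!r}")
    return BRBP_LADDER[level]


@dataclass(frozen=True)
class PerceptualEyePosition:
    """Horizontal/vertical perceptual eye-position deviation, in degrees.

    Deviations are magnitudes, hence non-negative. The vertical component is
    optional: it is carried for reporting but never enters the composite
    index (its pre/post change is not reliably different from zero).
    """

    horizontal: float
    vertical: float | None = None

    def __post_init__(self) -> None:
        if self.horizontal < 0:
            raise DomainError(f"horizontal PEP must be >= 0, got {self.horizontal}")
        if self.vertical is not None and self.vertical < 0:
            raise DomainError(f"vertical PEP must be >= 0, got {self.vertical}")


@dataclass(frozen=True)
class StereoLevel:
    """Ordinal stereoacuity level, 0 (none) .. 4 (100 arcsec)."""

    level: int

    def __post_init__(self) -> None:
        if self.level not in STEREO_LEVEL_TO_ARCSEC:
            raise DomainError(f"stereo level must be in 0..4, got {self.level!r}")

    @property
    def arcsec(self) -> int | None:
        return STEREO_LEVEL_TO_ARCSEC[self.level]


def encode_stereoacuity(threshold: int | None) -> StereoLevel:
    """Encode a stereo threshold (100/200/300/400 arcsec, or None) as a level.

    The test has exactly four plates, so only those thresholds exist;
    anything else is a :class:`DomainError`.
    """
    if threshold not in STEREO_ARCSEC_TO_LEVEL:
        raise DomainError(
            f"stereo threshold must be one of 100, 200, 300, 400 or None, got {threshold!r}"
        )
    return StereoLevel(STEREO_ARCSEC_TO_LEVEL[threshold])


def decode_stereoacuity(level: int | StereoLevel) -> int | None:
    """Inverse of :func:`encode_stereoacuity` (level -> arcsec, 0 -> None)."""
    if isinstance(level, StereoLevel):
        level = level.level
    if level not in STEREO_LEVEL_TO_ARCSEC:
        raise DomainError(f"stereo level must be in 0..4, got {level!r}")
    return STEREO_LEVEL_TO_ARCSEC[level]


def interocular_brbp_difference(left: int | BrbpLevel, right: int | BrbpLevel) -> int:
    """Absolute interocular BRBP level gap ``|left - right|``.

    The absolute value makes the index invariant to which eye is labelled
    amblyopic; it lies in 0..7.
    """
    left_level = left.level if isinstance(left, BrbpLevel) else BrbpLevel(left).level
    right_level = right.level if isinstance(right, BrbpLevel) else BrbpLevel(right).level
    return abs(left_level - right_level)


@dataclass(frozen=True)
class ExamRecord:
    """One subject's examination battery at a single phase (pre or post).

    ``brbp_right`` may be None for a flagged-missing measurement (the
    validation fixture contains one such cell); any record with a missing
    BRBP eye cannot contribute a BRBP difference score.
    """

    subject_id: str
    phase: str  # "pre" | "post"
    va: VisualAcuity
    brbp_right: BrbpLevel | None
    brbp_left: BrbpLevel | None
    pep: PerceptualEyePosition
    stereo: StereoLevel
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise DomainError("subject_id must be non-empty")
        if self.phase not in ("pre", "post"):
            raise DomainError(f"phase must be 'pre' or 'post', got {self.phase!r}")

    @classmethod
    def from_raw(
        cls,
        subject_id: str,
        phase: str,
        *,
        va_logmar: float,
        brbp_right: int | None,
        brbp_left: int | None,
        pep_h: float,
        pep_v: float | None = None,
        stereo_level: int,
        flags: tuple[str, ...] = (),
    ) -> "ExamRecord":
        """Build a record from plain numbers (levels as ints, VA in logMAR)."""
        return cls(
            subject_id=subject_id,
            phase=phase,
            va=VisualAcuity(va_logmar),
            brbp_right=None if brbp_right is None else BrbpLevel(brbp_right),
            brbp_left=None if brbp_left is None else BrbpLevel(brbp_left),
            pep=PerceptualEyePosition(pep_h, pep_v),
            stereo=StereoLevel(stereo_level),
            flags=flags,
        )

    def interocular_brbp(self) -> int:
        if self.brbp_right is None or self.brbp_left is None:
            raise IncompleteRecordError(
                f"subject {self.subject_id!r} ({self.phase}): BRBP level missing for one eye"
            )
        return interocular_brbp_difference(self.brbp_left, self.brbp_right)


@dataclass(frozen=True)
class DifferenceVector:
    """Post-minus-pre difference scores for one subject.

    ``d_va`` (logMAR), ``d_brbp`` (interocular level gap), ``d_hpep``
    (degrees) and ``d_sa`` (stereo levels) are the four indicators entering
    the composite index. ``d_vpep`` is carried when both phases measured
    vertical PEP but is excluded from coupling.
    """

    subject_id: str
    d_va: float
    d_brbp: float
    d_hpep: float
    d_sa: float
    d_vpep: float | None = None

    def __post_init__(self) -> None:
        if not -4 <= self.d_sa <= 4:
            raise DomainError(f"d_sa must lie in [-4, 4], got {self.d_sa}")
        if not -7 <= self.d_brbp <= 7:
            raise DomainError(f"d_brbp must lie in [-7, 7], got {self.d_brbp}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.d_va, self.d_brbp, self.d_hpep, self.d_sa)


def compute_difference_vector(pre: ExamRecord, post: ExamRecord) -> DifferenceVector:
    """Difference scores (post - pre) for one subject.

    The BRBP component differences the per-phase interocular level gaps, not
    the raw eye levels. Raises :class:`PairingError` when the two records do
    not form a pre/post pair for one subject.
    """
    if pre.subject_id != post.subject_id:
        raise PairingError(
            f"subject mismatch: {pre.subject_id!r} vs {post.subject_id!r}"
        )
    if pre.phase != "pre" or post.phase != "post":
        raise PairingError(
            f"expected phases (pre, post), got ({pre.phase!r}, {post.phase!r})"
        )
    d_vpep = None
    if pre.pep.vertical is not None and post.pep.vertical is not None:
        d_vpep = post.pep.vertical - pre.pep.vertical
    return DifferenceVector(
        subject_id=pre.subject_id,
        d_va=post.va.logmar - pre.va.logmar,
        d_brbp=post.interocular_brbp() - pre.interocular_brbp(),
        d_hpep=post.pep.horizontal - pre.pep.horizontal,
        d_sa=post.stereo.level - pre.stereo.level,
        d_vpep=d_vpep,
    )
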