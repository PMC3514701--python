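"""Vertebral-column data model and the deterministic classification rules.

A presacral column is an ordered list of vertebrae, each carrying one rib
observation per side.  The rules implemented here turn a column into

* a set of boundary shifts (cervico-thoracic, thoraco-lumbar, lumbo-sacral),
* one of eight pattern classes (``R`` … ``CT_TL_LS``),
* an ordinal severity score on the 0–9 anteriority scale, and
* regional vertebra counts in half-unit increments.

The regular human formula is 7 cervical + 12 thoracic + 5 lumbar = 24
presacral vertebrae.  Vertebra ordinals are 1-based counting caudally from
the atlas, so the seventh vertebra is the last cervical one, positions 8–19
are thoracic and positions 20+ are lumbar in a regular column.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

# anatomical landmarks of the regular formula (1-based ordinals)
C7_ORDINAL = 7
FIRST_THORACIC_ORDINAL = 8
LAST_THORACIC_ORDINAL = 19
FIRST_LUMBAR_ORDINAL = 20
REGULAR_PRESACRAL = 24

#: columns outside this presacral range are patterning-wise "extreme"
#: (absence-of-formation cases such as caudal regression), still counted.
EXTREME_PRESACRAL_RANGE = (22, 26)


class RibState(str, enum.Enum):
    ABSENT = "absent"
    TP_ENLARGED = "tp_enlarged"  # enlarged transverse process (apophysomegaly)
    PRESENT = "present"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class RibClass(str, enum.Enum):
    FULL = "full"
    RUDIMENTARY = "rudimentary"
    ABSENT = "absent"


class RibPosition(str, enum.Enum):
    FIRST_THORACIC = "first_thoracic"
    LAST_THORACIC = "last_thoracic"
    OTHER = "other"


class C7Class(str, enum.Enum):
    NORMAL = "normal"
    TRANSITIONAL = "transitional_cervicothoracic"
    THORACIC_IDENTITY = "thoracic_identity"


class ShiftDirection(str, enum.Enum):
    ANTERIOR = "anterior"
    POSTERIOR = "posterior"
    NONE = "none"


class Quality(str, enum.Enum):
    EVALUABLE = "evaluable"
    INSUFFICIENT_OSSIFICATION = "insufficient_ossification"
    UNINTERPRETABLE = "uninterpretable"


class PatternClass(str, enum.Enum):
    """Eight-class coding of which regional boundaries are shifted."""

    R = "R"
    LS = "LS"
    TL = "TL"
    TL_LS = "TL_LS"
    CT = "CT"
    CT_LS = "CT_LS"
    CT_TL = "CT_TL"
    CT_TL_LS = "CT_TL_LS"


#: Ordinal severity of each pattern class.  Anterior (cervico-thoracic)
#: changes are scored as more severe than posterior ones, and each extra
#: shifted boundary adds to the score; 2 and 5 are deliberately unused.
SEVERITY_SCALE: dict[PatternClass, int] = {
    PatternClass.R: 0,
    PatternClass.LS: 1,
    PatternClass.TL: 3,
    PatternClass.TL_LS: 4,
    PatternClass.CT: 6,
    PatternClass.CT_LS: 7,
    PatternClass.CT_TL: 8,
    PatternClass.CT_TL_LS: 9,
}


class ColumnError(ValueError):
    """Raised on structurally invalid or unclassifiable morphology input."""


@dataclass
class RibObservation:
    """One side's rib state at one vertebra.

    ``length_ratio`` is the rib length as a fraction of the adjacent
    thoracic rib's length; it is required when ``state`` is ``present`` and
    must be absent otherwise.  ``tp_exceeds_t1`` flags an enlarged
    transverse process longer than that of the first thoracic vertebra and
    is only meaningful at the seventh vertebra.
    """

    side: Side
    state: RibState
    length_ratio: float | None = None
    tp_exceeds_t1: bool = False

    def __post_init__(self) -> None:
        self.side = Side(self.side)
        self.state = RibState(self.state)
        if self.length_ratio is not None and self.length_ratio < 0:
            raise ColumnError(f"negative length_ratio {self.length_ratio}")
        if self.state is not RibState.PRESENT and self.length_ratio is not None:
            raise ColumnError(f"length_ratio given for state {self.state.value}")


@dataclass
class Vertebra:
    ordinal: int
    ribs: tuple[RibObservation, RibObservation]
    sacral_attached: bool = False
    ls_transitional: bool = False

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ColumnError(f"ordinal {self.ordinal} < 1")
        sides = {r.side for r in self.ribs}
        if sides != {Side.LEFT, Side.RIGHT}:
            raise ColumnError("need exactly one rib observation per side")

    def rib(self, side: Side) -> RibObservation:
        return next(r for r in self.ribs if r.side is side)


@dataclass
class VertebralColumn:
    """Presacral portion of one subject's vertebral column."""

    subject_id: str
    vertebrae: list[Vertebra]
    quality: Quality = Quality.EVALUABLE

    def __post_init__(self) -> None:
        self.quality = Quality(self.quality)
        ordinals = [v.ordinal for v in self.vertebrae]
        if ordinals != list(range(1, len(ordinals) + 1)):
            raise ColumnError(
                f"{self.subject_id}: ordinals must be contiguous from 1, got {ordinals}"
            )

    @property
    def presacral_count(self) -> int:
        return len(self.vertebrae)

    @property
    def is_extreme(self) -> bool:
        lo, hi = EXTREME_PRESACRAL_RANGE
        return not lo <= self.presacral_count <= hi

    @property
    def ls_transitional(self) -> bool:
        return any(v.ls_transitional for v in self.vertebrae)

    def vertebra(self, ordinal: int) -> Vertebra | None:
        if 1 <= ordinal <= len(self.vertebrae):
            return self.vertebrae[ordinal - 1]
        return None


@dataclass
class BoundaryShiftSet:
    ct: bool = False
    tl: bool = False
    ls: bool = False
    ct_direction: ShiftDirection = ShiftDirection.NONE
    tl_direction: ShiftDirection = ShiftDirection.NONE

    def __post_init__(self) -> None:
        if self.ct != (self.ct_direction is not ShiftDirection.NONE):
            raise ColumnError("ct flag inconsistent with ct_direction")
        if self.tl != (self.tl_direction is not ShiftDirection.NONE):
            raise ColumnError("tl flag inconsistent with tl_direction")


@dataclass
class RegionalCounts:
    """Vertebra counts per region, transitional vertebrae counted as halves."""

    cervical: float
    thoracic: float
    lumbar: float
    presacral: int
    segmentation_suspect: bool = False

    def __post_init__(self) -> None:
        total = self.cervical + self.thoracic + self.lumbar
        if abs(total - self.presacral) > 1e-9:
            raise ColumnError(
                f"regional counts {total} do not sum to presacral {self.presacral}"
            )


@dataclass
class ColumnClassification:
    """Bundle of everything the rule engine derives from one column."""

    subject_id: str
    shifts: BoundaryShiftSet
    pattern: PatternClass
    severity: int
    counts: RegionalCounts
    extreme: bool = False


def classify_rib(rib: RibObservation, position: RibPosition | str) -> RibClass:
    """Classify a single rib as full, rudimentary or absent.

    At the boundary thoracic positions (first and last), a present rib is
    rudimentary when it is shorter than half the adjacent thoracic rib
    (strictly ``< 0.5``); elsewhere any present rib counts as full.  An
    enlarged transverse process is no rib at a thoracic position.
    """
    position = RibPosition(position)
    if rib.state in (RibState.ABSENT, RibState.TP_ENLARGED):
        return RibClass.ABSENT
    if position is RibPosition.OTHER:
        return RibClass.FULL
    if rib.length_ratio is None:
        raise ColumnError(
            f"present rib at {position.value} needs a length_ratio to apply the half-length rule"
        )
    return RibClass.RUDIMENTARY if rib.length_ratio < 0.5 else RibClass.FULL


# per-side outcome severity used to break bilateral disagreements
_C7_ORDER = [C7Class.NORMAL, C7Class.TRANSITIONAL, C7Class.THORACIC_IDENTITY]


def _classify_c7_side(rib: RibObservation) -> C7Class:
    if rib.state is RibState.PRESENT:
        if rib.length_ratio is None:
            raise ColumnError("cervical rib present without length_ratio")
        # "longer than half the adjacent thoracic rib" -> full thoracic identity
        if rib.length_ratio > 0.5:
            return C7Class.THORACIC_IDENTITY
        return C7Class.TRANSITIONAL
    if rib.state is RibState.TP_ENLARGED and rib.tp_exceeds_t1:
        # apophysomegaly exceeding T1's transverse process = rudimentary
        # cervical rib fused to the transverse process
        return C7Class.TRANSITIONAL
    return C7Class.NORMAL


def classify_c7(v7: Vertebra) -> C7Class:
    """Classify the seventh vertebra from its (possibly unilateral) ribs.

    Sides may disagree (rudimentary ribs are frequently unilateral); the
    more severe side decides, with a warning when one side looks fully
    thoracic while the other is normal.
    """
    per_side = [_classify_c7_side(r) for r in v7.ribs]
    worst = max(per_side, key=_C7_ORDER.index)
    if C7Class.THORACIC_IDENTITY in per_side and C7Class.NORMAL in per_side:
        log.warning(
            "seventh vertebra: one side thoracic identity, other normal; "
            "classifying by the more severe side"
        )
    return worst


def _any_side(vertebra: Vertebra, position: RibPosition, classes: set[RibClass]) -> bool:
    return any(classify_rib(r, position) in classes for r in vertebra.ribs)


def detect_shifts(column: VertebralColumn) -> BoundaryShiftSet:
    """Detect boundary shifts at the three investigated regional boundaries.

    Cervico-thoracic: anterior when the seventh vertebra bears any cervical
    rib (incl. a qualifying enlarged transverse process); posterior when the
    first thoracic rib is rudimentary or absent.  Thoraco-lumbar: anterior
    when the twelfth thoracic rib is rudimentary or absent; posterior when
    the first lumbar-position vertebra bears a rib.  Lumbo-sacral: presacral
    count differing from 24, or an observer-flagged transitional
    lumbo-sacral vertebra.
    """
    if column.quality is not Quality.EVALUABLE:
        raise ColumnError(f"{column.subject_id}: column not evaluable ({column.quality.value})")
    if not column.vertebrae:
        raise ColumnError(f"{column.subject_id}: empty column")

    ct = False
    ct_dir = ShiftDirection.NONE
    v7 = column.vertebra(C7_ORDINAL)
    if v7 is not None and classify_c7(v7) is not C7Class.NORMAL:
        ct, ct_dir = True, ShiftDirection.ANTERIOR
    t1 = column.vertebra(FIRST_THORACIC_ORDINAL)
    if not ct and t1 is not None and _any_side(
        t1, RibPosition.FIRST_THORACIC, {RibClass.RUDIMENTARY, RibClass.ABSENT}
    ):
        ct, ct_dir = True, ShiftDirection.POSTERIOR

    tl = False
    tl_dir = ShiftDirection.NONE
    t12 = column.vertebra(LAST_THORACIC_ORDINAL)
    if t12 is not None and _any_side(
        t12, RibPosition.LAST_THORACIC, {RibClass.RUDIMENTARY, RibClass.ABSENT}
    ):
        tl, tl_dir = True, ShiftDirection.ANTERIOR
    l1 = column.vertebra(FIRST_LUMBAR_ORDINAL)
    if not tl and l1 is not None and any(
        r.state is RibState.PRESENT for r in l1.ribs
    ):
        tl, tl_dir = True, ShiftDirection.POSTERIOR

    ls = column.presacral_count != REGULAR_PRESACRAL or column.ls_transitional

    return BoundaryShiftSet(ct=ct, tl=tl, ls=ls, ct_direction=ct_dir, tl_direction=tl_dir)


_PATTERN_BY_FLAGS: dict[tuple[bool, bool, bool], PatternClass] = {
    (False, False, False): PatternClass.R,
    (False, False, True): PatternClass.LS,
    (False, True, False): PatternClass.TL,
    (False, True, True): PatternClass.TL_LS,
    (True, False, False): PatternClass.CT,
    (True, False, True): PatternClass.CT_LS,
    (True, True, False): PatternClass.CT_TL,
    (True, True, True): PatternClass.CT_TL_LS,
}


def pattern_class(shifts: BoundaryShiftSet) -> PatternClass:
    """Map the (ct, tl, ls) flag triple to its pattern class (a bijection)."""
    return _PATTERN_BY_FLAGS[(shifts.ct, shifts.tl, shifts.ls)]


def shift_flags(pattern: PatternClass) -> tuple[bool, bool, bool]:
    """Inverse of :func:`pattern_class`: (ct, tl, ls) flags of a class."""
    for flags, cls in _PATTERN_BY_FLAGS.items():
        if cls is pattern:
            return flags
    raise ColumnError(f"unknown pattern {pattern}")


def severity(pattern: PatternClass) -> int:
    """Severity-scale value (0–9, never 2 or 5) of a pattern class."""
    return SEVERITY_SCALE[PatternClass(pattern)]


def regional_counts(column: VertebralColumn) -> RegionalCounts:
    """Count cervical/thoracic/lumbar vertebrae, halves for transitionals.

    Starting from the regular assignment (ordinals 1–7 cervical, 8–19
    thoracic, 20+ lumbar, clipped for short columns), each transitional
    vertebra transfers half a unit to the neighbouring region and each full
    identity change transfers a whole unit, so the regional counts always
    sum exactly to the presacral count.
    """
    n = column.presacral_count
    if n == 0:
        raise ColumnError(f"{column.subject_id}: empty column")
    cervical = float(min(n, C7_ORDINAL))
    thoracic = float(min(max(n - C7_ORDINAL, 0), 12))
    lumbar = float(max(n - LAST_THORACIC_ORDINAL, 0))
    suspect = False

    v7 = column.vertebra(C7_ORDINAL)
    if v7 is not None and column.vertebra(FIRST_THORACIC_ORDINAL) is not None:
        c7 = classify_c7(v7)
        if c7 is C7Class.TRANSITIONAL:
            cervical -= 0.5
            thoracic += 0.5
        elif c7 is C7Class.THORACIC_IDENTITY:
            cervical -= 1.0
            thoracic += 1.0

    t1 = column.vertebra(FIRST_THORACIC_ORDINAL)
    if t1 is not None:
        classes = [classify_rib(r, RibPosition.FIRST_THORACIC) for r in t1.ribs]
        if all(c is RibClass.ABSENT for c in classes):
            cervical += 1.0
            thoracic -= 1.0
        elif any(c in (RibClass.RUDIMENTARY, RibClass.ABSENT) for c in classes):
            cervical += 0.5
            thoracic -= 0.5

    t12 = column.vertebra(LAST_THORACIC_ORDINAL)
    if t12 is not None:
        classes = [classify_rib(r, RibPosition.LAST_THORACIC) for r in t12.ribs]
        if all(c is RibClass.ABSENT for c in classes):
            thoracic -= 1.0
            lumbar += 1.0
        elif any(c in (RibClass.RUDIMENTARY, RibClass.ABSENT) for c in classes):
            thoracic -= 0.5
            lumbar += 0.5

    l1 = column.vertebra(FIRST_LUMBAR_ORDINAL)
    if l1 is not None:
        ratios = [r.length_ratio for r in l1.ribs if r.state is RibState.PRESENT]
        if ratios:
            # lumbar rib: full-sized -> thoracic identity, short -> transitional
            if any(x is not None and x >= 0.5 for x in ratios):
                lumbar -= 1.0
                thoracic += 1.0
            else:
                lumbar -= 0.5
                thoracic += 0.5
        # a rib further down the lumbar region breaks region contiguity
        for v in column.vertebrae[FIRST_LUMBAR_ORDINAL:]:
            if any(r.state is RibState.PRESENT for r in v.ribs):
                suspect = True

    if suspect:
        warnings.warn(
            f"{column.subject_id}: non-contiguous rib-bearing block; "
            "regional assignment is segmentation-suspect",
            stacklevel=2,
        )
    return RegionalCounts(cervical, thoracic, lumbar, n, segmentation_suspect=suspect)


def classify_column(column: VertebralColumn) -> ColumnClassification:
    """Run the full rule chain on one evaluable column."""
    shifts = detect_shifts(column)
    pattern = pattern_class(shifts)
    if column.is_extreme:
        log.warning(
            "%s: extreme presacral count %d", column.subject_id, column.presacral_count
        )
    return ColumnClassification(
        subject_id=column.subject_id,
        shifts=shifts,
        pattern=pattern,
        severity=severity(pattern),
        counts=regional_counts(column),
        extreme=column.is_extreme,
    )
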