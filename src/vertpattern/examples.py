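"""Hand-built columns reproducing the four schematic textbook variants.

These are the canonical worked examples: a regular column, an isolated
cervical rib, a cervical rib plus rudimentary twelfth ribs, and the
three-boundary variant with only 23 presacral vertebrae.  They are used in
the README, the test suite and the acceptance checks.
"""

from __future__ import annotations

from .columns import (
    RibObservation,
    RibState,
    Side,
    Vertebra,
    VertebralColumn,
)


def _rib(side: Side, state: RibState = RibState.ABSENT, ratio: float | None = None) -> RibObservation:
    return RibObservation(side=side, state=state, length_ratio=ratio)


def _vertebra(
    ordinal: int,
    left: RibObservation | None = None,
    right: RibObservation | None = None,
    ls_transitional: bool = False,
) -> Vertebra:
    return Vertebra(
        ordinal=ordinal,
        ribs=(
            left or _rib(Side.LEFT),
            right or _rib(Side.RIGHT),
        ),
        ls_transitional=ls_transitional,
    )


def _column(subject_id: str, vertebrae: dict[int, Vertebra], presacral: int) -> VertebralColumn:
    full = [
        vertebrae.get(i) or _default_vertebra(i, presacral)
        for i in range(1, presacral + 1)
    ]
    return VertebralColumn(subject_id=subject_id, vertebrae=full)


def _default_vertebra(ordinal: int, presacral: int) -> Vertebra:
    # thoracic block of a regular-shaped column: ordinals 8..19 bear full ribs
    if 8 <= ordinal <= min(19, presacral):
        return _vertebra(
            ordinal,
            _rib(Side.LEFT, RibState.PRESENT, 1.0),
            _rib(Side.RIGHT, RibState.PRESENT, 1.0),
        )
    return _vertebra(ordinal)


def regular_column(subject_id: str = "fig-regular") -> VertebralColumn:
    """7 cervical + 12 full-ribbed thoracic + 5 lumbar; pattern R, severity 0."""
    return _column(subject_id, {}, presacral=24)


def cervical_rib_column(subject_id: str = "fig-ct", bilateral: bool = True) -> VertebralColumn:
    """Cervical rib(s) on the seventh vertebra only; pattern CT, severity 6."""
    v7 = _vertebra(
        7,
        _rib(Side.LEFT, RibState.PRESENT, 0.3),
        _rib(Side.RIGHT, RibState.PRESENT, 0.3) if bilateral else _rib(Side.RIGHT),
    )
    return _column(subject_id, {7: v7}, presacral=24)


def cervical_and_twelfth_rib_column(subject_id: str = "fig-ct-tl") -> VertebralColumn:
    """Cervical ribs plus rudimentary twelfth ribs; pattern CT_TL, severity 8."""
    v7 = _vertebra(
        7,
        _rib(Side.LEFT, RibState.PRESENT, 0.3),
        _rib(Side.RIGHT, RibState.PRESENT, 0.3),
    )
    v19 = _vertebra(
        19,
        _rib(Side.LEFT, RibState.PRESENT, 0.3),
        _rib(Side.RIGHT, RibState.PRESENT, 0.3),
    )
    return _column(subject_id, {7: v7, 19: v19}, presacral=24)


def three_boundary_column(subject_id: str = "fig-ct-tl-ls") -> VertebralColumn:
    """Cervical ribs, unilateral rudimentary twelfth rib and four lumbar
    vertebrae (23 presacral); pattern CT_TL_LS, severity 9."""
    v7 = _vertebra(
        7,
        _rib(Side.LEFT, RibState.PRESENT, 0.3),
        _rib(Side.RIGHT, RibState.PRESENT, 0.3),
    )
    v19 = _vertebra(
        19,
        _rib(Side.LEFT, RibState.PRESENT, 0.3),
        _rib(Side.RIGHT, RibState.PRESENT, 1.0),
    )
    return _column(subject_id, {7: v7, 19: v19}, presacral=23)


def twelfth_rib_column(subject_id: str = "ex-tl") -> VertebralColumn:
    """Rudimentary twelfth thoracic rib only; pattern TL, severity 3."""
    v19 = _vertebra(
        19,
        _rib(Side.LEFT, RibState.PRESENT, 0.3),
        _rib(Side.RIGHT, RibState.PRESENT, 0.3),
    )
    return _column(subject_id, {19: v19}, presacral=24)


def depicted_columns() -> list[VertebralColumn]:
    """The four schematic variants in increasing severity order (0, 6, 8, 9)."""
    return [
        regular_column(),
        cervical_rib_column(),
        cervical_and_twelfth_rib_column(),
        three_boundary_column(),
    ]
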