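"""Unit and property tests for the vertebral-column rule engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertpattern import columns as vc
from vertpattern.columns import (
    BoundaryShiftSet,
    C7Class,
    ColumnError,
    PatternClass,
    RibClass,
    RibObservation,
    RibPosition,
    RibState,
    ShiftDirection,
    Side,
    classify_c7,
    classify_column,
    classify_rib,
    detect_shifts,
    pattern_class,
    regional_counts,
    severity,
    shift_flags,
)
from vertpattern.examples import (
    cervical_and_twelfth_rib_column,
    cervical_rib_column,
    depicted_columns,
    regular_column,
    three_boundary_column,
    twelfth_rib_column,
)
from vertpattern.simulate import GeneratorConfig, synthesize_morphology


def _rib(state=RibState.ABSENT, ratio=None, side=Side.LEFT, tp=False):
    return RibObservation(side=side, state=state, length_ratio=ratio, tp_exceeds_t1=tp)


class TestClassifyRib:
    @pytest.mark.parametrize(
        "state,ratio,position,expected",
        [
            # rudimentary = strictly shorter than half the adjacent rib
            (RibState.PRESENT, 0.4, RibPosition.LAST_THORACIC, RibClass.RUDIMENTARY),
            (RibState.PRESENT, 1.0, RibPosition.OTHER, RibClass.FULL),
            # boundary case: exactly half is NOT "less than half"
            (RibState.PRESENT, 0.5, RibPosition.FIRST_THORACIC, RibClass.FULL),
            (RibState.ABSENT, None, RibPosition.FIRST_THORACIC, RibClass.ABSENT),
            (RibState.TP_ENLARGED, None, RibPosition.LAST_THORACIC, RibClass.ABSENT),
            (RibState.PRESENT, 0.2, RibPosition.OTHER, RibClass.FULL),
        ],
    )
    def test_half_length_rule(self, state, ratio, position, expected):
        assert classify_rib(_rib(state, ratio), position) is expected

    def test_missing_ratio_at_boundary_rejected(self):
        rib = RibObservation(side=Side.LEFT, state=RibState.PRESENT, length_ratio=0.4)
        rib.length_ratio = None  # simulate a missing field slipping through I/O
        with pytest.raises(ColumnError, match="length_ratio"):
            classify_rib(rib, RibPosition.FIRST_THORACIC)

    def test_ratio_required_iff_present(self):
        with pytest.raises(ColumnError):
            RibObservation(side=Side.LEFT, state=RibState.ABSENT, length_ratio=0.4)
        with pytest.raises(ColumnError):
            RibObservation(side=Side.LEFT, state=RibState.PRESENT, length_ratio=-0.1)


class TestClassifyC7:
    def _v7(self, left, right):
        return vc.Vertebra(ordinal=7, ribs=(left, right))

    def test_bilateral_short_ribs_transitional(self):
        v = self._v7(_rib(RibState.PRESENT, 0.3), _rib(RibState.PRESENT, 0.3, Side.RIGHT))
        assert classify_c7(v) is C7Class.TRANSITIONAL

    def test_long_rib_is_thoracic_identity(self):
        # longer than half the adjacent thoracic rib
        v = self._v7(_rib(RibState.PRESENT, 0.7), _rib(side=Side.RIGHT))
        assert classify_c7(v) is C7Class.THORACIC_IDENTITY

    def test_exactly_half_is_transitional_not_thoracic(self):
        v = self._v7(_rib(RibState.PRESENT, 0.5), _rib(side=Side.RIGHT))
        assert classify_c7(v) is C7Class.TRANSITIONAL

    def test_enlarged_tp_requires_exceeding_t1(self):
        v = self._v7(_rib(RibState.TP_ENLARGED, tp=False), _rib(side=Side.RIGHT))
        assert classify_c7(v) is C7Class.NORMAL
        v = self._v7(_rib(RibState.TP_ENLARGED, tp=True), _rib(side=Side.RIGHT))
        assert classify_c7(v) is C7Class.TRANSITIONAL


class TestDetectShifts:
    def test_regular_column_no_shifts(self):
        s = detect_shifts(regular_column())
        assert (s.ct, s.tl, s.ls) == (False, False, False)

    def test_bilateral_cervical_ribs_anterior_ct(self):
        s = detect_shifts(cervical_rib_column())
        assert s.ct and s.ct_direction is ShiftDirection.ANTERIOR
        assert not s.tl and not s.ls

    def test_three_boundary_column(self):
        s = detect_shifts(three_boundary_column())
        assert (s.ct, s.tl, s.ls) == (True, True, True)

    def test_rudimentary_first_rib_posterior_ct(self):
        col = regular_column("posterior-ct")
        v8 = col.vertebrae[7]
        col.vertebrae[7] = vc.Vertebra(
            ordinal=8,
            ribs=(_rib(RibState.PRESENT, 0.3), v8.rib(Side.RIGHT)),
        )
        s = detect_shifts(col)
        assert s.ct and s.ct_direction is ShiftDirection.POSTERIOR

    def test_lumbar_rib_posterior_tl(self):
        col = regular_column("posterior-tl")
        col.vertebrae[19] = vc.Vertebra(
            ordinal=20,
            ribs=(_rib(RibState.PRESENT, 0.8), _rib(side=Side.RIGHT)),
        )
        s = detect_shifts(col)
        assert s.tl and s.tl_direction is ShiftDirection.POSTERIOR

    def test_ls_flag_without_count_change(self):
        col = regular_column("ls-flag")
        col.vertebrae[-1].ls_transitional = True
        s = detect_shifts(col)
        assert s.ls and not s.ct and not s.tl

    def test_non_evaluable_and_empty_columns_rejected(self):
        col = regular_column()
        col.quality = vc.Quality.UNINTERPRETABLE
        with pytest.raises(ColumnError):
            detect_shifts(col)
        with pytest.raises(ColumnError):
            detect_shifts(vc.VertebralColumn(subject_id="x", vertebrae=[]))


class TestPatternAndSeverity:
    def test_pattern_class_bijection(self):
        seen = set()
        for ct in (False, True):
            for tl in (False, True):
                for ls in (False, True):
                    shifts = BoundaryShiftSet(
                        ct=ct, tl=tl, ls=ls,
                        ct_direction=ShiftDirection.ANTERIOR if ct else ShiftDirection.NONE,
                        tl_direction=ShiftDirection.ANTERIOR if tl else ShiftDirection.NONE,
                    )
                    cls = pattern_class(shifts)
                    assert shift_flags(cls) == (ct, tl, ls)
                    seen.add(cls)
        assert seen == set(PatternClass)

    def test_severity_scale_values(self):
        expected = {"R": 0, "LS": 1, "TL": 3, "TL_LS": 4,
                    "CT": 6, "CT_LS": 7, "CT_TL": 8, "CT_TL_LS": 9}
        assert {p.value: severity(p) for p in PatternClass} == expected

    def test_anteriority_ordering(self):
        # any C-T shift scores >= 6, none scores <= 4
        for p in PatternClass:
            ct, _, _ = shift_flags(p)
            assert (severity(p) >= 6) == ct

    def test_direction_consistency_enforced(self):
        with pytest.raises(ColumnError):
            BoundaryShiftSet(ct=True, ct_direction=ShiftDirection.NONE)


class TestRegionalCounts:
    def test_regular(self):
        c = regional_counts(regular_column())
        assert (c.cervical, c.thoracic, c.lumbar, c.presacral) == (7, 12, 5, 24)

    def test_c7_transitional_half_counts(self):
        c = regional_counts(cervical_rib_column())
        assert (c.cervical, c.thoracic, c.lumbar, c.presacral) == (6.5, 12.5, 5, 24)

    def test_three_boundary_presacral_23(self):
        c = regional_counts(three_boundary_column())
        assert c.presacral == 23
        assert c.cervical + c.thoracic + c.lumbar == 23

    def test_isolated_rudimentary_twelfth(self):
        c = regional_counts(twelfth_rib_column())
        assert (c.cervical, c.thoracic, c.lumbar) == (7, 11.5, 5.5)

    def test_far_lumbar_rib_flagged_suspect(self):
        col = regular_column("suspect")
        col.vertebrae[21] = vc.Vertebra(
            ordinal=22, ribs=(_rib(RibState.PRESENT, 0.8), _rib(side=Side.RIGHT))
        )
        col.vertebrae[19] = vc.Vertebra(
            ordinal=20, ribs=(_rib(RibState.PRESENT, 0.8), _rib(side=Side.RIGHT))
        )
        with pytest.warns(UserWarning, match="segmentation-suspect"):
            c = regional_counts(col)
        assert c.segmentation_suspect


class TestClassifyColumn:
    def test_depicted_severities(self):
        assert [classify_column(c).severity for c in depicted_columns()] == [0, 6, 8, 9]

    def test_unilateral_equals_bilateral_class(self):
        uni = classify_column(cervical_rib_column(bilateral=False))
        bi = classify_column(cervical_rib_column(bilateral=True))
        assert uni.pattern is bi.pattern is PatternClass.CT

    def test_extreme_presacral_flag(self):
        col = vc.VertebralColumn(
            subject_id="crs",
            vertebrae=[
                vc.Vertebra(ordinal=i, ribs=(_rib(), _rib(side=Side.RIGHT)))
                for i in range(1, 18)
            ],
        )
        res = classify_column(col)
        assert res.extreme and res.shifts.ls


@settings(max_examples=120, deadline=None, derandomize=True)
@given(
    pattern=st.sampled_from(list(PatternClass)),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_synthesis_roundtrip_and_count_conservation(pattern, seed):
    """Synthesised morphology classifies back to its latent class, severity
    stays on the 0-9 scale (never 2 or 5), and regional counts are conserved."""
    rng = np.random.default_rng(seed)
    col = synthesize_morphology(pattern, GeneratorConfig(), rng)
    res = classify_column(col)
    assert res.pattern is pattern
    assert res.severity in {0, 1, 3, 4, 6, 7, 8, 9}
    c = res.counts
    assert c.cervical + c.thoracic + c.lumbar == pytest.approx(c.presacral, abs=1e-12)
    assert min(c.cervical, c.thoracic, c.lumbar) >= 0
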