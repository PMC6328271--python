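import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from saccmap import geometry as geo
from saccmap.records import Condition, TrialRecord


def _trial(**kw):
    base = dict(trial_id=0, participant=0, condition=Condition.CUE_SOA50,
                saccade_side="right", cue_side="up", matrix_offset=(0.0, 0.0),
                dt_pos=(3.0, -3.0), dt_tilt=5.0, dt_onset_ms=100.0,
                fixation_period_ms=600.0)
    base.update(kw)
    return TrialRecord(**base)


class TestLayout:
    @pytest.mark.parametrize("side,cue,ft,st_,cuepos", [
        ("right", "up", (-6, 0), (6, 0), (0, 6)),
        ("left", "none", (6, 0), (-6, 0), None),
        ("right", "down", (-6, 0), (6, 0), (0, -6)),
    ])
    def test_default_layout(self, side, cue, ft, st_, cuepos):
        lay = geo.default_layout(side, cue)
        assert lay.fixation_pos == ft
        assert lay.saccade_target_pos == st_
        assert lay.cue_pos == cuepos
        assert math.hypot(*lay.saccade_vector) == pytest.approx(12.0)

    def test_poi_remap_arithmetic(self, layout):
        poi = geo.positions_of_interest(layout)
        # the fixation target is the remapped location of the saccade target
        assert geo.remapped_location(poi.st, layout.saccade_vector) == poi.ft
        assert poi.remap == (-12.0, 6.0)
        assert geo.remapped_location((5.0, 2.0), (0.0, 0.0)) == (5.0, 2.0)

    @given(st.tuples(st.floats(-20, 20), st.floats(-20, 20)),
           st.tuples(st.floats(-20, 20), st.floats(-20, 20)))
    def test_remap_involution(self, p, v):
        q = geo.remapped_location(geo.remapped_location(p, v), (-v[0], -v[1]))
        assert q[0] == pytest.approx(p[0]) and q[1] == pytest.approx(p[1])

    def test_bad_amplitude_rejected(self):
        with pytest.raises(ValueError):
            geo.ScreenLayout(fixation_pos=(0, 0), saccade_target_pos=(5, 0))


class TestGrid:
    def test_contains_pois_and_count(self, grid, poi):
        for p in (poi.ft, poi.st, poi.cue, poi.remap, (-12.0, 6.0)):
            assert p in grid
        assert len(grid.nodes) == 31
        assert grid.extent == (24.0, 18.0)

    def test_row_structure(self, grid):
        arr = grid.as_array()
        for y, n_expected, xs in [(-9, 4, {-9, -3, 3, 9}), (0, 5, {-12, -6, 0, 6, 12}),
                                  (6, 5, {-12, -6, 0, 6, 12})]:
            row = arr[arr[:, 1] == y][:, 0]
            assert len(row) == n_expected and set(row) == xs

    def test_min_internode_distance(self, grid):
        arr = grid.as_array()
        d = np.hypot(*(arr[:, None, :] - arr[None, :, :]).transpose(2, 0, 1))
        d[np.eye(len(arr), dtype=bool)] = np.inf
        assert d.min() == pytest.approx(3 * math.sqrt(2))
        assert round(d.min(), 1) == 4.2


class TestMirroring:
    def test_left_saccade_negates_x(self):
        t = geo.mirror_trial(_trial(saccade_side="left", dt_pos=(3.0, -3.0)))
        assert t.dt_pos == (-3.0, -3.0) and t.saccade_side == "right"

    def test_bottom_cue_negates_y(self):
        t = geo.mirror_trial(_trial(cue_side="down", dt_pos=(3.0, -3.0),
                                    matrix_offset=(0.0, -6.0)))
        assert t.dt_pos == (3.0, 3.0) and t.cue_side == "up"
        assert t.matrix_offset == (0.0, 6.0)

    def test_canonical_unchanged_and_involution(self):
        t0 = _trial(saccade_side="left", cue_side="down", dt_tilt=-7.0)
        once = geo.mirror_trial(t0)
        assert geo.mirror_trial(once).dt_pos == once.dt_pos  # idempotent
        assert once.dt_tilt == t0.dt_tilt  # labels untouched
        canon = _trial()
        assert geo.mirror_trial(canon).dt_pos == canon.dt_pos


class TestEccentricityGroups:
    @pytest.mark.parametrize("p,expected", [
        ((-6.0, 0.0), 1),
        ((-3.0, 3.0), 2),    # distance 3*sqrt(2) ~ 4.24
        ((6.0, 0.0), 4),     # the saccade target, 12 dva out
        ((9.0, 3.0), 5),     # ~15.3 dva
    ])
    def test_printed_ranges(self, p, expected, poi):
        assert geo.eccentricity_group(p, poi.ft) == expected

    def test_every_node_grouped_nonstrict(self, grid, poi):
        groups = [geo.eccentricity_group(p, poi.ft, strict=False)
                  for p in grid.nodes]
        assert set(groups) == {1, 2, 3, 4, 5}

    def test_far_corner_raises_in_strict_mode(self, poi):
        with pytest.raises(ValueError, match="12.0"):
            geo.eccentricity_group((12.0, 6.0), poi.ft, strict=True)

    def test_ranges_disjoint(self):
        bounds = geo.ECCENTRICITY_RANGES
        for (lo1, hi1), (lo2, _) in zip(bounds, bounds[1:]):
            assert hi1 < lo2


class TestSurround:
    def test_interior_pois_have_four_diagonal_neighbors(self, grid, poi):
        for p in (poi.ft, poi.st, poi.cue):
            s = geo.surround_positions(p, grid)
            assert len(s) == 4
            for q in s:
                assert math.hypot(q[0] - p[0], q[1] - p[1]) == pytest.approx(
                    3 * math.sqrt(2))

    def test_border_remap_warns_with_two(self, grid, poi):
        with pytest.warns(UserWarning, match="border"):
            s = geo.surround_positions(poi.remap, grid)
        assert sorted(s) == [(-9.0, 3.0), (-9.0, 9.0)]

    def test_off_grid_raises(self, grid):
        with pytest.raises(ValueError):
            geo.surround_positions((1.0, 1.0), grid)


class TestStreamOverlap:
    def test_overlap_enumeration(self, layout):
        assert geo.streams_overlap_targets((-3.0, 0.0), layout)
        assert not geo.streams_overlap_targets((0.0, -3.0), layout)
        # targets are covered iff the matrix is shifted horizontally and the
        # row lattice lands on the meridian
        on = {off for off in geo.MATRIX_OFFSETS
              if geo.streams_overlap_targets(off, layout)}
        assert on == {(dx, dy) for dx in (-3.0, 3.0) for dy in (-6.0, 0.0, 6.0)}

    def test_invalid_offset_rejected(self, layout):
        with pytest.raises(ValueError):
            geo.streams_overlap_targets((1.0, 0.0), layout)
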