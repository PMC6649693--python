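import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titramap import (
    CspParams,
    InputError,
    ParameterError,
    PerResidueProfile,
    compute_csp,
    compute_intensity_ratio,
    smooth_track,
)
from titramap.binding_model import fraction_bound

from conftest import make_peaklist


class TestComputeCsp:
    def test_zero_change_gives_zero(self):
        free = make_peaklist("f", 0, [(1, "A", 8.2, 123.0, 1e6)])
        bound = make_peaklist("b", 1, [(1, "A", 8.2, 123.0, 1e6)])
        track = compute_csp(free, bound)
        assert track.values[0] == 0.0

    def test_hand_evaluated_weighted_form(self):
        # ΔδH = 0.10, ΔδN = 0.50, alpha_n = 0.14 -> sqrt(0.01 + 0.0049)
        free = make_peaklist("f", 0, [(1, "A", 8.00, 120.00, None)])
        bound = make_peaklist("b", 1, [(1, "A", 8.10, 120.50, None)])
        track = compute_csp(free, bound, CspParams(alpha_n=0.14))
        assert track.values[0] == pytest.approx(math.sqrt(0.0149), abs=1e-12)

    def test_residue_in_one_list_is_missing(self):
        free = make_peaklist("f", 0, [(1, "A", 8.2, 123.0, None), (2, "K", 8.3, 121.0, None)])
        bound = make_peaklist("b", 1, [(1, "A", 8.2, 123.0, None)])
        track = compute_csp(free, bound)
        assert track.value_at(2) is None and track.value_at(1) == 0.0

    def test_no_shared_residues_is_error(self):
        free = make_peaklist("f", 0, [(1, "A", 8.2, 123.0, None)])
        bound = make_peaklist("b", 1, [(2, "K", 8.3, 121.0, None)])
        with pytest.raises(InputError):
            compute_csp(free, bound)

    @given(
        dh=st.floats(-1, 1, allow_nan=False),
        dn=st.floats(-5, 5, allow_nan=False),
        k=st.floats(0, 3, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_linear_scaling(self, dh, dn, k):
        """Δδ is symmetric under free/bound swap and scales linearly with k >= 0."""
        free = make_peaklist("f", 0, [(1, "A", 8.0, 120.0, None)])
        bound = make_peaklist("b", 1, [(1, "A", 8.0 + dh, 120.0 + dn, None)])
        fwd = compute_csp(free, bound).values[0]
        rev = compute_csp(bound, free).values[0]
        assert fwd == pytest.approx(rev, abs=1e-12)
        assert fwd >= 0
        scaled = make_peaklist("s", 1, [(1, "A", 8.0 + k * dh, 120.0 + k * dn, None)])
        assert compute_csp(free, scaled).values[0] == pytest.approx(k * fwd, rel=1e-9, abs=1e-12)

    def test_monotone_in_molar_ratio_on_two_state_data(self, noiseless_dataset):
        """Fraction bound is monotone in total ligand, so per-residue CSP must be too."""
        series, gt = noiseless_dataset
        tracks = [compute_csp(series.free, b) for b in series.bound_points]
        for idx in gt.contact_residues:
            vals = [t.value_at(idx) for t in tracks]
            vals = [v for v in vals if v is not None]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestIntensityRatio:
    def test_basic_ratios_and_broadened_out(self):
        free = make_peaklist(
            "f", 0, [(1, "A", 8.2, 123.0, 1e6), (2, "K", 8.3, 121.0, 1e6), (3, "G", 8.33, 109.5, 1e6)]
        )
        bound = make_peaklist("b", 1, [(1, "A", 8.2, 123.0, 1e6), (2, "K", 8.3, 121.0, 2e5)])
        track = compute_intensity_ratio(free, bound)
        assert track.value_at(1) == 1.0
        assert track.value_at(2) == pytest.approx(0.2)
        # peak present free, absent bound -> 0 flagged broadened_out
        assert track.value_at(3) == 0.0
        assert track.flags[list(track.residue_index).index(3)] == "broadened_out"

    def test_zero_free_intensity_flagged_invalid(self):
        free = make_peaklist("f", 0, [(1, "A", 8.2, 123.0, 0.0), (2, "K", 8.3, 121.0, 1e6)])
        bound = make_peaklist("b", 1, [(1, "A", 8.2, 123.0, 1e5), (2, "K", 8.3, 121.0, 1e6)])
        track = compute_intensity_ratio(free, bound)
        k = list(track.residue_index).index(1)
        assert track.flags[k] == "invalid" and track.missing_mask[k]

    def test_normalization_by_reference_set(self):
        free = make_peaklist("f", 0, [(1, "A", 8.2, 123.0, 1e6), (2, "K", 8.3, 121.0, 1e6)])
        bound = make_peaklist("b", 1, [(1, "A", 8.2, 123.0, 5e5), (2, "K", 8.3, 121.0, 2.5e5)])
        track = compute_intensity_ratio(free, bound, normalize_to={1})
        assert track.value_at(1) == pytest.approx(1.0)
        assert track.value_at(2) == pytest.approx(0.5)


class TestSmoothTrack:
    def _track(self, indices, values):
        return PerResidueProfile(
            name="t",
            residue_index=indices,
            values=values,
            missing_mask=[math.isnan(v) for v in values],
            params={},
        )

    def test_constant_track_unchanged(self):
        t = smooth_track(self._track([1, 2, 3, 4], [2.0] * 4), 3)
        np.testing.assert_allclose(t.values, 2.0)

    def test_hand_average_and_truncated_ends(self):
        t = smooth_track(self._track([1, 2, 3], [1.0, 2.0, 3.0]), 3)
        np.testing.assert_allclose(t.values, [1.5, 2.0, 2.5])

    def test_window_one_is_identity(self):
        t0 = self._track([1, 2, 3], [1.0, 5.0, 9.0])
        assert smooth_track(t0, 1) is t0

    def test_numbering_gap_breaks_window(self):
        # residues 1,2 then 10,11: windows must not bridge the gap
        t = smooth_track(self._track([1, 2, 10, 11], [1.0, 1.0, 9.0, 9.0]), 3)
        np.testing.assert_allclose(t.values, [1.0, 1.0, 9.0, 9.0])

    def test_missing_values_excluded_from_mean_and_divisor(self):
        t = smooth_track(self._track([1, 2, 3], [1.0, math.nan, 3.0]), 3)
        assert t.values[0] == 1.0 and t.values[2] == 3.0
        assert t.values[1] == pytest.approx(2.0)  # bridged from neighbours

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            smooth_track(self._track([1], [1.0]), 2)

    def test_mean_preserved_on_gap_free_track_interior(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 50)
        t = smooth_track(self._track(list(range(1, 51)), list(vals)), 3)
        # up to end effects, smoothing preserves the track mean
        assert np.mean(t.values[1:-1]) == pytest.approx(np.mean(vals[1:-1]), abs=0.05)
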