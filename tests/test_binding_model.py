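import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titramap import (
    BindingParams,
    FitError,
    ParameterError,
    ResidueResponse,
    fit_kd,
    fraction_bound,
    observed_peak,
)
from titramap.binding_model import compound_domega


def bisection_fraction_bound(p, l, kd, tol=1e-14):
    """Independent oracle: bisection on free ligand concentration."""
    if l == 0:
        return 0.0
    lo, hi = 0.0, l
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        # bound protein implied by free ligand mid: PL = P*mid/(kd+mid)
        pl = p * mid / (kd + mid) if kd + mid > 0 else p
        if pl + mid > l:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * max(1.0, l):
            break
    mid = 0.5 * (lo + hi)
    return (p * mid / (kd + mid)) / p if kd + mid > 0 else 1.0


class TestFractionBound:
    def test_no_ligand_gives_zero(self):
        assert fraction_bound(50.0, 0.0, 10.0) == 0.0

    def test_stoichiometric_limit_at_kd_zero(self):
        assert fraction_bound(50.0, 100.0, 0.0) == 1.0
        assert fraction_bound(50.0, 25.0, 0.0) == 0.5

    def test_hand_case_p_l_kd_equal(self):
        # P = L = Kd = 1: f = (3 - sqrt(5)) / 2
        assert fraction_bound(1.0, 1.0, 1.0) == pytest.approx((3 - math.sqrt(5)) / 2, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            fraction_bound(-1.0, 1.0, 1.0)
        with pytest.raises(ParameterError):
            fraction_bound(1.0, -1.0, 1.0)

    def test_agrees_with_bisection_oracle_on_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = float(rng.uniform(1, 500))
            l = float(rng.uniform(0, 1000))
            kd = float(10 ** rng.uniform(-2, 3))
            assert fraction_bound(p, l, kd) == pytest.approx(
                bisection_fraction_bound(p, l, kd), abs=1e-10
            )

    @given(
        p=st.floats(1, 100),
        l1=st.floats(0, 200),
        dl=st.floats(0, 100),
        kd=st.floats(0.01, 100),
        dkd=st.floats(0, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_ligand_and_kd_and_bounded(self, p, l1, dl, kd, dkd):
        f1 = fraction_bound(p, l1, kd)
        assert 0.0 <= f1 <= 1.0
        assert fraction_bound(p, l1 + dl, kd) >= f1 - 1e-12
        assert fraction_bound(p, l1, kd + dkd) <= f1 + 1e-12


class TestObservedPeak:
    def test_free_endpoint(self):
        resp = ResidueResponse(1, ddh=0.2, ddn=1.0, contact=True)
        h, n, inten = observed_peak(resp, 0.0, 8.0, 120.0)
        assert (h, n, inten) == (8.0, 120.0, 1.0)

    def test_saturated_endpoint_has_no_exchange_term(self):
        params = BindingParams(r2_free=10.0, r2_bound=10.0)
        resp = ResidueResponse(1, ddh=0.2, ddn=1.0, contact=True)
        h, n, inten = observed_peak(resp, 1.0, 8.0, 120.0, params)
        assert h == pytest.approx(8.2) and n == pytest.approx(121.0)
        assert inten == pytest.approx(1.0)  # f(1-f) = 0 and no size term

    def test_contact_residue_broader_than_noncontact_at_half_saturation(self):
        params = BindingParams()
        contact = ResidueResponse(1, ddh=0.2, ddn=1.0, contact=True)
        inert = ResidueResponse(2, ddh=0.0, ddn=0.0, contact=False)
        _, _, i_contact = observed_peak(contact, 0.5, 8.0, 120.0, params)
        _, _, i_inert = observed_peak(inert, 0.5, 8.0, 120.0, params)
        assert i_contact < i_inert

    def test_exchange_broadening_maximal_at_half_saturation(self):
        params = BindingParams(r2_free=10.0, r2_bound=10.0)  # isolate the Rex term
        resp = ResidueResponse(1, ddh=0.2, ddn=1.0, contact=True)
        intensities = {
            f: observed_peak(resp, f, 8.0, 120.0, params)[2] for f in (0.1, 0.3, 0.5, 0.7, 0.9)
        }
        assert min(intensities, key=intensities.get) == 0.5

    def test_domega_field_scaling(self):
        # compound Δω is linear in the spectrometer field
        assert compound_domega(0.1, 1.0, 800.0) == pytest.approx(
            2 * compound_domega(0.1, 1.0, 400.0)
        )


class TestFitKd:
    P = 50.0
    L = np.array([0.0, 25.0, 50.0, 100.0])

    def _curves(self, kd, ddmax, noise_sd=0.0, rng=None):
        f = fraction_bound(self.P, self.L, kd)
        y = np.outer(ddmax, f)
        if noise_sd:
            y = y + rng.normal(0, noise_sd, y.shape)
        return y

    def test_noiseless_recovery_is_near_exact(self):
        y = self._curves(10.0, np.array([0.2, 0.3, 0.25]))
        kd, ddmax, resid = fit_kd(self.L, y, self.P)
        assert kd == pytest.approx(10.0, rel=1e-6)
        np.testing.assert_allclose(ddmax, [0.2, 0.3, 0.25], rtol=1e-6)
        assert np.max(np.abs(resid)) < 1e-8

    def test_flat_curves_raise_fit_error(self):
        with pytest.raises(FitError):
            fit_kd(self.L, np.zeros((3, 4)), self.P)

    def test_too_few_points_raise(self):
        with pytest.raises(FitError):
            fit_kd(self.L[:2], np.ones((3, 2)), self.P)

    def test_noisy_recovery_within_twenty_percent_median(self):
        """Monte-Carlo recovery: 10 responsive residues, 4 points, 0.005 ppm noise."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ddmax = rng.uniform(0.15, 0.35, 10)
            y = self._curves(10.0, ddmax, noise_sd=0.005, rng=rng)
            kd, _, _ = fit_kd(self.L, y, self.P, noise_sd=0.005)
            errs.append(abs(kd - 10.0) / 10.0)
        assert np.median(errs) <= 0.20
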