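"""Unit and property tests for the four saturation models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modhill import (
    AdairParams,
    HillClassicParams,
    ModulatedHillParams,
    ODCDataset,
    adair_saturation,
    hill_classic_saturation,
    hill_coefficient,
    hill_macroscopic_constant,
    modulated_hill_saturation,
)
from modhill.binding_models import DomainError

GRID = np.geomspace(1e-3, 1e3, 1000)


class TestODCDataset:
    def test_sorts_and_validates(self):
        d = ODCDataset([10.0, 1.0, 5.0], [0.5, 0.1, 0.3])
        assert np.all(np.diff(d.pressures) > 0)
        assert d.saturations[0] == 0.1

    @pytest.mark.parametrize(
        "p,y",
        [
            ([1.0, 2.0], [0.1]),        # length mismatch
            ([0.0, 2.0], [0.1, 0.2]),   # non-positive pressure
            ([1.0, 2.0], [0.1, 1.2]),   # saturation out of range
            ([], []),                   # empty
            ([1.0, np.nan], [0.1, 0.2]),
        ],
    )
    def test_rejects_invalid(self, p, y):
        with pytest.raises(ValueError):
            ODCDataset(p, y)


class TestHillClassic:
    def test_half_saturation_and_zero(self):
        params = HillClassicParams(30.0, 2.0)
        assert hill_classic_saturation(30.0, params) == pytest.approx(0.5)
        assert hill_classic_saturation(0.0, params) == 0.0
        # (60/30)^2 = 4 -> 4/5
        assert hill_classic_saturation(60.0, params) == pytest.approx(0.8)

    def test_rejects_bad_pressure(self):
        params = HillClassicParams(30.0, 2.0)
        with pytest.raises(DomainError):
            hill_classic_saturation(-1.0, params)
        with pytest.raises(DomainError):
            hill_classic_saturation(np.nan, params)

    def test_macroscopic_constant_round_trip(self):
        params = HillClassicParams(10.0, 2.0)
        K = hill_macroscopic_constant(params)
        assert K == pytest.approx(0.01)
        assert K ** (-1.0 / params.h) == pytest.approx(params.p50)
        assert hill_macroscopic_constant(HillClassicParams(1.0, 3.7)) == 1.0


class TestAdair:
    def test_zero_pressure(self):
        assert adair_saturation(0.0, AdairParams(0.1, 0.01, 1e-3, 1e-4)) == 0.0

    def test_collapses_to_hill_h4(self):
        """K1=K2=K3=0 leaves only the fully-concerted term: Hill with h=4."""
        k = 2e-6
        adair = AdairParams(0.0, 0.0, 0.0, k)
        hill = HillClassicParams(k ** -0.25, 4.0)
        np.testing.assert_allclose(
            adair_saturation(GRID, adair),
            hill_classic_saturation(GRID, hill),
            rtol=1e-12, atol=1e-15,
        )

    def test_binomial_constants_give_one_site_isotherm(self):
        """Binomial K_i (independent identical sites) reduce to k p/(1+k p)."""
        k = 1.0 / 27.0
        adair = AdairParams(4 * k, 6 * k**2, 4 * k**3, k**4)
        expected = k * GRID / (1.0 + k * GRID)
        np.testing.assert_allclose(
            adair_saturation(GRID, adair), expected, rtol=1e-12, atol=1e-15
        )

    @given(
        ks=st.tuples(*[st.floats(1e-8, 1e2) for _ in range(4)]),
        p=st.floats(1e-3, 1e3),
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_boltzmann_state_enumeration(self, ks, p):
        """Oracle: mean occupancy over the five ligation states with
        statistical weights {1, K1 p, K2 p^2, K3 p^3, K4 p^4}."""
        params = AdairParams(*ks)
        w = np.array([1.0] + [ks[i - 1] * p**i for i in range(1, 5)])
        oracle = float(np.sum(np.arange(5) * w) / (4.0 * np.sum(w)))
        assert adair_saturation(p, params) == pytest.approx(oracle, rel=1e-12)


class TestHillCoefficient:
    @pytest.mark.parametrize("profile", ["gauss", "lorentz"])
    def test_peak_and_asymptotes(self, profile):
        params = ModulatedHillParams(27.0, 1.7, np.log(50.0), 2.0, profile)
        assert hill_coefficient(50.0, params) == pytest.approx(2.7)
        # Lorentz tails decay like 1/x^2, so push far out on the log axis
        assert hill_coefficient(1e-300, params) == pytest.approx(1.0, abs=1e-4)
        assert hill_coefficient(1e300, params) == pytest.approx(1.0, abs=1e-4)

    def test_lorentz_half_maximum_at_one_width(self):
        params = ModulatedHillParams(27.0, 1.7, np.log(50.0), 2.0, "lorentz")
        p = np.exp(params.ln_pmax + params.s)
        assert hill_coefficient(p, params) == pytest.approx(1.0 + 1.7 / 2.0)

    @pytest.mark.parametrize("profile", ["gauss", "lorentz"])
    @given(d=st.floats(0.0, 10.0))
    @settings(deadline=None, max_examples=50)
    def test_symmetric_on_log_axis(self, profile, d):
        params = ModulatedHillParams(27.0, 1.7, np.log(50.0), 2.0, profile)
        hp = hill_coefficient(np.exp(params.ln_pmax + d), params)
        hm = hill_coefficient(np.exp(params.ln_pmax - d), params)
        assert hp == pytest.approx(hm, rel=1e-12)

    @pytest.mark.parametrize("profile", ["gauss", "lorentz"])
    def test_bounded_between_1_and_hmax(self, profile):
        params = ModulatedHillParams(27.0, 1.7, np.log(50.0), 2.0, profile)
        h = hill_coefficient(GRID, params)
        assert np.all(h > 1.0)
        assert np.all(h <= 2.7 + 1e-12)

    def test_rejects_nonpositive_pressure(self):
        params = ModulatedHillParams(27.0, 1.7, np.log(50.0), 2.0)
        with pytest.raises(DomainError):
            hill_coefficient(0.0, params)


class TestModulatedHillSaturation:
    @pytest.mark.parametrize(
        "dataset,profile,expected",
        [
            # published whole-blood estimates; saturation at the
            # cooperativity peak matches the printed percent values
            (("winslow", "lorentz"), "lorentz", 0.7909),
            (("severinghaus", "gauss"), "gauss", 0.9574),
        ],
    )
    def test_saturation_at_peak_matches_published(self, dataset, profile, expected):
        from modhill import REFERENCE_FITS

        params = REFERENCE_FITS[dataset]
        assert params.profile == profile
        sat = modulated_hill_saturation(params.pmax, params)
        assert sat == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("profile", ["gauss", "lorentz"])
    @given(
        p50=st.floats(1.0, 200.0),
        hm1=st.floats(0.0, 4.0),
        pmax=st.floats(1.0, 200.0),
        s=st.floats(0.1, 10.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_half_saturation_preserved(self, profile, p50, hm1, pmax, s):
        params = ModulatedHillParams(p50, hm1, np.log(pmax), s, profile)
        assert modulated_hill_saturation(p50, params) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_limit_equals_classic_h1(self):
        params = ModulatedHillParams(27.0, 0.0, np.log(50.0), 2.0, "gauss")
        classic = HillClassicParams(27.0, 1.0)
        np.testing.assert_allclose(
            modulated_hill_saturation(GRID, params),
            hill_classic_saturation(GRID, classic),
            rtol=1e-12,
        )


def _reference(study, profile):
    from modhill import REFERENCE_FITS

    return REFERENCE_FITS[(study, profile)]


@pytest.mark.parametrize(
    "fn",
    [
        lambda p: hill_classic_saturation(p, HillClassicParams(27.0, 2.6)),
        lambda p: adair_saturation(p, AdairParams(0.04, 1e-3, 1e-4, 2e-6)),
        lambda p: modulated_hill_saturation(p, _reference("winslow", "gauss")),
        lambda p: modulated_hill_saturation(p, _reference("winslow", "lorentz")),
        lambda p: modulated_hill_saturation(p, _reference("severinghaus", "gauss")),
        lambda p: modulated_hill_saturation(p, _reference("severinghaus", "lorentz")),
    ],
    ids=["hill_classic", "adair", "gauss_winslow", "lorentz_winslow",
         "gauss_severinghaus", "lorentz_severinghaus"],
)
def test_all_models_monotone_and_bounded(fn):
    """On the physiological parameter sets every saturation model maps
    (0, inf) into (0, 1) and is monotone non-decreasing on a dense
    log grid.  (Monotonicity is a property of these fits, not of the
    modulated family for arbitrary width parameters.)"""
    y = np.asarray(fn(GRID))
    assert np.all((y > 0) & (y < 1))
    assert np.all(np.diff(y) >= -1e-12)
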