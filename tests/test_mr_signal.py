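"""Signal-chain tests: SPGR signal laws, T1 inversion, concentration math."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcesim import (AIF_SETTINGS, PD_SETTINGS, TISSUE_SETTINGS,
                    AcquisitionSettings, InversionRangeError, RelaxationState,
                    estimate_m0, gd_concentration, hematocrit_correct,
                    pd_normalize, signal_series_to_concentration,
                    signal_to_t1, spgr_signal, t1_from_concentration)


class TestSpgrSignal:
    def test_short_t1_limit_is_full_recovery(self):
        s = spgr_signal(RelaxationState(t1=1e-4, t1_0=1.0, m0=2.0), AIF_SETTINGS)
        assert s == pytest.approx(2.0 * math.sin(math.radians(15.0)), rel=1e-6)

    def test_monotone_decreasing_in_t1(self):
        for settings_ in (AIF_SETTINGS, TISSUE_SETTINGS, PD_SETTINGS):
            t1s = np.linspace(0.05, 5.0, 200)
            sig = [spgr_signal(RelaxationState(t1=t, t1_0=t), settings_)
                   for t in t1s]
            assert np.all(np.diff(sig) < 0)

    def test_steady_state_closed_form(self):
        # independent arithmetic of the steady-state expression
        t1, tr, flip = 1.0, 0.010, math.radians(15.0)
        e = math.exp(-tr / t1)
        expected = math.sin(flip) * (1 - e) / (1 - math.cos(flip) * e)
        got = spgr_signal(RelaxationState(t1=1.0, t1_0=1.0, m0=1.0), AIF_SETTINGS)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_saturation_prepared_below_full_recovery(self):
        """A finite saturation delay never recovers the full equilibrium
        signal m0 sin(alpha), and longer delays recover more."""
        full = math.sin(math.radians(25.0))
        shorter = AcquisitionSettings(tr_ms=10, flip_deg=25, sat_delay_ms=300,
                                      ordering="centric")
        for t1 in (0.1, 0.5, 1.0, 2.0, 5.0):
            state = RelaxationState(t1=t1, t1_0=t1)
            s = spgr_signal(state, TISSUE_SETTINGS)
            assert s < full
            assert spgr_signal(state, shorter) < s


class TestSignalToT1:
    @pytest.mark.parametrize("settings_", [AIF_SETTINGS, TISSUE_SETTINGS])
    def test_round_trip(self, settings_):
        for t1 in (0.1, 0.8, 1.5, 3.9):
            s = spgr_signal(RelaxationState(t1=t1, t1_0=t1, m0=1.3), settings_)
            assert signal_to_t1(s, 1.3, settings_) == pytest.approx(t1, abs=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(t1=st.floats(0.1, 4.0))
    def test_round_trip_property(self, t1):
        s = spgr_signal(RelaxationState(t1=t1, t1_0=t1), AIF_SETTINGS)
        assert signal_to_t1(s, 1.0, AIF_SETTINGS) == pytest.approx(t1, abs=1e-6)

    def test_out_of_range_signal_raises_with_range(self):
        top = spgr_signal(RelaxationState(t1=0.01, t1_0=1.0), AIF_SETTINGS)
        with pytest.raises(InversionRangeError) as exc:
            signal_to_t1(2.0 * top, 1.0, AIF_SETTINGS)
        lo, hi = exc.value.attainable_range
        assert lo < hi


class TestConcentration:
    def test_precontrast_is_zero(self):
        assert gd_concentration(1.5, 1.5) == 0.0

    def test_direct_arithmetic(self):
        assert gd_concentration(0.2, 1.5, 4.2) == pytest.approx(
            (1 / 4.2) * (5.0 - 2.0 / 3.0), rel=1e-12)

    def test_algebraic_inverse_exact(self):
        for t1 in (0.05, 0.3, 1.2, 2.5):
            c = gd_concentration(t1, 1.5)
            assert t1_from_concentration(c, 1.5) == pytest.approx(t1, rel=1e-14)

    def test_strictly_decreasing_in_t1(self):
        t1s = np.linspace(0.05, 3.0, 100)
        cs = [gd_concentration(t, 1.5) for t in t1s]
        assert np.all(np.diff(cs) < 0)


class TestHematocritAndNormalization:
    def test_hct_zero_is_identity(self):
        assert hematocrit_correct(1.7, 0.0) == 1.7

    def test_hct_arithmetic(self):
        assert hematocrit_correct(1.0, 0.45) == pytest.approx(1.0 / 0.55)
        assert hematocrit_correct(0.0, 0.3) == 0.0

    def test_hct_out_of_range(self):
        with pytest.raises(ValueError):
            hematocrit_correct(1.0, 1.0)

    def test_pd_normalize(self):
        np.testing.assert_allclose(pd_normalize([2.0, 4.0], 2.0), [1.0, 2.0])
        np.testing.assert_allclose(pd_normalize([2.0, 4.0], 1.0), [2.0, 4.0])
        # common scaling of dynamic and reference cancels
        np.testing.assert_allclose(pd_normalize([6.0, 12.0], 6.0),
                                   pd_normalize([2.0, 4.0], 2.0))
        with pytest.raises(ValueError):
            pd_normalize([1.0], 0.0)


class TestFullChain:
    @pytest.mark.parametrize("settings_", [AIF_SETTINGS, TISSUE_SETTINGS])
    def test_concentration_round_trip_over_phantom_range(self, settings_):
        """concentration -> T1 -> signal -> T1 -> concentration is the
        identity within 1e-6 mM across the 0-5 mM phantom range."""
        t1_0, m0 = 1.8, 0.9
        for conc in np.linspace(0.0, 5.0, 21):
            t1 = t1_from_concentration(conc, t1_0)
            s = spgr_signal(RelaxationState(t1=t1, t1_0=t1_0, m0=m0), settings_)
            t1_back = signal_to_t1(s, m0, settings_)
            back = gd_concentration(t1_back, t1_0)
            assert back == pytest.approx(conc, abs=1e-6)

    def test_series_pipeline_with_m0_estimation(self):
        t1_0 = 1.4
        concs = np.array([0.0, 0.0, 0.0, 0.2, 1.0, 0.5])
        m0_true, pd_sig = 3.7, 2.0
        sigs = np.array([
            spgr_signal(RelaxationState(t1=t1_from_concentration(c, t1_0),
                                        t1_0=t1_0, m0=m0_true), TISSUE_SETTINGS)
            for c in concs]) * pd_sig
        got = signal_series_to_concentration(sigs, pd_sig, TISSUE_SETTINGS,
                                             t1_0, n_precontrast=3)
        np.testing.assert_allclose(got, concs, atol=1e-8)

    def test_estimate_m0(self):
        s = spgr_signal(RelaxationState(t1=1.2, t1_0=1.2, m0=5.0), AIF_SETTINGS)
        assert estimate_m0(s, 1.2, AIF_SETTINGS) == pytest.approx(5.0, rel=1e-12)
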