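"""Forward-model tests: AIF generation and the Tofts-Kermode convolution."""

import numpy as np
import pytest

from dcesim import (AIFModelSpec, ConcentrationCurve, KineticParams,
                    generate_aif, tofts_forward)


class TestAIF:
    def test_grid_arithmetic(self):
        aif = generate_aif(dt=0.1, duration=300.0)
        assert aif.n == 3001
        assert aif.times[0] == 0.0
        assert aif.times[-1] == pytest.approx(300.0)

    def test_causality_zero_before_bolus_arrival(self):
        spec = AIFModelSpec(bolus_arrival_s=20.0)
        aif = generate_aif(spec)
        assert np.all(aif.values[aif.times < 20.0] == 0.0)
        assert aif.values.max() > 1.0

    def test_nonnegative_with_first_pass_peak_then_washout(self):
        aif = generate_aif()
        assert np.all(aif.values >= 0.0)
        peak_idx = int(aif.values.argmax())
        # peak within the first minute, followed by a lower recirculation tail
        assert aif.times[peak_idx] < 60.0
        assert aif.values[-1] < 0.5 * aif.values[peak_idx]
        assert aif.values[-1] > 0.0

    def test_peak_matches_dense_grid_oracle(self):
        spec = AIFModelSpec()
        coarse_peak = generate_aif(spec, dt=0.1).values.max()
        dense = spec.evaluate(np.arange(0.0, 60.0, 0.001))
        assert coarse_peak == pytest.approx(dense.max(), rel=5e-3)

    def test_nonfinite_spec_rejected(self):
        with pytest.raises(ValueError):
            AIFModelSpec(alpha=float("nan"))

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_aif(dt=-0.1)


class TestCurve:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ConcentrationCurve(0.0, 0.0, np.zeros(5))
        with pytest.raises(ValueError):
            ConcentrationCurve(0.0, 0.1, np.array([1.0]))
        with pytest.raises(ValueError):
            ConcentrationCurve(0.0, 0.1, np.array([1.0, np.inf]))

    def test_text_round_trip(self, tmp_path, default_aif):
        path = tmp_path / "aif.tsv"
        default_aif.to_text(path)
        back = ConcentrationCurve.from_text(path)
        assert back.t0 == default_aif.t0
        assert back.dt == pytest.approx(default_aif.dt, rel=1e-12)
        np.testing.assert_allclose(back.values, default_aif.values, rtol=1e-12)


class TestKineticParams:
    def test_kep_is_derived(self):
        p = KineticParams(vp=0.05, ktrans=0.1, ve=0.4)
        assert p.kep == pytest.approx(0.25)

    @pytest.mark.parametrize("kwargs", [
        dict(vp=-0.1, ktrans=0.1, ve=0.3),
        dict(vp=0.1, ktrans=-0.1, ve=0.3),
        dict(vp=0.1, ktrans=0.1, ve=0.0),
        dict(vp=1.5, ktrans=0.1, ve=0.3),
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KineticParams(**kwargs)


class TestToftsForward:
    def test_zero_ktrans_is_scaled_aif(self, default_aif):
        p = KineticParams(vp=0.07, ktrans=0.0, ve=0.3)
        ct = tofts_forward(default_aif, p)
        np.testing.assert_allclose(ct.values, 0.07 * default_aif.values,
                                   rtol=1e-12, atol=1e-15)

    def test_all_zero_params_give_zero_curve(self, default_aif):
        ct = tofts_forward(default_aif, KineticParams(vp=0.0, ktrans=0.0, ve=0.3))
        assert np.all(ct.values == 0.0)

    def test_step_input_closed_form_on_full_grid(self, grid_params):
        """Constant plasma input has the closed-form uptake
        vp*c + ve*c*(1 - exp(-kep t)); the recursive convolution must match
        within 0.1% for every kinetic parameter set of the study grid."""
        c = 3.0
        aif = ConcentrationCurve(0.0, 0.1, np.full(1201, c))
        t = aif.times
        for p in grid_params:
            expected = p.vp * c + p.ve * c * (1.0 - np.exp(-p.kep / 60.0 * t))
            got = tofts_forward(aif, p).values
            np.testing.assert_allclose(got[1:], expected[1:], rtol=1e-3)

    def test_linearity_in_aif(self, default_aif):
        p = KineticParams(vp=0.02, ktrans=0.15, ve=0.4)
        scaled = ConcentrationCurve(default_aif.t0, default_aif.dt,
                                    2.5 * default_aif.values)
        np.testing.assert_allclose(tofts_forward(scaled, p).values,
                                   2.5 * tofts_forward(default_aif, p).values,
                                   rtol=1e-12)

    def test_monotone_in_ktrans(self, default_aif):
        lo = tofts_forward(default_aif, KineticParams(vp=0.02, ktrans=0.05, ve=0.4))
        hi = tofts_forward(default_aif, KineticParams(vp=0.02, ktrans=0.2, ve=0.4))
        assert np.all(hi.values >= lo.values - 1e-12)

    def test_discretization_convergence(self, grid_params):
        """Halving the grid from 0.1 s to 0.05 s moves the tissue curve by
        less than 0.1% of its peak for every grid parameter set."""
        spec = AIFModelSpec()
        coarse = generate_aif(spec, dt=0.1, duration=120.0)
        fine = generate_aif(spec, dt=0.05, duration=120.0)
        for p in grid_params[::7]:  # representative sweep across the grid
            ct_c = tofts_forward(coarse, p).values
            ct_f = tofts_forward(fine, p).values[::2]
            scale = ct_f.max()
            assert np.max(np.abs(ct_c - ct_f)) < 1e-3 * scale

    def test_nonnegative_output(self, default_aif, grid_params):
        for p in grid_params[::11]:
            assert np.all(tofts_forward(default_aif, p).values >= 0.0)
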