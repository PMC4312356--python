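import numpy as np
import pytest

import myoflux as mf


class TestGeometry:
    @pytest.mark.parametrize("cm,sav,vol", [(59.6, 5.06, 11.78),
                                            (125.9, 4.89, 25.75),
                                            (7.0, 7.0, 1.0)])
    def test_volume_from_capacitance(self, cm, sav, vol):
        assert mf.cell_volume_from_capacitance(cm, sav) == pytest.approx(vol, abs=0.01)

    def test_non_positive_inputs_raise(self):
        with pytest.raises(mf.FluxError):
            mf.cell_volume_from_capacitance(-1.0, 5.0)
        with pytest.raises(mf.FluxError):
            mf.CellGeometry(cm=59.6, sa_to_vol=0.0)

    def test_geometry_consistency(self):
        g = mf.CellGeometry(cm=59.6, sa_to_vol=5.06)
        assert g.volume * g.sa_to_vol == pytest.approx(g.cm, abs=1e-9)


def _square_pulse_trace(i_amp=100.0, dur=1.0, dt=1e-3, pre=2.5, post=2.0, base=0.0):
    t = np.arange(0, pre + dur + post, dt)
    i = np.full(t.size, base)
    i[(t >= pre) & (t < pre + dur)] = base - i_amp  # inward deflection
    return t, i


class TestSRContent:
    geom = mf.CellGeometry(cm=59.6, sa_to_vol=5.06)

    def test_analytic_square_pulse(self):
        """100 pA inward for 1 s in an 11.78 pl cell is 88.0 umol/l."""
        t, i = _square_pulse_trace()
        res = mf.integrate_ncx_sr_content(t, i, 2.5, self.geom)
        assert res.ncx_charge == pytest.approx(100.0, rel=1e-3)
        assert res.sr_content == pytest.approx(88.0, rel=2e-3)
        assert res.pmca_correction_factor == 1.0

    def test_zero_deflection_flagged(self):
        t = np.arange(0, 5.0, 1e-3)
        res = mf.integrate_ncx_sr_content(t, np.zeros(t.size), 2.5, self.geom)
        assert res.flagged
        assert res.sr_content == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_uniform_baseline_shift(self):
        t, i = _square_pulse_trace()
        a = mf.integrate_ncx_sr_content(t, i, 2.5, self.geom)
        b = mf.integrate_ncx_sr_content(t, i - 37.0, 2.5, self.geom)
        assert b.sr_content == pytest.approx(a.sr_content, rel=1e-12)

    def test_intensive_under_cell_size_scaling(self):
        """Doubling cm (hence volume) and the current together leaves the
        volumetric content unchanged."""
        t, i = _square_pulse_trace()
        a = mf.integrate_ncx_sr_content(t, i, 2.5, self.geom)
        big = mf.CellGeometry(cm=2 * self.geom.cm, sa_to_vol=self.geom.sa_to_vol)
        b = mf.integrate_ncx_sr_content(t, 2.0 * i, 2.5, big)
        assert b.sr_content == pytest.approx(a.sr_content, rel=1e-12)

    def test_window_outside_trace_raises(self):
        t, i = _square_pulse_trace()
        with pytest.raises(mf.FluxError):
            mf.integrate_ncx_sr_content(t, i, 99.0, self.geom)

    def test_pmca_share_correction_factor(self):
        t, i = _square_pulse_trace()
        res = mf.integrate_ncx_sr_content(t, i, 2.5, self.geom, pmca_share=0.1)
        assert res.pmca_correction_factor == pytest.approx(1.0 / 0.9)
        assert res.sr_content == pytest.approx(88.0 / 0.9, rel=2e-3)

    def test_simulator_truth_recovered(self, control_params):
        """Noiseless caffeine run with PMCA disabled: content equals the SR
        store at caffeine onset within 1%."""
        p = control_params.with_(k_pmca_flux=0.0)
        out = mf.simulate(p, mf.Protocol(mode="caffeine", n_beats=12, post_caffeine_s=12.0))
        geom = mf.CellGeometry(p.cm, p.sa_to_vol)
        bf = mf.buffer_power_fit(out.time, out.ca_free, out.i_ncx,
                                 out.caffeine_onset_s, geom)
        res = mf.integrate_ncx_sr_content(out.time, out.i_ncx, out.caffeine_onset_s,
                                          geom, beta=bf.beta, ca_free=out.ca_free)
        assert res.sr_content == pytest.approx(out.sr_at_caffeine_onset, rel=0.01)


class TestCalEntry:
    geom = mf.CellGeometry(cm=59.6, sa_to_vol=5.06)

    def test_analytic_square_step(self):
        """2 pA/pF x 59.6 pF inward for 100 ms -> 5.24 umol/l (2 charges per Ca)."""
        t, i = _square_pulse_trace(i_amp=2.0 * 59.6, dur=0.1, dt=1e-5,
                                   pre=0.5, post=0.5)
        entry = mf.integrate_cal_entry(t, i, (0.5, 0.6), self.geom)
        assert entry == pytest.approx(5.24, abs=0.01)

    def test_zero_current(self):
        t = np.arange(0, 1.0, 1e-3)
        assert mf.integrate_cal_entry(t, np.zeros(t.size), (0.5, 0.6), self.geom) == 0.0

    def test_window_outside_trace_raises(self):
        t = np.arange(0, 1.0, 1e-3)
        with pytest.raises(mf.FluxError):
            mf.integrate_cal_entry(t, np.zeros(t.size), (0.9, 1.5), self.geom)

    def test_simulator_entry_recovered(self, control_pacing):
        out = control_pacing
        geom = mf.CellGeometry(out.truth.cm, out.truth.sa_to_vol)
        last = out.stim_times[-1]
        entry = mf.integrate_cal_entry(out.time, out.i_cal, (last, last + 0.12), geom)
        assert entry == pytest.approx(out.truth.entry_per_beat_true(), rel=0.01)


class TestBufferPower:
    def test_recovers_control_beta(self, control_caffeine):
        out = control_caffeine
        p = out.truth
        bf = mf.buffer_power_fit(out.time, out.ca_free, out.i_ncx,
                                 out.caffeine_onset_s,
                                 mf.CellGeometry(p.cm, p.sa_to_vol),
                                 pmca_share=p.pmca_share_true)
        assert not bf.flagged
        assert bf.beta == pytest.approx(p.beta, rel=0.02)
        assert bf.r_squared > 0.999

    def test_recovers_hf_beta(self, hf_caffeine):
        out = hf_caffeine
        p = out.truth
        bf = mf.buffer_power_fit(out.time, out.ca_free, out.i_ncx,
                                 out.caffeine_onset_s,
                                 mf.CellGeometry(p.cm, p.sa_to_vol),
                                 pmca_share=p.pmca_share_true)
        assert bf.beta == pytest.approx(p.beta, rel=0.02)

    def test_degenerate_free_ca_flagged(self):
        t = np.arange(0, 10.0, 1e-3)
        ca = np.full(t.size, 100.0)
        i = -50.0 * np.exp(-(t - 2.0).clip(0))
        bf = mf.buffer_power_fit(t, ca, i, 2.0, mf.CellGeometry(59.6, 5.06))
        assert bf.flagged

    def test_unit_audit_total_at_decay_start(self, control_caffeine):
        """Flux-balance audit: at the start of the accepted decay window the
        outstanding (PMCA-corrected) extrusion charge equals
        beta * (free Ca above the end plateau), within regression error."""
        out = control_caffeine
        p = out.truth
        geom = mf.CellGeometry(p.cm, p.sa_to_vol)
        t, ca, i = out.time, out.ca_free, out.i_ncx
        bf = mf.buffer_power_fit(t, ca, i, out.caffeine_onset_s, geom,
                                 pmca_share=p.pmca_share_true)
        ipk = int(np.argmax(np.where(t >= out.caffeine_onset_s, ca, -np.inf)))
        t_start, _ = mf.decay_window(t, ca, ipk, 0.9, 0.1)
        plateau = t >= t[-1] - 0.5
        base = float(np.median(i[plateau]))
        m = t >= t_start
        charge = float(np.trapezoid(base - i[m], t[m]))
        total_outstanding = (charge / (1.0 - p.pmca_share_true)
                             * 1e6 / (mf.FARADAY * geom.volume))
        ca_start = float(ca[np.searchsorted(t, t_start)])
        ca_end = float(np.mean(ca[plateau]))
        predicted = bf.beta * (ca_start - ca_end) / 1000.0
        assert predicted == pytest.approx(total_outstanding, rel=0.02)


class TestNCXSlope:
    def test_exactly_linear_relationship(self):
        ca = np.linspace(70, 200, 100)
        dens = 0.007 * ca + 0.1
        fit = mf.ncx_ca_slope(ca, dens)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.007)

    def test_too_few_points_raises(self):
        with pytest.raises(mf.FluxError):
            mf.ncx_ca_slope(np.arange(5.0), np.arange(5.0))

    def test_recovers_generating_g_ncx(self, control_caffeine):
        out = control_caffeine
        p = out.truth
        t, ca, i = out.time, out.ca_free, out.i_ncx
        ipk = int(np.argmax(np.where(t >= out.caffeine_onset_s, ca, -np.inf)))
        win = mf.decay_window(t, ca, ipk, 0.9, 0.1)
        plateau = (t >= win[1] - 0.5) & (t <= win[1])
        base = float(np.median(i[plateau]))
        m = (t >= win[0]) & (t <= win[1])
        fit = mf.ncx_ca_slope(ca[m], (base - i[m]) / p.cm)
        assert fit.slope == pytest.approx(p.g_ncx, rel=0.01)

    def test_recovers_imposed_downregulation_contrast(self, control_params,
                                                      control_caffeine):
        """Imposing a 24.9% lower NCX coefficient is recovered as a 24.9%
        slope reduction (within 3% of the contrast)."""
        p2 = control_params.with_(g_ncx=control_params.g_ncx * (1 - 0.249))
        out2 = mf.simulate(p2, mf.Protocol(mode="caffeine", n_beats=12,
                                           post_caffeine_s=12.0))

        def slope(out):
            t, ca, i = out.time, out.ca_free, out.i_ncx
            ipk = int(np.argmax(np.where(t >= out.caffeine_onset_s, ca, -np.inf)))
            win = mf.decay_window(t, ca, ipk, 0.9, 0.1)
            plateau = (t >= win[1] - 0.5) & (t <= win[1])
            base = float(np.median(i[plateau]))
            m = (t >= win[0]) & (t <= win[1])
            return mf.ncx_ca_slope(ca[m], (base - i[m]) / out.truth.cm).slope

        contrast = mf.percent_change(slope(control_caffeine), slope(out2))
        assert contrast == pytest.approx(24.9, abs=0.75)
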