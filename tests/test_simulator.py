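import numpy as np
import pytest
from scipy.integrate import trapezoid

import myoflux as mf


def test_no_source_steady_state(control_params):
    """With no L-type current, no release and no background influx, the cell
    sits at its resting point and carries no current."""
    p = control_params.with_(g_CaL_peak=0.0, frac_release=0.0, j_leak=0.0)
    out = mf.simulate(p, mf.Protocol(mode="voltage_step", n_beats=3))
    assert np.allclose(out.ca_free, p.ca_rest, rtol=1e-12)
    assert np.allclose(out.i_cal, 0.0)
    assert np.allclose(out.i_ncx, 0.0, atol=1e-9)


def test_seeded_runs_are_bit_identical():
    p = mf.control_preset(noise_sd_current=5.0, noise_sd_fluo=0.01).with_(seed=99)
    proto = mf.Protocol(mode="voltage_step", n_beats=2)
    a, b = mf.simulate(p, proto), mf.simulate(p, proto)
    for name in ("ca_free", "ca_sr", "i_total", "i_cal", "i_ncx", "fluo", "fura_ratio"):
        assert np.array_equal(getattr(a, name), getattr(b, name)), name


def test_caffeine_conservation_closed_system(control_params):
    """In a closed cell (no background influx) all SR Ca released by caffeine
    leaves through NCX charge plus the PMCA flux integral."""
    p = control_params.with_(j_leak=0.0)
    out = mf.simulate(p, mf.Protocol(mode="caffeine", n_beats=12, post_caffeine_s=12.0))
    m = out.time >= out.caffeine_onset_s
    ncx_umol = 1e6 * trapezoid(-out.i_ncx[m], out.time[m]) / (mf.FARADAY * p.volume_pl)
    pmca_umol = trapezoid(p.k_pmca_flux * 1e-3 * (out.ca_free[m] - p.ca_rest), out.time[m])
    extruded = ncx_umol + pmca_umol
    assert extruded == pytest.approx(out.sr_at_caffeine_onset, rel=0.01)


def test_caffeine_decay_matches_closed_form(control_caffeine):
    """The late caffeine decay is mono-exponential with the documented rate
    (K_ncx + k_pmca)/beta."""
    out = control_caffeine
    t, ca = out.time, out.ca_free
    ipk = int(np.argmax(np.where(t >= out.caffeine_onset_s, ca, -np.inf)))
    win = mf.decay_window(t, ca, ipk, 0.9, 0.1)
    fit = mf.fit_mono_exponential_decay(t, ca, window=win)
    assert fit.ok
    assert fit.k == pytest.approx(out.truth.k_caff_true, rel=0.01)


def test_pacing_reaches_limit_cycle(control_pacing, control_params):
    """Beat-to-beat SR content settles to < 0.5% difference within the
    documented 20 beats from the preset initial store."""
    out = mf.simulate(control_params, mf.Protocol(mode="voltage_step", n_beats=22))
    idx = np.searchsorted(out.time, out.stim_times) - 1
    sr = out.ca_sr[idx]
    rel = np.abs(np.diff(sr)) / sr[:-1]
    assert np.all(rel[19:] < 0.005)


def test_integration_blowup_aborts(control_params):
    with pytest.raises(mf.SimulationError):
        mf.simulate(control_params.with_(k_serca=1e14),
                    mf.Protocol(mode="voltage_step", n_beats=1))


class TestApplyCondition:
    def test_nicardipine_scales_only_ical(self, control_params):
        p2 = mf.apply_condition(control_params, "nicardipine")
        assert p2.g_CaL_peak == pytest.approx(0.70 * control_params.g_CaL_peak)
        assert p2.k_serca == control_params.k_serca
        assert p2.g_ncx == control_params.g_ncx

    def test_none_is_identity(self, control_params):
        assert mf.apply_condition(control_params, "none") == control_params

    def test_isoprenaline_reaches_stimulated_ical_density(self, control_params):
        p2 = mf.apply_condition(control_params, "isoprenaline")
        assert p2.g_CaL_peak == pytest.approx(4.26, rel=1e-6)
        assert p2.k_serca > control_params.k_serca

    def test_unknown_condition_lists_valid_names(self, control_params):
        with pytest.raises(mf.SimulationError, match="nicardipine"):
            mf.apply_condition(control_params, "caffeine-latte")


class TestEmission:
    def test_constant_input_constant_output(self):
        ca = np.full(100, 60.7)
        f = mf.emit_fluorescence(ca, mf.FluoDye())
        assert np.allclose(f, f[0])

    def test_monotone_and_saturating(self):
        ca = np.logspace(0, 8, 200)
        dye = mf.FluoDye()
        f = mf.emit_fluorescence(ca, dye)
        assert np.all(np.diff(f) > 0)
        assert f[-1] < dye.f_max
        assert f[-1] == pytest.approx(dye.f_max, rel=1e-4)
        r = mf.emit_fluorescence(ca, mf.FuraDye())
        assert np.all(np.diff(r) > 0)
        assert r[-1] < mf.FuraDye().r_max


class TestMakeCohort:
    fast = {"pacing": mf.Protocol(mode="voltage_step", n_beats=1)}

    def test_bookkeeping(self):
        recs = mf.make_cohort(mf.control_preset(), None, 6, 4, seed=1,
                              protocols=self.fast)
        assert len(recs) == 24
        assert len({r.animal_id for r in recs}) == 6

    def test_zero_cv_gives_identical_parameters(self):
        recs = mf.make_cohort(mf.control_preset(), None, 2, 2,
                              cv_animal=0.0, cv_cell=0.0, seed=1,
                              protocols=self.fast)
        base = recs[0].truth
        for r in recs[1:]:
            assert r.truth.with_(seed=0) == base.with_(seed=0)

    def test_seeded_cohorts_identical(self):
        a = mf.make_cohort(mf.control_preset(), None, 1, 2, seed=5, protocols=self.fast)
        b = mf.make_cohort(mf.control_preset(), None, 1, 2, seed=5, protocols=self.fast)
        for ra, rb in zip(a, b):
            assert ra.truth == rb.truth
            assert np.array_equal(ra.traces["pacing"]["ca_free_nM"],
                                  rb.traces["pacing"]["ca_free_nM"])

    def test_both_arms(self):
        recs = mf.make_cohort(mf.control_preset(), mf.hf_preset(), 2, 1, seed=1,
                              protocols=self.fast)
        assert {r.group for r in recs} == {"control", "hf"}
        assert len(recs) == 4


def test_ap_clamp_replays_waveform_and_evokes_transients():
    """AP-clamp mode tiles the command waveform per beat; the replayed
    action potential keeps its APD90 and each beat evokes a transient."""
    wf = mf.ap_waveform(357.0, dt_s=1e-3)
    out = mf.simulate(mf.control_preset(),
                      mf.Protocol(mode="ap_clamp", waveform=wf,
                                  waveform_dt_s=1e-3, n_beats=3))
    last = out.stim_times[-1]
    m = (out.time >= last) & (out.time < last + 1.5)
    assert mf.apd(out.time[m], out.vm[m], 0.9) == pytest.approx(357.0, abs=1.0)
    tm = mf.transient_metrics(out.time, out.ca_free, [last])[0]
    assert tm.amplitude > 50.0


class TestProtocolValidation:
    def test_waveform_required_for_ap_clamp(self):
        with pytest.raises(mf.SimulationError):
            mf.Protocol(mode="ap_clamp")

    def test_waveform_rejected_otherwise(self):
        with pytest.raises(mf.SimulationError):
            mf.Protocol(mode="voltage_step", waveform=np.zeros(10))

    def test_unknown_mode(self):
        with pytest.raises(mf.SimulationError):
            mf.Protocol(mode="tetanus")
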