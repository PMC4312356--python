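import pytest

import myoflux as mf

#: cohort study conditions used for recovery tests: photometric noise 1% of
#: resting emission, 5 pA current noise, 8%/5% animal/cell parameter CV
NOISE_SD_CURRENT = 5.0
NOISE_SD_FLUO = 0.01
CV_ANIMAL = 0.08
CV_CELL = 0.05


@pytest.fixture(scope="session")
def control_params():
    return mf.control_preset()


@pytest.fixture(scope="session")
def hf_params():
    return mf.hf_preset()


@pytest.fixture(scope="session")
def control_pacing(control_params):
    """Noiseless steady-state 0.5 Hz voltage-clamp recording."""
    return mf.simulate(control_params, mf.Protocol(mode="voltage_step", n_beats=12))


@pytest.fixture(scope="session")
def control_caffeine(control_params):
    """Noiseless caffeine application after steady-state pacing."""
    return mf.simulate(control_params,
                       mf.Protocol(mode="caffeine", n_beats=12, post_caffeine_s=12.0))


@pytest.fixture(scope="session")
def hf_caffeine(hf_params):
    return mf.simulate(hf_params,
                       mf.Protocol(mode="caffeine", n_beats=12, post_caffeine_s=12.0))


@pytest.fixture(scope="session")
def cohort():
    """6+6 animals x 4 cells with measurement noise and nested variability."""
    pc = mf.control_preset(noise_sd_current=NOISE_SD_CURRENT, noise_sd_fluo=NOISE_SD_FLUO)
    ph = mf.hf_preset(noise_sd_current=NOISE_SD_CURRENT, noise_sd_fluo=NOISE_SD_FLUO)
    return mf.make_cohort(pc, ph, n_animals=6, cells_per_animal=4,
                          cv_animal=CV_ANIMAL, cv_cell=CV_CELL, seed=20150217)


@pytest.fixture(scope="session")
def cohort_results(cohort):
    return mf.run_pipeline(cohort)


@pytest.fixture(scope="session")
def mini_records():
    """Two clean (noiseless) cells from one animal."""
    return mf.make_cohort(mf.control_preset(), None, 1, 2,
                          cv_animal=0.0, cv_cell=0.02, seed=7)
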