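import numpy as np
import pytest

import ratafib as rf


@pytest.fixture(scope="session")
def quiet_params() -> rf.AutonomicParams:
    """Unmodulated, jitter-free sinus parameters (exact IPFM output)."""
    return rf.AutonomicParams(
        mean_hr=300.0,
        lf_mod_depth=0.0,
        hf_mod_depth=0.0,
        vlf_mod_depth=0.0,
        rr_jitter_cv=0.0,
    )


@pytest.fixture(scope="session")
def study_params() -> rf.AutonomicParams:
    """Defaults emulating the before-pacing study conditions."""
    return rf.autonomic_from_targets(344.7, 20.7, 2.1, 8.6)


@pytest.fixture(scope="session")
def af_recording(study_params):
    """A 600 s recording with 3 injected AF episodes and a few APBs."""
    arr = rf.ArrhythmiaParams(
        apb_rate=30.0, af_rate=0.0, af_duration_mean=15.0, af_duration_sd=4.0
    )
    rec = rf.generate_nn_times(study_params, 600.0, 11)
    rec = rf.inject_af_episodes(rec, arr, 12, n_episodes=3)
    rec = rf.inject_apbs(rec, arr, 13)
    return rec


@pytest.fixture(scope="session")
def rendered_clean(af_recording):
    wf = rf.render_ecg(af_recording, fs=1000.0, noise_sd=0.0, seed=21)
    return af_recording, wf
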