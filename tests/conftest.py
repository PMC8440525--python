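import numpy as np
import pytest

from ssvep_rca import pipeline, synth


@pytest.fixture(scope="session")
def montage32() -> synth.SensorMontage:
    return synth.spherical_montage(32)


@pytest.fixture(scope="session")
def montage16() -> synth.SensorMontage:
    return synth.spherical_montage(16)


@pytest.fixture(scope="session")
def schedule_10_2() -> synth.StimulusSchedule:
    return synth.make_schedule(10.0, 5, 12.0, 4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def clean_recording(montage, schedule, sources, fs=500.0, **truth_kw):
    """One noise-free single-subject recording from explicit sources."""
    truth = synth.GroundTruth(sources=tuple(sources), **truth_kw)
    return synth.simulate_recording(truth, schedule, montage, fs, 1)[0]


@pytest.fixture(scope="session")
def small_condition():
    """Reduced two-source condition dataset shared by slower tests."""
    spec = pipeline.ConditionSpec("c1", base_hz=10.0, items_per_deviant=5,
                                  n_trials=6)
    montage = synth.spherical_montage(24)
    # weaker second source separates the reliability eigenvalues, which keeps
    # the two components from mixing at this reduced scale
    truth = pipeline.default_truth(montage, spec, seed=11,
                                   deviant_amps=((4.0, 3.0, 2.0, 1.2),
                                                 (1.4, 0.9, 0.55, 0.33)),
                                   latency_jitter_ms=0.0, amp_jitter_frac=0.1,
                                   noise_1f_scale=1.5, noise_white_scale=0.5)
    recs = synth.simulate_recording(truth, spec.schedule(), montage, 500.0, 8,
                                    condition_id="c1")
    cfg = pipeline.StudyConfig(conditions=(spec,), n_subjects=8, n_sensors=24,
                               seed=11)
    return {"spec": spec, "montage": montage, "truth": truth, "recs": recs,
            "cfg": cfg}
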