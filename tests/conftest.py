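import pytest

import imuvitals as iv


@pytest.fixture(scope="session")
def config():
    return iv.PipelineConfig()


@pytest.fixture(scope="session")
def constant_subject():
    """Noiseless 120 s sitting subject breathing continuously at exactly
    15 BrPM with a heart rate of exactly 72 bpm."""
    protocol = iv.default_protocol(
        1, postures=("sitting",), noise_sd={"sitting": 0.0}, apnea_duration=0.0,
        hr_trajectory=iv.PiecewiseLinear.constant(72.0),
        rr_trajectory=iv.PiecewiseLinear.constant(15.0))
    rec, truth = iv.synthesize_mechanical(protocol)
    ref = iv.synthesize_reference(protocol)
    return protocol, rec, ref, truth


@pytest.fixture(scope="session")
def small_recording():
    """10 s noiseless recording for quick I/O and preprocessing tests."""
    protocol = iv.SubjectProtocol(
        segments=[("sitting", 10.0)],
        hr_trajectory=iv.PiecewiseLinear.constant(72.0),
        rr_trajectory=iv.PiecewiseLinear.constant(15.0),
        apnea_intervals=[], noise_sd_per_posture={"sitting": 0.0}, seed=3)
    rec, truth = iv.synthesize_mechanical(protocol)
    ref = iv.synthesize_reference(protocol)
    return protocol, rec, ref, truth


@pytest.fixture(scope="session")
def sitting_cohort():
    """Five noisy sitting subjects (seeds 1-5) run through the full study:
    smooth HR 60-80 bpm and RR 9-21 BrPM trajectories, sitting-posture
    noise, all six window lengths, both sensors."""
    report, series, cohort = iv.run_study(n_subjects=5, seed=1, postures=("sitting",))
    return report, series, cohort


def pooled_mae(report, vital, sensor, window):
    rows = report.lookup("mae", vital=vital, sensor=sensor, window_s=window)
    assert len(rows) == 1
    return float(rows["value"].iloc[0])
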