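import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibrated_sim():
    """A medium synthetic cohort with the calibrated planted occipital-alpha
    effect (band-power mode for speed); shared across model-level tests."""
    from eegboost.simulate import SimulationConfig, calibrated_effect, simulate_cohort

    cfg = SimulationConfig(
        n_subjects=300, effects=(calibrated_effect(),), seed=42, eeg_mode="bandpower"
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def calibrated_dataset(calibrated_sim):
    from eegboost.cohort import apply_exclusions
    from eegboost.search import AnalysisDataset

    cohort = apply_exclusions(calibrated_sim.cohort.subjects)
    return AnalysisDataset.from_cohort(cohort, calibrated_sim.band_powers)


@pytest.fixture(scope="session")
def tiny_recordings():
    """Six short waveform recordings for feature-extraction tests."""
    from eegboost.simulate import SimulationConfig, draw_profiles, simulate_recording

    cfg = SimulationConfig(n_subjects=6, duration=4.0, seed=7)
    rng = np.random.default_rng(cfg.seed)
    profiles = draw_profiles(cfg, rng)
    return {
        f"S{i:02d}": simulate_recording(p, cfg, rng) for i, p in enumerate(profiles)
    }
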