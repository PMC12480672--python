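import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 16000


@pytest.fixture(scope="session")
def clean_voice():
    """Zero-perturbation, noise-free voiced sample."""
    from copdmon.synth.voice import VoiceSpec, gen_voice

    return gen_voice(VoiceSpec(duration_s=2.0, f0_hz=150, jitter_pct=0.0,
                               shimmer_pct=0.0, noise_snr_db=np.inf, seed=1))


@pytest.fixture(scope="session")
def perturbed_voice():
    """Planted jitter 1%, shimmer 5% voiced sample with its ground truth."""
    from copdmon.synth.voice import VoiceSpec, gen_voice

    return gen_voice(VoiceSpec(duration_s=3.0, f0_hz=140, jitter_pct=1.0,
                               shimmer_pct=5.0, seed=1))


@pytest.fixture(scope="session")
def planted_cohort():
    """20 participants x 100 days with a planted jitter effect and
    jitter x pNN20 moderation."""
    from copdmon.synth.cohort import CohortSpec, gen_cohort

    spec = CohortSpec(
        n_participants=20, n_days=100,
        fixed_effects={"jitter": -0.3},
        interaction_effects={("jitter", "hrv_pnn20"): 0.5},
        seed=42,
    )
    return gen_cohort(spec)
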