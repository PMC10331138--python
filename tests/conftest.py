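import numpy as np
import pytest

from cravecast.synthdata import (EffectConfig, Participant, PersonProfile,
                                 PersonTruth, StudyDesign, generate_schedule,
                                 simulate_compliance, simulate_craving,
                                 simulate_sensor_streams)


def make_full_participant(seed=0, design=None, effects=None, p_answer=1.0,
                          profile=None):
    """One participant with full compliance and full sensor availability,
    built from the low-level generator operations (truth retained)."""
    design = design or StudyDesign()
    effects = effects or EffectConfig()
    profile = profile or PersonProfile()
    rng = np.random.default_rng(seed)
    prompts = generate_schedule(design, rng)
    ema = simulate_compliance(prompts, p_answer, rng)
    streams = simulate_sensor_streams(design, profile, rng)
    ema, extras = simulate_craving(streams, ema, effects, rng)
    truth = PersonTruth(
        u_person=extras["u_person"], weights=extras["weights"],
        p_answer=p_answer, availability_target=1.0, availability_observed=1.0,
        sensor_score=extras["sensor_score"], latent=extras["latent"],
        drivers=extras["drivers"],
    )
    return Participant(id=f"t{seed}", streams=streams, ema=ema, truth=truth,
                       full_streams=streams, profile=profile)


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def full_participant():
    return make_full_participant(seed=7)
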