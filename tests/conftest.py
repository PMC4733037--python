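import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from unblk import GeneratorConfig, Session, Trial, UnitRecording, generate_session

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    max_examples=15,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_trial(
    index=0,
    t0=10.0,
    trial_type="upshift",
    compound=True,
    latency=0.5,
    time_in_well=1.0,
    rewarded=True,
    completed=True,
):
    """Hand-built valid trial starting at house light ``t0``."""
    light = t0
    port = light + 0.5
    odor_on = port + 0.1
    novel = odor_on + 0.2 if compound else None
    odor_off = odor_on + 1.0
    well = odor_off + latency
    reward = well + 0.15 if rewarded else None
    exit_ = (reward if rewarded else well) + time_in_well
    return Trial(
        trial_index=index,
        trial_type=trial_type,
        t_light_on=light,
        t_port_entry=port,
        t_odor_on=odor_on,
        t_novel_odor_on=novel,
        t_odor_off=odor_off,
        t_well_entry=well,
        t_reward=reward,
        t_well_exit=exit_,
        reward_size="medium" if rewarded else "none",
        completed=completed,
    )


def make_session(trials, spikes_per_unit, metadata=None):
    units = [
        UnitRecording(uid, "ratA", "sessA", 1, np.asarray(s, dtype=float))
        for uid, s in spikes_per_unit.items()
    ]
    return Session(trials=list(trials), units=units,
                   metadata=metadata or {"session_end_s": 1000.0})


@pytest.fixture
def tiny_session():
    trials = [
        make_trial(0, 10.0, "initial", compound=False),
        make_trial(1, 25.0, "upshift"),
    ]
    return make_session(trials, {"u0": [10.2, 25.9, 26.4]})


def small_config(seed=0, **kw):
    """A fast generator config for tests that need real sessions."""
    defaults = dict(
        n_units_per_category={"nonresponsive": 2, "upshift_only": 2},
        n_trials_per_novel_odor=20,
        n_reminder_trials=8,
        n_probe_reminder_trials_per_type=3,
        n_probe_trials_per_odor=5,
        p_incomplete=0.0,
        seed=seed,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def asymptotic_tuned_session():
    """Day-2 session of tuned units with learning at asymptote (shared)."""
    cfg = GeneratorConfig(
        n_units_per_category={"upshift_only": 7, "downshift_only": 7,
                              "blocked_only": 6},
        learning_midpoint_trial=-50.0,
        p_incomplete=0.0,
        seed=202,
    )
    session, truth = generate_session(cfg, 2)
    return session, truth
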