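"""Generator contracts: Poisson machinery, learning curve, structure."""

import numpy as np
import pytest
from scipy import stats

from unblk import (
    GeneratorConfig,
    generate_session,
    generate_study,
    learning_factor,
    session_rates,
)
from unblk.rates import (
    ITI_EPOCH, NOVEL_ODOR_EPOCH, analyzable_trials, epoch_rates_for_trials,
)
from conftest import small_config


def _flat_unit_session(seed, rate=5.0, n_trials=20):
    cfg = small_config(
        seed=seed,
        n_units_per_category={"nonresponsive": 1},
        n_trials_per_novel_odor=n_trials,
        baseline_median_hz=rate,
        baseline_sigma=1e-9,
    )
    session, _ = generate_session(cfg, 1)
    return session


def test_homogeneous_poisson_count():
    """A flat 5 Hz unit emits ~rate x duration spikes (Poisson mean/var)."""
    session = _flat_unit_session(seed=1)
    T = session.end_time()
    n = session.units[0].spikes.size
    expected = 5.0 * T
    assert abs(n - expected) < 3 * np.sqrt(expected)


def test_isi_distribution_is_exponential():
    """Constant-rate ISIs pass a KS test vs exponential in >=19/20 seeds."""
    passes = 0
    for seed in range(20):
        session = _flat_unit_session(seed=100 + seed)
        isi = np.diff(session.units[0].spikes)
        p = stats.kstest(isi, "expon", args=(0, 1 / 5.0)).pvalue
        passes += p > 0.01
    assert passes >= 19


def test_learning_factor_monotone_and_small_at_start():
    c = np.arange(1, 200)
    f = learning_factor(c, 82.0, 0.10)
    assert np.all(np.diff(f) >= 0)
    cfg = GeneratorConfig()
    f1 = learning_factor(1, cfg.learning_midpoint_trial, cfg.learning_slope)
    assert f1 <= 0.1  # first trial of day 1: <=10% of asymptote


def test_value_profile_rate_ordering():
    """Asymptotic value cells: downshift < blocked < upshift, ~2 Hz steps."""
    cfg = small_config(
        seed=5,
        n_units_per_category={"value": 6},
        n_trials_per_novel_odor=30,
        learning_midpoint_trial=-50.0,  # asymptote from trial 1
        baseline_sigma=1e-9,
    )
    session, _ = generate_session(cfg, 1)
    means = {}
    for tt in ("downshift", "blocked", "upshift"):
        trials = analyzable_trials(session, trial_type=tt)
        rates = np.concatenate([
            epoch_rates_for_trials(u.spikes, trials, NOVEL_ODOR_EPOCH)
            for u in session.units
        ])
        means[tt] = np.nanmean(rates)
    assert means["downshift"] < means["blocked"] < means["upshift"]
    assert abs((means["blocked"] - means["downshift"]) - 2.0) < 0.5
    assert abs((means["upshift"] - means["blocked"]) - 2.0) < 0.5


def test_nonresponsive_units_have_null_modulation():
    """Cue-epoch minus ITI rate averages to zero over >=100 trials."""
    cfg = small_config(seed=9, n_units_per_category={"nonresponsive": 3},
                       n_trials_per_novel_odor=30, n_reminder_trials=30)
    session, _ = generate_session(cfg, 1)
    df = session_rates(session)
    assert len(df) >= 3 * 100
    norm = df["normalized"].to_numpy()
    se = norm.std(ddof=1) / np.sqrt(len(norm))
    assert abs(norm.mean()) < 3 * se


def test_generation_is_deterministic():
    cfg = small_config(seed=42)
    s1, g1 = generate_session(cfg, 2)
    s2, g2 = generate_session(small_config(seed=42), 2)
    assert s1 == s2
    assert g1.profiles.keys() == g2.profiles.keys()
    s3, _ = generate_session(small_config(seed=43), 2)
    assert s3 != s1


def test_study_structure_and_unique_unit_ids():
    cfg = small_config(seed=3)
    rounds = generate_study(cfg, 2)
    assert len(rounds) == 2
    sessions = [s for r in rounds for s in r.sessions]
    assert len(sessions) == 6
    ids = [u.unit_id for s in sessions for u in s.units]
    assert len(ids) == len(set(ids))
    days = {s.metadata["day"] for s in rounds[0].sessions}
    assert days == {1, 2, "probe"}


def test_probe_time_in_well_ordering():
    """First four-trial block: upshift > blocked > downshift (extinction)."""
    cfg = GeneratorConfig(n_units_per_category={}, seed=11)
    rounds = generate_study(cfg, 4)
    sums = {"upshift": [], "blocked": [], "downshift": []}
    for r in rounds:
        counts = {}
        for t in r.probe.trials:
            if not t.completed or t.t_reward is not None:
                continue
            counts[t.trial_type] = counts.get(t.trial_type, 0) + 1
            if counts[t.trial_type] <= 4:
                sums[t.trial_type].append(t.time_in_well_s)
    means = {k: np.mean(v) for k, v in sums.items()}
    assert means["upshift"] > means["blocked"] > means["downshift"]


def test_incomplete_trials_are_flagged_and_excluded():
    cfg = small_config(seed=7, p_incomplete=0.3)
    session, _ = generate_session(cfg, 1)
    incomplete = [t for t in session.trials if not t.completed]
    assert incomplete  # at 30% abort rate some must occur
    analyzable = analyzable_trials(session)
    assert all(t.completed for t in analyzable)
    # completed per-type counts still match the configured design
    per_type = {}
    for t in analyzable:
        per_type[t.trial_type] = per_type.get(t.trial_type, 0) + 1
    assert per_type["upshift"] == cfg.n_trials_per_novel_odor


@pytest.mark.parametrize(
    "kw",
    [
        {"n_trials_per_novel_odor": 10},     # below the 20-40 design range
        {"n_trials_per_novel_odor": 50},
        {"n_probe_trials_per_odor": 12},     # probe cap is 10
        {"n_units_per_category": {"sensory": 2}, "n_reminder_trials": 0},
        {"n_units_per_category": {"weird": 1}},
        {"p_incomplete": 1.0},
    ],
)
def test_config_validation_errors(kw):
    with pytest.raises(ValueError):
        small_config(**kw)


def test_spikes_quantized_and_valid():
    session = _flat_unit_session(seed=2)
    s = session.units[0].spikes
    assert np.all(np.abs(np.round(s, 4) - s) < 1e-9)
    assert np.all(np.diff(s) > 0)
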