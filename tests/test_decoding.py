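"""Pseudo-ensemble decoding and exact binomial significance."""

import math

import numpy as np
import pytest
from scipy import stats

from unblk import (
    binomial_significance,
    build_pseudotrials,
    decode_over_time,
    decode_over_trials,
    generate_session,
    shuffle_control,
)
from unblk.decoding import PseudoTrialMatrix
from conftest import small_config


def exhaustive_tail(k, n, p):
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


class TestBinomialSignificance:
    def test_all_correct_closed_form(self):
        assert math.isclose(binomial_significance(8, 8, 0.25), 0.25**8)

    @pytest.mark.parametrize("n", [4, 8, 12, 20, 40])
    def test_chance_level_never_significant(self, n):
        k = round(0.25 * n)
        assert binomial_significance(k, n, 0.25) > 0.05

    @pytest.mark.parametrize("n,k", [(10, 3), (20, 9), (33, 15), (50, 20),
                                     (50, 50), (7, 0)])
    def test_matches_exhaustive_tail_sum(self, n, k):
        assert math.isclose(
            binomial_significance(k, n, 0.25), exhaustive_tail(k, n, 0.25),
            rel_tol=1e-10,
        )

    def test_minimal_significant_k_at_n20(self):
        """The accuracy threshold for p<0.05 equals brute-force search."""
        brute = next(k for k in range(21) if exhaustive_tail(k, 20, 0.25) < 0.05)
        ours = next(k for k in range(21)
                    if binomial_significance(k, 20, 0.25) < 0.05)
        assert ours == brute == 9  # P(X>=9 | 20, 0.25) ~= 0.041

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_significance(9, 8, 0.25)


def _matrix(rates_by_class, n_trials=8, n_bins=5, bin_width=0.1):
    """Hand-built pseudo-trial matrix with constant per-class unit rates."""
    classes = tuple(rates_by_class)
    rows, labels, within = [], [], []
    for cls, unit_rates in rates_by_class.items():
        for i in range(n_trials):
            rows.append(np.tile(np.asarray(unit_rates)[:, None], (1, n_bins)))
            labels.append(cls)
            within.append(i)
    return PseudoTrialMatrix(
        rates=np.asarray(rows, dtype=float),
        labels=np.asarray(labels),
        within_index=np.asarray(within),
        unit_ids=[f"u{i}" for i in range(len(next(iter(rates_by_class.values()))))],
        classes=classes,
        bin_starts=np.arange(n_bins) * bin_width - 0.2,
        bin_width_s=bin_width,
    )


def test_perfectly_separable_unit_decodes_fully():
    m = _matrix({"a": [0.0], "b": [100.0]})
    res = decode_over_time(m, accuracy_window_s=0.3)
    assert res.accuracy == 1.0
    assert res.chance == 0.5
    assert res.p_value < 1e-6


def test_degenerate_single_class_rejected():
    m = _matrix({"a": [1.0]})
    with pytest.raises(ValueError):
        decode_over_time(m)


def test_build_single_unit_matches_own_trials():
    cfg = small_config(seed=21, n_units_per_category={"nonresponsive": 1})
    session, _ = generate_session(cfg, 1)
    unit = session.units[0]
    m = build_pseudotrials([(unit, session)])
    assert m.unit_ids == [unit.unit_id]
    n_types = len(session.trial_types)
    assert m.rates.shape[0] == m.n_per_class * n_types
    assert m.rates.shape[1] == 1
    # spot-check one pseudo-trial against direct binning
    from unblk.rates import bin_spikes
    from unblk.heatmaps import novel_anchor
    first_up = [t for t in session.trials
                if t.completed and t.trial_type == "upshift"][0]
    expected = bin_spikes(unit.spikes, novel_anchor(first_up), (-0.2, 1.2), 0.1)
    row = np.where((m.labels == "upshift") & (m.within_index == 0))[0][0]
    assert np.allclose(m.rates[row, 0], expected)


def test_build_two_units_shapes_and_exclusion():
    cfg = small_config(seed=22, n_units_per_category={"nonresponsive": 2},
                       n_trials_per_novel_odor=20, n_reminder_trials=20)
    session, _ = generate_session(cfg, 1)
    pairs = [(u, session) for u in session.units]
    m = build_pseudotrials(pairs)
    assert m.n_per_class == 20
    assert m.rates.shape == (80, 2, 14)
    # a unit below the minimum per-type count is excluded, not fatal:
    # pair one unit with a short session (min_trial_policy trims trials)
    short = build_pseudotrials(pairs, min_trial_policy=1)
    assert len(short.unit_ids) == 2


def test_build_all_units_below_minimum_is_error():
    cfg = small_config(seed=23, n_units_per_category={"nonresponsive": 1})
    session, _ = generate_session(cfg, 1)
    with pytest.raises(ValueError):
        build_pseudotrials([(session.units[0], session)], min_trials=10_000)


def test_trialwise_window_equals_full_span_decode(asymptotic_tuned_session):
    """A single trial window covering everything reproduces the static
    window-mean decode."""
    session, _ = asymptotic_tuned_session
    pairs = [(u, session) for u in session.units]
    m = build_pseudotrials(pairs)
    full = decode_over_trials(m, trial_window=m.n_per_class,
                              accuracy_window_s=0.5, smooth_k=1)
    static = decode_over_time(m, accuracy_window_s=0.5, augmentation="none")
    assert len(full.window_accuracy) == 1
    assert full.accuracy == static.accuracy


def test_shuffled_labels_decode_at_chance(asymptotic_tuned_session):
    session, _ = asymptotic_tuned_session
    pairs = [(u, session) for u in session.units]
    m = build_pseudotrials(pairs)
    accs = shuffle_control(m, n_shuffles=30, rng=np.random.default_rng(7))
    mean = np.nanmean(accs)
    se = np.nanstd(accs, ddof=1) / np.sqrt(np.isfinite(accs).sum())
    assert abs(mean - 0.25) < max(3 * se, 0.03)


def test_tuned_ensemble_beats_chance(asymptotic_tuned_session):
    session, _ = asymptotic_tuned_session
    pairs = [(u, session) for u in session.units]
    m = build_pseudotrials(pairs, min_trial_policy=8)
    res = decode_over_time(m, accuracy_window_s=0.5)
    assert res.accuracy > res.chance
    assert res.p_value < 0.01
    assert res.extras["n_window_bins"] == 5
    assert res.n_effective == m.rates.shape[0] * 5


def test_adding_informative_unit_never_hurts(asymptotic_tuned_session):
    """Appending a perfectly informative unit keeps or raises accuracy."""
    session, _ = asymptotic_tuned_session
    pairs = [(u, session) for u in session.units[:6]]
    m = build_pseudotrials(pairs)
    base = decode_over_time(m, accuracy_window_s=0.5, augmentation="none")
    class_rate = {c: 50.0 * i for i, c in enumerate(m.classes)}
    perfect = np.array([[np.full(m.rates.shape[2], class_rate[c])]
                        for c in m.labels])
    m2 = PseudoTrialMatrix(
        rates=np.concatenate([m.rates, perfect], axis=1),
        labels=m.labels, within_index=m.within_index,
        unit_ids=m.unit_ids + ["oracle"], classes=m.classes,
        bin_starts=m.bin_starts, bin_width_s=m.bin_width_s,
    )
    boosted = decode_over_time(m2, accuracy_window_s=0.5, augmentation="none")
    assert boosted.accuracy >= base.accuracy
    assert boosted.accuracy == 1.0


def test_decode_over_trials_reports_trend(asymptotic_tuned_session):
    session, _ = asymptotic_tuned_session
    pairs = [(u, session) for u in session.units]
    m = build_pseudotrials(pairs)
    res = decode_over_trials(m, trial_window=10)
    n_windows = m.n_per_class - 10 + 1
    assert len(res.window_accuracy) == n_windows
    assert len(res.smoothed_accuracy) == n_windows - 2
    assert res.rho is not None
    # asymptotic ensemble: most windows above chance at p<0.05
    assert (res.window_p < 0.05).mean() > 0.5


def test_logistic_classifier_switch(asymptotic_tuned_session):
    session, _ = asymptotic_tuned_session
    pairs = [(u, session) for u in session.units[:8]]
    m = build_pseudotrials(pairs)
    res = decode_over_time(m, accuracy_window_s=0.5, classifier="logistic",
                           augmentation="none")
    assert 0.0 <= res.accuracy <= 1.0
    with pytest.raises(ValueError):
        decode_over_time(m, classifier="banana")
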