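"""Screens, category assignment, chi-squared and latency correlations."""

import math

import numpy as np
import pytest

from unblk import (
    GeneratorConfig,
    UnitRecording,
    category_uniformity_test,
    classify_session,
    classify_unit,
    confusion_matrix,
    generate_session,
    is_value_coding,
    latency_firing_correlation,
    screen_responsive,
)
from unblk.taxonomy import OdorResponse, OdorTest
from conftest import make_session, make_trial, small_config

ODORS = ("initial", "blocked", "upshift", "downshift")


def _response(sig, eligible=True, unanalyzable=False):
    r = OdorResponse("u", baseline_mean_rate=3.0, eligible=eligible,
                     unanalyzable=unanalyzable)
    for o in ODORS:
        s = o in sig
        r.tests[o] = OdorTest(3.0 if s else 0.1, 0.001 if s else 0.5, s, "up", 25)
    return r


class TestUniformityChi2:
    def test_published_tuned_counts(self):
        """19/16/16 tuned cells: chi2 = 0.353, p = 0.84."""
        chi2, p = category_uniformity_test([19, 16, 16])
        assert round(chi2, 3) == 0.353
        assert round(p, 2) == 0.84

    def test_uniform_counts_give_zero(self):
        chi2, _ = category_uniformity_test([17, 17, 17])
        assert chi2 == 0.0

    @pytest.mark.parametrize("counts", [[51, 0, 0], [19, 16, 16], [8, 3, 1],
                                        [10, 20, 30, 40]])
    def test_matches_hand_formula(self, counts):
        chi2, _ = category_uniformity_test(counts)
        e = sum(counts) / len(counts)
        by_hand = sum((o - e) ** 2 / e for o in counts)
        assert math.isclose(chi2, by_hand, rel_tol=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            category_uniformity_test([5])
        with pytest.raises(ValueError):
            category_uniformity_test([3, -1, 2])


@pytest.mark.parametrize(
    "sig, value_flag, expected",
    [
        (set(), False, "nonresponsive"),
        ({"initial", "blocked", "upshift", "downshift"}, False, "sensory_excluded"),
        ({"initial", "blocked", "upshift", "downshift"}, True, "value"),
        ({"upshift"}, True, "value"),
        ({"initial"}, False, "initial_only"),
        ({"upshift"}, False, "upshift_only"),
        ({"downshift"}, False, "downshift_only"),
        ({"blocked"}, False, "blocked_only"),
        ({"upshift", "downshift"}, False, "predictive"),
        ({"blocked", "upshift", "downshift"}, False, "salience"),
        ({"initial", "upshift"}, False, "other_mixed"),
        ({"blocked", "downshift"}, False, "other_mixed"),
    ],
)
def test_classification_decision_order(sig, value_flag, expected):
    result = classify_unit(_response(sig), value_flag)
    assert result.category == expected


def test_ineligible_and_unanalyzable_units_fall_out():
    assert classify_unit(_response({"upshift"}, eligible=False), False).category \
        == "nonresponsive"
    assert classify_unit(_response(set(), unanalyzable=True), False).category \
        == "nonresponsive"


def _one_unit_session(category, seed, **kw):
    cfg = small_config(
        seed=seed,
        n_units_per_category={category: 1},
        n_trials_per_novel_odor=30,
        n_reminder_trials=30,
        learning_midpoint_trial=-50.0,  # asymptotic response
        **kw,
    )
    session, _ = generate_session(cfg, 2)
    return session


def test_high_baseline_unit_is_ineligible():
    """Baseline >= 10 Hz excludes a unit from the screen regardless of tuning."""
    session = _one_unit_session("upshift_only", 3, baseline_median_hz=14.0,
                                baseline_sigma=1e-9, modulation_hz=8.0)
    resp = screen_responsive(session.units[0], session)
    assert not resp.eligible
    assert resp.baseline_mean_rate > 10


def test_screen_recovers_tuned_unit():
    """An asymptotic upshift-only unit screens upshift-significant and
    nothing else in most seeds."""
    hits, false_odors = 0, 0
    n_seeds = 10
    for seed in range(n_seeds):
        session = _one_unit_session("upshift_only", 50 + seed)
        resp = screen_responsive(session.units[0], session)
        sig = resp.significant_odors()
        hits += sig == {"upshift"}
        false_odors += len(sig - {"upshift"})
    assert hits >= 0.8 * n_seeds
    assert false_odors <= 2


def test_screen_null_unit_rarely_significant():
    flags = 0
    for seed in range(10):
        session = _one_unit_session("nonresponsive", 80 + seed)
        flags += len(screen_responsive(session.units[0], session).significant_odors())
    assert flags <= 2  # ~alpha per odor over 40 odor tests


def test_value_coding_flag():
    """Asymptotic value cells satisfy the pairwise definition in most seeds;
    upshift-only cells (downshift ~ blocked) essentially never do."""
    value_hits = sum(
        is_value_coding(s.units[0], s)
        for s in (_one_unit_session("value", 120 + k) for k in range(12))
    )
    upshift_hits = sum(
        is_value_coding(s.units[0], s)
        for s in (_one_unit_session("upshift_only", 150 + k) for k in range(12))
    )
    assert value_hits >= 6      # conjunction of three directional tests
    assert upshift_hits <= 1


def test_confusion_matrix_recovery_small_study():
    cfg = GeneratorConfig(
        n_units_per_category={"nonresponsive": 10, "upshift_only": 10},
        p_incomplete=0.0, seed=31,
    )
    session, _ = generate_session(cfg, 2)
    tax = classify_session(session)
    conf = confusion_matrix(tax, session.metadata["ground_truth"])
    assert conf.loc["upshift_only", "upshift_only"] >= 7
    assert conf.loc["nonresponsive", "nonresponsive"] >= 8


class TestLatencyCorrelation:
    def _session_with_latency(self, coupled):
        """30 upshift trials; if coupled, latency is affine in epoch count."""
        rng = np.random.default_rng(0)
        trials, spikes = [], []
        for i in range(30):
            t0 = 40.0 * i + 10.0
            k = int(rng.integers(0, 8))
            lat = 0.2 + 0.05 * k if coupled else float(rng.uniform(0.2, 0.7))
            trials.append(make_trial(i, t0, "upshift", latency=lat))
            # k spikes inside the novel-odor epoch [odor_on+0.3, odor_on+1.3)
            odor_on = t0 + 0.6
            spikes.extend(odor_on + 0.35 + 0.1 * np.arange(k))
        return make_session(trials, {"u0": sorted(spikes)})

    def test_affine_latency_gives_unit_correlation(self):
        s = self._session_with_latency(coupled=True)
        df = latency_firing_correlation(s.unit("u0"), s)
        row = df[df["trial_type"] == "upshift"].iloc[0]
        assert row["analyzable"]
        assert row["r"] > 0.999

    def test_missing_trial_types_flagged_unanalyzable(self):
        s = self._session_with_latency(coupled=False)
        df = latency_firing_correlation(s.unit("u0"), s)
        others = df[df["trial_type"] != "upshift"]
        assert (~others["analyzable"]).all()
        assert others["r"].isna().all()

    def test_independent_latency_rarely_significant(self):
        sigs, total = 0, 0
        for seed in range(8):
            session = _one_unit_session("nonresponsive", 200 + seed)
            df = latency_firing_correlation(session.units[0], session)
            ok = df[df["analyzable"]]
            sigs += (ok["p"] < 0.05).sum()
            total += len(ok)
        assert total >= 20
        assert sigs <= 0.2 * total
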