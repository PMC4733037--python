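"""End-to-end orchestration: simulate -> rates -> classify -> heatmap ->
decode -> behavior -> report.

Every stage is a pure function of its upstream artifacts and the config;
a single master seed expands deterministically (the generator derives one
stream per round and day from ``SeedSequence([seed, round, day])``), so a
given config always produces bit-identical outputs.  Stage outputs are
written as CSV/JSON under the output directory; the machine-readable
report records the config hash, per-stage results and exclusion counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .session_io import Session, write_session
from .synthetic import GeneratorConfig, StudyRound, generate_study
from .rates import (
    DEFAULT_MIN_TRIAL, NOVEL_ODOR_EPOCH, NOVEL_ODOR_EPOCH_ALT, session_rates,
)
from .taxonomy import (
    TUNED_CATEGORIES, category_uniformity_test, classify_session,
    confusion_matrix,
)
from .heatmaps import significance_map, trialwise_heatmap
from .decoding import (
    ACCURACY_WINDOW_TUNED_S, build_pseudotrials, decode_over_time,
    decode_over_trials,
)
from .behavior import behavior_table, latency_anova, planned_block_comparisons, \
    probe_anova

logger = logging.getLogger("unblk")


@dataclass
class PipelineConfig:
    """Serializable configuration of the full pipeline."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_rounds: int = 1
    alpha: float = 0.01
    heatmap_alpha: float = 0.01
    min_trial: int = DEFAULT_MIN_TRIAL
    epoch: str = "default"          # "default" (300-1300 ms) | "alt" (200-1200 ms)
    classifier: str = "lda"
    trial_window: int = 10
    accuracy_window_s: float = ACCURACY_WINDOW_TUNED_S
    heatmap_trial_type: str = "upshift"
    heatmap_n_trials: int = 10
    seed: int = 0

    def __post_init__(self):
        # master seed drives the generator unless one was set explicitly
        if self.generator.seed == 0 and self.seed != 0:
            self.generator.seed = self.seed

    @property
    def epoch_definition(self):
        return {"default": NOVEL_ODOR_EPOCH, "alt": NOVEL_ODOR_EPOCH_ALT}[self.epoch]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(_jsonable(self.to_dict()), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig(**_tupled(d["generator"]))
        return cls(**d)


def _tupled(d: dict) -> dict:
    out = dict(d)
    if "iti_range_s" in out:
        out["iti_range_s"] = tuple(out["iti_range_s"])
    if "novelty_latency_s" in out:
        out["novelty_latency_s"] = {
            (int(k) if str(k).isdigit() else k): v
            for k, v in out["novelty_latency_s"].items()
        }
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _tuned_pairs(sessions, taxonomies):
    pairs = []
    for session, tax in zip(sessions, taxonomies):
        tuned = set(tax.loc[tax["category"].isin(TUNED_CATEGORIES), "unit_id"])
        pairs += [(u, session) for u in session.units if u.unit_id in tuned]
    return pairs


def run_pipeline(
    config: PipelineConfig,
    out_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Run the whole pipeline on a synthetic study; return the report dict.

    When ``out_dir`` is given, session files and tabular stage outputs are
    written there along with ``report.json``.  On a stage failure the
    partial report (with a ``failed_stage`` marker) is still written before
    the exception propagates.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "config_hash": config.hash()}
    epoch = config.epoch_definition
    try:
        # --- simulate ---------------------------------------------------
        report["stage"] = "simulate"
        rounds: list[StudyRound] = generate_study(config.generator, config.n_rounds)
        day1 = [r.day1 for r in rounds]
        day2 = [r.day2 for r in rounds]
        probes = [r.probe for r in rounds]
        all_sessions = [s for r in rounds for s in r.sessions]
        truth: dict[str, str] = {}
        for r in rounds:
            truth.update({u: p.category for u, p in r.ground_truth.profiles.items()})
        report["simulate"] = {
            "n_rounds": config.n_rounds,
            "n_units": len(truth),
            "n_trials_total": sum(len(s.trials) for s in all_sessions),
            "n_incomplete_trials": sum(
                sum(not t.completed for t in s.trials) for s in all_sessions
            ),
        }
        if out is not None:
            for s in all_sessions:
                write_session(s, out / "sessions" / s.metadata["rat_id"]
                              / f"day{s.metadata['day']}")
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(truth, fh, indent=1)

        # --- rates ------------------------------------------------------
        report["stage"] = "rates"
        rate_frames = []
        for s in day1 + day2:
            df = session_rates(s, epoch=epoch, min_trial=1)
            df.insert(0, "session_id", s.metadata["rat_id"] + f"_d{s.metadata['day']}")
            rate_frames.append(df)
        rates_df = (pd.concat(rate_frames, ignore_index=True)
                    if rate_frames else pd.DataFrame())
        report["rates"] = {"n_rows": int(len(rates_df))}
        if out is not None and not rates_df.empty:
            rates_df.to_csv(out / "rates.csv", index=False)

        # --- classify ---------------------------------------------------
        report["stage"] = "classify"
        tax1 = [classify_session(s, alpha=config.alpha, epoch=epoch,
                                 min_trial=config.min_trial) for s in day1]
        tax2 = [classify_session(s, alpha=config.alpha, epoch=epoch,
                                 min_trial=config.min_trial) for s in day2]
        taxonomy = pd.concat(tax1 + tax2, ignore_index=True) \
            if (tax1 or tax2) else pd.DataFrame(columns=["unit_id", "category"])
        counts = taxonomy["category"].value_counts().to_dict() \
            if not taxonomy.empty else {}
        tuned_counts = [int(counts.get(c, 0)) for c in TUNED_CATEGORIES]
        chi2 = p_chi2 = None
        if sum(tuned_counts) > 0:
            chi2, p_chi2 = category_uniformity_test(tuned_counts)
        conf = None
        if not taxonomy.empty:
            conf = confusion_matrix(taxonomy, truth)
        report["classify"] = {
            "category_counts": counts,
            "tuned_counts": dict(zip(TUNED_CATEGORIES, tuned_counts)),
            "tuned_uniformity_chi2": chi2,
            "tuned_uniformity_p": p_chi2,
            "confusion_matrix": (
                {t: conf.loc[t].to_dict() for t in conf.index}
                if conf is not None else None
            ),
        }
        if out is not None and not taxonomy.empty:
            taxonomy.to_csv(out / "taxonomy.csv", index=False)

        # --- heatmap ----------------------------------------------------
        report["stage"] = "heatmap"
        heat = None
        pairs = [(u, s) for s in day1 for u in s.units]
        if pairs:
            try:
                heat = trialwise_heatmap(
                    pairs, config.heatmap_trial_type,
                    n_trials=config.heatmap_n_trials,
                )
                sig, pvals = significance_map(heat, alpha=config.heatmap_alpha)
                report["heatmap"] = {
                    "trial_type": config.heatmap_trial_type,
                    "n_units": len(heat.unit_ids),
                    "shape": list(heat.values.shape),
                    "mean_value_hz": float(heat.values.mean()),
                    "significant_fraction": float(sig.mean()),
                }
                if out is not None:
                    np.savetxt(out / "heatmap.csv", heat.values, delimiter=",")
                    np.savetxt(out / "heatmap_sig.csv", sig.astype(int),
                               delimiter=",", fmt="%d")
            except ValueError as e:
                logger.warning("heatmap skipped: %s", e)
                report["heatmap"] = {"skipped": str(e)}
        else:
            report["heatmap"] = {"skipped": "no units"}

        # --- decode -----------------------------------------------------
        report["stage"] = "decode"
        decode_report = {}
        for label, sessions, taxes in (("day1", day1, tax1), ("day2", day2, tax2)):
            pairs = _tuned_pairs(sessions, taxes)
            if len(pairs) < 2:
                decode_report[label] = {"skipped": f"{len(pairs)} tuned units"}
                continue
            m_time = build_pseudotrials(pairs, min_trial_policy=config.min_trial)
            res_t = decode_over_time(m_time, config.accuracy_window_s,
                                     classifier=config.classifier)
            m_trials = build_pseudotrials(pairs, min_trial_policy=1)
            res_w = decode_over_trials(m_trials, trial_window=config.trial_window,
                                       accuracy_window_s=config.accuracy_window_s,
                                       classifier=config.classifier)
            decode_report[label] = {
                "n_tuned_units": len(pairs),
                "time": {
                    "accuracy": res_t.accuracy,
                    "p": res_t.p_value,
                    "n_effective": res_t.n_effective,
                    "bin_accuracy": res_t.bin_accuracy,
                },
                "trials": {
                    "window_accuracy": res_w.window_accuracy,
                    "window_p": res_w.window_p,
                    "rho": res_w.rho,
                    "rho_p": res_w.rho_p,
                },
            }
        report["decode"] = decode_report

        # --- behavior ---------------------------------------------------
        report["stage"] = "behavior"
        btable = behavior_table(all_sessions)
        report["behavior"] = {
            "probe_anova": probe_anova(btable),
            "planned_comparisons": planned_block_comparisons(btable),
            "latency_anova": latency_anova(btable),
        }
        if out is not None:
            btable.to_csv(out / "behavior.csv", index=False)

        report["stage"] = "done"
    except Exception as e:
        report["failed_stage"] = report.get("stage", "unknown")
        report["error"] = str(e)
        if out is not None:
            with open(out / "report.json", "w") as fh:
                json.dump(_jsonable(report), fh, indent=1)
        raise
    report = _jsonable(report)
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return report


def report_hash(report: dict) -> str:
    """Stable hash of a report (for determinism checks)."""
    return hashlib.sha1(
        json.dumps(report, sort_keys=True).encode()
    ).hexdigest()
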