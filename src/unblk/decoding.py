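"""Pseudo-ensemble decoding of trial type.

Units recorded in separate sessions are combined into pseudo-trials:
same-trial-type trials are aligned by their within-type index (so the
learning stage is preserved) and each pseudo-trial concatenates one trial
per unit, binned at 100 ms from novel-odor onset.  A linear classifier
(regularized linear discriminant with Ledoit-Wolf shrinkage by default;
multinomial logistic available) predicts the trial type under
leave-one-trial-index-out cross-validation: each fold holds out one
pseudo-trial of *every* class, which keeps the training folds class-
balanced and avoids the anti-chance bias plain leave-one-out exhibits
under the null.

Significance of accuracy is an exact binomial upper tail.  Within a stated
accuracy window following novel-odor onset (400 ms for unselected cells,
500 ms for tuned cells), every 100 ms bin of a held-out pseudo-trial is
scored as its own prediction and the effective trial count is
n_trials x n_bins (capped at that product) — bins count as extra trials to
offset low trial numbers.  Trial-resolved decoding (sliding windows of
trials) scores one prediction per pseudo-trial from the whole accuracy
window and uses n_effective = n_trials only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression

from .session_io import Session, UnitRecording
from .rates import analyzable_trials, bin_spikes, smooth_bins
from .heatmaps import novel_anchor

logger = logging.getLogger("unblk")

DECODING_BIN_S = 0.1
#: Accuracy windows after novel-odor onset (seconds).
ACCURACY_WINDOW_ALL_S = 0.4
ACCURACY_WINDOW_TUNED_S = 0.5


@dataclass
class PseudoTrialMatrix:
    """Pseudo-population activity: rows are pseudo-trials, features are
    unit x time-bin firing rates (Hz)."""

    rates: np.ndarray          # (n_rows, n_units, n_bins)
    labels: np.ndarray         # (n_rows,) trial type
    within_index: np.ndarray   # (n_rows,) within-type trial index, 0-based
    unit_ids: list[str]
    classes: tuple[str, ...]
    bin_starts: np.ndarray     # bin start offsets from novel-odor onset
    bin_width_s: float = DECODING_BIN_S

    @property
    def n_per_class(self) -> int:
        return int(np.sum(self.labels == self.classes[0]))

    def window_bins(self, accuracy_window_s: float) -> np.ndarray:
        """Indices of bins inside [0, accuracy_window_s) after odor onset."""
        return np.where(
            (self.bin_starts >= -1e-9)
            & (self.bin_starts < accuracy_window_s - 1e-9)
        )[0]


def build_pseudotrials(
    session_units: Sequence[tuple[UnitRecording, Session]],
    bin_width_s: float = DECODING_BIN_S,
    span_s: tuple[float, float] = (-0.2, 1.2),
    min_trials: int = 4,
    min_trial_policy: int = 1,
    alignment: str = "index",
    rng: Optional[np.random.Generator] = None,
) -> PseudoTrialMatrix:
    """Assemble the pseudo-trial matrix from units across sessions.

    ``min_trial_policy`` drops the first trials of each session (pass 8 for
    the odor-period rule; trial-resolved decoding conventionally uses 1).
    Units with fewer than ``min_trials`` completed trials of any type are
    excluded (logged).  ``alignment="random"`` pairs trials randomly within
    type instead of by index (ablation); deterministic given ``rng``.
    """
    if not session_units:
        raise ValueError("no units supplied")
    classes = session_units[0][1].trial_types
    per_unit: list[dict[str, np.ndarray]] = []
    kept: list[str] = []
    for unit, session in session_units:
        binned: dict[str, np.ndarray] = {}
        for cls in classes:
            trials = analyzable_trials(session, trial_type=cls,
                                       min_trial=min_trial_policy)
            anchored = [t for t in trials if novel_anchor(t) is not None]
            rows = [bin_spikes(unit.spikes, novel_anchor(t), span_s, bin_width_s)
                    for t in anchored]
            binned[cls] = np.asarray(rows) if rows else np.empty((0, 0))
        counts = {c: len(b) for c, b in binned.items()}
        if min(counts.values()) < min_trials:
            logger.info("pseudotrials: unit %s excluded (trial counts %s < %d)",
                        unit.unit_id, counts, min_trials)
            continue
        per_unit.append(binned)
        kept.append(unit.unit_id)
    if not per_unit:
        raise ValueError(f"no unit has >= {min_trials} trials of every type")
    n_common = min(len(b[c]) for b in per_unit for c in classes)
    n_bins = per_unit[0][classes[0]].shape[1]
    if alignment == "random":
        if rng is None:
            rng = np.random.default_rng(0)
        for b in per_unit:
            for c in classes:
                b[c] = b[c][rng.permutation(len(b[c]))]
    elif alignment != "index":
        raise ValueError("alignment must be 'index' or 'random'")
    rows, labels, within = [], [], []
    for cls in classes:
        for i in range(n_common):
            rows.append(np.stack([b[cls][i] for b in per_unit]))
            labels.append(cls)
            within.append(i)
    start = span_s[0]
    bin_starts = start + bin_width_s * np.arange(n_bins)
    return PseudoTrialMatrix(
        rates=np.asarray(rows),
        labels=np.asarray(labels),
        within_index=np.asarray(within),
        unit_ids=kept,
        classes=tuple(classes),
        bin_starts=bin_starts,
        bin_width_s=bin_width_s,
    )


def _make_classifier(kind: str):
    if kind == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if kind == "logistic":
        return LogisticRegression(max_iter=500)
    raise ValueError(f"unknown classifier {kind!r}")


def _fit_predict(X_train, y_train, X_test, classifier: str) -> np.ndarray:
    classes = np.unique(y_train)
    # zero within-class variance (noiseless classes) degenerates every
    # covariance estimate; assign by nearest class mean instead
    spread = max(
        float(np.abs(X_train[y_train == c] - X_train[y_train == c].mean(axis=0)).max(
            initial=0.0))
        for c in classes
    )
    if spread < 1e-12:
        means = np.stack([X_train[y_train == c].mean(axis=0) for c in classes])
        d = ((X_test[:, None, :] - means[None]) ** 2).sum(axis=-1)
        return classes[np.argmin(d, axis=1)]
    clf = _make_classifier(classifier)
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


def _cv_predict(X: np.ndarray, y: np.ndarray, folds: np.ndarray,
                classifier: str) -> np.ndarray:
    """Leave-one-fold-out predictions; folds are the within-type indices, so
    each fold holds out one pseudo-trial per class."""
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class input")
    if classifier not in ("lda", "logistic"):
        raise ValueError(f"unknown classifier {classifier!r}")
    pred = np.empty(len(y), dtype=y.dtype)
    for f in np.unique(folds):
        test = folds == f
        pred[test] = _fit_predict(X[~test], y[~test], X[test], classifier)
    return pred


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy with exact binomial significance."""

    mode: str                       # "time" | "trials"
    accuracy: float                 # aggregate accuracy in the stated window
    k_correct: int
    n_effective: int
    chance: float
    p_value: float
    smoothing_applied: bool
    bin_accuracy: Optional[np.ndarray] = None
    bin_starts: Optional[np.ndarray] = None
    smoothed_accuracy: Optional[np.ndarray] = None
    window_accuracy: Optional[np.ndarray] = None   # trials mode
    window_p: Optional[np.ndarray] = None
    window_first_trial: Optional[np.ndarray] = None
    rho: Optional[float] = None
    rho_p: Optional[float] = None
    extras: dict = field(default_factory=dict)


def binomial_significance(k_correct: int, n_effective: int, chance: float) -> float:
    """Exact upper-tail binomial probability P(X >= k) at the chance rate."""
    if not 0 <= k_correct <= n_effective:
        raise ValueError("need 0 <= k_correct <= n_effective")
    return float(stats.binom.sf(k_correct - 1, n_effective, chance))


def decode_over_time(
    matrix: PseudoTrialMatrix,
    accuracy_window_s: float = ACCURACY_WINDOW_TUNED_S,
    classifier: str = "lda",
    augmentation: str = "bins",
    smooth_k: int = 3,
) -> DecodingResult:
    """Per-bin cross-validated accuracy plus window-aggregated significance.

    Each 100 ms bin is decoded from the instantaneous population rate.
    With ``augmentation="bins"`` every bin inside the accuracy window is
    scored as its own prediction (n_effective = n_trials x n_window_bins);
    ``augmentation="none"`` scores one prediction per pseudo-trial from the
    window-mean rates.
    """
    y, folds = matrix.labels, matrix.within_index
    n_rows, n_units, n_bins = matrix.rates.shape
    if matrix.n_per_class < 4:
        raise ValueError("need >= 4 pseudo-trials per class")
    bin_acc = np.empty(n_bins)
    bin_correct = np.empty(n_bins, dtype=int)
    for b in range(n_bins):
        pred = _cv_predict(matrix.rates[:, :, b], y, folds, classifier)
        bin_correct[b] = int(np.sum(pred == y))
        bin_acc[b] = bin_correct[b] / n_rows
    wbins = matrix.window_bins(accuracy_window_s)
    if wbins.size == 0:
        raise ValueError("accuracy window contains no bins")
    chance = 1.0 / len(matrix.classes)
    if augmentation == "bins":
        k = int(bin_correct[wbins].sum())
        n_eff = n_rows * len(wbins)   # capped at n_trials x n_bins by construction
    elif augmentation == "none":
        Xw = matrix.rates[:, :, wbins].mean(axis=2)
        pred = _cv_predict(Xw, y, folds, classifier)
        k = int(np.sum(pred == y))
        n_eff = n_rows
    else:
        raise ValueError("augmentation must be 'bins' or 'none'")
    smoothed = smooth_bins(bin_acc, smooth_k) if n_bins >= smooth_k else None
    return DecodingResult(
        mode="time",
        accuracy=k / n_eff,
        k_correct=k,
        n_effective=n_eff,
        chance=chance,
        p_value=binomial_significance(k, n_eff, chance),
        smoothing_applied=smoothed is not None,
        bin_accuracy=bin_acc,
        bin_starts=matrix.bin_starts,
        smoothed_accuracy=smoothed,
        extras={"augmentation": augmentation, "n_window_bins": int(wbins.size)},
    )


def decode_over_trials(
    matrix: PseudoTrialMatrix,
    trial_window: int = 10,
    step: int = 1,
    accuracy_window_s: float = ACCURACY_WINDOW_TUNED_S,
    classifier: str = "lda",
    smooth_k: int = 3,
) -> DecodingResult:
    """Accuracy over sliding windows of trials (learning-resolved decoding).

    Each window decodes trial type from the accuracy-window bins of the
    pseudo-trials whose within-type index falls in the window; the Spearman
    correlation of window position vs accuracy summarizes the learning
    trend.  The reported aggregate is the last (most-trained) window.
    """
    n_common = matrix.n_per_class
    if trial_window > n_common:
        raise ValueError(f"trial_window {trial_window} exceeds per-class "
                         f"trial count {n_common}")
    wbins = matrix.window_bins(accuracy_window_s)
    # window-mean rates per unit: one prediction per pseudo-trial, matching
    # decode_over_time(augmentation="none") on the same span
    X = matrix.rates[:, :, wbins].mean(axis=2)
    chance = 1.0 / len(matrix.classes)
    starts = np.arange(0, n_common - trial_window + 1, step)
    accs = np.empty(len(starts))
    ks = np.empty(len(starts), dtype=int)
    ps = np.empty(len(starts))
    for i, s in enumerate(starts):
        mask = (matrix.within_index >= s) & (matrix.within_index < s + trial_window)
        pred = _cv_predict(X[mask], matrix.labels[mask],
                           matrix.within_index[mask], classifier)
        ks[i] = int(np.sum(pred == matrix.labels[mask]))
        n = int(mask.sum())
        accs[i] = ks[i] / n
        ps[i] = binomial_significance(ks[i], n, chance)
    smoothed = smooth_bins(accs, smooth_k) if len(accs) >= smooth_k else None
    # learning trend on the smoothed curve (trial curves are conventionally
    # three-trial averaged before summary statistics)
    trend = smoothed if smoothed is not None else accs
    if len(trend) >= 3:
        rho, rho_p = stats.spearmanr(np.arange(len(trend)), trend)
        rho, rho_p = float(rho), float(rho_p)
    else:
        rho = rho_p = None
    n_last = int(np.sum((matrix.within_index >= starts[-1])
                        & (matrix.within_index < starts[-1] + trial_window)))
    return DecodingResult(
        mode="trials",
        accuracy=float(accs[-1]),
        k_correct=int(ks[-1]),
        n_effective=n_last,
        chance=chance,
        p_value=float(ps[-1]),
        smoothing_applied=smoothed is not None,
        smoothed_accuracy=smoothed,
        window_accuracy=accs,
        window_p=ps,
        window_first_trial=starts + 1,
        rho=rho,
        rho_p=rho_p,
    )


def shuffle_control(
    matrix: PseudoTrialMatrix,
    n_shuffles: int = 100,
    accuracy_window_s: float = ACCURACY_WINDOW_TUNED_S,
    classifier: str = "lda",
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Label-shuffle null: window-mean decoding accuracy per shuffle."""
    if rng is None:
        rng = np.random.default_rng(0)
    wbins = matrix.window_bins(accuracy_window_s)
    X = matrix.rates[:, :, wbins].mean(axis=2)
    # permute labels within each trial-index group: folds stay class-
    # balanced, so the null stays centred on chance
    groups = [np.where(matrix.within_index == i)[0]
              for i in np.unique(matrix.within_index)]
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        y = matrix.labels.copy()
        for g in groups:
            y[g] = y[g[rng.permutation(len(g))]]
        try:
            pred = _cv_predict(X, y, matrix.within_index, classifier)
            out[i] = float(np.mean(pred == y))
        except ValueError:  # a fold lost a class entirely; score chance draw
            out[i] = np.nan
    return out
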