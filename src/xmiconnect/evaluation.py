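"""Classification metrics: accuracy, signal detection (HIT/FAR/d'), tests
against chance, participant-level modal accuracy, and a linear-SVM baseline.

The positive class is Control (= 1); ADHD maps to 0.  So a *hit* is a correct
Control classification and a *false alarm* is an ADHD vector classified as
Control:

    HIT = TP / (TP + FN)        FAR = FP / (FP + TN)
    d'  = z(HIT) - z(FAR)       (normal quantiles; right-tail convention)

Rates of exactly 0 or 1 are nudged by 1/(2N) before the quantile transform so
d' stays finite.  Per-model validation accuracies are tested against chance
(0.5) with one-sample right-tailed t-tests, Holm-corrected across outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from ._exceptions import DegenerateInputError, SpecValidationError
from .classifier import (
    ExperimentResult,
    stratified_kfold,
    undersample_balance,
)
from .connectivity import ConnectivityDataset

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "signal_detection",
    "modal_participant_accuracy",
    "accuracy_vs_chance_tests",
    "evaluate_experiment",
    "svm_baseline",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with Control (1) as the positive class."""

    true_positive: int
    false_negative: int
    false_positive: int
    true_negative: int

    @property
    def total(self) -> int:
        return (
            self.true_positive
            + self.false_negative
            + self.false_positive
            + self.true_negative
        )

    @property
    def accuracy(self) -> float:
        return (self.true_positive + self.true_negative) / self.total


@dataclass
class MetricsReport:
    """Aggregate metrics for one classification output."""

    output: str
    accuracy_mean: float
    accuracy_sd: float
    n_models: int
    hit: float
    far: float
    dprime: float
    t_statistic: float
    df: int
    p_raw: float
    p_holm: float

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts for binary predictions (positive class = 1 = Control)."""
    pred = np.asarray(pred, dtype=int).ravel()
    truth = np.asarray(truth, dtype=int).ravel()
    if pred.size != truth.size:
        raise SpecValidationError(f"length mismatch: {pred.size} vs {truth.size}")
    return ConfusionCounts(
        true_positive=int(((pred == 1) & (truth == 1)).sum()),
        false_negative=int(((pred == 0) & (truth == 1)).sum()),
        false_positive=int(((pred == 1) & (truth == 0)).sum()),
        true_negative=int(((pred == 0) & (truth == 0)).sum()),
    )


def _extreme_rate_correction(rate: float, n: int) -> float:
    # 1/(2N) log-linear correction keeps the quantile transform finite.
    if rate <= 0.0:
        return 1.0 / (2.0 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2.0 * n)
    return rate


def signal_detection(c: ConfusionCounts) -> tuple[float, float, float]:
    """(HIT, FAR, d') from confusion counts.

    d' = z(HIT) - z(FAR) with z the right-tail normal quantile convention,
    algebraically Phi^-1(HIT) - Phi^-1(FAR).
    """
    n_pos = c.true_positive + c.false_negative
    n_neg = c.false_positive + c.true_negative
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError(
            "signal detection requires both truth classes present"
        )
    hit = c.true_positive / n_pos
    far = c.false_positive / n_neg
    hit_adj = _extreme_rate_correction(hit, n_pos)
    far_adj = _extreme_rate_correction(far, n_neg)
    dprime = float(stats.norm.ppf(hit_adj) - stats.norm.ppf(far_adj))
    return float(hit), float(far), dprime


def modal_participant_accuracy(
    predictions: pd.DataFrame, output: str = "diagnosis"
) -> float:
    """Participant-level accuracy using the modal classification of the runs.

    Each participant's prediction is the majority vote over their per-run
    predictions; ties (possible with an even run count) are resolved by the
    mean sigmoid output thresholded at 0.5.
    """
    pred_col, out_col, true_col = f"{output}_pred", f"{output}_output", f"{output}_true"
    correct = 0
    groups = predictions.groupby("participant_id")
    for _, grp in groups:
        votes = grp[pred_col].to_numpy()
        n1 = int((votes == 1).sum())
        n0 = votes.size - n1
        if n1 != n0:
            modal = int(n1 > n0)
        else:
            modal = int(grp[out_col].mean() >= 0.5)
        truth = int(grp[true_col].iloc[0])
        correct += int(modal == truth)
    return correct / groups.ngroups


def accuracy_vs_chance_tests(
    accuracies: dict[str, np.ndarray], chance: float = 0.5
) -> pd.DataFrame:
    """Right-tailed one-sample t-tests of per-model accuracies against chance,
    Holm-corrected across outputs (the family = the reported tests)."""
    rows = []
    for output, acc in accuracies.items():
        acc = np.asarray(acc, dtype=float)
        if acc.size < 2:
            raise DegenerateInputError(f"need >= 2 accuracies for {output}")
        if np.ptp(acc) == 0 and acc[0] == chance:
            t, p = 0.0, 0.5
        elif np.ptp(acc) == 0:
            raise DegenerateInputError(
                f"zero variance in accuracies for {output}; t-test undefined"
            )
        else:
            t, p = stats.ttest_1samp(acc, chance, alternative="greater")
        rows.append(
            {
                "output": output,
                "mean": float(acc.mean()),
                "sd": float(acc.std(ddof=1)),
                "n": int(acc.size),
                "t": float(t),
                "df": int(acc.size - 1),
                "p_raw": float(p),
            }
        )
    frame = pd.DataFrame(rows)
    _, p_holm, _, _ = multipletests(frame["p_raw"], method="holm")
    frame["p_holm"] = p_holm
    return frame


def _tests_allowing_ceiling(accuracies: dict[str, np.ndarray]) -> pd.DataFrame:
    """Chance tests that tolerate zero-variance accuracy vectors.

    Every model scoring identically away from chance (a ceiling/floor effect
    on a strongly separable cohort) is reported with an infinite t statistic
    instead of the degenerate-input error the bare [OP] raises.
    """
    degenerate = {
        out: np.asarray(acc, dtype=float)
        for out, acc in accuracies.items()
        if np.ptp(acc) == 0 and np.asarray(acc).flat[0] != 0.5
    }
    testable = {k: v for k, v in accuracies.items() if k not in degenerate}
    frames = []
    if testable:
        frames.append(accuracy_vs_chance_tests(testable))
    for out, acc in degenerate.items():
        sign = 1.0 if acc.flat[0] > 0.5 else -1.0
        frames.append(
            pd.DataFrame(
                [
                    {
                        "output": out,
                        "mean": float(acc.mean()),
                        "sd": 0.0,
                        "n": int(acc.size),
                        "t": sign * float("inf"),
                        "df": int(acc.size - 1),
                        "p_raw": 0.0 if sign > 0 else 1.0,
                        "p_holm": 0.0 if sign > 0 else 1.0,
                    }
                ]
            )
        )
    return pd.concat(frames, ignore_index=True)


def evaluate_experiment(result: ExperimentResult) -> dict[str, MetricsReport]:
    """Full metrics per output for a batched k-fold experiment."""
    accuracies = {out: result.model_accuracies(out) for out in result.outputs}
    tests = _tests_allowing_ceiling(accuracies).set_index("output")
    reports: dict[str, MetricsReport] = {}
    for out in result.outputs:
        c = confusion_counts(
            result.predictions[f"{out}_pred"], result.predictions[f"{out}_true"]
        )
        hit, far, dprime = signal_detection(c)
        row = tests.loc[out]
        reports[out] = MetricsReport(
            output=out,
            accuracy_mean=float(row["mean"]),
            accuracy_sd=float(row["sd"]),
            n_models=int(row["n"]),
            hit=hit,
            far=far,
            dprime=dprime,
            t_statistic=float(row["t"]),
            df=int(row["df"]),
            p_raw=float(row["p_raw"]),
            p_holm=float(row["p_holm"]),
        )
    return reports


def write_metrics_json(reports: dict[str, MetricsReport], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: v.to_dict() for k, v in reports.items()}, indent=2)
    )


def svm_baseline(
    data: ConnectivityDataset,
    n_reps: int = 6,
    k: int = 5,
    outputs: Sequence[str] = ("diagnosis", "igt_class"),
    seed: int | None = None,
    max_iter: int = 20000,
) -> dict[str, MetricsReport]:
    """Linear soft-margin SVM baseline, trained independently per output.

    A single separating hyperplane cannot make simultaneous classification
    decisions about two orthogonal categories, so each output gets its own
    classifier; the under-sampling and stratified-fold machinery is shared
    with the multilayer experiment.
    """
    outputs = tuple(outputs)
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_reps)
    acc: dict[str, list[float]] = {out: [] for out in outputs}
    preds: dict[str, list[np.ndarray]] = {out: [] for out in outputs}
    truths: dict[str, list[np.ndarray]] = {out: [] for out in outputs}
    for rep in range(n_reps):
        us_seed, fold_seed, svm_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in rep_seeds[rep].spawn(3)
        ]
        balanced = undersample_balance(data, seed=us_seed)
        strata = balanced.targets(("diagnosis", "igt_class"))
        plan = stratified_kfold(strata, k=k, seed=fold_seed)
        X = balanced.features
        for out in outputs:
            y = balanced.tags[out].to_numpy(dtype=int)
            if np.ptp(y) == 0:
                raise DegenerateInputError(f"single class present for output {out!r}")
            for fold in range(k):
                tr, va = plan.train_indices(fold), plan.validation_indices(fold)
                clf = LinearSVC(max_iter=max_iter, random_state=svm_seed)
                clf.fit(X[tr], y[tr])
                p = clf.predict(X[va])
                acc[out].append(float((p == y[va]).mean()))
                preds[out].append(p)
                truths[out].append(y[va])
    tests = _tests_allowing_ceiling({out: np.asarray(acc[out]) for out in outputs})
    tests = tests.set_index("output")
    reports: dict[str, MetricsReport] = {}
    for out in outputs:
        c = confusion_counts(np.concatenate(preds[out]), np.concatenate(truths[out]))
        hit, far, dprime = signal_detection(c)
        row = tests.loc[out]
        reports[out] = MetricsReport(
            output=out,
            accuracy_mean=float(row["mean"]),
            accuracy_sd=float(row["sd"]),
            n_models=int(row["n"]),
            hit=hit,
            far=far,
            dprime=dprime,
            t_statistic=float(row["t"]),
            df=int(row["df"]),
            p_raw=float(row["p_raw"]),
            p_holm=float(row["p_holm"]),
        )
    return reports
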