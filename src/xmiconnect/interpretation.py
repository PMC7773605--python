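"""Per-connection influence via summed path weights, and feature-set tests.

In a multilayer network every input feature reaches a classifier unit along
many routes through the hidden layers.  A feature's total influence on an
output is the sum over all such paths of the product of the traversed
weights — algebraically, the corresponding entry of the product of the dense
weight matrices.  With ADHD mapped to 0 and Control to 1 at the sigmoid
output, a strongly negative summed path weight marks a connection whose
strong connectivity predicts ADHD, and a strongly positive one predicts
Control; the analogous reading holds for the IGT output (low = 0, high = 1).

Mean path weights across a batch of trained models are z-normalized across
features.  Connections with |Z| > 1.65 (the 95th percentile of the standard
normal) on either output are *predictive*; those whose Z product exceeds
1.65^2 are *highly predictive* — extreme for both classifications jointly.
Because parametric thresholds on network weights rest on shaky assumptions,
a permutation-style comparison backs them up: models trained on the targeted
features only are compared with models trained on equal-size random feature
draws.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DegenerateInputError, SpecValidationError
from .classifier import MultilayerClassifier, TrainConfig, run_experiment
from .connectivity import ConnectivityDataset

__all__ = [
    "summed_path_weights",
    "normalize_path_weights",
    "reduced_feature_selection",
    "predictive_connection_table",
    "targeted_vs_random_test",
    "ComparisonReport",
]


def summed_path_weights(model: MultilayerClassifier) -> np.ndarray:
    """Sum of weight products over all input->output paths, per feature and output.

    Equals the matrix product of the dense layer weight matrices; biases and
    batch-norm parameters are excluded (they shift activations but do not
    route input influence along paths).  Shape (n_features, n_outputs).
    """
    weights = model.weights_
    for a, b in zip(weights[:-1], weights[1:]):
        if a.shape[1] != b.shape[0]:
            raise SpecValidationError(
                f"inconsistent layer shapes: {a.shape} -> {b.shape}"
            )
    return np.linalg.multi_dot(weights) if len(weights) > 1 else weights[0].copy()


def normalize_path_weights(
    per_model: Sequence[np.ndarray],
    feature_names: Sequence[str] | None = None,
    output_names: Sequence[str] = ("clinical", "igt"),
) -> pd.DataFrame:
    """Across-model mean path weight per feature, z-scored across features.

    Returns a table with one row per input feature: mean_<output> and
    z_<output> columns (sample-SD convention, so each Z column has mean 0
    and SD 1 across features).
    """
    if not per_model:
        raise SpecValidationError("need at least one model's path weights")
    stack = np.stack([np.atleast_2d(np.asarray(w, dtype=float)) for w in per_model])
    if stack.shape[1] < 2:
        raise SpecValidationError("need >= 2 features to normalize across features")
    mean = stack.mean(axis=0)  # (n_features, n_outputs)
    n_outputs = mean.shape[1]
    names = list(output_names)[:n_outputs]
    if len(names) < n_outputs:
        names += [f"output{k}" for k in range(len(names), n_outputs)]
    table = {}
    if feature_names is None:
        feature_names = [str(i) for i in range(mean.shape[0])]
    table["feature"] = list(feature_names)
    for col, name in enumerate(names):
        w = mean[:, col]
        sd = w.std(ddof=1)
        if sd <= 0:
            raise DegenerateInputError(
                f"degenerate path weights: zero variance across features for {name}"
            )
        table[f"mean_{name}"] = w
        table[f"z_{name}"] = (w - w.mean()) / sd
    return pd.DataFrame(table)


def reduced_feature_selection(table: pd.DataFrame, tail: float = 0.025) -> list[int]:
    """Features in the +-``tail`` tails of the mean clinical path-weight distribution.

    Mirrors backward-stepwise logic: only the connections most diagnostic of
    the clinical output across all models survive into the reduced model.
    Boundary-equal features are included; ordering is by feature index.
    """
    if not (0.0 < tail < 0.5):
        raise SpecValidationError("tail must lie in (0, 0.5)")
    w = table["mean_clinical"].to_numpy(dtype=float)
    lo = np.quantile(w, tail)
    hi = np.quantile(w, 1.0 - tail)
    return [int(i) for i in np.flatnonzero((w <= lo) | (w >= hi))]


def predictive_connection_table(
    table: pd.DataFrame, z_thresh: float = 1.65
) -> pd.DataFrame:
    """Predictive connections: |Z| > ``z_thresh`` on either output.

    Adds the Z product and the *highly predictive* flag (|product| >
    ``z_thresh**2``, i.e. extreme tails for both classifications).  Rows are
    grouped by the sign of the IGT weight (positive — high-IGT profile —
    first) and sorted by |product| descending within groups, mirroring how
    such tables are conventionally reported.
    """
    zc = table["z_clinical"].to_numpy(dtype=float)
    zi = table["z_igt"].to_numpy(dtype=float)
    included = (np.abs(zc) > z_thresh) | (np.abs(zi) > z_thresh)
    out = table.loc[included, ["feature", "z_clinical", "z_igt"]].copy()
    out["product"] = out["z_clinical"] * out["z_igt"]
    out["included"] = True
    out["highly_predictive"] = np.abs(out["product"]) > z_thresh**2
    out["_grp"] = (out["z_igt"] < 0).astype(int)  # high-IGT (positive) first
    out["_mag"] = np.abs(out["product"])
    out = (
        out.sort_values(["_grp", "_mag"], ascending=[True, False])
        .drop(columns=["_grp", "_mag"])
        .reset_index(drop=True)
    )
    return out


@dataclass
class ComparisonReport:
    """Targeted-vs-random feature comparison: per-repetition accuracies and tests."""

    targeted_accuracy: pd.DataFrame  # one row per repetition, one column per output
    random_accuracy: pd.DataFrame
    t_statistic: dict[str, float]
    p_value: dict[str, float]
    df: int
    targeted_features: list[int]
    random_draws: list[list[int]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "targeted_accuracy": self.targeted_accuracy.to_dict(orient="list"),
            "random_accuracy": self.random_accuracy.to_dict(orient="list"),
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "df": self.df,
            "targeted_features": self.targeted_features,
            "random_draws": self.random_draws,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def targeted_vs_random_test(
    data: ConnectivityDataset,
    targeted_features: Sequence[int],
    pool_features: Sequence[int],
    n_sets: int = 10,
    k: int = 10,
    config: TrainConfig = TrainConfig(),
    outputs: Sequence[str] = ("diagnosis", "igt_class"),
    seed: int | None = None,
) -> ComparisonReport:
    """Do the targeted connections beat equal-size random draws?

    Condition A trains ``n_sets`` repetitions of stratified ``k``-fold models
    on the targeted features only; condition B does the same on independent
    equal-size random draws from ``pool_features``.  Per-repetition mean
    validation accuracy feeds an independent-samples t-test per output with
    df = 2 * n_sets - 2.
    """
    targeted = [int(i) for i in targeted_features]
    pool = [int(i) for i in pool_features]
    if not targeted:
        raise SpecValidationError("targeted feature set is empty")
    if len(targeted) > len(pool):
        raise SpecValidationError(
            f"pool ({len(pool)}) must be at least as large as the targeted set "
            f"({len(targeted)}) for equal-size draws"
        )
    outputs = tuple(outputs)
    root = np.random.SeedSequence(seed)
    seed_targeted, seed_random, seed_draws = root.spawn(3)
    draw_rng = np.random.default_rng(seed_draws)

    def _condition(features: list[list[int]], ss: np.random.SeedSequence) -> pd.DataFrame:
        rep_seeds = ss.spawn(len(features))
        rows = []
        for rep, feats in enumerate(features):
            sub = data.select_features(feats)
            res = run_experiment(
                sub,
                n_batches=1,
                k=k,
                config=config,
                outputs=outputs,
                seed=int(rep_seeds[rep].generate_state(1)[0] % (2**31)),
            )
            rows.append({out: float(res.model_accuracies(out).mean()) for out in outputs})
        return pd.DataFrame(rows)

    targeted_sets = [targeted for _ in range(n_sets)]
    random_sets = [
        sorted(draw_rng.choice(pool, size=len(targeted), replace=False).tolist())
        for _ in range(n_sets)
    ]
    acc_t = _condition(targeted_sets, seed_targeted)
    acc_r = _condition(random_sets, seed_random)

    t_stat: dict[str, float] = {}
    p_val: dict[str, float] = {}
    for out in outputs:
        t, p = stats.ttest_ind(acc_t[out], acc_r[out], equal_var=True)
        t_stat[out] = float(t)
        p_val[out] = float(p)
    return ComparisonReport(
        targeted_accuracy=acc_t,
        random_accuracy=acc_r,
        t_statistic=t_stat,
        p_value=p_val,
        df=2 * n_sets - 2,
        targeted_features=targeted,
        random_draws=random_sets,
    )
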