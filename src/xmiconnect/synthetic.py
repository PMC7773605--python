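"""Synthetic cohorts of regional time series with planted connectivity effects.

The generator emulates a go/no-go fMRI cohort of the dimensions used in the
study design this package targets (80 participants, 25 control / 55 ADHD,
4 runs, ~300 regions, 154 timepoints) without any imaging physics: each
region's signal is a unit-variance mixture of white noise, a weak global
signal, and per-pair shared latent signals whose mixing coefficient depends
on a participant's diagnosis or Iowa Gambling Task (IGT) class.  Two regions
that share a latent with coefficient ``c`` have product-moment correlation
``c**2`` (before measurement noise), so dependency strength is analytically
known and parameter recovery can be tested exactly.

Three kinds of region pairs exist:

* *planted clinical pairs* — coupling is ``coupling_strong`` for one diagnosis
  group and ``coupling_weak`` for the other (direction configurable per pair,
  so both hyper- and hypoconnectivity profiles can be planted);
* *planted IGT pairs* — analogous, split by IGT class; may overlap the
  clinical pairs;
* *background pairs* — label-independent coupling, identical for everyone.
  These emulate the stable, non-diagnostic connections that dominate real
  connectomes and guarantee the correlation-based connection-of-interest
  filter has a non-trivial, label-uninformative pool.

All randomness derives from ``CohortSpec.seed`` through a
``numpy.random.SeedSequence`` spawn tree, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import DegenerateInputError, SpecValidationError

__all__ = [
    "CohortSpec",
    "RegionalTimeSeries",
    "GroundTruth",
    "generate_cohort",
    "label_orthogonality",
    "default_spec",
]

# IGT net scores (advantageous minus disadvantageous picks) are drawn from two
# overlapping normals by target class; the class label is then recomputed as
# the median split of the drawn scores so the LabelTable invariant holds
# exactly.  Separation 2.5 SD keeps near-median flips rare.
IGT_SCORE_MEAN_LOW = -10.0
IGT_SCORE_MEAN_HIGH = 10.0
IGT_SCORE_SD = 8.0

Pair = tuple[int, int]


@dataclass(frozen=True)
class RegionalTimeSeries:
    """One run's region-by-timepoint signal matrix for one participant."""

    participant_id: str
    run_id: int
    signal: np.ndarray  # (n_rois, n_timepoints), arbitrary units

    @property
    def n_rois(self) -> int:
        return self.signal.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class CohortSpec:
    """Dimensions and effect structure of a synthetic cohort.

    Defaults mirror the target study design: 80 participants of whom 25 are
    controls, 4 task runs, 302 regions of interest, 154 volumes per run.
    """

    n_participants: int = 80
    n_controls: int = 25
    n_runs: int = 4
    n_rois: int = 302
    n_timepoints: int = 154
    planted_clinical_pairs: tuple[Pair, ...] = (
        (0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11),
    )
    planted_igt_pairs: tuple[Pair, ...] = (
        (8, 9), (10, 11), (12, 13), (14, 15), (16, 17), (18, 19),
    )
    # +1: strong coupling for label 1 (Control / high IGT); -1: strong for
    # label 0 (ADHD / low IGT), i.e. ADHD-hyperconnectivity.
    clinical_directions: tuple[int, ...] | None = None
    igt_directions: tuple[int, ...] | None = None
    coupling_strong: float = 0.8
    coupling_weak: float = 0.3
    noise_sd: float = 0.5
    global_coupling: float = 0.15
    n_background_pairs: int = 40
    background_coupling: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.n_controls < self.n_participants):
            raise SpecValidationError(
                "invariant violated: 0 < n_controls < n_participants "
                f"(got n_controls={self.n_controls}, n_participants={self.n_participants})"
            )
        if self.n_runs < 1 or self.n_rois < 2:
            raise SpecValidationError("invariant violated: n_runs >= 1 and n_rois >= 2")
        if self.n_timepoints < 8:
            raise SpecValidationError(
                f"invariant violated: n_timepoints >= 8 (got {self.n_timepoints})"
            )
        for name in ("planted_clinical_pairs", "planted_igt_pairs"):
            pairs = getattr(self, name)
            seen = set()
            for i, j in pairs:
                if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                    raise SpecValidationError(
                        f"invariant violated: {name} index out of range for n_rois={self.n_rois}: ({i}, {j})"
                    )
                if i == j:
                    raise SpecValidationError(
                        f"invariant violated: {name} pair must join distinct ROIs: ({i}, {j})"
                    )
                key = (min(i, j), max(i, j))
                if key in seen:
                    raise SpecValidationError(
                        f"invariant violated: duplicate pair in {name}: ({i}, {j})"
                    )
                seen.add(key)
        for cname, dname in (
            ("planted_clinical_pairs", "clinical_directions"),
            ("planted_igt_pairs", "igt_directions"),
        ):
            dirs = getattr(self, dname)
            if dirs is not None:
                if len(dirs) != len(getattr(self, cname)):
                    raise SpecValidationError(
                        f"invariant violated: {dname} length must match {cname}"
                    )
                if any(d not in (-1, 1) for d in dirs):
                    raise SpecValidationError(f"invariant violated: {dname} entries must be +-1")
        if not (0.0 <= self.coupling_weak < 1.0 and 0.0 <= self.coupling_strong < 1.0):
            raise SpecValidationError("invariant violated: couplings must lie in [0, 1)")
        if self.coupling_weak > self.coupling_strong:
            raise SpecValidationError(
                "invariant violated: coupling_weak <= coupling_strong "
                f"(got {self.coupling_weak} > {self.coupling_strong})"
            )
        if self.noise_sd <= 0:
            raise SpecValidationError("invariant violated: noise_sd must be positive")
        if not (0.0 <= self.global_coupling < 1.0):
            raise SpecValidationError("invariant violated: global_coupling in [0, 1)")
        if not (0.0 <= self.background_coupling < 1.0):
            raise SpecValidationError("invariant violated: background_coupling in [0, 1)")
        if self.n_background_pairs < 0:
            raise SpecValidationError("invariant violated: n_background_pairs >= 0")

    def resolved_directions(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Per-pair effect directions, alternating +1/-1 when unspecified."""
        clin = self.clinical_directions or tuple(
            1 if q % 2 == 0 else -1 for q in range(len(self.planted_clinical_pairs))
        )
        igt = self.igt_directions or tuple(
            1 if q % 2 == 0 else -1 for q in range(len(self.planted_igt_pairs))
        )
        return clin, igt


@dataclass(frozen=True)
class GroundTruth:
    """Record of the effects a cohort was generated with (for recovery tests)."""

    planted_clinical_pairs: tuple[Pair, ...]
    planted_igt_pairs: tuple[Pair, ...]
    clinical_directions: tuple[int, ...]
    igt_directions: tuple[int, ...]
    background_pairs: tuple[Pair, ...]
    coupling_strong: float
    coupling_weak: float
    background_coupling: float
    global_coupling: float
    noise_sd: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        for key in (
            "planted_clinical_pairs",
            "planted_igt_pairs",
            "background_pairs",
        ):
            raw[key] = tuple(tuple(p) for p in raw[key])
        for key in ("clinical_directions", "igt_directions"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


def default_spec(**overrides) -> CohortSpec:
    """Study-condition cohort spec with keyword overrides."""
    return CohortSpec(**overrides)


def _participant_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _assign_labels(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Stratified diagnosis/IGT crossing plus class-conditional IGT scores."""
    n = spec.n_participants
    diagnosis = np.zeros(n, dtype=int)
    diagnosis[rng.choice(n, size=spec.n_controls, replace=False)] = 1

    # Target IGT class: within each diagnosis group, assign half high so the
    # 2x2 design is as close to balanced crossing as the group sizes allow.
    target = np.zeros(n, dtype=int)
    for group in (0, 1):
        idx = np.flatnonzero(diagnosis == group)
        idx = rng.permutation(idx)
        target[idx[: len(idx) // 2 + (len(idx) % 2) * int(rng.integers(2))]] = 1

    means = np.where(target == 1, IGT_SCORE_MEAN_HIGH, IGT_SCORE_MEAN_LOW)
    igt_score = rng.normal(means, IGT_SCORE_SD)
    # Recompute the class as the median split of the realized scores so the
    # LabelTable invariant holds exactly (ties at the median go low).
    median = float(np.median(igt_score))
    igt_class = (igt_score > median).astype(int)

    return pd.DataFrame(
        {
            "participant_id": _participant_ids(n),
            "diagnosis": diagnosis,
            "igt_score": igt_score,
            "igt_class": igt_class,
        }
    )


def _background_pairs(spec: CohortSpec, rng: np.random.Generator) -> tuple[Pair, ...]:
    """Label-independent coupled pairs, disjoint from the planted pairs."""
    planted = {(min(p), max(p)) for p in spec.planted_clinical_pairs}
    planted |= {(min(p), max(p)) for p in spec.planted_igt_pairs}
    planted_rois = {r for p in planted for r in p}
    # Only ROIs untouched by planted effects, so mixing weights stay valid;
    # a free ROI may serve several background pairs within its variance budget.
    free = np.array([r for r in range(spec.n_rois) if r not in planted_rois])
    budget = 0.95 - spec.global_coupling**2
    max_use = max(1, int(budget // max(spec.background_coupling**2, 1e-12)))
    use = {int(r): 0 for r in free}
    pairs: set[Pair] = set()
    attempts = 0
    while len(pairs) < spec.n_background_pairs and attempts < 200 * max(
        spec.n_background_pairs, 1
    ):
        attempts += 1
        avail = [r for r in use if use[r] < max_use]
        if len(avail) < 2:
            break
        i, j = sorted(rng.choice(avail, size=2, replace=False).tolist())
        if (i, j) in pairs:
            continue
        pairs.add((i, j))
        use[i] += 1
        use[j] += 1
    if len(pairs) < spec.n_background_pairs:
        raise SpecValidationError(
            "invariant violated: not enough free ROI capacity for "
            f"{spec.n_background_pairs} background pairs (n_rois={spec.n_rois})"
        )
    return tuple(sorted(pairs))


def _mixing_table(
    spec: CohortSpec,
    labels: pd.DataFrame,
    background: tuple[Pair, ...],
) -> tuple[list[list[tuple[int, np.ndarray]]], int]:
    """Per-ROI list of (latent index, per-participant coupling vector).

    Latents are indexed: clinical pairs, then IGT pairs, then background
    pairs.  A pair planted under BOTH labels gets two latents whose couplings
    are scaled by 1/sqrt(2), so its regions' mixing variance stays within
    budget and the pair correlation is (c_clin^2 + c_igt^2) / 2 — equal to
    the single-label c^2 when both conditions are strong.  Returns the table
    and the number of latents.
    """
    clin_dir, igt_dir = spec.resolved_directions()
    diagnosis = labels["diagnosis"].to_numpy()
    igt_class = labels["igt_class"].to_numpy()
    n = spec.n_participants

    norm = lambda p: (min(p), max(p))
    overlap = {norm(p) for p in spec.planted_clinical_pairs} & {
        norm(p) for p in spec.planted_igt_pairs
    }

    table: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(spec.n_rois)]
    latent = 0
    for (i, j), d in zip(spec.planted_clinical_pairs, clin_dir):
        strong = diagnosis == (1 if d == 1 else 0)
        c = np.where(strong, spec.coupling_strong, spec.coupling_weak)
        if norm((i, j)) in overlap:
            c = c / np.sqrt(2.0)
        table[i].append((latent, c))
        table[j].append((latent, c))
        latent += 1
    for (i, j), d in zip(spec.planted_igt_pairs, igt_dir):
        strong = igt_class == (1 if d == 1 else 0)
        c = np.where(strong, spec.coupling_strong, spec.coupling_weak)
        if norm((i, j)) in overlap:
            c = c / np.sqrt(2.0)
        table[i].append((latent, c))
        table[j].append((latent, c))
        latent += 1
    for i, j in background:
        c = np.full(n, spec.background_coupling)
        table[i].append((latent, c))
        table[j].append((latent, c))
        latent += 1

    for roi, entries in enumerate(table):
        total = spec.global_coupling**2 + sum(c**2 for _, c in entries)
        if np.any(total >= 1.0):
            raise SpecValidationError(
                f"invariant violated: squared mixing weights for ROI {roi} reach "
                f"{float(np.max(total)):.3f} >= 1; reduce couplings or pair overlap"
            )
    return table, latent


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[RegionalTimeSeries], pd.DataFrame, GroundTruth]:
    """Generate a cohort of regional time series with planted effects.

    Returns
    -------
    series : list of RegionalTimeSeries
        ``n_participants * n_runs`` matrices of shape (n_rois, n_timepoints),
        ordered by participant then run.
    labels : pandas.DataFrame
        One row per participant: participant_id, diagnosis (0 = ADHD,
        1 = Control), igt_score, igt_class (median split, ties low).
    truth : GroundTruth
        The planted pairs, directions and couplings actually used.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_labels, ss_background, ss_series = root.spawn(3)

    labels = _assign_labels(spec, np.random.default_rng(ss_labels))
    background = _background_pairs(spec, np.random.default_rng(ss_background))
    table, n_latents = _mixing_table(spec, labels, background)

    clin_dir, igt_dir = spec.resolved_directions()
    truth = GroundTruth(
        planted_clinical_pairs=tuple(
            (min(p), max(p)) for p in spec.planted_clinical_pairs
        ),
        planted_igt_pairs=tuple((min(p), max(p)) for p in spec.planted_igt_pairs),
        clinical_directions=clin_dir,
        igt_directions=igt_dir,
        background_pairs=background,
        coupling_strong=spec.coupling_strong,
        coupling_weak=spec.coupling_weak,
        background_coupling=spec.background_coupling,
        global_coupling=spec.global_coupling,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )

    n, t = spec.n_rois, spec.n_timepoints
    series: list[RegionalTimeSeries] = []
    run_seeds = ss_series.spawn(spec.n_participants * spec.n_runs)
    for p_idx, pid in enumerate(labels["participant_id"]):
        for run in range(spec.n_runs):
            rng = np.random.default_rng(run_seeds[p_idx * spec.n_runs + run])
            latents = rng.standard_normal((n_latents, t))
            global_sig = rng.standard_normal(t)
            eps = rng.standard_normal((n, t))
            meas = rng.standard_normal((n, t))

            signal = np.empty((n, t))
            for roi in range(n):
                entries = table[roi]
                shared = spec.global_coupling * global_sig
                sq = spec.global_coupling**2
                for latent_idx, c in entries:
                    shared = shared + c[p_idx] * latents[latent_idx]
                    sq = sq + c[p_idx] ** 2
                signal[roi] = np.sqrt(1.0 - sq) * eps[roi] + shared
            signal = signal + spec.noise_sd * meas
            series.append(RegionalTimeSeries(pid, run, signal))
    return series, labels, truth


def label_orthogonality(labels: pd.DataFrame) -> float:
    """Sample correlation between diagnosis and IGT class across participants.

    Near-zero means the two classifications are mutually uninformative, the
    regime the dual-output classifier assumes.
    """
    if len(labels) < 2:
        raise DegenerateInputError("need >= 2 participants for label correlation")
    d = labels["diagnosis"].to_numpy(dtype=float)
    g = labels["igt_class"].to_numpy(dtype=float)
    if np.ptp(d) == 0 or np.ptp(g) == 0:
        raise DegenerateInputError(
            "label correlation undefined: a label column is constant"
        )
    return float(np.corrcoef(d, g)[0, 1])


def write_cohort_csv(
    series: Sequence[RegionalTimeSeries],
    labels: pd.DataFrame,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a cohort in the package's CSV dialect.

    One wide CSV per participant-run (rows = ROIs, columns = timepoints,
    first column ``roi``), ``labels.csv``, and ``ground_truth.json``.
    """
    out = Path(out_dir)
    (out / "series").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for ts in series:
        frame = pd.DataFrame(
            ts.signal, columns=[f"t{k}" for k in range(ts.n_timepoints)]
        )
        frame.insert(0, "roi", np.arange(ts.n_rois))
        path = out / "series" / f"{ts.participant_id}_run{ts.run_id}.csv"
        frame.to_csv(path, index=False)
        paths[f"{ts.participant_id}_run{ts.run_id}"] = path
    labels_path = out / "labels.csv"
    labels.to_csv(labels_path, index=False)
    paths["labels"] = labels_path
    truth_path = out / "ground_truth.json"
    truth.to_json(truth_path)
    paths["ground_truth"] = truth_path
    return paths


def read_cohort_csv(in_dir: str | Path) -> tuple[list[RegionalTimeSeries], pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort_csv`."""
    root = Path(in_dir)
    labels_path = root / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"missing labels file: {labels_path}")
    labels = pd.read_csv(labels_path)
    series = []
    for path in sorted((root / "series").glob("*.csv")):
        stem = path.stem
        pid, run = stem.rsplit("_run", 1)
        frame = pd.read_csv(path)
        signal = frame.drop(columns=["roi"]).to_numpy(dtype=float)
        series.append(RegionalTimeSeries(pid, int(run), signal))
    if not series:
        raise FileNotFoundError(f"no series CSVs found under {root / 'series'}")
    return series, labels
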