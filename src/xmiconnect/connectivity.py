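"""Cross-mutual-information (XMI) functional connectivity.

Regional time series are detrended, z-scored and outlier-clipped; Pearson
correlation matrices screen for connections of interest (COIs: region pairs
in the top 5% of correlations in at least 30% of all run matrices); and the
dependency strength of each COI is then estimated as the average cross-mutual
information

    M = sum_{k,l : P(k,l) > 0} P(k,l) * log[ P(k,l) / (P(k) P(l)) ]

over a two-dimensional density obtained by smoothing the joint histogram with
a Gaussian kernel via FFT convolution.  Bin counts per axis come from Scott's
rule, (max - min) / (3.5 * s * n^(-1/3)), appropriate because regional
connectivity values are approximately normal after preprocessing.  M is
normalized by log(Nc * Nr), its maximum for the grid, so values lie in [0, 1]
and capture non-linear as well as linear dependence while remaining
nonnegative (anticorrelation does not flip sign).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator, TransformerMixin

from ._exceptions import DegenerateInputError, SpecValidationError
from .synthetic import RegionalTimeSeries

__all__ = [
    "preprocess_series",
    "correlation_matrix",
    "select_cois",
    "scott_bins",
    "xmi",
    "median_split",
    "build_connectivity_dataset",
    "ConnectivityDataset",
    "ConnectivityExtractor",
    "CorrelationMatrix",
]

Pair = tuple[int, int]

TAG_COLUMNS = ("participant_id", "run_id", "diagnosis", "igt_class")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlation matrix for one participant-run."""

    participant_id: str
    run_id: int
    values: np.ndarray


def preprocess_series(ts: RegionalTimeSeries, clip_z: float = 3.0) -> RegionalTimeSeries:
    """Detrend, z-score and clip each regional time series.

    Per region: remove the best-fit linear trend, scale to mean 0 / SD 1, and
    clip values with |z| > ``clip_z`` to +-``clip_z``.  A region that is
    constant (or an exact linear ramp, which detrending reduces to a
    constant) cannot be normalized and raises ``DegenerateInputError`` naming
    the region.
    """
    if clip_z <= 0:
        raise SpecValidationError("clip_z must be positive")
    x = np.asarray(ts.signal, dtype=float)
    detrended = sp_signal.detrend(x, axis=1, type="linear")
    sd = detrended.std(axis=1)
    bad = np.flatnonzero(sd <= 1e-12)
    if bad.size:
        raise DegenerateInputError(
            f"degenerate series: ROI(s) {bad.tolist()} constant after detrending "
            f"(participant {ts.participant_id}, run {ts.run_id})"
        )
    z = (detrended - detrended.mean(axis=1, keepdims=True)) / sd[:, None]
    return RegionalTimeSeries(ts.participant_id, ts.run_id, np.clip(z, -clip_z, clip_z))


def correlation_matrix(ts: RegionalTimeSeries) -> CorrelationMatrix:
    """All-pairs Pearson correlations for one run (unit diagonal)."""
    if ts.n_timepoints < 3:
        raise DegenerateInputError("need >= 3 timepoints for correlation")
    values = np.corrcoef(ts.signal)
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(ts.participant_id, ts.run_id, values)


def select_cois(
    matrices: Sequence[CorrelationMatrix],
    top_frac: float = 0.05,
    min_prop: float = 0.30,
    absolute: bool = False,
) -> list[Pair]:
    """Connections of interest: pairs in the per-matrix top correlations often enough.

    For each matrix the ``ceil(top_frac * n_pairs)`` largest upper-triangle
    correlations are marked (signed values by default; set ``absolute`` to
    rank by magnitude).  Pairs marked in at least ``ceil(min_prop *
    n_matrices)`` matrices are returned in lexicographic (i, j) order, which
    fixes the feature order of every downstream connectivity vector.
    """
    if not matrices:
        raise SpecValidationError("need at least one correlation matrix")
    if not (0 < top_frac <= 1):
        raise SpecValidationError("top_frac must lie in (0, 1]")
    if not (0 <= min_prop <= 1):
        raise SpecValidationError("min_prop must lie in [0, 1]")
    n = matrices[0].values.shape[0]
    for m in matrices:
        if m.values.shape != (n, n):
            raise SpecValidationError(
                f"inconsistent matrix dimensions: {m.values.shape} vs {(n, n)}"
            )
    iu = np.triu_indices(n, k=1)
    n_pairs = iu[0].size
    n_top = math.ceil(top_frac * n_pairs)
    counts = np.zeros(n_pairs, dtype=int)
    for m in matrices:
        vals = m.values[iu]
        if absolute:
            vals = np.abs(vals)
        top = np.argpartition(vals, n_pairs - n_top)[n_pairs - n_top:]
        counts[top] += 1
    threshold = math.ceil(min_prop * len(matrices))
    keep = counts >= max(threshold, 1)
    pairs = [(int(i), int(j)) for i, j in zip(iu[0][keep], iu[1][keep])]
    pairs.sort()
    return pairs


def scott_bins(x: np.ndarray) -> int:
    """Number of histogram bins for ``x`` by Scott's normal-reference rule.

    round((max - min) / (3.5 * s * n^(-1/3))), floored at 2 so a joint grid
    always exists.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need >= 2 values for binning")
    s = x.std(ddof=1)
    if s <= 0 or np.ptp(x) == 0:
        raise DegenerateInputError("degenerate input: zero spread")
    width = 3.5 * s * x.size ** (-1.0 / 3.0)
    bins = int(math.floor(np.ptp(x) / width + 0.5))
    return max(bins, 2)


def _gaussian_kernel_2d(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    kernel = np.outer(g, g)
    return kernel / kernel.sum()


def _joint_density(
    x: np.ndarray, y: np.ndarray, nc: int, nr: int, bandwidth: float
) -> np.ndarray:
    """Joint density on an Nc x Nr grid: histogram, optionally smoothed by FFT
    convolution with a Gaussian kernel (bandwidth in grid cells; 0 disables,
    yielding the plain plug-in histogram density)."""
    hist, _, _ = np.histogram2d(x, y, bins=[nc, nr])
    if bandwidth > 0:
        radius = max(1, int(math.ceil(4.0 * bandwidth)))
        kernel = _gaussian_kernel_2d(bandwidth, radius)
        hist = sp_signal.fftconvolve(hist, kernel, mode="same")
        # FFT round-off can produce tiny negative mass; clamp before renormalizing.
        np.clip(hist, 0.0, None, out=hist)
    total = hist.sum()
    if total <= 0:
        raise DegenerateInputError("degenerate input: empty joint histogram")
    return hist / total


def xmi(
    x: np.ndarray,
    y: np.ndarray,
    bandwidth: float = 1.0,
    normalized: bool = True,
) -> float:
    """Average cross-mutual information between two series, in [0, 1].

    Bin counts Nc (from ``x``) and Nr (from ``y``) come from Scott's rule;
    the joint density is the 2-D histogram smoothed by FFT Gaussian-kernel
    convolution (``bandwidth`` in grid cells; 0 gives the unsmoothed plug-in
    estimator used as an oracle in testing).  Natural logs are used
    throughout; zero-probability cells are excluded.  With ``normalized``
    the statistic is divided by log(Nc * Nr), its maximum on the grid.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise SpecValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 8:
        raise DegenerateInputError("need >= 8 samples for XMI")
    nc = scott_bins(x)
    nr = scott_bins(y)
    joint = _joint_density(x, y, nc, nr, bandwidth)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(px, py)
    m = float(np.sum(joint[mask] * np.log(joint[mask] / outer[mask])))
    m = max(m, 0.0)  # guard against -0.0 / round-off at independence
    if normalized:
        return m / math.log(nc * nr)
    return m


def median_split(scores: np.ndarray) -> np.ndarray:
    """Binarize scores at the sample median: above -> 1 (high), at or below -> 0."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise DegenerateInputError("need >= 2 scores for a median split")
    if np.ptp(scores) == 0:
        raise DegenerateInputError("degenerate split: all scores equal")
    return (scores > np.median(scores)).astype(int)


@dataclass
class ConnectivityDataset:
    """Tagged XMI connectivity vectors: one row per participant-run.

    ``features`` is (n_vectors, n_cois) with columns in ``pairs`` order;
    ``tags`` carries participant_id, run_id, diagnosis, igt_class per row.
    """

    features: np.ndarray
    pairs: list[Pair]
    tags: pd.DataFrame

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != len(self.tags):
            raise SpecValidationError("feature rows must match tag rows")
        if self.features.shape[1] != len(self.pairs):
            raise SpecValidationError("feature columns must match COI pairs")
        missing = [c for c in TAG_COLUMNS if c not in self.tags.columns]
        if missing:
            raise SpecValidationError(f"tags missing columns: {missing}")

    @property
    def n_vectors(self) -> int:
        return self.features.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return [f"{i}-{j}" for i, j in self.pairs]

    def targets(self, outputs: Sequence[str] = ("diagnosis", "igt_class")) -> np.ndarray:
        return self.tags.loc[:, list(outputs)].to_numpy(dtype=int)

    def select_features(self, indices: Sequence[int]) -> "ConnectivityDataset":
        idx = list(indices)
        return ConnectivityDataset(
            self.features[:, idx],
            [self.pairs[i] for i in idx],
            self.tags.reset_index(drop=True),
        )

    def select_rows(self, indices: Sequence[int]) -> "ConnectivityDataset":
        idx = list(indices)
        return ConnectivityDataset(
            self.features[idx],
            list(self.pairs),
            self.tags.iloc[idx].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = self.tags.loc[:, list(TAG_COLUMNS)].copy()
        for k, name in enumerate(self.feature_names):
            frame[name] = self.features[:, k]
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConnectivityDataset":
        missing = [c for c in TAG_COLUMNS if c not in frame.columns]
        if missing:
            raise SpecValidationError(f"dataset header missing tag columns: {missing}")
        feature_cols = [c for c in frame.columns if c not in TAG_COLUMNS]
        pairs = []
        for col in feature_cols:
            try:
                i, j = col.split("-")
                pairs.append((int(i), int(j)))
            except ValueError as exc:
                raise SpecValidationError(
                    f"malformed feature column name {col!r}; expected 'i-j'"
                ) from exc
        return cls(
            frame.loc[:, feature_cols].to_numpy(dtype=float),
            pairs,
            frame.loc[:, list(TAG_COLUMNS)].reset_index(drop=True),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConnectivityDataset":
        try:
            frame = pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise SpecValidationError(f"malformed dataset CSV {path}: {exc}") from exc
        return cls.from_frame(frame)


def build_connectivity_dataset(
    cohort: Iterable[RegionalTimeSeries],
    cois: Sequence[Pair],
    labels: pd.DataFrame,
    clip_z: float = 3.0,
    bandwidth: float = 1.0,
    preprocessed: bool = False,
) -> ConnectivityDataset:
    """XMI vectors over the COI set for every participant-run, tagged with labels."""
    cois = list(cois)
    if not cois:
        raise SpecValidationError("COI set is empty")
    label_map = labels.set_index("participant_id")
    rows = []
    tags = []
    for ts in cohort:
        if ts.participant_id not in label_map.index:
            raise SpecValidationError(
                f"missing label row for participant {ts.participant_id!r}"
            )
        clean = ts if preprocessed else preprocess_series(ts, clip_z=clip_z)
        row = np.empty(len(cois))
        for k, (i, j) in enumerate(cois):
            row[k] = xmi(clean.signal[i], clean.signal[j], bandwidth=bandwidth)
        rows.append(row)
        rec = label_map.loc[ts.participant_id]
        tags.append(
            {
                "participant_id": ts.participant_id,
                "run_id": ts.run_id,
                "diagnosis": int(rec["diagnosis"]),
                "igt_class": int(rec["igt_class"]),
            }
        )
    return ConnectivityDataset(np.vstack(rows), cois, pd.DataFrame(tags))


class ConnectivityExtractor(BaseEstimator, TransformerMixin):
    """Transformer from regional time series to XMI connectivity vectors.

    ``fit`` preprocesses every run, computes Pearson matrices and selects the
    COI set; ``transform`` returns the (n_runs, n_cois) XMI feature matrix in
    COI order.  Composes with scikit-learn pipelines over lists of
    :class:`RegionalTimeSeries`.

    Parameters
    ----------
    clip_z : outlier clip threshold in SD units after z-scoring.
    top_frac : per-matrix fraction of largest correlations marked.
    min_prop : minimum proportion of matrices a pair must be marked in.
    absolute : rank correlations by magnitude instead of signed value.
    bandwidth : Gaussian smoothing bandwidth of the XMI density, in grid
        cells; 0 disables smoothing (plug-in histogram estimator).
    """

    def __init__(
        self,
        clip_z: float = 3.0,
        top_frac: float = 0.05,
        min_prop: float = 0.30,
        absolute: bool = False,
        bandwidth: float = 1.0,
    ):
        self.clip_z = clip_z
        self.top_frac = top_frac
        self.min_prop = min_prop
        self.absolute = absolute
        self.bandwidth = bandwidth

    def fit(self, X: Sequence[RegionalTimeSeries], y=None) -> "ConnectivityExtractor":
        matrices = [
            correlation_matrix(preprocess_series(ts, clip_z=self.clip_z)) for ts in X
        ]
        self.cois_ = select_cois(
            matrices,
            top_frac=self.top_frac,
            min_prop=self.min_prop,
            absolute=self.absolute,
        )
        self.n_rois_ = matrices[0].values.shape[0]
        return self

    def transform(self, X: Sequence[RegionalTimeSeries]) -> np.ndarray:
        if not hasattr(self, "cois_"):
            raise SpecValidationError("ConnectivityExtractor is not fitted")
        out = np.empty((len(X), len(self.cois_)))
        for r, ts in enumerate(X):
            clean = preprocess_series(ts, clip_z=self.clip_z)
            for k, (i, j) in enumerate(self.cois_):
                out[r, k] = xmi(clean.signal[i], clean.signal[j], bandwidth=self.bandwidth)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray([f"{i}-{j}" for i, j in self.cois_], dtype=object)
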