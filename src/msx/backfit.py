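"""Backfitting meta-maps to study maps and EEG, and commonality matrices.

*Backfitting* labels data by a fixed set of template maps: each study map
(or each EEG sample, after average referencing and normalization) is
assigned to the class whose meta-map maximizes the squared spatial
correlation — polarity-invariant, consistent with the clustering
objective.  Backfitting the same EEG with two solutions of different
class counts yields two label series; their cross-tabulation, normalized
to 100% within each source class, is the *commonality matrix*: entry
C[j, k] is the percentage of time points labeled k by the first (from)
solution that are labeled j by the second (to) solution.  Columns over
non-empty source classes therefore sum to exactly 100.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import MontageMismatchError, ValidationError
from .metacluster import MetaClusterSolution
from .spline import SplineOperator
from .templates import Atlas, ElectrodeMontage, StudySet, TemplateMap

__all__ = [
    "EEGRecording",
    "AssignmentSeries",
    "CommonalityMatrix",
    "MapAssignment",
    "backfit_maps",
    "backfit_eeg",
    "commonality",
    "load_eeg_csv",
    "save_eeg_csv",
]


@dataclass
class EEGRecording:
    """Continuous EEG: montage, sampling rate, channels x samples data (µV).

    Data is average-referenced per sample on construction;
    ``input_was_average_referenced`` records whether it already was.
    """

    montage: ElectrodeMontage
    sampling_rate: float
    data: np.ndarray
    input_was_average_referenced: bool | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValidationError(f"EEG data must be 2-D (channels x samples), got {d.shape}")
        if d.shape[0] != self.montage.n_channels:
            raise ValidationError(
                f"EEG has {d.shape[0]} channels but montage has {self.montage.n_channels}"
            )
        if d.shape[1] < 1:
            raise ValidationError("EEG must have at least one sample")
        if not np.all(np.isfinite(d)):
            raise ValidationError("EEG data must be finite")
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.sampling_rate}")
        means = d.mean(axis=0, keepdims=True)
        if self.input_was_average_referenced is None:
            object.__setattr__(
                self,
                "input_was_average_referenced",
                bool(np.abs(means).max() <= 1e-9 * max(1.0, np.abs(d).max())),
            )
        self.data = d - means

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def gfp(self) -> np.ndarray:
        """Per-sample global field power (RMS about the channel mean)."""
        return self.data.std(axis=0)


@dataclass
class AssignmentSeries:
    """Per-sample class labels from backfitting one K-class solution."""

    solution_K: int
    labels: np.ndarray  # (T,), 0-based class indices
    sampling_rate: float | None = None
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.ndim != 1 or lab.size < 1:
            raise ValidationError("labels must be a non-empty 1-D array")
        if lab.min() < 0 or lab.max() >= self.solution_K:
            raise ValidationError(f"labels out of range 0..{self.solution_K - 1}")
        self.labels = lab

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass
class CommonalityMatrix:
    """Percent overlap of assignments between two solutions (Fig.-7-style).

    ``values[j, k]`` = percentage of samples labeled k by the K_from
    solution that are labeled j by the K_to solution.  Columns over
    non-empty source classes sum to 100; empty source classes give zero
    columns and are listed in ``empty_from_classes``.
    """

    K_from: int
    K_to: int
    values: np.ndarray  # (K_to, K_from)
    empty_from_classes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.K_to, self.K_from):
            raise ValidationError(f"commonality shape {v.shape} != ({self.K_to}, {self.K_from})")
        if v.min() < -1e-9 or v.max() > 100.0 + 1e-9:
            raise ValidationError("commonality entries must lie in [0, 100]")
        sums = v.sum(axis=0)
        for k in range(self.K_from):
            if k in self.empty_from_classes:
                continue
            if abs(sums[k] - 100.0) > 1e-9:
                raise ValidationError(
                    f"column {k} sums to {sums[k]!r}, expected 100"
                )
        self.values = v


@dataclass(frozen=True)
class MapAssignment:
    """Backfit result for one study template map."""

    study_id: str
    map_label: str
    class_index: int
    shared_variance: float


def backfit_maps(
    solution: MetaClusterSolution,
    atlas: Atlas | Sequence[StudySet],
) -> list[MapAssignment]:
    """Assign every study map to its best-matching meta-class.

    Maps are spline-resampled to the solution's common montage where
    needed; assignment is argmax over classes of the shared variance, ties
    to the lowest class index.
    """
    from .metacluster import prepare_items

    X, _, index = prepare_items(atlas, solution.montage)
    corr = X @ solution.maps.T  # (n_maps, K)
    sv = 100.0 * corr * corr
    classes = np.argmax(sv, axis=1)
    return [
        MapAssignment(
            study_id=sid,
            map_label=lab,
            class_index=int(classes[i]),
            shared_variance=float(sv[i, classes[i]]),
        )
        for i, (sid, lab) in enumerate(index)
    ]


def backfit_eeg(
    solution: MetaClusterSolution,
    eeg: EEGRecording,
    operator: SplineOperator | None = None,
    min_gfp: float = 0.0,
    smooth_half_width: int = 0,
) -> AssignmentSeries:
    """Label every EEG sample with its best-matching meta-class.

    Each sample is average-referenced and unit-normalized, then assigned
    by polarity-invariant squared correlation (ties to the lowest class).
    All samples are labeled; a zero-variance sample inherits the previous
    sample's label (class 0 if it is the first) and is counted in
    ``n_degenerate``.  Samples with GFP below ``min_gfp`` are treated the
    same way when that optional exclusion is enabled; ``smooth_half_width``
    > 0 applies a majority-vote relabeling over a +/- window.  Both
    options are off by default.
    """
    if eeg.montage != solution.montage:
        if operator is None:
            raise MontageMismatchError(
                "EEG montage differs from the solution's common montage; "
                "supply a resampling operator"
            )
        if operator.source != eeg.montage or operator.target != solution.montage:
            raise MontageMismatchError("operator does not map EEG montage to solution montage")
        data = operator.transfer @ eeg.data
        data = data - data.mean(axis=0, keepdims=True)
    else:
        data = eeg.data

    norms = np.linalg.norm(data, axis=0)
    scale = max(1.0, float(np.abs(data).max()))
    good = norms > 1e-12 * scale
    if min_gfp > 0.0:
        good &= data.std(axis=0) >= min_gfp

    T = data.shape[1]
    labels = np.zeros(T, dtype=int)
    safe_norms = np.where(good, norms, 1.0)
    normalized = data / safe_norms[None, :]
    corr = solution.maps @ normalized  # (K, T)
    best = np.argmax(corr * corr, axis=0)

    n_degenerate = int(np.sum(~good))
    if n_degenerate == 0:
        labels = best.astype(int)
    else:
        prev = 0  # first degenerate sample falls back to class 0
        for t in range(T):
            labels[t] = best[t] if good[t] else prev
            prev = labels[t]

    if smooth_half_width > 0:
        labels = _majority_smooth(labels, solution.K, smooth_half_width)

    return AssignmentSeries(
        solution_K=solution.K,
        labels=labels,
        sampling_rate=eeg.sampling_rate,
        n_degenerate=n_degenerate,
    )


def _majority_smooth(labels: np.ndarray, K: int, half_width: int) -> np.ndarray:
    """Majority vote over a +/- half_width window; ties keep the current label."""
    T = labels.size
    out = labels.copy()
    for t in range(T):
        lo, hi = max(0, t - half_width), min(T, t + half_width + 1)
        counts = np.bincount(labels[lo:hi], minlength=K)
        if counts.max() > counts[labels[t]]:
            out[t] = int(np.argmax(counts))
    return out


def commonality(a: AssignmentSeries, b: AssignmentSeries) -> CommonalityMatrix:
    """Percent overlap of assignments between two label series.

    ``a`` is the *from* solution (columns), ``b`` the *to* solution (rows):
    C[j, k] = 100 * #{t : a_t = k and b_t = j} / #{t : a_t = k}.
    """
    if a.n_samples != b.n_samples:
        raise ValidationError(
            f"assignment series length mismatch: {a.n_samples} vs {b.n_samples}"
        )
    K_from, K_to = a.solution_K, b.solution_K
    counts = np.zeros((K_to, K_from))
    np.add.at(counts, (b.labels, a.labels), 1.0)
    col_totals = counts.sum(axis=0)
    empty = [int(k) for k in np.flatnonzero(col_totals == 0)]
    denom = np.where(col_totals > 0, col_totals, 1.0)
    values = 100.0 * counts / denom[None, :]
    return CommonalityMatrix(
        K_from=K_from, K_to=K_to, values=values, empty_from_classes=empty
    )


# ---------------------------------------------------------------------------
# EEG CSV I/O (rows = samples, columns = channels; header = channel labels)


def load_eeg_csv(
    path: str | Path, montage: ElectrodeMontage, sampling_rate: float
) -> EEGRecording:
    """Read EEG from a headered CSV (rows = samples, columns = channels).

    The header must list the montage's channel labels; columns are
    reordered to the montage order if needed.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    missing = [l for l in montage.labels if l.lower() not in cols]
    if missing:
        raise ValidationError(f"{path}: EEG CSV missing channels {missing}")
    data = df[[cols[l.lower()] for l in montage.labels]].to_numpy(dtype=float).T
    return EEGRecording(montage=montage, sampling_rate=sampling_rate, data=data)


def save_eeg_csv(eeg: EEGRecording, path: str | Path) -> None:
    """Write EEG as a headered CSV (rows = samples, columns = channels)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(eeg.montage.labels)
        for row in eeg.data.T:
            writer.writerow([f"{x:.10g}" for x in row])
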