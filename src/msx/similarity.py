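"""Polarity-invariant topographic similarity, dissimilarity, and MDS embedding.

The spatial correlation r between two canonical maps (average-referenced,
unit-norm) is simply their dot product, identically the Pearson correlation
over channels.  Shared variance SV = 100 * r^2 is the polarity-invariant
similarity used throughout microstate work: a map and its negation share
100% of their variance.  The global map dissimilarity is

    d = sqrt(2 * (1 - |r|))

i.e. the L2 distance between the two unit maps after choosing the polarity
that brings them closest; a signed variant (using r instead of |r|) is
available behind a flag.

For maps from different montages, the map from the montage with *more*
electrodes is spline-resampled onto the montage with fewer electrodes
before comparison.  The embedding is classical (Torgerson) MDS of the
dissimilarity matrix — deterministic, no iterations, no seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import MontageMismatchError, ValidationError
from .spline import OperatorCache, SplineConfig, resample_map
from .templates import Atlas, StudySet, TemplateMap

__all__ = [
    "SimilarityMatrix",
    "MdsEmbedding",
    "spatial_correlation",
    "shared_variance",
    "dissimilarity",
    "similarity_matrix",
    "dissimilarity_matrix",
    "mds_embed",
]


def spatial_correlation(u: TemplateMap, v: TemplateMap) -> float:
    """Pearson spatial correlation between two canonical maps on one montage."""
    if u.montage != v.montage:
        raise MontageMismatchError(
            f"maps {u.label!r} and {v.label!r} are on different montages; resample first"
        )
    return float(np.clip(u.values @ v.values, -1.0, 1.0))


def shared_variance(u: TemplateMap, v: TemplateMap) -> float:
    """Shared variance in percent: 100 * r^2. Polarity-invariant."""
    r = spatial_correlation(u, v)
    return 100.0 * r * r


def dissimilarity(u: TemplateMap, v: TemplateMap, polarity_invariant: bool = True) -> float:
    """Global map dissimilarity d = sqrt(2 (1 - |r|)) (or 1 - r if signed).

    With ``polarity_invariant`` (the default, consistent with SV), d equals
    min(||u - v||, ||u + v||); the signed variant equals ||u - v|| exactly.
    """
    r = spatial_correlation(u, v)
    if polarity_invariant:
        r = abs(r)
    return float(np.sqrt(max(0.0, 2.0 * (1.0 - r))))


def sv_to_dissimilarity(sv: float | np.ndarray) -> float | np.ndarray:
    """Convert shared variance (percent) to the polarity-invariant d."""
    sv = np.clip(np.asarray(sv, dtype=float), 0.0, 100.0)
    out = np.sqrt(2.0 * (1.0 - np.sqrt(sv / 100.0)))
    return float(out) if out.ndim == 0 else out


@dataclass
class SimilarityMatrix:
    """Pairwise shared variance (percent) over all maps of selected studies."""

    map_index: list[tuple[str, str]]  # (study_id, map_label), matrix order
    values: np.ndarray  # (n_maps, n_maps), symmetric, diagonal 100

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.map_index)
        if v.shape != (n, n):
            raise ValidationError(f"similarity matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, rtol=0, atol=1e-9):
            raise ValidationError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0, rtol=0, atol=1e-9):
            raise ValidationError("similarity matrix diagonal must be 100")
        if v.min() < -1e-9 or v.max() > 100.0 + 1e-9:
            raise ValidationError("shared variance entries must lie in [0, 100]")
        self.values = np.clip(v, 0.0, 100.0)

    @property
    def n_maps(self) -> int:
        return len(self.map_index)


def _pair_shared_variance(
    u: TemplateMap, v: TemplateMap, cache: OperatorCache
) -> float:
    """SV between maps on possibly different montages (resample to the smaller).

    Equal channel counts with an identical montage compare directly;
    otherwise the map on the larger montage (ties: the second map) is
    spline-resampled onto the other's montage.
    """
    if u.montage == v.montage:
        return shared_variance(u, v)
    if u.montage.n_channels > v.montage.n_channels:
        u = resample_map(u, cache.get(u.montage, v.montage))
    else:
        v = resample_map(v, cache.get(v.montage, u.montage))
    return shared_variance(u, v)


def similarity_matrix(
    studies: Sequence[StudySet] | Atlas,
    spline_config: SplineConfig = SplineConfig(),
) -> SimilarityMatrix:
    """Shared-variance matrix over all maps of all selected studies.

    Cross-montage pairs are resampled to the montage with fewer electrodes
    before the shared variance is computed; spline operators are cached per
    montage pair.
    """
    study_list = list(studies)
    items: list[tuple[str, TemplateMap]] = []
    for s in study_list:
        for m in s.maps:
            items.append((s.study_id, m))
    if len(items) < 2:
        raise ValidationError("similarity matrix needs at least 2 maps")
    n = len(items)
    cache = OperatorCache(spline_config)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            sv = _pair_shared_variance(items[i][1], items[j][1], cache)
            out[i, j] = out[j, i] = sv
    index = [(sid, m.label) for sid, m in items]
    return SimilarityMatrix(map_index=index, values=out)


def dissimilarity_matrix(sim: SimilarityMatrix) -> np.ndarray:
    """Polarity-invariant dissimilarity matrix from a similarity matrix."""
    d = sv_to_dissimilarity(sim.values)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class MdsEmbedding:
    """Classical-MDS coordinates of maps, with the retained eigenvalue spectrum."""

    coordinates: np.ndarray  # (n_points, dims)
    eigenvalues: np.ndarray  # full spectrum, descending
    map_index: list[tuple[str, str]] | None = None

    @property
    def dims(self) -> int:
        return self.coordinates.shape[1]


def mds_embed(
    D: np.ndarray,
    dims: int = 2,
    map_index: list[tuple[str, str]] | None = None,
) -> MdsEmbedding:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and returns the top ``dims``
    axes scaled by the square roots of their (non-negative) eigenvalues.
    Axes are ordered by eigenvalue; each axis's sign is fixed so that its
    largest-magnitude coordinate is positive, making the embedding fully
    deterministic.  If fewer than ``dims`` eigenvalues are positive the
    remaining axes are zero (with a warning).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValidationError(f"distance matrix must be square, got {D.shape}")
    if dims not in (2, 3):
        raise ValidationError(f"dims must be 2 or 3, got {dims}")
    if not np.allclose(D, D.T, rtol=0, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, rtol=0, atol=1e-9):
        raise ValidationError("distance matrix must have a zero diagonal")

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]

    n_pos = int(np.sum(eigval > 1e-12))
    if n_pos < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues for a {dims}-D embedding; "
            "remaining axes are zero",
            stacklevel=2,
        )
    coords = np.zeros((n, dims))
    for a in range(min(dims, n_pos)):
        axis = eigvec[:, a] * np.sqrt(eigval[a])
        peak = np.argmax(np.abs(axis))
        if axis[peak] < 0:
            axis = -axis
        coords[:, a] = axis
    return MdsEmbedding(coordinates=coords, eigenvalues=eigval, map_index=map_index)
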