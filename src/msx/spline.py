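"""Spherical-spline interpolation of scalp maps between electrode montages.

Scalp potentials from different studies live on different montages; before
any cross-montage comparison or clustering, maps are resampled with the
classic spherical-spline scheme: electrode positions are projected onto the
unit sphere, a spline of order ``m`` is fitted through the source values,
and the fitted surface is evaluated at the target positions.

The spline kernel is the truncated Legendre series

    g(x) = (1 / 4*pi) * sum_{n=1..N} (2n + 1) / (n^m (n + 1)^m) * P_n(x)

with ``x`` the cosine of the angle between two points on the sphere and
``P_n`` the Legendre polynomial of degree ``n``.  Fitting solves the
bordered system

    [ G + ridge*I   1 ] [ c  ]   [ v ]
    [     1^T       0 ] [ c0 ] = [ 0 ]

for the spline coefficients ``c`` (constrained to sum to zero) and the
constant ``c0``; the interpolated value at target position ``y`` is
``c0 + sum_i c_i g(cos angle(y, x_i))``.  Because both steps are linear,
the whole interpolation collapses into a single target x source transfer
matrix that is precomputed once per montage pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MontageMismatchError, SingularSplineSystemError, ValidationError
from .templates import ElectrodeMontage, TemplateMap

__all__ = ["SplineConfig", "SplineOperator", "g_kernel", "build_interpolator", "resample_map"]


@dataclass(frozen=True)
class SplineConfig:
    """Spherical-spline parameters.

    m : spline order (>= 2). Order 4 is the standard choice for scalp
        potentials; lower orders give stiffer surfaces.
    n_terms : truncation N of the Legendre series. The series terms decay
        like n^(1-2m), so for m=4 the tail beyond N=50 is far below 1e-10.
    ridge : small diagonal regularization protecting against nearly
        coincident electrodes; 0 gives exact interpolation at the nodes.
    """

    m: int = 4
    n_terms: int = 50
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if int(self.m) < 2:
            raise ValidationError(f"spline order m must be >= 2, got {self.m}")
        if int(self.n_terms) < 1:
            raise ValidationError(f"n_terms must be >= 1, got {self.n_terms}")
        if self.ridge < 0:
            raise ValidationError(f"ridge must be non-negative, got {self.ridge}")


def g_kernel(cos_angle, config: SplineConfig = SplineConfig()) -> np.ndarray | float:
    """Evaluate the spherical-spline kernel g at cosine(s) of angle.

    Accepts a scalar or array of cosines in [-1, 1] (values overshooting by
    up to 1e-12 are clamped).  Legendre polynomials are evaluated with the
    stable three-term Bonnet recurrence, accumulating the series in one
    pass.
    """
    x = np.asarray(cos_angle, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValidationError("cos_angle must lie in [-1, 1]")
    x = np.clip(x, -1.0, 1.0)

    m = int(config.m)
    out = np.zeros_like(x)
    p_prev = np.ones_like(x)  # P_0
    p_curr = x.copy()  # P_1
    for n in range(1, int(config.n_terms) + 1):
        coeff = (2 * n + 1) / (n ** m * (n + 1) ** m)
        out += coeff * p_curr
        # Bonnet: (n+1) P_{n+1}(x) = (2n+1) x P_n(x) - n P_{n-1}(x)
        p_next = ((2 * n + 1) * x * p_curr - n * p_prev) / (n + 1)
        p_prev, p_curr = p_curr, p_next
    out /= 4.0 * np.pi
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class SplineOperator:
    """Precomputed linear map from source-montage values to target-montage values.

    ``transfer`` is (n_target, n_source) with the constant term folded in;
    it reproduces constants exactly (the all-ones source vector maps to the
    all-ones target vector).
    """

    source: ElectrodeMontage
    target: ElectrodeMontage
    config: SplineConfig
    transfer: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Interpolate raw (non-canonicalized) per-channel values."""
        v = np.asarray(values, dtype=float)
        if v.shape != (self.source.n_channels,):
            raise MontageMismatchError(
                f"operator expects {self.source.n_channels} source values, got {v.shape}"
            )
        return self.transfer @ v


def build_interpolator(
    source: ElectrodeMontage,
    target: ElectrodeMontage,
    config: SplineConfig = SplineConfig(),
) -> SplineOperator:
    """Build the spline transfer operator from ``source`` to ``target``.

    Positions of both montages are projected to the unit sphere (each
    divided by its own length).  The bordered spline system is solved once
    against the identity so the fit+evaluate composition becomes a single
    matrix; see the module docstring for the formulation.
    """
    ns = source.n_channels
    src = source.unit_positions
    tgt = target.unit_positions

    cos_ss = np.clip(src @ src.T, -1.0, 1.0)
    cos_ts = np.clip(tgt @ src.T, -1.0, 1.0)
    G = g_kernel(cos_ss, config).reshape(ns, ns)
    Gt = g_kernel(cos_ts, config).reshape(target.n_channels, ns)

    A = np.zeros((ns + 1, ns + 1))
    A[:ns, :ns] = G + config.ridge * np.eye(ns)
    A[:ns, ns] = 1.0
    A[ns, :ns] = 1.0
    rhs = np.zeros((ns + 1, ns))
    rhs[:ns, :] = np.eye(ns)
    try:
        Z = np.linalg.solve(A, rhs)  # (ns+1, ns): rows = [c; c0] per unit input
    except np.linalg.LinAlgError as exc:
        raise SingularSplineSystemError(
            "singular spherical-spline system (coincident source electrodes?)"
        ) from exc

    E = np.hstack([Gt, np.ones((target.n_channels, 1))])
    transfer = E @ Z
    return SplineOperator(source=source, target=target, config=config, transfer=transfer)


def resample_map(tmap: TemplateMap, operator: SplineOperator) -> TemplateMap:
    """Spline-resample a template map onto the operator's target montage.

    The interpolated values are re-canonicalized (average reference + unit
    norm), since interpolation does not preserve either exactly.
    """
    if tmap.montage != operator.source:
        raise MontageMismatchError(
            f"map {tmap.label!r} is not on the operator's source montage"
        )
    interpolated = operator.apply(tmap.values)
    return TemplateMap.from_raw(tmap.label, interpolated, operator.target)


class OperatorCache:
    """Memoized :func:`build_interpolator`, keyed by (source, target) montage pair.

    Pairwise similarity over an atlas builds the same few operators many
    times; montage hashing is by lowered label tuple with full equality on
    positions.
    """

    def __init__(self, config: SplineConfig = SplineConfig()) -> None:
        self.config = config
        self._cache: dict[tuple[int, int], SplineOperator] = {}
        self._montages: list[ElectrodeMontage] = []

    def _key(self, montage: ElectrodeMontage) -> int:
        for i, m in enumerate(self._montages):
            if m == montage:
                return i
        self._montages.append(montage)
        return len(self._montages) - 1

    def get(self, source: ElectrodeMontage, target: ElectrodeMontage) -> SplineOperator:
        key = (self._key(source), self._key(target))
        if key not in self._cache:
            self._cache[key] = build_interpolator(source, target, self.config)
        return self._cache[key]
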