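"""Seeded generators for montages, prototype topographies, atlases, and EEG.

These generators give every other module a download-free test surface that
emulates the structure of a multi-study microstate template-map collection
and of microstate-structured resting EEG:

* montages — the built-in idealized 19-channel 10–20 set, or near-uniform
  seeded points on the upper hemisphere for other channel counts;
* prototype maps — smooth random scalp fields built from low-order real
  spherical harmonics, kept mutually decorrelated (pairwise shared
  variance < 25%).  Prototypes are stored as harmonic *coefficients*, so
  the same field can be evaluated consistently on any montage;
* atlases — per study, each prototype perturbed by a fixed-angle rotation
  on the map hypersphere toward a random orthogonal direction, so the
  angular noise maps directly onto an expected shared-variance loss;
* EEG — a piecewise-constant microstate sequence with geometric
  (memoryless) state durations, random per-sample polarity and amplitude,
  plus spatial white noise at a configurable GFP signal-to-noise ratio.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import sph_harm_y

from .backfit import AssignmentSeries, EEGRecording
from .errors import MsxError, ValidationError
from .findings import Finding, validate_finding
from .templates import (
    Atlas,
    ElectrodeMontage,
    StudySet,
    TemplateMap,
    canonicalize_map,
)

__all__ = [
    "FixtureSpec",
    "PrototypeField",
    "standard_1020_montage",
    "make_montage",
    "make_prototype_fields",
    "make_prototypes",
    "make_atlas",
    "make_eeg",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic multi-study atlas and EEG.

    Defaults describe a mid-sized template-map collection: 20 studies of
    10–50 subjects each, montages spanning common densities (19–64
    channels), 5 underlying prototype topographies, and per-study map
    noise of 0.3 rad on the map hypersphere (about 91% expected shared
    variance with the prototype).  EEG defaults emulate resting-state
    recordings: 250 Hz, mean microstate duration 80 ms, GFP signal-to-
    noise ratio 4.
    """

    seed: int = 0
    n_studies: int = 20
    n_prototypes: int = 5
    channels: tuple[int, ...] = (19, 32, 64)
    angular_noise_sd: float = 0.3
    subjects_range: tuple[int, int] = (10, 50)
    smoothness: int = 3
    sampling_rate: float = 250.0
    mean_state_duration_ms: float = 80.0
    snr: float = 4.0
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_prototypes < 1:
            raise ValidationError("n_studies and n_prototypes must be positive")
        if self.angular_noise_sd < 0:
            raise ValidationError("angular_noise_sd must be non-negative")
        if min(self.channels) < 8:
            raise ValidationError("all channel counts must be >= 8")
        if self.subjects_range[0] < 1 or self.subjects_range[1] < self.subjects_range[0]:
            raise ValidationError("invalid subjects_range")
        if min(self.sampling_rate, self.mean_state_duration_ms, self.snr, self.duration_s) <= 0:
            raise ValidationError("EEG parameters must be positive")


# ---------------------------------------------------------------------------
# Montages

# Idealized 10-20 positions: ring electrodes on the equator at the classic
# circumference fractions (azimuth from nasion, degrees), midline/coronal
# electrodes at 45 deg inclination, F3/F4/P3/P4 as arc midpoints.
_RING = {
    "Fp1": -18, "Fp2": 18, "F7": -54, "F8": 54, "T7": -90, "T8": 90,
    "P7": -126, "P8": 126, "O1": -162, "O2": 162,
}

_1020_ORDER = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)


def _sph(inclination_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit position; x = right, y = nasion (front), z = vertex."""
    th = np.deg2rad(inclination_deg)
    ph = np.deg2rad(azimuth_deg)
    return np.array([np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)])


def standard_1020_montage() -> ElectrodeMontage:
    """The built-in idealized 19-channel 10–20 montage on the unit sphere."""
    pos: dict[str, np.ndarray] = {"Cz": _sph(0, 0)}
    pos["Fz"] = _sph(45, 0)
    pos["Pz"] = _sph(45, 180)
    pos["C3"] = _sph(45, -90)
    pos["C4"] = _sph(45, 90)
    for lab, az in _RING.items():
        pos[lab] = _sph(90, az)

    def mid(a: str, b: str) -> np.ndarray:
        v = pos[a] + pos[b]
        return v / np.linalg.norm(v)

    pos["F3"] = mid("Fz", "F7")
    pos["F4"] = mid("Fz", "F8")
    pos["P3"] = mid("Pz", "P7")
    pos["P4"] = mid("Pz", "P8")
    return ElectrodeMontage(
        labels=_1020_ORDER,
        positions=np.stack([pos[l] for l in _1020_ORDER]),
    )


def make_montage(n_channels: int, seed: int = 0) -> ElectrodeMontage:
    """A deterministic n-channel montage on the unit sphere.

    ``n_channels == 19`` returns the built-in 10–20 set; otherwise a
    golden-ratio (Fibonacci) spiral over the upper hemisphere, rotated by a
    seeded azimuth so different seeds give different but equally
    well-spaced montages.
    """
    if n_channels < 8:
        raise ValidationError(f"montage needs >= 8 channels, got {n_channels}")
    if n_channels == 19:
        return standard_1020_montage()
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0, 2 * np.pi)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_channels)
    # z spread over the upper hemisphere, staying a little above the equator
    z = 1.0 - 0.95 * (i + 0.5) / n_channels
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = offset + golden * i
    positions = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    labels = tuple(f"E{j + 1}" for j in range(n_channels))
    return ElectrodeMontage(labels=labels, positions=positions)


# ---------------------------------------------------------------------------
# Prototype scalp fields


@dataclass(frozen=True)
class PrototypeField:
    """A smooth scalp field as real-spherical-harmonic coefficients.

    Storing coefficients (rather than sampled values) lets the same
    prototype be evaluated on any montage, giving exact cross-montage
    consistency for synthetic multi-montage atlases.
    """

    coefficients: tuple[tuple[int, int, float], ...]  # (l, m, weight)

    def evaluate(self, montage: ElectrodeMontage) -> np.ndarray:
        """Canonical map values of this field on ``montage``."""
        pos = montage.unit_positions
        theta = np.arccos(np.clip(pos[:, 2], -1.0, 1.0))  # polar angle from vertex
        phi = np.arctan2(pos[:, 1], pos[:, 0])
        out = np.zeros(montage.n_channels)
        for l, m, w in self.coefficients:
            y = sph_harm_y(l, abs(m), theta, phi)
            if m > 0:
                out += w * np.sqrt(2.0) * np.real(y)
            elif m < 0:
                out += w * np.sqrt(2.0) * np.imag(y)
            else:
                out += w * np.real(y)
        return canonicalize_map(out)


def _draw_field(rng: np.random.Generator, smoothness: int) -> PrototypeField:
    coeffs = []
    for l in range(1, smoothness + 1):
        for m in range(-l, l + 1):
            # taper high orders so the field stays smooth
            coeffs.append((l, m, float(rng.normal(scale=1.0 / l))))
    return PrototypeField(coefficients=tuple(coeffs))


MAX_DECORRELATION_DRAWS = 1000
MAX_PAIRWISE_SV = 25.0


def make_prototype_fields(
    K: int,
    seed: int = 0,
    smoothness: int = 3,
    reference_montage: ElectrodeMontage | None = None,
) -> list[PrototypeField]:
    """Draw K smooth prototype fields with pairwise shared variance < 25%.

    Fields are drawn sequentially and each candidate is accepted only if it
    is sufficiently decorrelated (on the reference montage, default the
    built-in 10–20 set) from all previously accepted fields.  Sequential
    acceptance means the first K fields of a (K+1, seed) draw equal the
    (K, seed) draw — the nested-prototype construction the commonality
    analyses rely on.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    montage = reference_montage or standard_1020_montage()
    rng = np.random.default_rng(seed)
    fields: list[PrototypeField] = []
    accepted: list[np.ndarray] = []
    draws = 0
    while len(fields) < K:
        if draws >= MAX_DECORRELATION_DRAWS:
            raise MsxError(
                f"could not draw {K} decorrelated prototypes in "
                f"{MAX_DECORRELATION_DRAWS} attempts"
            )
        draws += 1
        cand = _draw_field(rng, smoothness)
        vals = cand.evaluate(montage)
        if all(100.0 * (vals @ prev) ** 2 < MAX_PAIRWISE_SV for prev in accepted):
            fields.append(cand)
            accepted.append(vals)
    return fields


def make_prototypes(
    K: int,
    montage: ElectrodeMontage,
    smoothness: int = 3,
    seed: int = 0,
) -> list[TemplateMap]:
    """K canonical, mutually decorrelated prototype maps on ``montage``."""
    fields = make_prototype_fields(K, seed=seed, smoothness=smoothness)
    return [
        TemplateMap(label=str(k + 1), values=f.evaluate(montage), montage=montage)
        for k, f in enumerate(fields)
    ]


def _perturb_on_sphere(
    v: np.ndarray, angle: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate a canonical map by ``angle`` toward a random orthogonal direction.

    The direction is zero-mean and orthogonal to v, so the result stays in
    the canonical subspace; cos(angle) is exactly the spatial correlation
    with the original.
    """
    if angle == 0.0:
        return v.copy()
    e = rng.standard_normal(v.size)
    e -= e.mean()
    e -= (e @ v) * v
    norm = np.linalg.norm(e)
    if norm < 1e-12:  # pragma: no cover - measure-zero draw
        return v.copy()
    e /= norm
    out = np.cos(angle) * v + np.sin(angle) * e
    return out / np.linalg.norm(out)


_SYNTH_CONTRASTS = (
    ("Task vs. rest", "More Duration"),
    ("Patients vs. controls", "Less Occurrence"),
    ("Eyes closed vs. eyes open", "More GEV"),
    ("Old vs. young", "Less Contribution"),
)


def make_atlas(spec: FixtureSpec) -> Atlas:
    """A synthetic multi-study atlas with ground-truth prototype labels.

    Each study gets a montage from ``spec.channels`` (cycled), one map per
    prototype (evaluated on the study montage, then rotated by
    ``angular_noise_sd`` on the map hypersphere), a subject count drawn
    from ``subjects_range``, ground-truth class stored in metadata, and a
    small deterministic set of synthetic findings.
    """
    rng = np.random.default_rng(spec.seed)
    fields = make_prototype_fields(spec.n_prototypes, seed=spec.seed, smoothness=spec.smoothness)
    studies: list[StudySet] = []
    for s in range(spec.n_studies):
        n_ch = spec.channels[s % len(spec.channels)]
        montage = make_montage(n_ch, seed=spec.seed * 1000 + s)
        maps = []
        truth = {}
        findings: list[Finding] = []
        for k, f2 in enumerate(fields):
            label = chr(ord("A") + k) if k < 26 else f"M{k + 1}"
            base = f2.evaluate(montage)
            values = _perturb_on_sphere(base, spec.angular_noise_sd, rng)
            maps.append(TemplateMap(label=label, values=values, montage=montage))
            truth[f"truth_{label}"] = str(k)
            if (s + k) % 3 == 0:
                contrast, effect = _SYNTH_CONTRASTS[(s + k) % len(_SYNTH_CONTRASTS)]
                findings.append(
                    validate_finding(f"Study{s + 1:02d}", label, contrast, effect)
                )
            else:
                findings.append(validate_finding(f"Study{s + 1:02d}", label, "", "No findings"))
        n_subjects = int(rng.integers(spec.subjects_range[0], spec.subjects_range[1] + 1))
        studies.append(
            StudySet(
                study_id=f"Study{s + 1:02d}",
                montage=montage,
                maps=maps,
                n_subjects=n_subjects,
                metadata={"seed": str(spec.seed), **truth},
                findings=findings,
            )
        )
    return Atlas(studies=studies)


def make_eeg(
    prototypes: Sequence[TemplateMap] | np.ndarray,
    spec: FixtureSpec,
    montage: ElectrodeMontage | None = None,
    seed: int | None = None,
) -> tuple[EEGRecording, AssignmentSeries]:
    """Microstate-structured synthetic EEG plus its ground-truth labels.

    The label sequence is piecewise constant with geometric run lengths
    (memoryless; mean = mean_state_duration_ms); consecutive runs always
    switch state.  Each sample is (random polarity) x (random positive
    amplitude) x (its state's prototype map) + spatial white noise scaled
    so the per-sample GFP ratio of signal to noise equals ``spec.snr``.
    Data is average-referenced.
    """
    if isinstance(prototypes, np.ndarray):
        if montage is None:
            raise ValidationError("montage required when prototypes is an array")
        proto = np.asarray(prototypes, dtype=float)
    else:
        prototypes = list(prototypes)
        if not prototypes:
            raise ValidationError("need at least one prototype")
        montage = prototypes[0].montage
        proto = np.stack([p.values for p in prototypes])
    K, n_ch = proto.shape

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    T = int(round(spec.duration_s * spec.sampling_rate))
    if T < 1:
        raise ValidationError("EEG duration too short for the sampling rate")
    mean_run = spec.mean_state_duration_ms * spec.sampling_rate / 1000.0
    if mean_run < 1.0:
        raise ValidationError("mean state duration must be >= one sample")
    p_switch = 1.0 / mean_run

    labels = np.empty(T, dtype=int)
    state = int(rng.integers(K))
    for t in range(T):
        labels[t] = state
        if rng.random() < p_switch and K > 1:
            nxt = int(rng.integers(K - 1))
            state = nxt if nxt < state else nxt + 1

    amplitudes = np.abs(rng.normal(loc=10.0, scale=2.0, size=T)) + 0.5  # µV-scale
    signs = rng.choice([-1.0, 1.0], size=T)
    signal = (signs * amplitudes)[None, :] * proto[labels].T  # (n_ch, T)

    noise = rng.standard_normal((n_ch, T))
    noise -= noise.mean(axis=0, keepdims=True)
    noise_norm = np.linalg.norm(noise, axis=0)
    noise_norm[noise_norm == 0] = 1.0
    noise *= (amplitudes / (spec.snr * noise_norm))[None, :]

    eeg = EEGRecording(
        montage=montage, sampling_rate=spec.sampling_rate, data=signal + noise
    )
    truth = AssignmentSeries(
        solution_K=K, labels=labels, sampling_rate=spec.sampling_rate
    )
    return eeg, truth
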