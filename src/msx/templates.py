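"""Domain types and file I/O for microstate template maps.

A *template map* summarises the scalp topography of one EEG microstate
class: a vector of potentials, one per electrode.  Microstate convention
treats maps as average-referenced (zero mean over channels) and amplitude
normalised; here the canonical form is unit L2 norm, which makes the
global field power (GFP, the RMS about the channel mean) a constant
1/sqrt(n_channels) per montage.  All similarity math downstream is
invariant to this scaling choice.

The module also defines the containers a cross-study comparison needs:
an :class:`ElectrodeMontage` (labels + 3-D head-centered positions), a
:class:`StudySet` (one study's montage, ordered maps, subject count and
findings) and an :class:`Atlas` (a collection of studies), plus plain-text
readers/writers (.sfp / CSV montages, JSON study files).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import DegenerateMapError, ValidationError
from .findings import Finding, validate_finding

__all__ = [
    "ElectrodeMontage",
    "TemplateMap",
    "StudySet",
    "Atlas",
    "canonicalize_map",
    "load_montage",
    "save_montage",
    "load_study",
    "save_study",
    "load_atlas",
]

#: Minimum number of electrodes for any montage or map.
MIN_CHANNELS = 8

#: Two projected electrodes closer than this angle (radians) are coincident.
COINCIDENCE_TOL = 1e-6


def canonicalize_map(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Return the canonical form of a scalp map.

    The canonical form is average-referenced (channel mean removed) and
    scaled to unit L2 norm::

        v' = (v - mean(v)) / ||v - mean(v)||_2

    The map's polarity (sign) is preserved; canonicalization is idempotent
    and invariant to positive rescaling of the input.

    Parameters
    ----------
    values
        Per-channel potentials, length >= 8, all finite.

    Raises
    ------
    ValidationError
        If fewer than 8 values or any value is non-finite.
    DegenerateMapError
        If the map is constant across channels (zero vector after average
        referencing), which carries no topographic information.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValidationError(f"map values must be 1-D, got shape {v.shape}")
    if v.size < MIN_CHANNELS:
        raise ValidationError(
            f"map needs at least {MIN_CHANNELS} channels, got {v.size}"
        )
    if not np.all(np.isfinite(v)):
        raise ValidationError("map values must all be finite")
    centered = v - v.mean()
    norm = float(np.linalg.norm(centered))
    if norm <= 1e-12 * max(1.0, float(np.abs(v).max())):
        raise DegenerateMapError(
            "map is constant across channels (degenerate after average reference)"
        )
    return centered / norm


@dataclass(frozen=True)
class ElectrodeMontage:
    """An electrode set: channel labels and 3-D head-centered positions.

    Positions are Cartesian in arbitrary length units; they are only ever
    used through their directions (projection onto the unit sphere), so no
    particular head radius is assumed.
    """

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValidationError(f"positions must be (n, 3), got {pos.shape}")
        if len(labels) != pos.shape[0]:
            raise ValidationError("labels and positions length mismatch")
        if len(labels) < MIN_CHANNELS:
            raise ValidationError(
                f"montage needs at least {MIN_CHANNELS} channels, got {len(labels)}"
            )
        lowered = [l.lower() for l in labels]
        if len(set(lowered)) != len(lowered):
            dupes = sorted({l for l in lowered if lowered.count(l) > 1})
            raise ValidationError(f"duplicate channel labels (case-insensitive): {dupes}")
        if not np.all(np.isfinite(pos)):
            raise ValidationError("electrode positions must be finite")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            bad = [labels[i] for i in np.flatnonzero(norms == 0)]
            raise ValidationError(f"zero-length electrode positions: {bad}")
        unit = pos / norms[:, None]
        cos = np.clip(unit @ unit.T, -1.0, 1.0)
        ang = np.arccos(cos)
        np.fill_diagonal(ang, np.inf)
        if np.any(ang < COINCIDENCE_TOL):
            i, j = np.unravel_index(int(np.argmin(ang)), ang.shape)
            raise ValidationError(
                f"coincident electrode projections: {labels[i]} and {labels[j]}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def unit_positions(self) -> np.ndarray:
        """Positions projected to the unit sphere (each divided by its length)."""
        pos = self.positions
        return pos / np.linalg.norm(pos, axis=1)[:, None]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElectrodeMontage):
            return NotImplemented
        return (
            tuple(l.lower() for l in self.labels)
            == tuple(l.lower() for l in other.labels)
            and self.positions.shape == other.positions.shape
            and np.allclose(self.positions, other.positions, rtol=0, atol=1e-9)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(tuple(l.lower() for l in self.labels))

    def __repr__(self) -> str:
        return f"ElectrodeMontage(n_channels={self.n_channels})"


@dataclass(frozen=True)
class TemplateMap:
    """One canonicalized microstate template map tied to a montage.

    ``values`` are always stored canonical (zero mean, unit L2 norm);
    construct with :meth:`from_raw` to canonicalize arbitrary potentials.
    ``input_was_canonical`` records whether the source data already
    satisfied the canonical form (within 1e-6) before loading.
    """

    label: str
    values: np.ndarray
    montage: ElectrodeMontage
    input_was_canonical: bool | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.montage.n_channels,):
            raise ValidationError(
                f"map {self.label!r}: {v.size} values for "
                f"{self.montage.n_channels}-channel montage"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"map {self.label!r}: non-finite values")
        if abs(float(v.mean())) > 1e-10 or abs(float(np.linalg.norm(v)) - 1.0) > 1e-10:
            raise ValidationError(
                f"map {self.label!r} is not canonical; use TemplateMap.from_raw"
            )

    @classmethod
    def from_raw(
        cls, label: str, values: Sequence[float] | np.ndarray, montage: ElectrodeMontage
    ) -> "TemplateMap":
        raw = np.asarray(values, dtype=float)
        if raw.shape != (montage.n_channels,):
            raise ValidationError(
                f"map {label!r}: {raw.size} values for "
                f"{montage.n_channels}-channel montage"
            )
        canon = canonicalize_map(raw)
        was = bool(np.allclose(raw, canon, rtol=0, atol=1e-6))
        return cls(label=str(label), values=canon, montage=montage, input_was_canonical=was)

    def flipped(self) -> "TemplateMap":
        """The same topography with inverted polarity."""
        return TemplateMap(
            label=self.label,
            values=-self.values,
            montage=self.montage,
            input_was_canonical=self.input_was_canonical,
        )


@dataclass
class StudySet:
    """One study's template maps plus the metadata a meta-analysis needs.

    ``n_subjects`` is the study's sample size; it is the weight *w* used
    when template maps enter the across-study meta-clustering.
    """

    study_id: str
    montage: ElectrodeMontage
    maps: list[TemplateMap]
    n_subjects: int
    metadata: dict[str, str] = field(default_factory=dict)
    findings: list[Finding] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be non-empty")
        if not self.maps:
            raise ValidationError(f"study {self.study_id!r} has no maps")
        if int(self.n_subjects) < 1:
            raise ValidationError(
                f"study {self.study_id!r}: n_subjects must be >= 1, got {self.n_subjects}"
            )
        self.n_subjects = int(self.n_subjects)
        labels = [m.label for m in self.maps]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"study {self.study_id!r}: duplicate map labels")
        for m in self.maps:
            if m.montage != self.montage:
                raise ValidationError(
                    f"study {self.study_id!r}: map {m.label!r} on a different montage"
                )

    @property
    def map_labels(self) -> list[str]:
        return [m.label for m in self.maps]

    def get_map(self, label: str) -> TemplateMap:
        for m in self.maps:
            if m.label == label:
                return m
        raise KeyError(f"study {self.study_id!r} has no map {label!r}")


@dataclass
class Atlas:
    """A collection of studies — the in-memory template-map database."""

    studies: list[StudySet]

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate study_ids in atlas")
        if sum(len(s.maps) for s in self.studies) < 1:
            raise ValidationError("atlas contains no maps")

    def __iter__(self) -> Iterator[StudySet]:
        return iter(self.studies)

    def __len__(self) -> int:
        return len(self.studies)

    def get_study(self, study_id: str) -> StudySet:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(f"no study {study_id!r} in atlas")

    def iter_maps(self) -> Iterator[tuple[StudySet, TemplateMap]]:
        """Yield (study, map) over all maps of all studies, in atlas order."""
        for s in self.studies:
            for m in s.maps:
                yield s, m

    @property
    def n_maps(self) -> int:
        return sum(len(s.maps) for s in self.studies)


# ---------------------------------------------------------------------------
# Montage I/O


def load_montage(path: str | Path, dialect: str | None = None) -> ElectrodeMontage:
    """Read an electrode montage from an .sfp or CSV file.

    ``.sfp`` is whitespace-delimited ``label x y z``, one electrode per
    line, ``#`` comments allowed.  CSV needs a ``label,x,y,z`` header.
    The dialect is inferred from the file extension when not given.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "sfp"
    if dialect not in ("sfp", "csv"):
        raise ValidationError(f"unknown montage dialect {dialect!r}")

    labels: list[str] = []
    rows: list[list[float]] = []
    if dialect == "sfp":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 'label x y z', got {line!r}")
            try:
                xyz = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: unparsable coordinates") from exc
            labels.append(parts[0])
            rows.append(xyz)
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            fields = [f.strip().lower() for f in (reader.fieldnames or [])]
            if fields[:4] != ["label", "x", "y", "z"]:
                raise ValidationError(f"{path}: CSV montage needs header label,x,y,z")
            for lineno, row in enumerate(reader, 2):
                row = {k.strip().lower(): v for k, v in row.items() if k}
                try:
                    xyz = [float(row[c]) for c in ("x", "y", "z")]
                except (KeyError, TypeError, ValueError) as exc:
                    raise ValidationError(f"{path}:{lineno}: unparsable row") from exc
                labels.append(row["label"].strip())
                rows.append(xyz)
    return ElectrodeMontage(labels=tuple(labels), positions=np.array(rows, dtype=float))


def save_montage(montage: ElectrodeMontage, path: str | Path, dialect: str | None = None) -> None:
    """Write a montage as .sfp or CSV (dialect inferred from extension)."""
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "sfp"
    if dialect == "sfp":
        lines = [
            f"{lab} {x:.17g} {y:.17g} {z:.17g}"
            for lab, (x, y, z) in zip(montage.labels, montage.positions)
        ]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "x", "y", "z"])
            for lab, (x, y, z) in zip(montage.labels, montage.positions):
                writer.writerow([lab, f"{x:.17g}", f"{y:.17g}", f"{z:.17g}"])
    else:
        raise ValidationError(f"unknown montage dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Study JSON I/O
#
# Schema: {study_id, n_subjects, metadata{}, montage{labels[], positions[][3]},
#          maps[{label, values[]}], findings[{map_label, contrast, effect}]}


def _study_to_dict(study: StudySet) -> dict:
    return {
        "study_id": study.study_id,
        "n_subjects": study.n_subjects,
        "metadata": dict(study.metadata),
        "montage": {
            "labels": list(study.montage.labels),
            "positions": study.montage.positions.tolist(),
        },
        "maps": [
            {
                "label": m.label,
                "values": m.values.tolist(),
                "input_was_canonical": m.input_was_canonical,
            }
            for m in study.maps
        ],
        "findings": [
            {"map_label": f.map_label, "contrast": f.contrast, "effect": f.effect_text()}
            for f in study.findings
        ],
    }


def _study_from_dict(doc: Mapping) -> StudySet:
    try:
        study_id = doc["study_id"]
        n_subjects = doc["n_subjects"]
        mdoc = doc["montage"]
        maps_doc = doc["maps"]
    except KeyError as exc:
        raise ValidationError(f"study file missing required field {exc}") from exc
    montage = ElectrodeMontage(
        labels=tuple(mdoc["labels"]), positions=np.asarray(mdoc["positions"], dtype=float)
    )
    maps = []
    for m in maps_doc:
        values = np.asarray(m["values"], dtype=float)
        if values.size != montage.n_channels:
            raise ValidationError(
                f"study {study_id!r}, map {m.get('label')!r}: {values.size} values "
                f"for {montage.n_channels}-channel montage"
            )
        maps.append(TemplateMap.from_raw(m["label"], values, montage))
    findings = [
        validate_finding(
            study_id=study_id,
            map_label=f["map_label"],
            contrast=f.get("contrast", ""),
            effect=f.get("effect", ""),
        )
        for f in doc.get("findings", [])
    ]
    return StudySet(
        study_id=study_id,
        montage=montage,
        maps=maps,
        n_subjects=n_subjects,
        metadata={str(k): str(v) for k, v in doc.get("metadata", {}).items()},
        findings=findings,
    )


def save_study(study: StudySet, path: str | Path) -> None:
    """Write a study to a JSON study file (round-trips via :func:`load_study`)."""
    Path(path).write_text(json.dumps(_study_to_dict(study), indent=1) + "\n")


def load_study(path: str | Path) -> StudySet:
    """Read a JSON study file; maps are canonicalized on load.

    Whether each map was already canonical in the file is recorded in
    ``TemplateMap.input_was_canonical``.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return _study_from_dict(doc)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def load_atlas(path: str | Path) -> Atlas:
    """Load an atlas from a directory of study JSON files or one JSON array.

    Directory entries are read in sorted filename order so the atlas map
    order is deterministic.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix == ".json")
        if not files:
            raise ValidationError(f"{path}: no .json study files found")
        return Atlas(studies=[load_study(p) for p in files])
    doc = json.loads(path.read_text())
    if not isinstance(doc, list):
        raise ValidationError(f"{path}: atlas file must be a JSON array of studies")
    return Atlas(studies=[_study_from_dict(d) for d in doc])


def save_atlas(atlas: Atlas, path: str | Path) -> None:
    """Write an atlas as a single JSON array of study documents."""
    docs = [_study_to_dict(s) for s in atlas.studies]
    Path(path).write_text(json.dumps(docs, indent=1) + "\n")
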