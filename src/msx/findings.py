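"""Empirical findings attached to template maps: validation, queries, export.

A finding records what a study reported about one microstate class under
some contrast ("Hypnagogic state vs. wake"), as a direction (More/Less)
on a microstate parameter (Duration, Occurrence, Contribution, GEV,
current density, or free text).  The point of the database is to query
findings by *topographic* similarity — via a selection of maps or a
meta-microstate class — rather than by the (inconsistent) class labels
studies use.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .backfit import backfit_maps as _backfit_maps
    from .metacluster import MetaClusterSolution
    from .templates import Atlas

__all__ = [
    "Finding",
    "FindingsTable",
    "validate_finding",
    "query_by_selection",
    "query_by_metaclass",
    "export_table",
    "import_table",
]

DIRECTIONS = ("More", "Less", "NoFinding")

#: Normalized parameter vocabulary -> canonical token.
_PARAMETERS = {
    "duration": "Duration",
    "occurrence": "Occurrence",
    "contribution": "Contribution",
    "gev": "GEV",
    "current density": "CurrentDensity",
    "currentdensity": "CurrentDensity",
}

_NO_FINDING_TOKENS = {"no findings", "no finding", "nofinding", "nofindings", ""}


@dataclass(frozen=True)
class Finding:
    """One study's reported effect for one of its template maps.

    ``direction`` is "More", "Less" or "NoFinding"; ``parameter`` is one of
    the canonical tokens (Duration, Occurrence, Contribution, GEV,
    CurrentDensity) or, for non-standard quantities, ``"Other"`` with the
    verbatim text kept in ``parameter_text``.  A NoFinding row has empty
    contrast and parameter.
    """

    study_id: str
    map_label: str
    contrast: str
    direction: str
    parameter: str = ""
    parameter_text: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown finding direction {self.direction!r}")
        if self.direction == "NoFinding":
            if self.contrast or self.parameter:
                raise ValidationError("NoFinding rows must have empty contrast and parameter")
        else:
            if not self.contrast:
                raise ValidationError(
                    f"finding for {self.study_id}_{self.map_label}: contrast required"
                )
            if not self.parameter:
                raise ValidationError(
                    f"finding for {self.study_id}_{self.map_label}: parameter required"
                )

    def effect_text(self) -> str:
        """The human-readable effect, as it appears in findings tables."""
        if self.direction == "NoFinding":
            return "No findings"
        param = self.parameter_text if self.parameter == "Other" else self.parameter
        return f"{self.direction} {param}"


def validate_finding(study_id: str, map_label: str, contrast: str, effect: str) -> Finding:
    """Parse and normalize one raw finding record.

    ``effect`` is free text like ``"More Duration"``, ``"Less GEV"``,
    ``"More current density"`` or ``"No findings"``.  The leading token is
    the direction; the remainder is matched case-insensitively against the
    parameter vocabulary, falling back to Other with the text preserved
    verbatim.
    """
    contrast = (contrast or "").strip()
    text = (effect or "").strip()
    if text.lower() in _NO_FINDING_TOKENS:
        if contrast:
            raise ValidationError(
                f"finding for {study_id}_{map_label}: 'No findings' with a contrast"
            )
        return Finding(study_id=study_id, map_label=map_label, contrast="", direction="NoFinding")
    head, _, rest = text.partition(" ")
    direction = head.capitalize()
    if direction not in ("More", "Less"):
        raise ValidationError(
            f"finding for {study_id}_{map_label}: unknown direction token {head!r}"
        )
    if not contrast:
        raise ValidationError(
            f"finding for {study_id}_{map_label}: contrast required for {text!r}"
        )
    rest = rest.strip()
    if not rest:
        raise ValidationError(f"finding for {study_id}_{map_label}: effect missing parameter")
    param = _PARAMETERS.get(rest.lower())
    if param is not None:
        return Finding(study_id, map_label, contrast, direction, param)
    return Finding(study_id, map_label, contrast, direction, "Other", parameter_text=rest)


_SORT_KEY = ("study_id", "map_label", "parameter", "contrast", "direction")


@dataclass
class FindingsTable:
    """A deterministic, query-provenanced table of findings."""

    rows: list[Finding]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.rows = sorted(
            self.rows,
            key=lambda f: (f.study_id, f.map_label, f.parameter, f.contrast, f.direction),
        )

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "study_id": f.study_id,
                    "map_label": f.map_label,
                    "contrast": f.contrast,
                    "effect": f.effect_text(),
                }
                for f in self.rows
            ],
            columns=["study_id", "map_label", "contrast", "effect"],
        )


def query_by_selection(
    atlas: "Atlas", selection: Iterable[tuple[str, str]]
) -> FindingsTable:
    """All findings of exactly the selected (study_id, map_label) pairs.

    A selected map with no stored findings contributes a single NoFinding
    row, so every selected map is visible in the result.
    """
    pairs = list(dict.fromkeys((str(s), str(m)) for s, m in selection))
    if not pairs:
        raise ValidationError("empty selection")
    known = {(s.study_id, m.label) for s, m in atlas.iter_maps()}
    unknown = [p for p in pairs if p not in known]
    if unknown:
        raise KeyError(f"selection refers to unknown maps: {unknown}")
    wanted = set(pairs)
    rows: list[Finding] = []
    covered: set[tuple[str, str]] = set()
    for study in atlas:
        for f in study.findings:
            key = (study.study_id, f.map_label)
            if key in wanted:
                rows.append(f)
                covered.add(key)
    for sid, lab in sorted(wanted - covered):
        rows.append(Finding(study_id=sid, map_label=lab, contrast="", direction="NoFinding"))
    prov = "selection: " + "; ".join(f"{s}_{m}" for s, m in sorted(wanted))
    return FindingsTable(rows=rows, provenance=prov)


def query_by_metaclass(
    atlas: "Atlas", solution: "MetaClusterSolution", class_index: int
) -> FindingsTable:
    """Findings of all study maps that backfit to meta-class ``class_index``.

    Equivalent to :func:`query_by_selection` over the maps the solution's
    polarity-invariant backfitting assigns to that class.  A class with no
    assigned maps yields an empty table whose provenance notes the fact.
    """
    from .backfit import backfit_maps

    if not 0 <= class_index < solution.K:
        raise ValidationError(
            f"class index {class_index} out of range for K={solution.K}"
        )
    assigned = backfit_maps(solution, atlas)
    pairs = [
        (r.study_id, r.map_label) for r in assigned if r.class_index == class_index
    ]
    if not pairs:
        return FindingsTable(
            rows=[],
            provenance=f"meta-class {class_index} of K={solution.K}: no assigned maps",
        )
    table = query_by_selection(atlas, pairs)
    table.provenance = (
        f"meta-class {class_index} of K={solution.K}; " + table.provenance
    )
    return table


def export_table(table: FindingsTable, path: str | Path) -> None:
    """Write a findings table as CSV (header always present)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["study_id", "map_label", "contrast", "effect"])
        for f in table.rows:
            writer.writerow([f.study_id, f.map_label, f.contrast, f.effect_text()])


def import_table(path: str | Path) -> FindingsTable:
    """Read back a CSV written by :func:`export_table`."""
    rows: list[Finding] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = ["study_id", "map_label", "contrast", "effect"]
        if [c.strip() for c in (reader.fieldnames or [])] != expected:
            raise ValidationError(f"{path}: expected header {','.join(expected)}")
        for rec in reader:
            rows.append(
                validate_finding(
                    rec["study_id"], rec["map_label"], rec["contrast"], rec["effect"]
                )
            )
    return FindingsTable(rows=rows, provenance=f"imported from {path}")
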