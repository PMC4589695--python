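"""Structured specimen-based character data.

Characters are either *categorical* (an ordered vocabulary of two or more
state labels; a specimen may exhibit several — polymorphism) or
*quantitative* (measurements with a unit, recorded as exact values and/or a
min–max range read from a label).  A :class:`SpecimenDescription` binds the
scored entries of one character set to exactly one unit of a derivative
hierarchy, which is what makes the data specimen-based rather than merely
taxon-based.

State labels match case-sensitively by exact string; an absent entry means
"not scored", and recording an empty state set deletes the entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd

from .core import NotFoundError, Store, ValidationError

__all__ = [
    "CharacterDef",
    "CharacterSet",
    "QuantitativeSummary",
    "SpecimenDescription",
    "AggregatedQuantitative",
    "TaxonDescription",
    "record_categorical",
    "record_quantitative",
    "link_description",
    "CompatibilityReport",
    "check_compatibility",
    "union_charsets",
    "matrix_view",
    "descriptions_from_matrix",
    "MISSING",
]

#: Explicit missing-cell marker used in matrix views.
MISSING = None


@dataclass
class CharacterDef:
    char_id: str
    name: str
    kind: str  # "categorical" | "quantitative"
    states: list[str] = field(default_factory=list)
    unit_label: str = ""

    def validate(self) -> None:
        if self.kind not in ("categorical", "quantitative"):
            raise ValidationError(f"unknown character kind: {self.kind!r}")
        if self.kind == "categorical":
            if len(self.states) < 2:
                raise ValidationError(f"categorical character {self.char_id} needs >= 2 states")
            if len(set(self.states)) != len(self.states):
                raise ValidationError(f"duplicate state labels in {self.char_id}")
        else:
            if not self.unit_label:
                raise ValidationError(f"quantitative character {self.char_id} needs a unit label")

    def same_definition(self, other: "CharacterDef") -> bool:
        if self.kind != other.kind:
            return False
        if self.kind == "categorical":
            return self.states == other.states
        return self.unit_label == other.unit_label


class CharacterSet:
    """An ordered collection of character definitions with unique ids."""

    def __init__(self, set_id: str, characters: list[CharacterDef]) -> None:
        ids = [c.char_id for c in characters]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate char_ids in character set {set_id}")
        for c in characters:
            c.validate()
        self.set_id = set_id
        self.characters = list(characters)
        self._by_id = {c.char_id: c for c in characters}

    def __iter__(self):
        return iter(self.characters)

    def __contains__(self, char_id: str) -> bool:
        return char_id in self._by_id

    def __getitem__(self, char_id: str) -> CharacterDef:
        try:
            return self._by_id[char_id]
        except KeyError:
            raise NotFoundError(char_id) from None

    def char_ids(self) -> list[str]:
        return [c.char_id for c in self.characters]


@dataclass
class QuantitativeSummary:
    """Measurements for one quantitative character on one specimen.

    ``exact_values`` are individual measurements; ``range_min``/``range_max``
    capture a range read from a label without the underlying values.
    ``sample_size`` is the number of underlying measurements and defaults to
    ``len(exact_values)``.
    """

    exact_values: list[float] = field(default_factory=list)
    range_min: Optional[float] = None
    range_max: Optional[float] = None
    sample_size: int = 0

    def __post_init__(self) -> None:
        self.exact_values = [float(v) for v in self.exact_values]
        for v in self.exact_values:
            if math.isnan(v):
                raise ValidationError("NaN measurement value")
        if self.range_min is not None and self.range_max is not None:
            if self.range_min > self.range_max:
                raise ValidationError(
                    f"range_min {self.range_min} > range_max {self.range_max}"
                )
        if self.sample_size == 0:
            self.sample_size = len(self.exact_values)
        if self.sample_size < len(self.exact_values):
            raise ValidationError("sample_size smaller than number of exact values")

    def bounds(self) -> tuple[Optional[float], Optional[float]]:
        lo = [v for v in self.exact_values]
        hi = list(lo)
        if self.range_min is not None:
            lo.append(self.range_min)
        if self.range_max is not None:
            hi.append(self.range_max)
        return (min(lo) if lo else None, max(hi) if hi else None)


Entry = Union[frozenset, QuantitativeSummary]


@dataclass
class SpecimenDescription:
    """Character entries of one character set scored on one unit."""

    subject_unit_id: str
    charset_id: str
    entries: dict[str, Entry] = field(default_factory=dict)


@dataclass
class AggregatedQuantitative:
    """Merged statistics for one quantitative character at taxon level."""

    min: Optional[float]
    max: Optional[float]
    mean: Optional[float]
    n_values: int
    n_specimens: int


@dataclass
class TaxonDescription:
    """Character data of a taxon: either aggregated from specimens (with
    per-character specimen provenance) or entered manually."""

    taxon_id: str
    charset_id: str
    entries: dict[str, Union[dict, AggregatedQuantitative]] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)
    generated_at: str = ""
    is_aggregated: bool = True


def record_categorical(
    desc: SpecimenDescription, charset: CharacterSet, char_id: str, states
) -> SpecimenDescription:
    """Score a categorical character; an empty state set removes the entry."""
    char = charset[char_id]
    if char.kind != "categorical":
        raise ValidationError(f"{char_id} is quantitative, not categorical")
    states = frozenset(states)
    unknown = states - set(char.states)
    if unknown:
        raise ValidationError(f"undefined state(s) for {char_id}: {sorted(unknown)}")
    if not states:
        desc.entries.pop(char_id, None)
    else:
        desc.entries[char_id] = states
    return desc


def record_quantitative(
    desc: SpecimenDescription,
    charset: CharacterSet,
    char_id: str,
    values=None,
    range_min: Optional[float] = None,
    range_max: Optional[float] = None,
    sample_size: int = 0,
) -> SpecimenDescription:
    """Score a quantitative character from exact values and/or a range."""
    char = charset[char_id]
    if char.kind != "quantitative":
        raise ValidationError(f"{char_id} is categorical, not quantitative")
    summary = QuantitativeSummary(
        exact_values=list(values or []),
        range_min=range_min,
        range_max=range_max,
        sample_size=sample_size,
    )
    desc.entries[char_id] = summary
    return desc


def link_description(store: Store, desc: SpecimenDescription, unit_id: str) -> None:
    """Bind a description to a unit of the store.

    Several descriptions (e.g. from different character sets or scoring
    campaigns) may be linked to the same unit; tree listings flag units
    that carry character data.
    """
    store.unit(unit_id)
    if desc.charset_id not in store.charsets:
        raise NotFoundError(desc.charset_id)
    charset = store.charsets[desc.charset_id]
    for char_id in desc.entries:
        if char_id not in charset:
            raise ValidationError(f"entry for unknown character {char_id}")
    desc.subject_unit_id = unit_id
    store.descriptions.append(desc)


@dataclass
class CompatibilityReport:
    identical: list[str] = field(default_factory=list)
    missing_in_one: list[str] = field(default_factory=list)
    conflicting: list[str] = field(default_factory=list)

    @property
    def compatible(self) -> bool:
        return not self.conflicting


def check_compatibility(a: CharacterSet, b: CharacterSet) -> CompatibilityReport:
    """Classify every character id as identical / missing-in-one / conflicting.

    Two sets are aggregation-compatible iff no character id is defined with
    a different kind, state vocabulary or measurement unit in the two sets;
    aggregations at higher ranks must not pool data scored on conflicting
    definitions.
    """
    report = CompatibilityReport()
    ids = list(dict.fromkeys(a.char_ids() + b.char_ids()))
    for cid in ids:
        if cid in a and cid in b:
            if a[cid].same_definition(b[cid]):
                report.identical.append(cid)
            else:
                report.conflicting.append(cid)
        else:
            report.missing_in_one.append(cid)
    return report


def union_charsets(set_id: str, a: CharacterSet, b: CharacterSet) -> CharacterSet:
    """Union of two compatible character sets (order: a's chars, then b's extras)."""
    report = check_compatibility(a, b)
    if not report.compatible:
        raise ValidationError(f"incompatible characters: {report.conflicting}")
    chars = list(a.characters) + [c for c in b.characters if c.char_id not in a]
    return CharacterSet(set_id, chars)


def _charset_usable(desc_charset: CharacterSet, target: CharacterSet) -> bool:
    return check_compatibility(desc_charset, target).compatible


def matrix_view(
    descriptions: list[SpecimenDescription],
    charset: CharacterSet,
    charsets: Optional[dict] = None,
) -> pd.DataFrame:
    """Rectangular matrix: rows = descriptions (labelled by subject unit),
    columns = characters in charset order, cells = entry or ``None``.

    Descriptions scored on a different character set are accepted when that
    set is compatible with ``charset``; ``charsets`` maps set ids to sets
    for the check.
    """
    for d in descriptions:
        if d.charset_id != charset.set_id:
            other = (charsets or {}).get(d.charset_id)
            if other is None or not _charset_usable(other, charset):
                raise ValidationError(
                    f"description of unit {d.subject_unit_id} uses incompatible "
                    f"character set {d.charset_id}"
                )
    cols = charset.char_ids()
    data = [[d.entries.get(c, MISSING) for c in cols] for d in descriptions]
    index = [d.subject_unit_id for d in descriptions]
    return pd.DataFrame(data, index=index, columns=cols, dtype=object)


def descriptions_from_matrix(matrix: pd.DataFrame, charset_id: str) -> list[SpecimenDescription]:
    """Inverse of :func:`matrix_view` on scored cells."""
    out = []
    for unit_id, row in zip(matrix.index, matrix.itertuples(index=False)):
        entries = {
            c: v for c, v in zip(matrix.columns, row) if v is not MISSING and v is not None
        }
        out.append(SpecimenDescription(subject_unit_id=unit_id, charset_id=charset_id, entries=entries))
    return out
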