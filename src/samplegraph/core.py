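"""Core domain types for specimen-based taxonomic data management.

The model follows collection-data practice: a *gathering* (one collector
team, one place, one time) is represented by a :class:`FieldUnit`, the
obligatory root of a *derivative hierarchy*.  Every physical or digital
sample obtained from it — specimen, tissue sample, DNA isolate, micrograph,
trace file, consensus sequence — is a :class:`DerivedUnit` produced by a
:class:`DerivationEvent`.  Determinations (taxon assignments) are stored on
the unit where they were made and *inherited* across the whole hierarchy as
a computed view, which keeps them reversible.

A :class:`Store` is the in-memory container tying everything together:
units, derivation events, determinations, character data, one
classification, occurrence records, the placement audit trail and versioned
provider records.  :func:`validate_store` checks every structural invariant
and returns a report rather than raising.
"""

from __future__ import annotations

import re
import uuid
from dataclasses import dataclass, field
from typing import Any, Iterator, Optional

__all__ = [
    "ValidationError",
    "NotFoundError",
    "PartialDate",
    "GatheringEvent",
    "FieldUnit",
    "DerivedUnit",
    "DerivationEvent",
    "CollectionUnit",
    "Determination",
    "TaxonNode",
    "Classification",
    "ValidationIssue",
    "ValidationReport",
    "Store",
    "validate_store",
    "DERIVATIVE_KINDS",
    "DERIVATION_EVENT_TYPES",
    "TYPE_STATUSES",
    "DEFAULT_RANKS",
]


class ValidationError(ValueError):
    """A domain invariant was violated on input."""


class NotFoundError(KeyError):
    """A referenced unit, taxon, area or record does not exist."""


DERIVATIVE_KINDS = frozenset(
    {"specimen", "tissue_sample", "dna_sample", "media", "sequence", "other"}
)
DERIVATION_EVENT_TYPES = frozenset(
    {
        "accessioning",
        "duplicate_split",
        "tissue_sampling",
        "dna_extraction",
        "sequencing",
        "imaging",
        "other",
    }
)
TYPE_STATUSES = frozenset({"none", "holotype", "isotype", "lectotype", "other-type"})

#: Default rank order, highest first.  A classification may use any subset.
DEFAULT_RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "subspecies",
)

# IUPAC nucleotide one-letter codes, plus gap.
_IUPAC_NT = frozenset("ACGTURYSWKMBDHVN-")

_DATE_RE = re.compile(r"^(\d{4})(?:-(\d{2}))?(?:-(\d{2}))?$")


@dataclass(frozen=True, order=False)
class PartialDate:
    """ISO-8601 date that may be year-only or year-month.

    Comparisons use the earliest possible interpretation (missing month and
    day count as January / the 1st), which is the conservative reading for
    historical specimens with incomplete labels.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.year <= 9999):
            raise ValidationError(f"year out of range: {self.year}")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValidationError(f"month out of range: {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValidationError("day given without month")
            if not (1 <= self.day <= 31):
                raise ValidationError(f"day out of range: {self.day}")

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        m = _DATE_RE.match(text.strip())
        if not m:
            raise ValidationError(f"unparseable date: {text!r}")
        y, mo, d = m.groups()
        return cls(int(y), int(mo) if mo else None, int(d) if d else None)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 1, self.day or 1)

    def isoformat(self) -> str:
        s = f"{self.year:04d}"
        if self.month is not None:
            s += f"-{self.month:02d}"
        if self.day is not None:
            s += f"-{self.day:02d}"
        return s

    def __lt__(self, other: "PartialDate") -> bool:
        return self.sort_key() < other.sort_key()

    def __le__(self, other: "PartialDate") -> bool:
        return self.sort_key() <= other.sort_key()


@dataclass
class GatheringEvent:
    """One collecting event: collectors, field number, place and time."""

    collectors: list[str] = field(default_factory=list)
    field_number: str = ""
    date: Optional[PartialDate] = None
    country: str = ""
    locality_text: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    coordinate_uncertainty: Optional[float] = None
    elevation: Optional[float] = None
    habitat_notes: str = ""
    field_observations: str = ""

    def validate(self) -> None:
        if (self.latitude is None) != (self.longitude is None):
            raise ValidationError("latitude and longitude must both be present or both absent")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude out of range: {self.longitude}")
        if self.coordinate_uncertainty is not None and self.coordinate_uncertainty < 0:
            raise ValidationError("coordinate_uncertainty must be >= 0")

    @property
    def georeferenced(self) -> bool:
        return self.latitude is not None and self.longitude is not None

    def copy(self) -> "GatheringEvent":
        return GatheringEvent(
            collectors=list(self.collectors),
            field_number=self.field_number,
            date=self.date,
            country=self.country,
            locality_text=self.locality_text,
            latitude=self.latitude,
            longitude=self.longitude,
            coordinate_uncertainty=self.coordinate_uncertainty,
            elevation=self.elevation,
            habitat_notes=self.habitat_notes,
            field_observations=self.field_observations,
        )


@dataclass
class CollectionUnit:
    """Accession metadata once a derivative enters a research collection."""

    collection_code: str
    accession_number: str
    stable_uri: Optional[str] = None


@dataclass
class FieldUnit:
    """Root of a derivative hierarchy; one gathering, one (possibly unknown) taxon."""

    unit_id: str
    gathering: GatheringEvent
    publish: bool = False
    notes: str = ""

    parent_id: None = field(default=None, init=False, repr=False)


@dataclass
class DerivedUnit:
    """Any sample or digital object derived from a field unit or another derivative."""

    unit_id: str
    kind: str
    parent_id: str
    collection_unit: Optional[CollectionUnit] = None
    external_link: Optional[str] = None
    payload: dict[str, Any] = field(default_factory=dict)
    publish: bool = False

    def validate(self) -> None:
        if self.kind not in DERIVATIVE_KINDS:
            raise ValidationError(f"unknown derivative kind: {self.kind!r}")
        if self.kind == "sequence":
            seq = self.payload.get("sequence")
            if seq is not None and not set(seq.upper()) <= _IUPAC_NT:
                bad = sorted(set(seq.upper()) - _IUPAC_NT)
                raise ValidationError(f"non-IUPAC symbols in sequence payload: {bad}")


Unit = FieldUnit | DerivedUnit


@dataclass
class DerivationEvent:
    """The documented act producing derivatives from a parent unit."""

    event_id: str
    event_type: str
    input_id: str
    output_ids: list[str] = field(default_factory=list)
    actor: str = ""
    date: Optional[PartialDate] = None
    method_notes: str = ""


@dataclass
class Determination:
    """Taxon assignment of a unit, with determiner and history flags.

    ``seq`` is a store-wide insertion counter used to break ties between
    determinations with equal or absent dates (latest entry wins).
    """

    taxon_id: str
    determiner: str = ""
    date: Optional[PartialDate] = None
    is_current: bool = True
    type_status: str = "none"
    note: str = ""
    seq: int = 0

    def sort_key(self) -> tuple[tuple[int, int, int], int]:
        d = self.date.sort_key() if self.date is not None else (0, 0, 0)
        return (d, self.seq)


@dataclass
class TaxonNode:
    taxon_id: str
    accepted_name: str
    rank: str
    parent_taxon_id: Optional[str] = None
    synonyms: list[str] = field(default_factory=list)


class Classification:
    """A single rooted taxonomy tree with ordered ranks."""

    def __init__(self, ranks: tuple[str, ...] = DEFAULT_RANKS) -> None:
        self.ranks = tuple(ranks)
        self.nodes: dict[str, TaxonNode] = {}

    def rank_index(self, rank: str) -> int:
        try:
            return self.ranks.index(rank)
        except ValueError:
            raise ValidationError(f"unknown rank: {rank!r}") from None

    def add(self, node: TaxonNode) -> TaxonNode:
        if node.taxon_id in self.nodes:
            raise ValidationError(f"duplicate taxon id: {node.taxon_id}")
        if node.parent_taxon_id is not None:
            parent = self.nodes.get(node.parent_taxon_id)
            if parent is None:
                raise NotFoundError(node.parent_taxon_id)
            if self.rank_index(node.rank) <= self.rank_index(parent.rank):
                raise ValidationError(
                    f"rank of {node.accepted_name!r} ({node.rank}) not below parent rank ({parent.rank})"
                )
        elif any(n.parent_taxon_id is None for n in self.nodes.values()):
            raise ValidationError("classification already has a root")
        self.nodes[node.taxon_id] = node
        return node

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __getitem__(self, taxon_id: str) -> TaxonNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise NotFoundError(taxon_id) from None

    @property
    def root(self) -> TaxonNode:
        for n in self.nodes.values():
            if n.parent_taxon_id is None:
                return n
        raise NotFoundError("classification has no root")

    def children(self, taxon_id: str) -> list[TaxonNode]:
        return [n for n in self.nodes.values() if n.parent_taxon_id == taxon_id]

    def subtree_ids(self, taxon_id: str) -> set[str]:
        """``taxon_id`` plus all its descendants."""
        if taxon_id not in self.nodes:
            raise NotFoundError(taxon_id)
        out: set[str] = set()
        stack = [taxon_id]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(c.taxon_id for c in self.children(t))
        return out

    def is_descendant(self, taxon_id: str, ancestor_id: str) -> bool:
        t: Optional[str] = taxon_id
        seen: set[str] = set()
        while t is not None and t not in seen:
            seen.add(t)
            if t == ancestor_id:
                return taxon_id != ancestor_id or len(seen) > 1
            t = self.nodes[t].parent_taxon_id if t in self.nodes else None
        return False

    def copy(self) -> "Classification":
        out = Classification(self.ranks)
        for n in self.nodes.values():
            out.nodes[n.taxon_id] = TaxonNode(
                n.taxon_id, n.accepted_name, n.rank, n.parent_taxon_id, list(n.synonyms)
            )
        return out


@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    subject_id: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, kind: str, subject_id: str, message: str) -> None:
        self.issues.append(ValidationIssue(kind, subject_id, message))

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:  # truthy iff clean, mirroring "empty report = consistent"
        return self.ok

    def __iter__(self) -> Iterator[ValidationIssue]:
        return iter(self.issues)

    def kinds(self) -> list[str]:
        return [i.kind for i in self.issues]


class Store:
    """In-memory container for one working dataset.

    Identifiers are UUIDv4 strings minted at creation time; an
    ``id_factory`` can be supplied to make identifier generation
    deterministic (the fixtures module does this).  Identifiers are never
    reused: deletion removes the object but the factory never repeats.
    """

    def __init__(self, id_factory=None) -> None:
        self._id_factory = id_factory or (lambda: str(uuid.uuid4()))
        self.units: dict[str, Unit] = {}
        self.derivation_events: dict[str, DerivationEvent] = {}
        #: unit_id -> ordered list of Determinations (history)
        self.determinations: dict[str, list[Determination]] = {}
        self.classification: Optional[Classification] = None
        # populated by the character_data / aggregation / classification /
        # versioning modules; declared here so one container carries the store
        self.charsets: dict[str, Any] = {}
        self.descriptions: list[Any] = []
        self.taxon_descriptions: list[Any] = []
        self.occurrence_records: list[Any] = []
        self.area_tree: Optional[Any] = None
        self.status_priority: Optional[Any] = None
        self.audit: list[Any] = []
        self.versioned_records: dict[tuple[str, str], Any] = {}
        self._det_seq = 0

    # -- identifiers ---------------------------------------------------
    def new_id(self) -> str:
        while True:
            i = self._id_factory()
            if i not in self.units and i not in self.derivation_events:
                return i

    def next_det_seq(self) -> int:
        self._det_seq += 1
        return self._det_seq

    # -- lookups -------------------------------------------------------
    def unit(self, unit_id: str) -> Unit:
        try:
            return self.units[unit_id]
        except KeyError:
            raise NotFoundError(unit_id) from None

    def children_map(self) -> dict[Optional[str], list[str]]:
        """parent_id -> child unit ids, in insertion order."""
        out: dict[Optional[str], list[str]] = {}
        for u in self.units.values():
            out.setdefault(u.parent_id, []).append(u.unit_id)
        return out

    def field_units(self) -> list[FieldUnit]:
        return [u for u in self.units.values() if isinstance(u, FieldUnit)]

    def determinations_of(self, unit_id: str) -> list[Determination]:
        return self.determinations.get(unit_id, [])


def _find_cycles(store: Store) -> list[list[str]]:
    """Distinct parent-link cycles, each as the list of unit ids on it."""
    cycles: list[list[str]] = []
    state: dict[str, int] = {}  # 0 = on current path, 1 = finished
    for start in store.units:
        path: list[str] = []
        u: Optional[str] = start
        while u is not None and u in store.units and u not in state:
            state[u] = 0
            path.append(u)
            u = store.units[u].parent_id
        if u is not None and u in state and state[u] == 0 and u in path:
            cycles.append(path[path.index(u):])
        for p in path:
            state[p] = 1
    return cycles


def validate_store(store: Store) -> ValidationReport:
    """Check every structural invariant; returns a report, never raises.

    An empty report means the store is consistent.  Detected issue kinds:
    ``dangling-parent``, ``cycle``, ``duplicate-accession``,
    ``multiple-current-determinations``, ``unknown-taxon``,
    ``invalid-gathering``, ``invalid-derivative``, ``dangling-event-unit``.
    """
    report = ValidationReport()
    on_cycle: set[str] = set()
    for cyc in _find_cycles(store):
        on_cycle.update(cyc)
        report.add("cycle", min(cyc), "parent links form a cycle: " + " -> ".join(cyc))
    seen_accessions: dict[tuple[str, str], str] = {}
    for u in store.units.values():
        if isinstance(u, DerivedUnit):
            if u.parent_id not in store.units:
                report.add("dangling-parent", u.unit_id, f"parent {u.parent_id} does not exist")
            try:
                u.validate()
            except ValidationError as e:
                report.add("invalid-derivative", u.unit_id, str(e))
            if u.collection_unit is not None:
                key = (u.collection_unit.collection_code, u.collection_unit.accession_number)
                if key in seen_accessions:
                    report.add(
                        "duplicate-accession",
                        u.unit_id,
                        f"accession {key} already used by unit {seen_accessions[key]}",
                    )
                else:
                    seen_accessions[key] = u.unit_id
        else:
            try:
                u.gathering.validate()
            except ValidationError as e:
                report.add("invalid-gathering", u.unit_id, str(e))
    for uid, dets in store.determinations.items():
        if uid not in store.units:
            report.add("dangling-parent", uid, "determination on unknown unit")
        if sum(1 for d in dets if d.is_current) > 1:
            report.add(
                "multiple-current-determinations", uid, "more than one current determination"
            )
        for d in dets:
            if store.classification is not None and d.taxon_id not in store.classification:
                report.add("unknown-taxon", uid, f"determination references {d.taxon_id}")
    for ev in store.derivation_events.values():
        for out_id in [ev.input_id, *ev.output_ids]:
            if out_id not in store.units:
                report.add("dangling-event-unit", ev.event_id, f"event references {out_id}")
    return report
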