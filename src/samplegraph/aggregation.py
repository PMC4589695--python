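"""Aggregation of specimen-based data into taxon characterizations.

Two aggregation modes exist, matching how taxonomists summarise data:

* **appending** aggregation for categorical data — state sets of the
  contributing specimens are unioned, each state keeping the count of
  specimens exhibiting it, and the specimen data themselves are left
  unchanged;
* **merging** aggregation for quantitative data — measurements are pooled
  into min / max / mean / n statistics (label-derived ranges contribute to
  min and max only, so unverifiable label statistics never distort the
  mean).

Aggregating a higher taxon is the same computation run over the pooled
specimen data of its whole subtree, so aggregation is additive: the
characterization of a genus equals the direct aggregation of all its
species' specimens.  Re-running an aggregation *replaces* the previous
aggregated description for that (taxon, character set), which is what makes
taxon characterizations reproducible under changing sample sets and taxon
delimitations.  Manually entered taxon descriptions are never overwritten.

The same recursive logic drives the occurrence-status *transmission
engine*: the status of a taxon in an area is the highest-priority status
among all records of the taxon or its subtaxa in the area or its subareas.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable, Optional, Sequence

from .characters import (
    AggregatedQuantitative,
    CharacterSet,
    QuantitativeSummary,
    SpecimenDescription,
    TaxonDescription,
    check_compatibility,
)
from .core import Classification, NotFoundError, Store, ValidationError
from .hierarchy import effective_determination

__all__ = [
    "OccurrenceRecord",
    "AreaTree",
    "StatusPriority",
    "DEFAULT_STATUS_PRIORITY",
    "aggregate_categorical",
    "aggregate_quantitative",
    "aggregate_taxon",
    "aggregate_distribution",
    "collect_occurrence_points",
    "render_description",
]


# ---------------------------------------------------------------------------
# occurrence data types

@dataclass
class OccurrenceRecord:
    """One taxon-in-area statement with an occurrence status and its source
    (a unit id or a literature citation string)."""

    taxon_id: str
    area_id: str
    status: str
    source: str = ""


class AreaTree:
    """A rooted hierarchy of named geographic areas."""

    def __init__(self) -> None:
        self.areas: dict[str, tuple[str, Optional[str]]] = {}  # id -> (name, parent)

    def add(self, area_id: str, name: str, parent_id: Optional[str] = None) -> None:
        if area_id in self.areas:
            raise ValidationError(f"duplicate area id: {area_id}")
        if parent_id is not None and parent_id not in self.areas:
            raise NotFoundError(parent_id)
        if parent_id is None and any(p is None for _, p in self.areas.values()):
            raise ValidationError("area tree already has a root")
        self.areas[area_id] = (name, parent_id)

    def __contains__(self, area_id: str) -> bool:
        return area_id in self.areas

    def subtree_ids(self, area_id: str) -> set[str]:
        if area_id not in self.areas:
            raise NotFoundError(area_id)
        children: dict[Optional[str], list[str]] = {}
        for aid, (_, parent) in self.areas.items():
            children.setdefault(parent, []).append(aid)
        out: set[str] = set()
        stack = [area_id]
        while stack:
            a = stack.pop()
            out.add(a)
            stack.extend(children.get(a, []))
        return out


class StatusPriority:
    """Strictly ordered occurrence-status vocabulary, highest priority first."""

    def __init__(self, statuses: Sequence[str]) -> None:
        statuses = list(statuses)
        if len(set(statuses)) != len(statuses):
            raise ValidationError("status labels must be unique")
        self.statuses = statuses
        self._index = {s: i for i, s in enumerate(statuses)}

    def index(self, status: str) -> int:
        try:
            return self._index[status]
        except KeyError:
            raise ValidationError(f"status {status!r} not covered by the priority list") from None

    def __contains__(self, status: str) -> bool:
        return status in self._index


DEFAULT_STATUS_PRIORITY = StatusPriority(
    ["native", "naturalized", "introduced", "cultivated", "present-doubtful", "absent"]
)


# ---------------------------------------------------------------------------
# character aggregation primitives

def aggregate_categorical(
    entries: Iterable[tuple[str, frozenset]],
    vocabulary: Optional[Sequence[str]] = None,
) -> dict[str, int]:
    """Appending aggregation: union of state sets with per-state support.

    ``entries`` are (source unit id, state set) pairs; the support count of
    a state is the number of distinct source units exhibiting it.  Inputs
    are left unchanged.
    """
    by_state: dict[str, set[str]] = {}
    for unit_id, states in entries:
        for s in states:
            if vocabulary is not None and s not in vocabulary:
                raise ValidationError(f"state {s!r} not in character vocabulary")
            by_state.setdefault(s, set()).add(unit_id)
    if vocabulary is not None:
        return {s: len(by_state[s]) for s in vocabulary if s in by_state}
    return {s: len(units) for s, units in sorted(by_state.items())}


def aggregate_quantitative(
    entries: Iterable[tuple[str, QuantitativeSummary]],
) -> Optional[AggregatedQuantitative]:
    """Merging aggregation: pool measurements into min/max/mean/n statistics.

    Exact values and label ranges both bound min and max; the mean is the
    unweighted arithmetic mean of the pooled exact values and is absent
    when no exact values exist.  ``None`` on empty input (character not
    aggregated).
    """
    entries = list(entries)
    if not entries:
        return None
    los: list[float] = []
    his: list[float] = []
    pooled: list[float] = []
    units: set[str] = set()
    for unit_id, summary in entries:
        units.add(unit_id)
        lo, hi = summary.bounds()
        if lo is not None:
            los.append(lo)
        if hi is not None:
            his.append(hi)
        pooled.extend(summary.exact_values)
    return AggregatedQuantitative(
        min=min(los) if los else None,
        max=max(his) if his else None,
        mean=(sum(pooled) / len(pooled)) if pooled else None,
        n_values=len(pooled),
        n_specimens=len(units),
    )


# ---------------------------------------------------------------------------
# taxon-level aggregation

def _contributing_descriptions(
    store: Store, taxon_id: str, charset: CharacterSet
) -> list[SpecimenDescription]:
    """Specimen descriptions whose unit's effective determination lies in the
    subtree of ``taxon_id`` and whose character set is usable with ``charset``.

    Raises naming the offenders when a contributing description was scored
    on a character set that conflicts with the aggregation set.
    """
    classification = store.classification
    if classification is None or taxon_id not in classification:
        raise NotFoundError(taxon_id)
    subtree = classification.subtree_ids(taxon_id)
    cmap = store.children_map()
    selected: list[SpecimenDescription] = []
    offenders: list[str] = []
    for desc in store.descriptions:
        det = effective_determination(store, desc.subject_unit_id, cmap)
        if det is None or det.taxon_id not in subtree:
            continue
        if desc.charset_id != charset.set_id:
            other = store.charsets.get(desc.charset_id)
            if other is None or not check_compatibility(other, charset).compatible:
                offenders.append(desc.subject_unit_id)
                continue
        selected.append(desc)
    if offenders:
        raise ValidationError(
            "incompatible character sets on descriptions of units: " + ", ".join(sorted(offenders))
        )
    return selected


def aggregate_taxon(
    store: Store, taxon_id: str, charset: CharacterSet
) -> TaxonDescription:
    """Aggregate all specimen-based character data of a taxon (including its
    subtaxa) into a taxon description, replacing any previous aggregated
    description for this (taxon, character set).

    Higher taxa are recomputed from specimen level rather than from child
    taxon descriptions; under additivity the result is identical, but the
    recomputation can never see a stale child cache.
    """
    descs = _contributing_descriptions(store, taxon_id, charset)
    entries: dict = {}
    provenance: dict[str, list[str]] = {}
    for char in charset:
        pairs = [
            (d.subject_unit_id, d.entries[char.char_id])
            for d in descs
            if char.char_id in d.entries
        ]
        if not pairs:
            continue
        if char.kind == "categorical":
            entries[char.char_id] = aggregate_categorical(pairs, vocabulary=char.states)
        else:
            agg = aggregate_quantitative(pairs)
            if agg is not None:
                entries[char.char_id] = agg
        provenance[char.char_id] = sorted({u for u, _ in pairs})
    td = TaxonDescription(
        taxon_id=taxon_id,
        charset_id=charset.set_id,
        entries=entries,
        provenance=provenance,
        generated_at=datetime.now(timezone.utc).isoformat(),
        is_aggregated=True,
    )
    store.taxon_descriptions = [
        t
        for t in store.taxon_descriptions
        if not (t.is_aggregated and t.taxon_id == taxon_id and t.charset_id == charset.set_id)
    ]
    store.taxon_descriptions.append(td)
    return td


# ---------------------------------------------------------------------------
# occurrence aggregation ("transmission engine")

def aggregate_distribution(
    taxon_id: str,
    target_area_id: str,
    records: Iterable[OccurrenceRecord],
    classification: Classification,
    area_tree: AreaTree,
    priority: StatusPriority = DEFAULT_STATUS_PRIORITY,
) -> Optional[str]:
    """Occurrence status of a taxon in an area, aggregated recursively over
    subtaxa and subareas; conflicts resolve to the highest-priority status.

    Returns ``None`` when no record matches.  Order-independent by
    construction (a pure maximum over the candidate set).
    """
    taxa = classification.subtree_ids(taxon_id)
    areas = area_tree.subtree_ids(target_area_id)
    best: Optional[str] = None
    for rec in records:
        idx = priority.index(rec.status)  # validates even non-matching records' vocab
        if rec.taxon_id in taxa and rec.area_id in areas:
            if best is None or idx < priority.index(best):
                best = rec.status
    return best


def collect_occurrence_points(
    store: Store, taxon_id: str
) -> list[tuple[float, float, str]]:
    """(latitude, longitude, field_unit_id) for every georeferenced field
    unit assigned to the taxon or a descendant; ordered by unit id.

    This is the primary aggregation of coordinates behind dot distribution
    maps.
    """
    classification = store.classification
    if classification is None or taxon_id not in classification:
        raise NotFoundError(taxon_id)
    subtree = classification.subtree_ids(taxon_id)
    cmap = store.children_map()
    points = []
    for fu in store.field_units():
        if not fu.gathering.georeferenced:
            continue
        det = effective_determination(store, fu.unit_id, cmap)
        if det is not None and det.taxon_id in subtree:
            points.append((fu.gathering.latitude, fu.gathering.longitude, fu.unit_id))
    points.sort(key=lambda p: p[2])
    return points


# ---------------------------------------------------------------------------
# natural-language rendering

def _fmt(value: float) -> str:
    if float(value).is_integer():
        return f"{value:.1f}"
    return f"{value:g}"


def render_description(
    description: TaxonDescription, charset: CharacterSet
) -> str:
    """Deterministic natural-language rendering of a taxon description.

    Characters appear in character-set order; categorical states are joined
    by descending support (ties keep vocabulary order); quantitative
    entries render as ``min–max unit (mean m, n = k)``.  Unscored
    characters are omitted.  A description template of the same shape could
    replace this default rendering downstream.
    """
    if description.charset_id != charset.set_id:
        raise ValidationError("description does not use the given character set")
    sentences: list[str] = []
    for char in charset:
        entry = description.entries.get(char.char_id)
        if entry is None:
            continue
        name = char.name[:1].upper() + char.name[1:]
        if char.kind == "categorical":
            order = {s: i for i, s in enumerate(char.states)}
            states = sorted(entry, key=lambda s: (-entry[s], order.get(s, len(order))))
            sentences.append(f"{name} {', '.join(states)}.")
        else:
            parts = []
            if entry.min is not None and entry.max is not None:
                parts.append(f"{_fmt(entry.min)}–{_fmt(entry.max)} {char.unit_label}")
            inner = []
            if entry.mean is not None:
                inner.append(f"mean {entry.mean:.2f}")
            if entry.n_values:
                inner.append(f"n = {entry.n_values}")
            if inner:
                parts.append("(" + ", ".join(inner) + ")")
            if parts:
                sentences.append(f"{name} {' '.join(parts)}.")
    return " ".join(sentences)
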