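"""Lossless JSON serialization of a whole store.

This is the persistence format of the ``sg`` command line tool and the
canonical byte representation used to check generator determinism: the
serialization is a pure function of store content and insertion order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Union

from ..aggregation import AreaTree, OccurrenceRecord, StatusPriority
from ..characters import (
    AggregatedQuantitative,
    CharacterSet,
    QuantitativeSummary,
    SpecimenDescription,
    TaxonDescription,
)
from ..classification import AuditEntry
from ..core import (
    Classification,
    CollectionUnit,
    Determination,
    DerivationEvent,
    DerivedUnit,
    FieldUnit,
    GatheringEvent,
    PartialDate,
    Store,
    TaxonNode,
)
from ..versioning import MISSING, CoreCopy, EditEntry, Version, VersionedRecord

__all__ = ["store_to_json", "store_from_json", "save_store", "load_store"]

_MISSING_MARK = {"$missing": True}


def _date(d: Optional[PartialDate]):
    return None if d is None else d.isoformat()


def _parse_date(s) -> Optional[PartialDate]:
    return None if s in (None, "") else PartialDate.parse(s)


def _value(v: Any) -> Any:
    return _MISSING_MARK if v is MISSING else v


def _unvalue(v: Any) -> Any:
    if isinstance(v, dict) and v.get("$missing"):
        return MISSING
    return v


def _gathering_dict(g: GatheringEvent) -> dict:
    return {
        "collectors": g.collectors,
        "field_number": g.field_number,
        "date": _date(g.date),
        "country": g.country,
        "locality_text": g.locality_text,
        "latitude": g.latitude,
        "longitude": g.longitude,
        "coordinate_uncertainty": g.coordinate_uncertainty,
        "elevation": g.elevation,
        "habitat_notes": g.habitat_notes,
        "field_observations": g.field_observations,
    }


def _gathering_from(d: dict) -> GatheringEvent:
    d = dict(d)
    d["date"] = _parse_date(d.get("date"))
    return GatheringEvent(**d)


def _entry_dict(entry) -> Any:
    if isinstance(entry, QuantitativeSummary):
        return {
            "exact_values": entry.exact_values,
            "range_min": entry.range_min,
            "range_max": entry.range_max,
            "sample_size": entry.sample_size,
        }
    return {"states": sorted(entry)}


def _entry_from(d: Any):
    if "states" in d:
        return frozenset(d["states"])
    return QuantitativeSummary(
        exact_values=d["exact_values"],
        range_min=d["range_min"],
        range_max=d["range_max"],
        sample_size=d["sample_size"],
    )


def store_to_json(store: Store) -> str:
    units = []
    for u in store.units.values():
        if isinstance(u, FieldUnit):
            units.append(
                {
                    "type": "field_unit",
                    "unit_id": u.unit_id,
                    "gathering": _gathering_dict(u.gathering),
                    "publish": u.publish,
                    "notes": u.notes,
                }
            )
        else:
            units.append(
                {
                    "type": "derived_unit",
                    "unit_id": u.unit_id,
                    "kind": u.kind,
                    "parent_id": u.parent_id,
                    "collection_unit": (
                        {
                            "collection_code": u.collection_unit.collection_code,
                            "accession_number": u.collection_unit.accession_number,
                            "stable_uri": u.collection_unit.stable_uri,
                        }
                        if u.collection_unit
                        else None
                    ),
                    "external_link": u.external_link,
                    "payload": u.payload,
                    "publish": u.publish,
                }
            )
    doc: dict[str, Any] = {
        "units": units,
        "derivation_events": [
            {
                "event_id": e.event_id,
                "event_type": e.event_type,
                "input_id": e.input_id,
                "output_ids": e.output_ids,
                "actor": e.actor,
                "date": _date(e.date),
                "method_notes": e.method_notes,
            }
            for e in store.derivation_events.values()
        ],
        "determinations": {
            uid: [
                {
                    "taxon_id": d.taxon_id,
                    "determiner": d.determiner,
                    "date": _date(d.date),
                    "is_current": d.is_current,
                    "type_status": d.type_status,
                    "note": d.note,
                    "seq": d.seq,
                }
                for d in dets
            ]
            for uid, dets in store.determinations.items()
        },
        "det_seq": store._det_seq,
        "classification": (
            {
                "ranks": list(store.classification.ranks),
                "nodes": [
                    {
                        "taxon_id": n.taxon_id,
                        "accepted_name": n.accepted_name,
                        "rank": n.rank,
                        "parent_taxon_id": n.parent_taxon_id,
                        "synonyms": n.synonyms,
                    }
                    for n in store.classification.nodes.values()
                ],
            }
            if store.classification
            else None
        ),
        "charsets": {
            cs.set_id: [
                {
                    "char_id": c.char_id,
                    "name": c.name,
                    "kind": c.kind,
                    "states": list(c.states),
                    "unit_label": c.unit_label,
                }
                for c in cs
            ]
            for cs in store.charsets.values()
        },
        "descriptions": [
            {
                "subject_unit_id": d.subject_unit_id,
                "charset_id": d.charset_id,
                "entries": {cid: _entry_dict(e) for cid, e in d.entries.items()},
            }
            for d in store.descriptions
        ],
        "taxon_descriptions": [
            {
                "taxon_id": t.taxon_id,
                "charset_id": t.charset_id,
                "entries": {
                    cid: (
                        {"aggregated_quantitative": vars(e)}
                        if isinstance(e, AggregatedQuantitative)
                        else {"support": e}
                    )
                    for cid, e in t.entries.items()
                },
                "provenance": t.provenance,
                "generated_at": t.generated_at,
                "is_aggregated": t.is_aggregated,
            }
            for t in store.taxon_descriptions
        ],
        "occurrence_records": [
            {"taxon_id": r.taxon_id, "area_id": r.area_id, "status": r.status, "source": r.source}
            for r in store.occurrence_records
        ],
        "area_tree": (
            [
                {"area_id": aid, "name": name, "parent_area_id": parent}
                for aid, (name, parent) in store.area_tree.areas.items()
            ]
            if store.area_tree
            else None
        ),
        "status_priority": store.status_priority.statuses if store.status_priority else None,
        "audit": [vars(a) for a in store.audit],
        "versioned_records": [
            {
                "provider_name": r.provider_name,
                "provider_record_id": r.provider_record_id,
                "bases": [
                    {"snapshot": b.snapshot, "retrieved_at": b.retrieved_at} for b in r.bases
                ],
                "edit_logs": [
                    [
                        {
                            "field_path": e.field_path,
                            "old_value": _value(e.old_value),
                            "new_value": _value(e.new_value),
                            "category": e.category,
                            "author": e.author,
                            "timestamp": e.timestamp,
                        }
                        for e in log
                    ]
                    for log in r.edit_logs
                ],
                "versions": [vars(v) for v in r.versions],
            }
            for r in store.versioned_records.values()
        ],
    }
    return json.dumps(doc, indent=1)


def store_from_json(text: str) -> Store:
    doc = json.loads(text)
    store = Store()
    for u in doc["units"]:
        if u["type"] == "field_unit":
            store.units[u["unit_id"]] = FieldUnit(
                unit_id=u["unit_id"],
                gathering=_gathering_from(u["gathering"]),
                publish=u["publish"],
                notes=u["notes"],
            )
        else:
            cu = u["collection_unit"]
            store.units[u["unit_id"]] = DerivedUnit(
                unit_id=u["unit_id"],
                kind=u["kind"],
                parent_id=u["parent_id"],
                collection_unit=CollectionUnit(**cu) if cu else None,
                external_link=u["external_link"],
                payload=u["payload"],
                publish=u["publish"],
            )
    for e in doc["derivation_events"]:
        store.derivation_events[e["event_id"]] = DerivationEvent(
            event_id=e["event_id"],
            event_type=e["event_type"],
            input_id=e["input_id"],
            output_ids=e["output_ids"],
            actor=e["actor"],
            date=_parse_date(e["date"]),
            method_notes=e["method_notes"],
        )
    for uid, dets in doc["determinations"].items():
        store.determinations[uid] = [
            Determination(
                taxon_id=d["taxon_id"],
                determiner=d["determiner"],
                date=_parse_date(d["date"]),
                is_current=d["is_current"],
                type_status=d["type_status"],
                note=d["note"],
                seq=d["seq"],
            )
            for d in dets
        ]
    store._det_seq = doc.get("det_seq", 0)
    if doc["classification"]:
        cls = Classification(tuple(doc["classification"]["ranks"]))
        for n in doc["classification"]["nodes"]:
            cls.nodes[n["taxon_id"]] = TaxonNode(
                taxon_id=n["taxon_id"],
                accepted_name=n["accepted_name"],
                rank=n["rank"],
                parent_taxon_id=n["parent_taxon_id"],
                synonyms=n["synonyms"],
            )
        store.classification = cls
    from ..characters import CharacterDef  # local import to avoid cycle at module load

    for set_id, chars in doc["charsets"].items():
        store.charsets[set_id] = CharacterSet(
            set_id,
            [
                CharacterDef(
                    char_id=c["char_id"],
                    name=c["name"],
                    kind=c["kind"],
                    states=c["states"],
                    unit_label=c["unit_label"],
                )
                for c in chars
            ],
        )
    for d in doc["descriptions"]:
        store.descriptions.append(
            SpecimenDescription(
                subject_unit_id=d["subject_unit_id"],
                charset_id=d["charset_id"],
                entries={cid: _entry_from(e) for cid, e in d["entries"].items()},
            )
        )
    for t in doc["taxon_descriptions"]:
        entries: dict[str, Any] = {}
        for cid, e in t["entries"].items():
            if "aggregated_quantitative" in e:
                entries[cid] = AggregatedQuantitative(**e["aggregated_quantitative"])
            else:
                entries[cid] = e["support"]
        store.taxon_descriptions.append(
            TaxonDescription(
                taxon_id=t["taxon_id"],
                charset_id=t["charset_id"],
                entries=entries,
                provenance=t["provenance"],
                generated_at=t["generated_at"],
                is_aggregated=t["is_aggregated"],
            )
        )
    for r in doc["occurrence_records"]:
        store.occurrence_records.append(OccurrenceRecord(**r))
    if doc["area_tree"]:
        tree = AreaTree()
        for a in doc["area_tree"]:
            tree.areas[a["area_id"]] = (a["name"], a["parent_area_id"])
        store.area_tree = tree
    if doc["status_priority"]:
        store.status_priority = StatusPriority(doc["status_priority"])
    for a in doc["audit"]:
        store.audit.append(AuditEntry(**a))
    for r in doc["versioned_records"]:
        bases = [
            CoreCopy(r["provider_name"], r["provider_record_id"], b["snapshot"], b["retrieved_at"])
            for b in r["bases"]
        ]
        record = VersionedRecord(bases[0])
        record.bases = bases
        record.edit_logs = [
            [
                EditEntry(
                    field_path=e["field_path"],
                    old_value=_unvalue(e["old_value"]),
                    new_value=_unvalue(e["new_value"]),
                    category=e["category"],
                    author=e["author"],
                    timestamp=e["timestamp"],
                )
                for e in log
            ]
            for log in r["edit_logs"]
        ]
        record.versions = [Version(**v) for v in r["versions"]]
        store.versioned_records[(r["provider_name"], r["provider_record_id"])] = record
    return store


def save_store(store: Store, path: Union[str, Path]) -> None:
    Path(path).write_text(store_to_json(store), encoding="utf-8")


def load_store(path: Union[str, Path]) -> Store:
    return store_from_json(Path(path).read_text(encoding="utf-8"))
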