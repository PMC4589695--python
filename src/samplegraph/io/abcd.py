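"""ABCD 2.x-style XML exchange of entire derivative hierarchies.

This is a documented *subset* dialect of Access to Biological Collection
Data, not full schema coverage: one ``Unit`` element per field unit, the
gathering data and determination history inline, every derivative of the
hierarchy as a ``Derivative`` element referencing its parent by id (so
chains of any depth survive), and specimen-based character data in the
standard ``MeasurementsOrFacts`` container — the established workaround
for carrying atomized character data, whole matrices or links to them
inside collection-data exchange.  For units backed by a versioned provider
record, an ``EditTrail`` block distinguishes original from edited values.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Union

from lxml import etree

from ..characters import CharacterSet, QuantitativeSummary, SpecimenDescription
from ..core import (
    CollectionUnit,
    Determination,
    DerivedUnit,
    FieldUnit,
    GatheringEvent,
    PartialDate,
    Store,
    ValidationError,
)
from ..versioning import export_annotated

NS = "urn:samplegraph:abcd-subset:1.0"
_E = "{%s}" % NS
NSMAP = {"sg": NS}

__all__ = ["NS", "read_abcd_xml", "write_abcd_xml"]

_RANGE_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*[–-]\s*(-?\d+(?:\.\d+)?)(?:\s+(\S.*))?$")
_VALUE_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)(?:\s+(\S.*))?$")
_N_RE = re.compile(r"^\s*n\s*=\s*(\d+)\s*$")


def _el(node, tag: str, text: Optional[str] = None, **attrs) -> etree._Element:
    e = etree.SubElement(node, _E + tag, {k: v for k, v in attrs.items() if v is not None})
    if text is not None:
        e.text = text
    return e


def _fnum(v: Optional[float]) -> Optional[str]:
    return None if v is None else repr(float(v))


def _write_gathering(parent, g: GatheringEvent) -> None:
    gat = _el(parent, "Gathering")
    if g.collectors:
        _el(gat, "Agents", "|".join(g.collectors))
    if g.field_number:
        _el(gat, "FieldNumber", g.field_number)
    if g.date is not None:
        _el(gat, "DateTime", g.date.isoformat())
    if g.country:
        _el(gat, "Country", g.country)
    if g.locality_text:
        _el(gat, "LocalityText", g.locality_text)
    if g.georeferenced:
        _el(
            gat,
            "Coordinates",
            latitude=_fnum(g.latitude),
            longitude=_fnum(g.longitude),
            uncertainty=_fnum(g.coordinate_uncertainty),
        )
    if g.elevation is not None:
        _el(gat, "Elevation", repr(float(g.elevation)))
    if g.habitat_notes:
        _el(gat, "HabitatNotes", g.habitat_notes)
    if g.field_observations:
        _el(gat, "FieldObservations", g.field_observations)


def _read_gathering(gat) -> GatheringEvent:
    def text(tag: str) -> str:
        e = gat.find(_E + tag)
        return e.text or "" if e is not None else ""

    coords = gat.find(_E + "Coordinates")
    date_s = text("DateTime")
    elev = text("Elevation")
    return GatheringEvent(
        collectors=[c for c in text("Agents").split("|") if c],
        field_number=text("FieldNumber"),
        date=PartialDate.parse(date_s) if date_s else None,
        country=text("Country"),
        locality_text=text("LocalityText"),
        latitude=float(coords.get("latitude")) if coords is not None else None,
        longitude=float(coords.get("longitude")) if coords is not None else None,
        coordinate_uncertainty=(
            float(coords.get("uncertainty"))
            if coords is not None and coords.get("uncertainty")
            else None
        ),
        elevation=float(elev) if elev else None,
        habitat_notes=text("HabitatNotes"),
        field_observations=text("FieldObservations"),
    )


def _entry_texts(char, entry) -> list[str]:
    """One MeasurementOrFactText per atomized component of an entry."""
    if isinstance(entry, QuantitativeSummary):
        out = [f"{char.name}: {repr(v)} {char.unit_label}" for v in entry.exact_values]
        if entry.range_min is not None or entry.range_max is not None:
            lo = entry.range_min if entry.range_min is not None else entry.range_max
            hi = entry.range_max if entry.range_max is not None else entry.range_min
            out.append(f"{char.name}: {repr(float(lo))}–{repr(float(hi))} {char.unit_label}")
        if entry.sample_size != len(entry.exact_values):
            out.append(f"{char.name}: n={entry.sample_size}")
        return out
    return [f"{char.name}: {s}" for s in sorted(entry)]


def write_abcd_xml(store: Store, path: Union[str, Path, None] = None,
                   publish_only: bool = False) -> bytes:
    """Serialize all derivative hierarchies of the store; returns the XML
    bytes and writes them to ``path`` when given."""
    root = etree.Element(_E + "DataSets", nsmap=NSMAP)
    units_el = etree.SubElement(root, _E + "Units")
    cmap = store.children_map()
    descs_by_unit: dict[str, list[SpecimenDescription]] = {}
    for d in store.descriptions:
        descs_by_unit.setdefault(d.subject_unit_id, []).append(d)

    for fu in store.field_units():
        if publish_only and not fu.publish:
            continue
        unit_el = _el(
            units_el, "Unit", unitId=fu.unit_id, publish=str(fu.publish).lower()
        )
        if fu.notes:
            _el(unit_el, "Notes", fu.notes)
        _write_gathering(unit_el, fu.gathering)

        # whole-hierarchy member ids, depth-first under the field unit
        member_ids: list[str] = []
        stack = list(reversed(cmap.get(fu.unit_id, [])))
        while stack:
            uid = stack.pop()
            member_ids.append(uid)
            stack.extend(reversed(cmap.get(uid, [])))

        ids_el = _el(unit_el, "Identifications")
        for uid in [fu.unit_id, *member_ids]:
            for det in store.determinations.get(uid, []):
                name = det.taxon_id
                if store.classification is not None and det.taxon_id in store.classification:
                    name = store.classification[det.taxon_id].accepted_name
                ident = _el(
                    ids_el,
                    "Identification",
                    onUnit=uid,
                    taxonId=det.taxon_id,
                    current=str(det.is_current).lower(),
                    typeStatus=det.type_status,
                    date=det.date.isoformat() if det.date else None,
                )
                _el(ident, "TaxonName", name)
                if det.determiner:
                    _el(ident, "Identifier", det.determiner)
                if det.note:
                    _el(ident, "Note", det.note)

        ext = _el(unit_el, "UnitExtension")
        for uid in member_ids:
            du = store.units[uid]
            assert isinstance(du, DerivedUnit)
            d_el = _el(
                ext,
                "Derivative",
                unitId=du.unit_id,
                parent=du.parent_id,
                kind=du.kind,
                publish=str(du.publish).lower(),
            )
            if du.collection_unit is not None:
                _el(
                    d_el,
                    "CollectionUnit",
                    code=du.collection_unit.collection_code,
                    accession=du.collection_unit.accession_number,
                    uri=du.collection_unit.stable_uri,
                )
            if du.external_link:
                _el(d_el, "ExternalLink", du.external_link)
            for key, value in du.payload.items():
                _el(d_el, "Payload", str(value), key=key)

        mof_container = _el(unit_el, "MeasurementsOrFacts")
        for uid in [fu.unit_id, *member_ids]:
            for desc in descs_by_unit.get(uid, []):
                charset = store.charsets.get(desc.charset_id)
                for char_id, entry in desc.entries.items():
                    char = charset[char_id] if charset is not None else None
                    if char is None:
                        continue
                    mof = _el(
                        mof_container,
                        "MeasurementOrFact",
                        onUnit=uid,
                        charsetId=desc.charset_id,
                        charId=char_id,
                    )
                    for text in _entry_texts(char, entry):
                        _el(mof, "MeasurementOrFactText", text)
        # original vs edited data for provider-backed specimens
        for uid in member_ids:
            du = store.units[uid]
            occ = du.payload.get("occurrenceID") if isinstance(du, DerivedUnit) else None
            if occ is None:
                continue
            for (prov, rid), record in store.versioned_records.items():
                if rid != occ:
                    continue
                annotated = export_annotated(record)
                trail = _el(unit_el, "EditTrail", onUnit=uid, provider=prov, recordId=rid)
                for fname, info in annotated["fields"].items():
                    for e in info["edits"]:
                        _el(
                            trail,
                            "Edit",
                            str(e["new_value"]),
                            field=fname,
                            original=str(info["original"]),
                            category=e["category"],
                            author=e["author"],
                            timestamp=e["timestamp"],
                        )
    data = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    if path is not None:
        Path(path).write_bytes(data)
    return data


def _parse_mof(store: Store, fu_ids: dict, mof) -> None:
    char_id = mof.get("charId")
    charset_id = mof.get("charsetId")
    unit_id = mof.get("onUnit")
    charset: Optional[CharacterSet] = store.charsets.get(charset_id)
    texts = [t.text or "" for t in mof.findall(_E + "MeasurementOrFactText")]
    char = None
    if charset is not None and char_id in charset:
        char = charset[char_id]
    if char is None:
        # fall back to matching "name: value" against any known charset
        for cs in store.charsets.values():
            for c in cs:
                if texts and texts[0].startswith(c.name + ":"):
                    char, charset, char_id, charset_id = c, cs, c.char_id, cs.set_id
                    break
            if char is not None:
                break
    if char is None or charset is None:
        return
    key = (unit_id, charset_id)
    desc = fu_ids.get(key)
    if desc is None:
        desc = SpecimenDescription(subject_unit_id=unit_id, charset_id=charset_id)
        fu_ids[key] = desc
        store.descriptions.append(desc)
    if char.kind == "categorical":
        states = set(desc.entries.get(char_id, frozenset()))
        for t in texts:
            states.add(t.split(":", 1)[1].strip() if ":" in t else t.strip())
        desc.entries[char_id] = frozenset(states)
        return
    exact: list[float] = []
    rmin = rmax = None
    n = 0
    if char_id in desc.entries:
        prev = desc.entries[char_id]
        exact, rmin, rmax, n = list(prev.exact_values), prev.range_min, prev.range_max, prev.sample_size
    for t in texts:
        body = t.split(":", 1)[1] if ":" in t else t
        body = body.strip()
        if char.unit_label and body.endswith(char.unit_label):
            body = body[: -len(char.unit_label)].strip()
        m = _N_RE.match(body)
        if m:
            n = int(m.group(1))
            continue
        m = _RANGE_RE.match(body)
        if m:
            rmin, rmax = float(m.group(1)), float(m.group(2))
            continue
        m = _VALUE_RE.match(body)
        if m:
            exact.append(float(m.group(1)))
    desc.entries[char_id] = QuantitativeSummary(
        exact_values=exact, range_min=rmin, range_max=rmax,
        sample_size=max(n, len(exact)),
    )


def read_abcd_xml(path_or_bytes, store: Store) -> list[FieldUnit]:
    """Parse the dialect back into the store, reconstructing derivative
    hierarchies, determination histories and specimen descriptions.

    Character sets referenced by ``MeasurementsOrFacts`` must already be
    registered in ``store.charsets`` (the dialect exchanges data, not
    character definitions).
    """
    if isinstance(path_or_bytes, (bytes, bytearray)):
        root = etree.fromstring(bytes(path_or_bytes))
    else:
        root = etree.parse(str(path_or_bytes)).getroot()
    imported: list[FieldUnit] = []
    desc_index: dict = {}
    pending_dets: list[tuple[str, Determination]] = []
    for unit_el in root.iter(_E + "Unit"):
        fu_id = unit_el.get("unitId")
        gat_el = unit_el.find(_E + "Gathering")
        if fu_id is None or gat_el is None:
            raise ValidationError("Unit element without unitId or Gathering")
        gathering = _read_gathering(gat_el)
        gathering.validate()
        notes_el = unit_el.find(_E + "Notes")
        fu = FieldUnit(
            unit_id=fu_id,
            gathering=gathering,
            publish=unit_el.get("publish") == "true",
            notes=notes_el.text or "" if notes_el is not None else "",
        )
        store.units[fu.unit_id] = fu
        imported.append(fu)
        ext = unit_el.find(_E + "UnitExtension")
        if ext is not None:
            for d_el in ext.findall(_E + "Derivative"):
                parent = d_el.get("parent")
                if parent != fu_id and parent not in store.units:
                    raise ValidationError(
                        f"derivative {d_el.get('unitId')} references unknown parent {parent}"
                    )
                cu_el = d_el.find(_E + "CollectionUnit")
                link_el = d_el.find(_E + "ExternalLink")
                du = DerivedUnit(
                    unit_id=d_el.get("unitId"),
                    kind=d_el.get("kind", "other"),
                    parent_id=parent,
                    collection_unit=(
                        CollectionUnit(
                            collection_code=cu_el.get("code", ""),
                            accession_number=cu_el.get("accession", ""),
                            stable_uri=cu_el.get("uri"),
                        )
                        if cu_el is not None
                        else None
                    ),
                    external_link=link_el.text if link_el is not None else None,
                    payload={p.get("key"): p.text or "" for p in d_el.findall(_E + "Payload")},
                    publish=d_el.get("publish") == "true",
                )
                du.validate()
                store.units[du.unit_id] = du
        ids_el = unit_el.find(_E + "Identifications")
        if ids_el is not None:
            for ident in ids_el.findall(_E + "Identification"):
                det_note = ident.find(_E + "Note")
                det_ident = ident.find(_E + "Identifier")
                date_s = ident.get("date")
                det = Determination(
                    taxon_id=ident.get("taxonId"),
                    determiner=det_ident.text or "" if det_ident is not None else "",
                    date=PartialDate.parse(date_s) if date_s else None,
                    is_current=ident.get("current") == "true",
                    type_status=ident.get("typeStatus", "none"),
                    note=det_note.text or "" if det_note is not None else "",
                    seq=store.next_det_seq(),
                )
                pending_dets.append((ident.get("onUnit"), det))
        mof_container = unit_el.find(_E + "MeasurementsOrFacts")
        if mof_container is not None:
            for mof in mof_container.findall(_E + "MeasurementOrFact"):
                _parse_mof(store, desc_index, mof)
    for uid, det in pending_dets:
        store.determinations.setdefault(uid, []).append(det)
    return imported
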