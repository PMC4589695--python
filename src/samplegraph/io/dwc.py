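"""Darwin Core occurrence CSV import/export.

One CSV row represents one occurrence: a field unit (gathering data) with
its first specimen derivative and, optionally, a determination.  The
``occurrenceID`` is preserved as the provider record identifier so imported
rows can later be versioned and resynchronized.  Import is tolerant at row
level: a malformed row produces an error entry in the report instead of
aborting the file.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from ..core import (
    DerivedUnit,
    CollectionUnit,
    FieldUnit,
    GatheringEvent,
    PartialDate,
    Store,
    ValidationError,
)
from ..hierarchy import assign_taxon, create_field_unit, derive, effective_determination

DWC_COLUMNS = [
    "occurrenceID",
    "recordedBy",
    "recordNumber",
    "eventDate",
    "country",
    "locality",
    "decimalLatitude",
    "decimalLongitude",
    "scientificName",
    "typeStatus",
    "collectionCode",
    "catalogNumber",
]

__all__ = ["DWC_COLUMNS", "DwcImportReport", "read_dwc_csv", "write_dwc_csv"]


@dataclass
class DwcImportReport:
    imported: list[tuple[FieldUnit, DerivedUnit, Optional[object]]] = field(default_factory=list)
    errors: list[tuple[int, str]] = field(default_factory=list)  # (row number, message)


def _taxon_by_name(store: Store, name: str) -> Optional[str]:
    if store.classification is None:
        return None
    for node in store.classification.nodes.values():
        if node.accepted_name == name or name in node.synonyms:
            return node.taxon_id
    return None


def read_dwc_csv(path: Union[str, Path], store: Store) -> DwcImportReport:
    """Import occurrence rows into the store.

    Each valid row creates a field unit plus one specimen derivative; the
    ``scientificName`` is matched against the store's classification (by
    accepted name or synonym) to create a determination.  Unmatched or
    empty names leave the unit undetermined.
    """
    report = DwcImportReport()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "occurrenceID" not in reader.fieldnames:
            raise ValidationError("missing occurrenceID column")
        for i, row in enumerate(reader, start=2):
            try:
                report.imported.append(_import_row(store, row))
            except (ValidationError, ValueError) as exc:
                report.errors.append((i, str(exc)))
    return report


def _import_row(store: Store, row: dict) -> tuple[FieldUnit, DerivedUnit, Optional[object]]:
    occurrence_id = (row.get("occurrenceID") or "").strip()
    if not occurrence_id:
        raise ValidationError("missing occurrenceID")
    lat_s = (row.get("decimalLatitude") or "").strip()
    lon_s = (row.get("decimalLongitude") or "").strip()
    lat = float(lat_s) if lat_s else None
    lon = float(lon_s) if lon_s else None
    date_s = (row.get("eventDate") or "").strip()
    gathering = GatheringEvent(
        collectors=[c.strip() for c in (row.get("recordedBy") or "").split("|") if c.strip()],
        field_number=(row.get("recordNumber") or "").strip(),
        date=PartialDate.parse(date_s) if date_s else None,
        country=(row.get("country") or "").strip(),
        locality_text=(row.get("locality") or "").strip(),
        latitude=lat,
        longitude=lon,
    )
    fu = create_field_unit(store, gathering)
    collection_unit = None
    code = (row.get("collectionCode") or "").strip()
    number = (row.get("catalogNumber") or "").strip()
    if code or number:
        collection_unit = CollectionUnit(collection_code=code, accession_number=number)
    specimen = derive(
        store,
        fu.unit_id,
        "specimen",
        event_type="accessioning",
        collection_unit=collection_unit,
        payload={"occurrenceID": occurrence_id},
    )
    det = None
    name = (row.get("scientificName") or "").strip()
    if name:
        taxon_id = _taxon_by_name(store, name)
        if taxon_id is not None:
            det = assign_taxon(
                store,
                fu.unit_id,
                taxon_id,
                type_status=(row.get("typeStatus") or "none").strip() or "none",
            )
        else:
            fu.notes = (fu.notes + f" unmatched name: {name}").strip()
    return fu, specimen, det


def _fmt_coord(v: Optional[float]) -> str:
    return "" if v is None else repr(float(v))


def write_dwc_csv(
    store: Store, path: Union[str, Path, None] = None, publish_only: bool = False
) -> str:
    """Export one row per field unit (with its first specimen derivative).

    Returns the CSV text; writes it to ``path`` when given.  With
    ``publish_only`` only field units flagged for publication are exported.
    """
    cmap = store.children_map()
    buf = _io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=DWC_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for fu in store.field_units():
        if publish_only and not fu.publish:
            continue
        specimen = None
        for child_id in cmap.get(fu.unit_id, []):
            child = store.units[child_id]
            if isinstance(child, DerivedUnit) and child.kind == "specimen":
                specimen = child
                break
        det = effective_determination(store, fu.unit_id, cmap)
        name = ""
        if det is not None and store.classification is not None and det.taxon_id in store.classification:
            name = store.classification[det.taxon_id].accepted_name
        g = fu.gathering
        cu = specimen.collection_unit if specimen is not None else None
        writer.writerow(
            {
                "occurrenceID": (specimen.payload.get("occurrenceID") if specimen else "")
                or (specimen.unit_id if specimen else fu.unit_id),
                "recordedBy": "|".join(g.collectors),
                "recordNumber": g.field_number,
                "eventDate": g.date.isoformat() if g.date else "",
                "country": g.country,
                "locality": g.locality_text,
                "decimalLatitude": _fmt_coord(g.latitude),
                "decimalLongitude": _fmt_coord(g.longitude),
                "scientificName": name,
                "typeStatus": det.type_status if det and det.type_status != "none" else "",
                "collectionCode": cu.collection_code if cu else "",
                "catalogNumber": cu.accession_number if cu else "",
            }
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
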