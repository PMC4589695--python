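"""GeoJSON dot-map export and FASTA export of sequence derivatives.

Axis orders are stated bit-exactly to avoid the classic swap: Darwin Core
columns carry latitude then longitude, GeoJSON coordinates carry
``[longitude, latitude]``.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional, Union

from Bio.Seq import Seq
from Bio.SeqIO import parse as _seqio_parse
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from ..core import DerivedUnit, Store
from ..hierarchy import effective_determination

__all__ = ["write_geojson", "write_fasta", "read_fasta"]


def write_geojson(
    points: list[tuple[float, float, str]], path: Union[str, Path, None] = None
) -> str:
    """Serialize (latitude, longitude, field_unit_id) points as a GeoJSON
    FeatureCollection of Point features in [lon, lat] order."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [lon, lat]},
            "properties": {"field_unit_id": unit_id},
        }
        for lat, lon, unit_id in points
    ]
    doc = {"type": "FeatureCollection", "features": features}
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def write_fasta(
    store: Store,
    path: Union[str, Path, None] = None,
    unit_ids: Optional[list[str]] = None,
) -> str:
    """Export consensus-sequence derivatives as FASTA.

    Headers are ``>unit_id|taxon_name|marker``; sequences wrap at 80
    columns.  ``unit_ids`` restricts the export; default is every sequence
    unit with a non-empty payload, in store order.
    """
    cmap = store.children_map()
    records = []
    for u in store.units.values():
        if not isinstance(u, DerivedUnit) or u.kind != "sequence":
            continue
        if unit_ids is not None and u.unit_id not in unit_ids:
            continue
        seq = u.payload.get("sequence")
        if not seq:
            continue
        det = effective_determination(store, u.unit_id, cmap)
        name = ""
        if det is not None and store.classification is not None and det.taxon_id in store.classification:
            name = store.classification[det.taxon_id].accepted_name.replace(" ", "_")
        marker = u.payload.get("marker", "")
        records.append(SeqRecord(Seq(seq), id=f"{u.unit_id}|{name}|{marker}", description=""))
    buf = _io.StringIO()
    writer = FastaWriter(buf, wrap=80)
    writer.write_file(records)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """(header id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in _seqio_parse(str(path), "fasta")]
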