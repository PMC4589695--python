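"""Character-matrix exchange: CSV values + JSON character-set descriptor,
and Nexus export of the categorical columns.

CSV cell encoding (empty cell = not scored):

* categorical — state labels joined with ``|`` (vocabulary order);
* quantitative — components joined with ``|``: plain numbers are exact
  values, ``lo–hi`` is a label range, ``n=k`` an explicit sample size.

Nexus export writes a ``TAXA`` + ``CHARACTERS`` block pair with states
coded as symbols in vocabulary order, ``?`` for missing cells and
``{..}`` for polymorphic ones.  Quantitative characters have no standard
symbol coding and are excluded with a logged notice.
"""

from __future__ import annotations

import csv
import io as _io
import json
import logging
import re
from pathlib import Path
from typing import Union

from ..characters import (
    CharacterDef,
    CharacterSet,
    QuantitativeSummary,
    SpecimenDescription,
)
from ..core import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["read_matrix", "write_matrix", "export_nexus", "charset_to_json", "charset_from_json"]

_RANGE_RE = re.compile(r"^(-?\d+(?:\.\d+)?)–(-?\d+(?:\.\d+)?)$")
_N_RE = re.compile(r"^n=(\d+)$")

_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def charset_to_json(charset: CharacterSet) -> str:
    chars = []
    for c in charset:
        d: dict = {"char_id": c.char_id, "name": c.name, "kind": c.kind}
        if c.kind == "categorical":
            d["states"] = list(c.states)
        else:
            d["unit_label"] = c.unit_label
        chars.append(d)
    return json.dumps({"set_id": charset.set_id, "characters": chars}, indent=2)


def charset_from_json(text: str) -> CharacterSet:
    data = json.loads(text)
    chars = [
        CharacterDef(
            char_id=c["char_id"],
            name=c["name"],
            kind=c["kind"],
            states=list(c.get("states", [])),
            unit_label=c.get("unit_label", ""),
        )
        for c in data["characters"]
    ]
    return CharacterSet(data["set_id"], chars)


def _encode_cell(char: CharacterDef, entry) -> str:
    if entry is None:
        return ""
    if char.kind == "categorical":
        return "|".join(s for s in char.states if s in entry)
    parts = [repr(v) for v in entry.exact_values]
    if entry.range_min is not None or entry.range_max is not None:
        lo = entry.range_min if entry.range_min is not None else entry.range_max
        hi = entry.range_max if entry.range_max is not None else entry.range_min
        parts.append(f"{repr(float(lo))}–{repr(float(hi))}")
    if entry.sample_size != len(entry.exact_values):
        parts.append(f"n={entry.sample_size}")
    return "|".join(parts)


def _decode_cell(char: CharacterDef, text: str):
    text = text.strip()
    if not text:
        return None
    if char.kind == "categorical":
        states = frozenset(s for s in text.split("|") if s)
        unknown = states - set(char.states)
        if unknown:
            raise ValidationError(f"state(s) {sorted(unknown)} not in vocabulary of {char.char_id}")
        return states
    exact: list[float] = []
    rmin = rmax = None
    n = 0
    for part in text.split("|"):
        part = part.strip()
        m = _N_RE.match(part)
        if m:
            n = int(m.group(1))
            continue
        m = _RANGE_RE.match(part)
        if m:
            rmin, rmax = float(m.group(1)), float(m.group(2))
            continue
        exact.append(float(part))
    return QuantitativeSummary(
        exact_values=exact, range_min=rmin, range_max=rmax, sample_size=max(n, len(exact))
    )


def write_matrix(
    descriptions: list[SpecimenDescription],
    charset: CharacterSet,
    values_path: Union[str, Path, None] = None,
    charset_path: Union[str, Path, None] = None,
) -> tuple[str, str]:
    """Write the matrix as (values CSV text, charset JSON text)."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["unit_id", *charset.char_ids()])
    for desc in descriptions:
        row = [desc.subject_unit_id]
        for char in charset:
            row.append(_encode_cell(char, desc.entries.get(char.char_id)))
        writer.writerow(row)
    csv_text = buf.getvalue()
    json_text = charset_to_json(charset)
    if values_path is not None:
        Path(values_path).write_text(csv_text, encoding="utf-8")
    if charset_path is not None:
        Path(charset_path).write_text(json_text, encoding="utf-8")
    return csv_text, json_text


def read_matrix(
    values_csv: Union[str, Path],
    charset_json: Union[str, Path],
) -> tuple[list[SpecimenDescription], CharacterSet]:
    """Read a values CSV + charset JSON pair back into descriptions."""
    charset = charset_from_json(Path(charset_json).read_text(encoding="utf-8"))
    descriptions: list[SpecimenDescription] = []
    with open(values_csv, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if not header or header[0] != "unit_id":
            raise ValidationError("matrix CSV must start with a unit_id column")
        for col in header[1:]:
            if col not in charset:
                raise ValidationError(f"CSV column {col!r} not in character set {charset.set_id}")
        for row in reader:
            entries = {}
            for col, cell in zip(header[1:], row[1:]):
                value = _decode_cell(charset[col], cell)
                if value is not None:
                    entries[col] = value
            descriptions.append(
                SpecimenDescription(
                    subject_unit_id=row[0], charset_id=charset.set_id, entries=entries
                )
            )
    return descriptions, charset


def _nexus_label(text: str) -> str:
    return re.sub(r"\W", "_", text)


def export_nexus(
    descriptions: list[SpecimenDescription],
    charset: CharacterSet,
    path: Union[str, Path, None] = None,
) -> str:
    """Nexus serialization of the categorical part of a matrix."""
    categorical = [c for c in charset if c.kind == "categorical"]
    skipped = [c.char_id for c in charset if c.kind == "quantitative"]
    if skipped:
        logger.info(
            "Nexus export: quantitative character(s) excluded (no symbol coding): %s",
            ", ".join(skipped),
        )
    if any(len(c.states) > len(_SYMBOLS) for c in categorical):
        raise ValidationError(f"more than {len(_SYMBOLS)} states cannot be symbol-coded")
    max_states = max((len(c.states) for c in categorical), default=0)
    symbols = " ".join(_SYMBOLS[:max_states])
    taxa = [_nexus_label(d.subject_unit_id) for d in descriptions]

    lines = ["#NEXUS", ""]
    lines += [
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={len(descriptions)};",
        "    TAXLABELS",
    ]
    lines += [f"        {t}" for t in taxa]
    lines += ["    ;", "END;", ""]
    lines += [
        "BEGIN CHARACTERS;",
        f"    DIMENSIONS NCHAR={len(categorical)};",
        f'    FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="{symbols}";',
    ]
    if categorical:
        lines.append("    CHARSTATELABELS")
        for i, c in enumerate(categorical, start=1):
            states = " ".join(_nexus_label(s) for s in c.states)
            sep = "," if i < len(categorical) else ""
            lines.append(f"        {i} {_nexus_label(c.name)} / {states}{sep}")
        lines.append("    ;")
    lines.append("    MATRIX")
    width = max((len(t) for t in taxa), default=0)
    for d, t in zip(descriptions, taxa):
        codes = []
        for c in categorical:
            entry = d.entries.get(c.char_id)
            if entry is None:
                codes.append("?")
                continue
            syms = [_SYMBOLS[c.states.index(s)] for s in c.states if s in entry]
            codes.append(syms[0] if len(syms) == 1 else "{" + "".join(syms) + "}")
        lines.append(f"        {t:<{width}} {''.join(codes)}")
    lines += ["    ;", "END;", ""]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
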