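"""Core-copy / enrichment versioning of imported collection records.

An imported provider record is split into two semantic parts: the **core
copy** — the provider's original dataset, stored immutably under the
provider's own record identifier — and the **enrichment** layer, an ordered
list of field-level edits (label completion, standardization, parsing
correction, georeferencing, typification ...).  Versions are commit points
over the edit list; the materialized state of a version is always
recomputable as *core copy + edits up to the commit*.

Reverting appends compensating edits instead of rewriting history, so the
record remains a complete audit of every change.  Re-querying the provider
stores a **new** core copy and replays the local enrichment on it with a
three-way merge per field: provider-unchanged fields keep the local edit,
edits the provider made identically are dropped as redundant, and fields
both sides changed differently are conflicts — the provider value
materializes and the parked local edit is listed in the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Optional

from .core import Store, ValidationError

__all__ = [
    "MISSING",
    "EDIT_CATEGORIES",
    "CoreCopy",
    "EditEntry",
    "Version",
    "FieldChange",
    "ConflictReport",
    "VersionedRecord",
    "import_core_copy",
    "apply_edit",
    "commit_version",
    "materialize",
    "diff_versions",
    "apply_patch",
    "revert_to",
    "refresh_core_copy",
    "export_annotated",
    "import_annotated",
]


class _Missing:
    """Sentinel for 'field absent' (distinct from None, which is a value)."""

    _instance: Optional["_Missing"] = None

    def __new__(cls) -> "_Missing":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"


MISSING = _Missing()

EDIT_CATEGORIES = frozenset(
    {
        "label_completion",
        "external_source_addition",
        "standardization",
        "parsing_correction",
        "georeferencing",
        "typification",
    }
)


class CoreCopy:
    """Immutable snapshot of a provider record (flat field → value map)."""

    def __init__(self, provider_name: str, provider_record_id: str,
                 snapshot: dict[str, Any], retrieved_at: str) -> None:
        self.provider_name = provider_name
        self.provider_record_id = provider_record_id
        self._snapshot = dict(snapshot)
        self.retrieved_at = retrieved_at

    @property
    def snapshot(self) -> dict[str, Any]:
        return dict(self._snapshot)

    def digest(self) -> str:
        payload = json.dumps(self._snapshot, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class EditEntry:
    field_path: str
    old_value: Any
    new_value: Any
    category: str
    author: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.category not in EDIT_CATEGORIES:
            raise ValidationError(f"unknown edit category: {self.category!r}")
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()


@dataclass(frozen=True)
class Version:
    version_id: int
    base_index: int
    n_edits: int


@dataclass(frozen=True)
class FieldChange:
    field_path: str
    value_a: Any  # MISSING when absent in a
    value_b: Any  # MISSING when absent in b


@dataclass
class ConflictReport:
    conflicts: list[tuple[str, Any, Any, Any]] = field(default_factory=list)  # (field, base, local, provider)
    replayed: list[str] = field(default_factory=list)
    dropped_redundant: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.conflicts


class VersionedRecord:
    """One provider record with its core copies, enrichment edits and versions."""

    def __init__(self, base: CoreCopy) -> None:
        self.provider_name = base.provider_name
        self.provider_record_id = base.provider_record_id
        self.bases: list[CoreCopy] = [base]
        #: one edit list per base; edits always append to the last
        self.edit_logs: list[list[EditEntry]] = [[]]
        self.versions: list[Version] = [Version(1, 0, 0)]

    # -- internals -----------------------------------------------------
    @property
    def current_base(self) -> CoreCopy:
        return self.bases[-1]

    @property
    def pending_edits(self) -> list[EditEntry]:
        return self.edit_logs[-1]

    def version(self, version_id: int) -> Version:
        for v in self.versions:
            if v.version_id == version_id:
                return v
        raise ValidationError(f"unknown version id: {version_id}")


def _apply_edits(snapshot: dict[str, Any], edits: list[EditEntry]) -> dict[str, Any]:
    state = dict(snapshot)
    for e in edits:
        if e.new_value is MISSING:
            state.pop(e.field_path, None)
        else:
            state[e.field_path] = e.new_value
    return state


def import_core_copy(
    store: Store,
    provider_name: str,
    provider_record_id: str,
    snapshot: dict[str, Any],
    retrieved_at: Optional[str] = None,
) -> VersionedRecord:
    """Store a provider record as an immutable core copy at version 1."""
    key = (provider_name, provider_record_id)
    if key in store.versioned_records:
        raise ValidationError(
            f"record {provider_record_id} from {provider_name} already imported; "
            "use refresh_core_copy to resynchronize"
        )
    base = CoreCopy(
        provider_name,
        provider_record_id,
        snapshot,
        retrieved_at or datetime.now(timezone.utc).isoformat(),
    )
    record = VersionedRecord(base)
    store.versioned_records[key] = record
    return record


def materialize(record: VersionedRecord, version_id: Optional[int] = None) -> dict[str, Any]:
    """State of the record at a version (default: current, with pending edits)."""
    if version_id is None:
        return _apply_edits(record.current_base.snapshot, record.pending_edits)
    v = record.version(version_id)
    return _apply_edits(record.bases[v.base_index].snapshot, record.edit_logs[v.base_index][: v.n_edits])


def apply_edit(
    record: VersionedRecord,
    field_path: str,
    new_value: Any,
    category: str,
    author: str = "",
) -> EditEntry:
    """Append an enrichment edit; the core copy is untouched.

    New fields may be added (label completion, georeferencing); setting
    ``new_value`` to :data:`MISSING` removes a field.
    """
    current = materialize(record)
    entry = EditEntry(
        field_path=field_path,
        old_value=current.get(field_path, MISSING),
        new_value=new_value,
        category=category,
        author=author,
    )
    record.pending_edits.append(entry)
    return entry


def commit_version(record: VersionedRecord) -> Version:
    """Freeze the current edit count as a new version."""
    v = Version(
        version_id=record.versions[-1].version_id + 1,
        base_index=len(record.bases) - 1,
        n_edits=len(record.pending_edits),
    )
    record.versions.append(v)
    return v


def diff_versions(record: VersionedRecord, a: int, b: int) -> list[FieldChange]:
    """Field-level changes between two versions (changed, added, removed)."""
    state_a = materialize(record, a)
    state_b = materialize(record, b)
    changes = []
    for f in sorted(set(state_a) | set(state_b)):
        va = state_a.get(f, MISSING)
        vb = state_b.get(f, MISSING)
        if va != vb or (va is MISSING) != (vb is MISSING):
            changes.append(FieldChange(f, va, vb))
    return changes


def apply_patch(state: dict[str, Any], changes: list[FieldChange]) -> dict[str, Any]:
    """Apply a diff to a field map (forward direction: a → b)."""
    out = dict(state)
    for ch in changes:
        if ch.value_b is MISSING:
            out.pop(ch.field_path, None)
        else:
            out[ch.field_path] = ch.value_b
    return out


def _category_for(record: VersionedRecord, field_path: str) -> str:
    for e in reversed(record.pending_edits):
        if e.field_path == field_path:
            return e.category
    return "standardization"


def revert_to(record: VersionedRecord, version_id: int) -> list[EditEntry]:
    """Make the materialized state equal an older version by appending
    compensating edits — history is never rewritten."""
    target = materialize(record, version_id)
    current = materialize(record)
    appended = []
    for f in sorted(set(current) | set(target)):
        cur = current.get(f, MISSING)
        tgt = target.get(f, MISSING)
        if cur != tgt or (cur is MISSING) != (tgt is MISSING):
            appended.append(apply_edit(record, f, tgt, _category_for(record, f)))
    return appended


def refresh_core_copy(
    record: VersionedRecord,
    new_snapshot: dict[str, Any],
    retrieved_at: Optional[str] = None,
) -> ConflictReport:
    """Resynchronize with the provider: store a new core copy, replay the
    enrichment on it, and report per-field three-way-merge conflicts.

    Provider wins on conflict; the parked local edit appears only in the
    report.  A new version on the new base is committed automatically.
    """
    old_base = record.current_base.snapshot
    local = materialize(record)
    edits_by_field: dict[str, EditEntry] = {}
    for e in record.pending_edits:
        edits_by_field[e.field_path] = e

    new_base = CoreCopy(
        record.provider_name,
        record.provider_record_id,
        new_snapshot,
        retrieved_at or datetime.now(timezone.utc).isoformat(),
    )
    record.bases.append(new_base)
    record.edit_logs.append([])

    report = ConflictReport()
    for f in sorted(set(old_base) | set(local) | set(new_snapshot)):
        base_v = old_base.get(f, MISSING)
        local_v = local.get(f, MISSING)
        prov_v = new_snapshot.get(f, MISSING)
        locally_changed = local_v != base_v or (local_v is MISSING) != (base_v is MISSING)
        provider_changed = prov_v != base_v or (prov_v is MISSING) != (base_v is MISSING)
        if not locally_changed:
            continue
        if not provider_changed:
            src = edits_by_field.get(f)
            record.pending_edits.append(
                EditEntry(
                    field_path=f,
                    old_value=prov_v,
                    new_value=local_v,
                    category=src.category if src else "standardization",
                    author=src.author if src else "",
                )
            )
            report.replayed.append(f)
        elif prov_v == local_v and (prov_v is MISSING) == (local_v is MISSING):
            report.dropped_redundant.append(f)
        else:
            report.conflicts.append((f, base_v, local_v, prov_v))
    commit_version(record)
    return report


def export_annotated(record: VersionedRecord) -> dict[str, Any]:
    """Exchange structure that clearly distinguishes original and edited
    data: per field the provider's original value, the current value, and
    the full edit trail."""
    base = record.current_base.snapshot
    current = materialize(record)
    fields: dict[str, Any] = {}
    for f in sorted(set(base) | set(current)):
        trail = [
            {
                "category": e.category,
                "author": e.author,
                "timestamp": e.timestamp,
                "old_value": None if e.old_value is MISSING else e.old_value,
                "new_value": None if e.new_value is MISSING else e.new_value,
            }
            for e in record.pending_edits
            if e.field_path == f
        ]
        fields[f] = {
            "original": base.get(f),
            "current": current.get(f),
            "edits": trail,
        }
    return {
        "provider_name": record.provider_name,
        "provider_record_id": record.provider_record_id,
        "retrieved_at": record.current_base.retrieved_at,
        "fields": fields,
    }


def import_annotated(data: dict[str, Any]) -> VersionedRecord:
    """Rebuild a versioned record from an annotated export; the materialized
    state round-trips exactly."""
    snapshot = {
        f: v["original"] for f, v in data["fields"].items() if v["original"] is not None
    }
    base = CoreCopy(
        data["provider_name"], data["provider_record_id"], snapshot, data["retrieved_at"]
    )
    record = VersionedRecord(base)
    for f, v in data["fields"].items():
        for e in v["edits"]:
            record.pending_edits.append(
                EditEntry(
                    field_path=f,
                    old_value=MISSING if e["old_value"] is None else e["old_value"],
                    new_value=MISSING if e["new_value"] is None else e["new_value"],
                    category=e["category"],
                    author=e["author"],
                    timestamp=e["timestamp"],
                )
            )
    return record
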