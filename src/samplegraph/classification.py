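"""Data-preserving restructuring of the classification.

Moving or renaming a taxon never touches the link between samples and
taxa.  Uniting one taxon with another moves its specimens, descriptions
and occurrence records to the target and records their former placement;
re-delimiting a taxon moves individual specimens, again with the former
placement recorded.  The append-only :class:`AuditEntry` log makes every
restructuring replayable: applying the log to the initial classification
reproduces the current one, including specimen placements.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable, Optional

from .core import Classification, Store, ValidationError
from .hierarchy import assign_taxon, effective_determination

__all__ = [
    "AuditEntry",
    "move_taxon",
    "rename_taxon",
    "unite_taxa",
    "reassign_specimens",
    "replay_audit",
]

AUDIT_ACTIONS = ("assign", "move_taxon", "rename", "unite", "reassign_specimen")


@dataclass(frozen=True)
class AuditEntry:
    timestamp: str
    action: str
    subject_id: str
    former: Optional[str]
    new: Optional[str]
    actor: str = ""


def _audit(store: Store, action: str, subject: str, former, new, actor: str = "") -> None:
    store.audit.append(
        AuditEntry(
            timestamp=datetime.now(timezone.utc).isoformat(),
            action=action,
            subject_id=subject,
            former=former,
            new=new,
            actor=actor,
        )
    )


def _classification(store: Store) -> Classification:
    if store.classification is None:
        raise ValidationError("store has no classification")
    return store.classification


def move_taxon(
    store: Store, taxon_id: str, new_parent_id: str, actor: str = "", check_rank: bool = True
) -> None:
    """Re-parent a taxon subtree; specimen links and descriptions are untouched.

    ``check_rank`` enforces that the moved taxon's rank stays strictly below
    the new parent's; switch it off for rank-less working classifications.
    """
    cls = _classification(store)
    node = cls[taxon_id]
    new_parent = cls[new_parent_id]
    if node.parent_taxon_id is None:
        raise ValidationError("cannot move the classification root")
    if taxon_id == new_parent_id or cls.is_descendant(new_parent_id, taxon_id):
        raise ValidationError("move would create a cycle")
    if check_rank and cls.rank_index(node.rank) <= cls.rank_index(new_parent.rank):
        raise ValidationError(
            f"rank inversion: {node.rank} not below {new_parent.rank}"
        )
    former = node.parent_taxon_id
    node.parent_taxon_id = new_parent_id
    _audit(store, "move_taxon", taxon_id, former, new_parent_id, actor)


def rename_taxon(store: Store, taxon_id: str, new_name: str, actor: str = "") -> None:
    """Rename a taxon; the old accepted name joins the synonym list."""
    cls = _classification(store)
    node = cls[taxon_id]
    former = node.accepted_name
    if former and former != new_name:
        node.synonyms.append(former)
    node.accepted_name = new_name
    _audit(store, "rename", taxon_id, former, new_name, actor)


def unite_taxa(store: Store, source_taxon_id: str, target_taxon_id: str, actor: str = "") -> None:
    """Unite ``source`` into ``target``: specimens, descriptions and
    occurrence records move to the target with their former placement
    recorded; the source's accepted name becomes a synonym of the target
    and the source node disappears (children re-parented to the target)."""
    cls = _classification(store)
    source = cls[source_taxon_id]
    target = cls[target_taxon_id]
    if source_taxon_id == target_taxon_id:
        raise ValidationError("cannot unite a taxon with itself")
    if cls.is_descendant(target_taxon_id, source_taxon_id):
        raise ValidationError("cannot unite a taxon with its own descendant")

    # determinations: re-point, keeping the dissolved name in the note
    for uid, dets in store.determinations.items():
        for det in dets:
            if det.taxon_id == source_taxon_id:
                det.taxon_id = target_taxon_id
                tag = f"formerly {source.accepted_name}"
                det.note = f"{det.note}; {tag}" if det.note else tag
                if det.is_current:
                    _audit(
                        store, "reassign_specimen", uid, source_taxon_id, target_taxon_id, actor
                    )
    # taxon descriptions and occurrence records follow the taxon
    for td in store.taxon_descriptions:
        if td.taxon_id == source_taxon_id:
            td.taxon_id = target_taxon_id
    for rec in store.occurrence_records:
        if rec.taxon_id == source_taxon_id:
            rec.taxon_id = target_taxon_id
    # children re-parent to the target
    for child in cls.children(source_taxon_id):
        child.parent_taxon_id = target_taxon_id
    target.synonyms.append(source.accepted_name)
    target.synonyms.extend(source.synonyms)
    del cls.nodes[source_taxon_id]
    _audit(store, "unite", source_taxon_id, source.parent_taxon_id, target_taxon_id, actor)


def reassign_specimens(
    store: Store,
    unit_ids: Iterable[str],
    from_taxon_id: str,
    to_taxon_id: str,
    determiner: str = "",
    actor: str = "",
) -> None:
    """Move units from one taxon to another (re-delimitation of a taxon).

    Each unit must currently resolve to ``from_taxon_id``; each gets a new
    current determination to ``to_taxon_id`` and an audit entry with the
    former placement.
    """
    cls = _classification(store)
    cls[to_taxon_id]
    unit_ids = list(unit_ids)
    for uid in unit_ids:  # validate all preconditions before mutating
        det = effective_determination(store, uid)
        if det is None or det.taxon_id != from_taxon_id:
            have = det.taxon_id if det else None
            raise ValidationError(
                f"unit {uid} is not currently assigned to {from_taxon_id} (found {have})"
            )
    for uid in unit_ids:
        assign_taxon(store, uid, to_taxon_id, determiner=determiner)
        _audit(store, "reassign_specimen", uid, from_taxon_id, to_taxon_id, actor)


def replay_audit(
    initial: Classification,
    initial_placements: dict[str, str],
    audit: Iterable[AuditEntry],
) -> tuple[Classification, dict[str, str]]:
    """Apply an audit log to an initial classification and specimen→taxon
    placement map, reproducing the current state.

    This is the audit-completeness guarantee: the log is a sufficient
    record of every restructuring.
    """
    cls = initial.copy()
    placements = dict(initial_placements)
    for entry in audit:
        if entry.action == "move_taxon":
            cls.nodes[entry.subject_id].parent_taxon_id = entry.new
        elif entry.action == "rename":
            node = cls.nodes[entry.subject_id]
            if entry.former and entry.former != entry.new:
                node.synonyms.append(entry.former)
            node.accepted_name = entry.new
        elif entry.action == "unite":
            source = cls.nodes[entry.subject_id]
            target = cls.nodes[entry.new]
            for child in cls.children(entry.subject_id):
                child.parent_taxon_id = entry.new
            target.synonyms.append(source.accepted_name)
            target.synonyms.extend(source.synonyms)
            del cls.nodes[entry.subject_id]
        elif entry.action in ("reassign_specimen", "assign"):
            placements[entry.subject_id] = entry.new
    return cls, placements
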