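"""Construction and traversal of derivative hierarchies.

Every hierarchy is rooted in exactly one :class:`~samplegraph.core.FieldUnit`;
derivatives of any kind may attach to any unit, so intermediate levels that
were lost, ephemeral or never recorded can simply be skipped (a consensus
sequence may hang directly off a specimen).

Taxon assignment works at the hierarchy level: a determination is *stored*
on the unit where it was made, but :func:`effective_determination` computes
the determination valid for every node of the tree — the most recent
current determination anywhere in the hierarchy.  Because inheritance is a
view rather than a copy, retracting an assignment is a single deletion and
the whole tree reverts.
"""

from __future__ import annotations

from typing import Optional

from .core import (
    Determination,
    DerivationEvent,
    DerivedUnit,
    FieldUnit,
    GatheringEvent,
    NotFoundError,
    PartialDate,
    Store,
    Unit,
    ValidationError,
)

__all__ = [
    "create_field_unit",
    "derive",
    "root_of",
    "tree_unit_ids",
    "detach_to_new_field_unit",
    "assign_taxon",
    "retract_determination",
    "effective_determination",
    "ascii_tree",
]


def create_field_unit(
    store: Store,
    gathering: GatheringEvent,
    publish: bool = False,
    notes: str = "",
) -> FieldUnit:
    """Register a new gathering as the root of a fresh derivative hierarchy."""
    gathering.validate()
    fu = FieldUnit(unit_id=store.new_id(), gathering=gathering, publish=publish, notes=notes)
    store.units[fu.unit_id] = fu
    return fu


def derive(
    store: Store,
    parent_id: str,
    kind: str,
    event_type: str = "other",
    actor: str = "",
    date: Optional[PartialDate] = None,
    method_notes: str = "",
    collection_unit=None,
    external_link: Optional[str] = None,
    payload: Optional[dict] = None,
    publish: bool = False,
) -> DerivedUnit:
    """Create a new derivative of ``parent_id`` and record the derivation event."""
    store.unit(parent_id)  # raises NotFoundError on unknown parent
    du = DerivedUnit(
        unit_id=store.new_id(),
        kind=kind,
        parent_id=parent_id,
        collection_unit=collection_unit,
        external_link=external_link,
        payload=dict(payload or {}),
        publish=publish,
    )
    du.validate()
    ev = DerivationEvent(
        event_id=store.new_id(),
        event_type=event_type,
        input_id=parent_id,
        output_ids=[du.unit_id],
        actor=actor,
        date=date,
        method_notes=method_notes,
    )
    store.units[du.unit_id] = du
    store.derivation_events[ev.event_id] = ev
    return du


def root_of(store: Store, unit_id: str) -> FieldUnit:
    """The field unit reached by following parent links from ``unit_id``."""
    u: Unit = store.unit(unit_id)
    seen = {u.unit_id}
    while u.parent_id is not None:
        u = store.unit(u.parent_id)
        if u.unit_id in seen:
            raise ValidationError(f"parent links of {unit_id} form a cycle")
        seen.add(u.unit_id)
    if not isinstance(u, FieldUnit):
        raise ValidationError(f"hierarchy of {unit_id} is not rooted in a field unit")
    return u


def tree_unit_ids(
    store: Store, unit_id: str, children: Optional[dict] = None
) -> list[str]:
    """All unit ids of the hierarchy containing ``unit_id`` (root first).

    ``children`` may be a precomputed :meth:`Store.children_map` to avoid
    rebuilding it in tight loops.
    """
    root = root_of(store, unit_id)
    return subtree_unit_ids(store, root.unit_id, children)


def subtree_unit_ids(
    store: Store, unit_id: str, children: Optional[dict] = None
) -> list[str]:
    """``unit_id`` and all units below it, in depth-first order."""
    store.unit(unit_id)
    cmap = children if children is not None else store.children_map()
    out: list[str] = []
    stack = [unit_id]
    while stack:
        u = stack.pop()
        out.append(u)
        stack.extend(reversed(cmap.get(u, [])))
    return out


def detach_to_new_field_unit(
    store: Store,
    unit_id: str,
    gathering_override: Optional[dict] = None,
) -> FieldUnit:
    """Split a derivative (with its subtree) off into a new field unit.

    Needed when a sample turns out to belong to a taxon outside the scope
    of the original gathering (epiphytes, parasites) or when a multi-taxon
    gathering is resolved.  The new field unit copies the original
    gathering data — the collecting event really was the same — with any
    fields from ``gathering_override`` replaced.  Determinations stored on
    units of the detached subtree travel with it; determinations that were
    merely inherited from outside the subtree do not, because inheritance
    is computed per hierarchy.
    """
    u = store.unit(unit_id)
    if isinstance(u, FieldUnit):
        raise ValidationError("cannot detach a field unit: it is already a hierarchy root")
    old_root = root_of(store, unit_id)
    gathering = old_root.gathering.copy()
    for key, value in (gathering_override or {}).items():
        if not hasattr(gathering, key):
            raise ValidationError(f"unknown gathering field: {key}")
        setattr(gathering, key, value)
    new_root = create_field_unit(
        store,
        gathering,
        publish=old_root.publish,
        notes=f"detached from field unit {old_root.unit_id}",
    )
    u.parent_id = new_root.unit_id
    return new_root


def assign_taxon(
    store: Store,
    unit_id: str,
    taxon_id: str,
    determiner: str = "",
    date: Optional[PartialDate] = None,
    type_status: str = "none",
    note: str = "",
) -> Determination:
    """Record a new current determination on ``unit_id``.

    The assignment is effective for the entire derivative hierarchy (and
    reversible): any previously current determination anywhere in the tree
    is demoted to the history.
    """
    store.unit(unit_id)
    if store.classification is not None and taxon_id not in store.classification:
        raise NotFoundError(taxon_id)
    for uid in tree_unit_ids(store, unit_id):
        for d in store.determinations.get(uid, []):
            d.is_current = False
    det = Determination(
        taxon_id=taxon_id,
        determiner=determiner,
        date=date,
        is_current=True,
        type_status=type_status,
        note=note,
        seq=store.next_det_seq(),
    )
    store.determinations.setdefault(unit_id, []).append(det)
    return det


def retract_determination(store: Store, unit_id: str) -> Optional[Determination]:
    """Remove the current determination stored on ``unit_id``, if any.

    The whole hierarchy immediately reverts to whatever the remaining
    determination history implies (possibly none).
    """
    dets = store.determinations.get(unit_id, [])
    for d in reversed(dets):
        if d.is_current:
            dets.remove(d)
            if not dets:
                store.determinations.pop(unit_id, None)
            return d
    return None


def effective_determination(
    store: Store, unit_id: str, children: Optional[dict] = None
) -> Optional[Determination]:
    """The determination valid for ``unit_id``: the latest current
    determination anywhere in its hierarchy, or ``None``.

    Ties on date (including absent dates) break by insertion order.
    """
    best: Optional[Determination] = None
    for uid in tree_unit_ids(store, unit_id, children):
        for d in store.determinations.get(uid, []):
            if d.is_current and (best is None or d.sort_key() > best.sort_key()):
                best = d
    return best


def ascii_tree(store: Store, field_unit_id: str) -> str:
    """Render a derivative hierarchy as an indented ASCII tree.

    Units carrying linked character datasets are flagged with ``[+data]``,
    mirroring the joint display of derivatives and their data.
    """
    root = store.unit(field_unit_id)
    if not isinstance(root, FieldUnit):
        root = root_of(store, field_unit_id)
    cmap = store.children_map()
    described = {d.subject_unit_id for d in store.descriptions}
    lines: list[str] = []

    def label(uid: str) -> str:
        u = store.unit(uid)
        kind = "field_unit" if isinstance(u, FieldUnit) else u.kind
        extra = " [+data]" if uid in described else ""
        det = effective_determination(store, uid, cmap) if isinstance(u, FieldUnit) else None
        name = ""
        if det is not None and store.classification is not None and det.taxon_id in store.classification:
            name = f" <{store.classification[det.taxon_id].accepted_name}>"
        return f"{kind}:{uid}{name}{extra}"

    def walk(uid: str, prefix: str, is_last: bool, is_root: bool) -> None:
        if is_root:
            lines.append(label(uid))
            child_prefix = ""
        else:
            lines.append(prefix + ("`-- " if is_last else "|-- ") + label(uid))
            child_prefix = prefix + ("    " if is_last else "|   ")
        kids = cmap.get(uid, [])
        for i, kid in enumerate(kids):
            walk(kid, child_prefix, i == len(kids) - 1, False)

    walk(root.unit_id, "", True, True)
    return "\n".join(lines)
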