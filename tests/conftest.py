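import random

import pytest

from samplegraph.characters import (
    CharacterDef,
    CharacterSet,
    SpecimenDescription,
    record_categorical,
    record_quantitative,
    link_description,
)
from samplegraph.core import (
    Classification,
    GatheringEvent,
    PartialDate,
    Store,
    TaxonNode,
)
from samplegraph.hierarchy import assign_taxon, create_field_unit, derive


def make_classification() -> Classification:
    cls = Classification(("family", "genus", "species", "subspecies"))
    cls.add(TaxonNode("fam", "Campanulaceae", "family", None))
    cls.add(TaxonNode("gen1", "Campanula", "genus", "fam"))
    cls.add(TaxonNode("gen2", "Adenophora", "genus", "fam"))
    cls.add(TaxonNode("sp1", "Campanula alpina", "species", "gen1"))
    cls.add(TaxonNode("sp2", "Campanula patula", "species", "gen1"))
    cls.add(TaxonNode("sp3", "Adenophora liliifolia", "species", "gen2"))
    return cls


def make_charset() -> CharacterSet:
    return CharacterSet(
        "cs1",
        [
            CharacterDef("c-col", "corolla colour", "categorical",
                         states=["blue", "violet", "white"]),
            CharacterDef("c-len", "petal length", "quantitative", unit_label="mm"),
        ],
    )


def add_specimen(store, taxon_id=None, lat=None, lon=None, states=None, values=None,
                 chain=("specimen",)):
    """One field unit with a derivative chain and, optionally, a description
    on the specimen and a determination on the field unit."""
    g = GatheringEvent(collectors=["Kilian"], latitude=lat, longitude=lon,
                      country="DE", date=PartialDate(2014, 6))
    fu = create_field_unit(store, g)
    parent = fu.unit_id
    first = None
    for kind in chain:
        du = derive(store, parent, kind)
        if first is None:
            first = du
        parent = du.unit_id
    if taxon_id is not None:
        assign_taxon(store, fu.unit_id, taxon_id, determiner="NK")
    if states is not None or values is not None:
        charset = store.charsets["cs1"]
        desc = SpecimenDescription(subject_unit_id=first.unit_id, charset_id="cs1")
        if states is not None:
            record_categorical(desc, charset, "c-col", states)
        if values is not None:
            if isinstance(values, tuple):
                record_quantitative(desc, charset, "c-len",
                                    range_min=values[0], range_max=values[1],
                                    sample_size=values[2] if len(values) > 2 else 0)
            else:
                record_quantitative(desc, charset, "c-len", values=values)
        link_description(store, desc, first.unit_id)
    return fu, first


@pytest.fixture
def store():
    s = Store()
    s.classification = make_classification()
    s.charsets["cs1"] = make_charset()
    return s


@pytest.fixture
def rng():
    return random.Random(20150930)


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)

def brute_root(store, unit_id):
    u = store.units[unit_id]
    while u.parent_id is not None:
        u = store.units[u.parent_id]
    return u


def brute_tree_members(store, unit_id):
    """Connected component of unit_id under undirected parent links."""
    root = brute_root(store, unit_id)
    members = set()
    changed = True
    members.add(root.unit_id)
    while changed:
        changed = False
        for u in store.units.values():
            if u.unit_id not in members and u.parent_id in members:
                members.add(u.unit_id)
                changed = True
    return members


def brute_effective(store, unit_id):
    """Latest current determination over the whole tree, scanning everything."""
    best = None
    for uid in brute_tree_members(store, unit_id):
        for det in store.determinations.get(uid, []):
            if not det.is_current:
                continue
            key = (det.date.sort_key() if det.date else (0, 0, 0), det.seq)
            if best is None or key > best[0]:
                best = (key, det)
    return best[1] if best else None


def random_derivative_tree(store, rng, max_nodes=50):
    """A random hierarchy: each new derivative picks any existing unit as parent."""
    fu = create_field_unit(store, GatheringEvent())
    ids = [fu.unit_id]
    kinds = ["specimen", "tissue_sample", "dna_sample", "media", "other"]
    for _ in range(rng.randint(0, max_nodes - 1)):
        parent = rng.choice(ids)
        du = derive(store, parent, rng.choice(kinds))
        ids.append(du.unit_id)
    return fu, ids
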