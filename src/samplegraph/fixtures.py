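"""Deterministic synthetic stores for testing and demonstration.

The generator emulates a small revisionary study: a classification of
genera and species under one family, per-species gatherings inside a
bounding box, full derivative chains (specimen → tissue sample → DNA
isolate → trace media + consensus sequence), specimen descriptions drawn
from per-species ground truth, and occurrence records over a nested area
tree.  Every random draw flows from one seeded generator, so an identical
seed yields a byte-identical serialized store.  A ground-truth *sidecar*
records the generating parameters and the per-species true state subsets
and measurement ranges, so recovery tests never re-derive truth from the
store itself.
"""

from __future__ import annotations

import random
import uuid
from dataclasses import asdict, dataclass
from typing import Optional

from .aggregation import AreaTree, DEFAULT_STATUS_PRIORITY, OccurrenceRecord, StatusPriority
from .characters import CharacterDef, CharacterSet, SpecimenDescription, record_categorical, record_quantitative
from .core import (
    Classification,
    CollectionUnit,
    GatheringEvent,
    PartialDate,
    Store,
    TaxonNode,
    ValidationError,
)
from .hierarchy import assign_taxon, create_field_unit, derive
from .characters import link_description

__all__ = ["FixtureSpec", "generate_store"]

#: Bounding box for generated coordinates (central Europe, WGS84).
LAT_RANGE = (40.0, 55.0)
LON_RANGE = (5.0, 15.0)

_STATE_POOL = [
    "blue", "violet", "white", "pink", "yellow", "red", "green", "purple", "brown", "orange"
]


@dataclass
class FixtureSpec:
    """Generating conditions for one synthetic store."""

    seed: int = 0
    n_genera: int = 2
    n_species_per_genus: int = 2
    n_specimens_per_species: int = 5
    georef_fraction: float = 0.8
    n_categorical: int = 2
    n_states: int = 3
    n_quantitative: int = 1
    #: fixed true range for every quantitative character of every species;
    #: None draws a species-specific range
    quant_range: Optional[tuple[float, float]] = None
    measurements_per_specimen: int = 1
    derivative_chain: tuple[str, ...] = ("specimen", "tissue_sample", "dna_sample")
    with_sequence: bool = True
    sequence_length: int = 60
    area_depth: int = 2
    areas_per_node: int = 2
    occurrence_density: float = 0.5

    def validate(self) -> None:
        counts = (
            self.n_genera,
            self.n_species_per_genus,
            self.n_specimens_per_species,
            self.n_categorical,
            self.n_quantitative,
            self.area_depth,
            self.areas_per_node,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("counts must be >= 0")
        for f in (self.georef_fraction, self.occurrence_density):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("fractions must lie in [0, 1]")
        if self.n_categorical and self.n_states < 2:
            raise ValidationError("categorical characters need >= 2 states")
        if self.n_states > len(_STATE_POOL):
            raise ValidationError(f"at most {len(_STATE_POOL)} states supported")


def _build_classification(spec: FixtureSpec, rng: random.Random) -> tuple[Classification, list[str]]:
    cls = Classification(("family", "genus", "species", "subspecies"))
    cls.add(TaxonNode("t-family", "Fixaceae", "family", None))
    species_ids: list[str] = []
    for g in range(spec.n_genera):
        gid = f"t-gen-{g}"
        cls.add(TaxonNode(gid, f"Fixus{g}", "genus", "t-family"))
        for s in range(spec.n_species_per_genus):
            sid = f"t-sp-{g}-{s}"
            cls.add(TaxonNode(sid, f"Fixus{g} specius{s}", "species", gid))
            species_ids.append(sid)
    return cls, species_ids


def _build_charset(spec: FixtureSpec) -> CharacterSet:
    chars = []
    for i in range(spec.n_categorical):
        chars.append(
            CharacterDef(
                char_id=f"cat-{i}",
                name=f"character {i}",
                kind="categorical",
                states=_STATE_POOL[: spec.n_states],
            )
        )
    for i in range(spec.n_quantitative):
        chars.append(
            CharacterDef(
                char_id=f"quant-{i}",
                name=f"measurement {i}",
                kind="quantitative",
                unit_label="mm",
            )
        )
    return CharacterSet("cs-fixture", chars)


def _build_area_tree(spec: FixtureSpec) -> tuple[AreaTree, list[str]]:
    tree = AreaTree()
    tree.add("area-root", "Study region", None)
    leaves: list[str] = []
    frontier = ["area-root"]
    for depth in range(spec.area_depth):
        nxt = []
        for parent in frontier:
            for i in range(spec.areas_per_node):
                aid = f"{parent}.{i}"
                tree.add(aid, f"Area {aid[5:]}", parent)
                nxt.append(aid)
        frontier = nxt
    leaves = frontier if frontier else ["area-root"]
    return tree, leaves


def generate_store(spec: FixtureSpec) -> tuple[Store, dict]:
    """Generate a complete valid store plus its ground-truth sidecar."""
    spec.validate()
    rng = random.Random(spec.seed)
    store = Store(id_factory=lambda: str(uuid.UUID(int=rng.getrandbits(128), version=4)))

    cls, species_ids = _build_classification(spec, rng)
    store.classification = cls
    charset = _build_charset(spec)
    store.charsets[charset.set_id] = charset
    area_tree, leaf_areas = _build_area_tree(spec)
    store.area_tree = area_tree
    store.status_priority = StatusPriority(list(DEFAULT_STATUS_PRIORITY.statuses))

    truth: dict[str, dict] = {}
    accession = 1000
    for sid in species_ids:
        cat_truth: dict[str, list[str]] = {}
        for i in range(spec.n_categorical):
            k = rng.randint(1, max(1, spec.n_states - 1))
            subset = sorted(
                rng.sample(_STATE_POOL[: spec.n_states], k),
                key=_STATE_POOL.index,
            )
            cat_truth[f"cat-{i}"] = subset
        quant_truth: dict[str, tuple[float, float]] = {}
        for i in range(spec.n_quantitative):
            if spec.quant_range is not None:
                lo, hi = spec.quant_range
            else:
                lo = round(rng.uniform(1.0, 8.0), 2)
                hi = round(lo + rng.uniform(1.0, 4.0), 2)
            quant_truth[f"quant-{i}"] = (lo, hi)
        truth[sid] = {"categorical": cat_truth, "quantitative": quant_truth}

        for _ in range(spec.n_specimens_per_species):
            georef = rng.random() < spec.georef_fraction
            lat = round(rng.uniform(*LAT_RANGE), 4) if georef else None
            lon = round(rng.uniform(*LON_RANGE), 4) if georef else None
            gathering = GatheringEvent(
                collectors=[f"Collector {rng.randint(1, 5)}"],
                field_number=str(rng.randint(100, 9999)),
                date=PartialDate(rng.randint(1950, 2015), rng.randint(1, 12)),
                country="Synthetica",
                locality_text=f"locality {rng.randint(1, 99)}",
                latitude=lat,
                longitude=lon,
            )
            fu = create_field_unit(store, gathering, publish=rng.random() < 0.5)
            parent = fu.unit_id
            chain_units = {}
            for step, kind in enumerate(spec.derivative_chain):
                cu = None
                if kind == "specimen":
                    accession += 1
                    cu = CollectionUnit("B", f"B-{accession}")
                du = derive(
                    store,
                    parent,
                    kind,
                    event_type={
                        "specimen": "accessioning",
                        "tissue_sample": "tissue_sampling",
                        "dna_sample": "dna_extraction",
                    }.get(kind, "other"),
                    collection_unit=cu,
                )
                chain_units[kind] = du
                parent = du.unit_id
            if spec.with_sequence and spec.derivative_chain:
                seq = "".join(rng.choice("ACGT") for _ in range(spec.sequence_length))
                derive(store, parent, "media", event_type="sequencing",
                       payload={"content": "trace file"})
                derive(
                    store,
                    parent,
                    "sequence",
                    event_type="sequencing",
                    payload={"sequence": seq, "marker": "ITS"},
                )
            assign_taxon(
                store,
                fu.unit_id,
                sid,
                determiner=f"Collector {rng.randint(1, 5)}",
                date=PartialDate(rng.randint(2010, 2015), rng.randint(1, 12)),
            )
            subject = chain_units.get("specimen", fu)
            desc = SpecimenDescription(subject_unit_id=subject.unit_id, charset_id=charset.set_id)
            for char_id, subset in cat_truth.items():
                exhibited = [s for s in subset if rng.random() < 0.7]
                if not exhibited:
                    exhibited = [rng.choice(subset)]
                record_categorical(desc, charset, char_id, exhibited)
            for char_id, (lo, hi) in quant_truth.items():
                values = [
                    round(rng.uniform(lo, hi), 6)
                    for _ in range(spec.measurements_per_specimen)
                ]
                record_quantitative(desc, charset, char_id, values=values)
            link_description(store, desc, subject.unit_id)

        for area in leaf_areas:
            if rng.random() < spec.occurrence_density:
                status = rng.choices(
                    store.status_priority.statuses, weights=[8, 2, 2, 1, 1, 1]
                )[0]
                store.occurrence_records.append(
                    OccurrenceRecord(taxon_id=sid, area_id=area, status=status, source="fixture")
                )

    sidecar = {
        "spec": asdict(spec),
        "species": truth,
        "species_ids": species_ids,
        "leaf_areas": leaf_areas,
        "charset_id": charset.set_id,
    }
    return store, sidecar
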