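import copy

import pytest

from samplegraph.core import (
    Determination,
    FieldUnit,
    GatheringEvent,
    NotFoundError,
    PartialDate,
    Store,
    ValidationError,
    validate_store,
)
from samplegraph.hierarchy import (
    ascii_tree,
    assign_taxon,
    create_field_unit,
    derive,
    detach_to_new_field_unit,
    effective_determination,
    retract_determination,
    root_of,
    subtree_unit_ids,
)

from conftest import (
    add_specimen,
    brute_effective,
    brute_root,
    random_derivative_tree,
)


class TestCreateFieldUnit:
    def test_gathering_attached(self, store):
        fu = create_field_unit(store, GatheringEvent(latitude=52.45, longitude=13.30))
        assert store.units[fu.unit_id].gathering.latitude == 52.45

    def test_invalid_coordinates_rejected(self, store):
        with pytest.raises(ValidationError, match="latitude"):
            create_field_unit(store, GatheringEvent(latitude=95.0, longitude=0.0))

    def test_identical_gatherings_distinct_ids(self, store):
        a = create_field_unit(store, GatheringEvent(country="ES"))
        b = create_field_unit(store, GatheringEvent(country="ES"))
        assert a.unit_id != b.unit_id


class TestDerive:
    def test_full_chain(self, store):
        """field unit -> specimen -> tissue -> DNA -> {trace media, sequence}"""
        fu = create_field_unit(store, GatheringEvent())
        sp = derive(store, fu.unit_id, "specimen")
        ti = derive(store, sp.unit_id, "tissue_sample")
        dna = derive(store, ti.unit_id, "dna_sample")
        derive(store, dna.unit_id, "media")
        seq = derive(store, dna.unit_id, "sequence", payload={"sequence": "ACGT"})
        assert len(store.units) == 6
        assert root_of(store, seq.unit_id) is fu
        assert len(store.derivation_events) == 5

    def test_intermediate_levels_may_be_skipped(self, store):
        fu = create_field_unit(store, GatheringEvent())
        sp = derive(store, fu.unit_id, "specimen")
        seq = derive(store, sp.unit_id, "sequence", payload={"sequence": "ACGT"})
        assert seq.parent_id == sp.unit_id

    def test_unknown_parent(self, store):
        with pytest.raises(NotFoundError):
            derive(store, "no-such-id", "tissue_sample")

    def test_non_iupac_sequence_rejected(self, store):
        fu = create_field_unit(store, GatheringEvent())
        with pytest.raises(ValidationError):
            derive(store, fu.unit_id, "sequence", payload={"sequence": "ACGT99"})


class TestRootOf:
    def test_field_unit_is_its_own_root(self, store):
        fu = create_field_unit(store, GatheringEvent())
        assert root_of(store, fu.unit_id) is fu

    def test_matches_brute_force_on_random_trees(self, rng):
        store = Store()
        for _ in range(100):
            random_derivative_tree(store, rng, max_nodes=20)
        for uid in store.units:
            assert root_of(store, uid) is brute_root(store, uid)

    def test_root_is_shared_by_all_tree_nodes(self, rng):
        store = Store()
        fu, ids = random_derivative_tree(store, rng, max_nodes=30)
        assert {root_of(store, uid).unit_id for uid in ids} == {fu.unit_id}


class TestTaxonAssignmentInheritance:
    def test_assignment_on_root_reaches_every_derivative(self, store):
        fu, _ = add_specimen(store, chain=("specimen", "tissue_sample", "dna_sample"))
        assign_taxon(store, fu.unit_id, "sp1")
        for uid in subtree_unit_ids(store, fu.unit_id):
            det = effective_determination(store, uid)
            assert det is not None and det.taxon_id == "sp1"

    def test_assignment_on_derivative_reaches_field_unit_and_siblings(self, store):
        fu = create_field_unit(store, GatheringEvent())
        sp = derive(store, fu.unit_id, "specimen")
        sibling = derive(store, fu.unit_id, "specimen")
        dna = derive(store, sp.unit_id, "dna_sample")
        assign_taxon(store, dna.unit_id, "sp2")
        for uid in (fu.unit_id, sp.unit_id, sibling.unit_id, dna.unit_id):
            assert effective_determination(store, uid).taxon_id == "sp2"

    def test_history_preserved_in_order(self, store):
        fu, _ = add_specimen(store)
        assign_taxon(store, fu.unit_id, "sp1")
        assign_taxon(store, fu.unit_id, "sp2")
        history = store.determinations[fu.unit_id]
        assert [d.taxon_id for d in history] == ["sp1", "sp2"]
        assert [d.is_current for d in history] == [False, True]

    def test_newer_dated_determination_wins_everywhere(self, store):
        fu = create_field_unit(store, GatheringEvent())
        sp = derive(store, fu.unit_id, "specimen")
        store.determinations[fu.unit_id] = [
            Determination(taxon_id="sp1", date=PartialDate(2001), is_current=True,
                          seq=store.next_det_seq())
        ]
        store.determinations[sp.unit_id] = [
            Determination(taxon_id="sp2", date=PartialDate(2014), is_current=True,
                          seq=store.next_det_seq())
        ]
        for uid in (fu.unit_id, sp.unit_id):
            assert effective_determination(store, uid).taxon_id == "sp2"
            assert effective_determination(store, uid) is brute_effective(store, uid)

    def test_undetermined_tree_returns_none(self, store):
        fu, _ = add_specimen(store)
        assert effective_determination(store, fu.unit_id) is None

    def test_matches_brute_force_on_random_stores(self, store, rng):
        taxa = ["sp1", "sp2", "sp3", "gen1"]
        for _ in range(30):
            fu, ids = random_derivative_tree(store, rng, max_nodes=15)
            for uid in rng.sample(ids, k=rng.randint(0, min(3, len(ids)))):
                assign_taxon(store, uid, rng.choice(taxa))
        for uid in store.units:
            assert effective_determination(store, uid) is brute_effective(store, uid)

    def test_effective_constant_across_tree(self, store, rng):
        fu, ids = random_derivative_tree(store, rng, max_nodes=25)
        assign_taxon(store, rng.choice(ids), "sp3")
        dets = {effective_determination(store, uid).taxon_id for uid in ids}
        assert dets == {"sp3"}

    def test_assign_then_retract_is_reversible(self, store):
        fu, _ = add_specimen(store, taxon_id="sp1", chain=("specimen", "dna_sample"))
        before = copy.deepcopy(store.determinations)
        assign_taxon(store, fu.unit_id, "sp2")
        retract_determination(store, fu.unit_id)
        # the pre-existing sp1 determination was demoted; effective view restores it
        for d in store.determinations[fu.unit_id]:
            d.is_current = d.taxon_id == "sp1"
        assert {u: [x.taxon_id for x in ds] for u, ds in store.determinations.items()} == {
            u: [x.taxon_id for x in ds] for u, ds in before.items()
        }


class TestDetach:
    def test_epiphyte_split_shares_gathering(self, store):
        """Host plant and epiphytic lichen collected together, then separated."""
        fu = create_field_unit(store, GatheringEvent(country="PE", latitude=-9.5, longitude=-77.0))
        host = derive(store, fu.unit_id, "specimen")
        lichen = derive(store, fu.unit_id, "specimen")
        assign_taxon(store, fu.unit_id, "sp1")
        new_fu = detach_to_new_field_unit(store, lichen.unit_id)
        assert isinstance(new_fu, FieldUnit)
        assert new_fu.gathering.country == "PE"
        assert new_fu.gathering.latitude == -9.5
        assert root_of(store, lichen.unit_id) is new_fu
        assert root_of(store, host.unit_id) is fu
        # inherited determination does not travel to the new hierarchy
        assert effective_determination(store, lichen.unit_id) is None
        assert effective_determination(store, host.unit_id).taxon_id == "sp1"

    def test_local_determinations_travel(self, store):
        fu = create_field_unit(store, GatheringEvent())
        sp = derive(store, fu.unit_id, "specimen")
        assign_taxon(store, sp.unit_id, "sp2")
        detach_to_new_field_unit(store, sp.unit_id)
        assert effective_determination(store, sp.unit_id).taxon_id == "sp2"

    def test_gathering_override(self, store):
        fu = create_field_unit(store, GatheringEvent(country="DE", locality_text="Berlin"))
        media = derive(store, fu.unit_id, "media")
        new_fu = detach_to_new_field_unit(store, media.unit_id, {"locality_text": "on host bark"})
        assert new_fu.gathering.country == "DE"
        assert new_fu.gathering.locality_text == "on host bark"

    def test_cannot_detach_root(self, store):
        fu = create_field_unit(store, GatheringEvent())
        with pytest.raises(ValidationError):
            detach_to_new_field_unit(store, fu.unit_id)

    def test_conserves_units_and_validity(self, store, rng):
        fu, ids = random_derivative_tree(store, rng, max_nodes=20)
        derived = [i for i in ids if i != fu.unit_id]
        if not derived:
            derived = [derive(store, fu.unit_id, "specimen").unit_id]
        n_before = len(store.units)
        target = rng.choice(derived)
        new_fu = detach_to_new_field_unit(store, target)
        assert len(store.units) == n_before + 1  # only the new field unit appeared
        assert validate_store(store).ok
        assert brute_root(store, target) is new_fu


class TestAsciiTree:
    def test_flags_units_with_character_data(self, store):
        fu, specimen = add_specimen(store, taxon_id="sp1", states={"blue"})
        text = ascii_tree(store, fu.unit_id)
        assert f"specimen:{specimen.unit_id} [+data]" in text
        assert "Campanula alpina" in text
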