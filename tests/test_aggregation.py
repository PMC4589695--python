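import copy

import pytest

from samplegraph.aggregation import (
    AreaTree,
    DEFAULT_STATUS_PRIORITY,
    OccurrenceRecord,
    aggregate_categorical,
    aggregate_distribution,
    aggregate_quantitative,
    aggregate_taxon,
    collect_occurrence_points,
    render_description,
)
from samplegraph.characters import (
    AggregatedQuantitative,
    QuantitativeSummary,
    TaxonDescription,
)
from samplegraph.core import NotFoundError, ValidationError
from samplegraph.fixtures import FixtureSpec, generate_store
from conftest import add_specimen, brute_effective, make_charset


class TestAggregateCategorical:
    def test_union_with_support_counts(self):
        entries = [("u1", {"blue"}), ("u2", {"blue", "violet"}), ("u3", {"white"})]
        assert aggregate_categorical(entries) == {"blue": 2, "violet": 1, "white": 1}

    def test_singleton_equals_specimen_data(self):
        assert aggregate_categorical([("u1", {"blue"})]) == {"blue": 1}

    def test_empty(self):
        assert aggregate_categorical([]) == {}

    def test_inputs_unchanged(self):
        states = {"blue", "violet"}
        entries = [("u1", states)]
        before = copy.deepcopy(entries)
        aggregate_categorical(entries)
        assert entries == before

    def test_vocabulary_violation(self):
        with pytest.raises(ValidationError):
            aggregate_categorical([("u1", {"pink"})], vocabulary=["blue", "white"])

    def test_counts_distinct_specimens_not_entries(self):
        # the same unit scored twice supports a state once
        assert aggregate_categorical([("u1", {"blue"}), ("u1", {"blue"})]) == {"blue": 1}


class TestAggregateQuantitative:
    def test_pool_values_and_ranges(self):
        entries = [
            ("u1", QuantitativeSummary(exact_values=[4.0, 5.0])),
            ("u2", QuantitativeSummary(range_min=3.5, range_max=6.0)),
            ("u3", QuantitativeSummary(exact_values=[5.5])),
        ]
        agg = aggregate_quantitative(entries)
        assert (agg.min, agg.max) == (3.5, 6.0)
        assert agg.mean == pytest.approx(4.8333, abs=1e-4)
        assert (agg.n_values, agg.n_specimens) == (3, 3)

    def test_single_range_has_no_mean(self):
        agg = aggregate_quantitative([("u1", QuantitativeSummary(range_min=2, range_max=3))])
        assert (agg.min, agg.max, agg.mean) == (2, 3, None)

    def test_empty_input_is_absent(self):
        assert aggregate_quantitative([]) is None


def _pooled_oracle(store, taxon_id, charset):
    """Independent flat re-aggregation: scan all descriptions, pool per character."""
    subtree = store.classification.subtree_ids(taxon_id)
    per_char_cat = {}
    per_char_quant = {}
    for d in store.descriptions:
        det = brute_effective(store, d.subject_unit_id)
        if det is None or det.taxon_id not in subtree:
            continue
        for cid, entry in d.entries.items():
            if isinstance(entry, QuantitativeSummary):
                per_char_quant.setdefault(cid, []).append((d.subject_unit_id, entry))
            else:
                per_char_cat.setdefault(cid, []).append((d.subject_unit_id, entry))
    cat = {}
    for cid, pairs in per_char_cat.items():
        counts = {}
        for s in {s for _, states in pairs for s in states}:
            counts[s] = len({u for u, states in pairs if s in states})
        cat[cid] = counts
    quant = {}
    for cid, pairs in per_char_quant.items():
        values = [v for _, s in pairs for v in s.exact_values]
        bounds_lo = [min(s.exact_values + ([s.range_min] if s.range_min is not None else []))
                     for _, s in pairs if s.exact_values or s.range_min is not None]
        bounds_hi = [max(s.exact_values + ([s.range_max] if s.range_max is not None else []))
                     for _, s in pairs if s.exact_values or s.range_max is not None]
        quant[cid] = (
            min(bounds_lo) if bounds_lo else None,
            max(bounds_hi) if bounds_hi else None,
            sum(values) / len(values) if values else None,
            len(values),
            len({u for u, _ in pairs}),
        )
    return cat, quant


def _assert_matches_oracle(store, taxon_id, charset):
    td = aggregate_taxon(store, taxon_id, charset)
    cat, quant = _pooled_oracle(store, taxon_id, charset)
    for cid, counts in cat.items():
        assert td.entries[cid] == counts
    for cid, (lo, hi, mean, n_values, n_specimens) in quant.items():
        e = td.entries[cid]
        assert (e.min, e.max) == (lo, hi)
        if mean is None:
            assert e.mean is None
        else:
            assert abs(e.mean - mean) < 1e-9
        assert (e.n_values, e.n_specimens) == (n_values, n_specimens)
    assert set(td.entries) == set(cat) | set(quant)


class TestAggregateTaxon:
    def test_species_aggregation_matches_per_character_oracle(self, store):
        add_specimen(store, "sp1", states={"blue"}, values=[4.0, 5.0])
        add_specimen(store, "sp1", states={"blue", "violet"}, values=(3.5, 6.0))
        add_specimen(store, "sp1", states={"white"}, values=[5.5])
        _assert_matches_oracle(store, "sp1", store.charsets["cs1"])

    def test_genus_equals_pooled_species_specimens(self, store):
        add_specimen(store, "sp1", states={"blue"}, values=[4.0])
        add_specimen(store, "sp1", states={"violet"}, values=[5.0])
        add_specimen(store, "sp2", states={"white"}, values=(2.0, 3.0))
        _assert_matches_oracle(store, "gen1", store.charsets["cs1"])
        # additivity: genus aggregate equals aggregation over both species' units
        td = aggregate_taxon(store, "gen1", store.charsets["cs1"])
        assert td.entries["c-col"] == {"blue": 1, "violet": 1, "white": 1}
        assert td.entries["c-len"].min == 2.0 and td.entries["c-len"].max == 5.0

    def test_replacement_semantics(self, store):
        charset = store.charsets["cs1"]
        add_specimen(store, "sp1", states={"blue"})
        aggregate_taxon(store, "sp1", charset)
        add_specimen(store, "sp1", states={"blue"})
        aggregate_taxon(store, "sp1", charset)
        aggregated = [t for t in store.taxon_descriptions
                      if t.is_aggregated and t.taxon_id == "sp1"]
        assert len(aggregated) == 1
        assert aggregated[0].entries["c-col"] == {"blue": 2}

    def test_manual_description_never_overwritten(self, store):
        manual = TaxonDescription(taxon_id="sp1", charset_id="cs1",
                                  entries={"c-col": {"white": 1}}, is_aggregated=False)
        store.taxon_descriptions.append(manual)
        add_specimen(store, "sp1", states={"blue"})
        aggregate_taxon(store, "sp1", store.charsets["cs1"])
        assert manual in store.taxon_descriptions
        assert len(store.taxon_descriptions) == 2

    def test_incompatible_charset_errors_with_offenders(self, store):
        from samplegraph.characters import CharacterDef, CharacterSet, SpecimenDescription
        bad = CharacterSet("cs-bad", [
            CharacterDef("c-col", "corolla colour", "categorical", states=["red", "black"]),
        ])
        store.charsets["cs-bad"] = bad
        fu, specimen = add_specimen(store, "sp1")
        d = SpecimenDescription(subject_unit_id=specimen.unit_id, charset_id="cs-bad",
                                entries={"c-col": frozenset({"red"})})
        store.descriptions.append(d)
        with pytest.raises(ValidationError, match=specimen.unit_id):
            aggregate_taxon(store, "sp1", store.charsets["cs1"])

    def test_unknown_taxon(self, store):
        with pytest.raises(NotFoundError):
            aggregate_taxon(store, "nope", store.charsets["cs1"])

    def test_provenance_lists_contributing_units(self, store):
        fu, specimen = add_specimen(store, "sp1", states={"blue"})
        td = aggregate_taxon(store, "sp1", store.charsets["cs1"])
        assert td.provenance["c-col"] == [specimen.unit_id]

    def test_additivity_on_generated_store(self):
        store, sidecar = generate_store(FixtureSpec(seed=3, n_genera=2,
                                                    n_species_per_genus=3,
                                                    n_specimens_per_species=6))
        charset = store.charsets[sidecar["charset_id"]]
        for taxon_id in store.classification.nodes:
            _assert_matches_oracle(store, taxon_id, charset)


def _area_tree():
    t = AreaTree()
    t.add("A", "Region A", None)
    t.add("A1", "Subarea 1", "A")
    t.add("A2", "Subarea 2", "A")
    return t


class TestDistributionEngine:
    def test_priority_resolves_conflicts(self, store):
        records = [
            OccurrenceRecord("sp1", "A1", "native"),
            OccurrenceRecord("sp2", "A2", "cultivated"),
        ]
        status = aggregate_distribution("gen1", "A", records, store.classification,
                                        _area_tree(), DEFAULT_STATUS_PRIORITY)
        assert status == "native"

    def test_singleton(self, store):
        records = [OccurrenceRecord("sp1", "A", "introduced")]
        assert aggregate_distribution("sp1", "A", records, store.classification,
                                      _area_tree()) == "introduced"

    def test_no_matching_records(self, store):
        records = [OccurrenceRecord("sp3", "A1", "native")]
        assert aggregate_distribution("gen1", "A2", records, store.classification,
                                      _area_tree()) is None

    def test_unlisted_status_rejected(self, store):
        records = [OccurrenceRecord("sp1", "A", "endemic")]
        with pytest.raises(ValidationError):
            aggregate_distribution("sp1", "A", records, store.classification, _area_tree())

    def test_order_independence_and_monotonicity(self, store, rng):
        tree = _area_tree()
        taxa = list(store.classification.nodes)
        areas = list(tree.areas)
        statuses = DEFAULT_STATUS_PRIORITY.statuses
        records = [
            OccurrenceRecord(rng.choice(taxa), rng.choice(areas), rng.choice(statuses))
            for _ in range(40)
        ]
        base = aggregate_distribution("fam", "A", records, store.classification, tree)
        for _ in range(5):
            shuffled = records[:]
            rng.shuffle(shuffled)
            assert aggregate_distribution("fam", "A", shuffled, store.classification,
                                          tree) == base
        # adding a record can only raise (or keep) the priority
        extra = records + [OccurrenceRecord("sp1", "A1", rng.choice(statuses))]
        after = aggregate_distribution("fam", "A", extra, store.classification, tree)
        assert DEFAULT_STATUS_PRIORITY.index(after) <= DEFAULT_STATUS_PRIORITY.index(base)


class TestOccurrencePoints:
    def test_only_georeferenced_units_counted(self, store):
        add_specimen(store, "sp1", lat=52.0, lon=13.0)
        add_specimen(store, "sp1", lat=48.1, lon=11.5)
        add_specimen(store, "sp1")  # no coordinates
        assert len(collect_occurrence_points(store, "sp1")) == 2

    def test_genus_is_union_of_species(self, store):
        add_specimen(store, "sp1", lat=52.0, lon=13.0)
        add_specimen(store, "sp2", lat=48.1, lon=11.5)
        genus = collect_occurrence_points(store, "gen1")
        flat = collect_occurrence_points(store, "sp1") + collect_occurrence_points(store, "sp2")
        assert sorted(genus) == sorted(flat)

    def test_empty_taxon(self, store):
        assert collect_occurrence_points(store, "sp3") == []

    def test_deterministic_order(self, store):
        for _ in range(5):
            add_specimen(store, "sp1", lat=50.0, lon=10.0)
        pts = collect_occurrence_points(store, "sp1")
        assert pts == sorted(pts, key=lambda p: p[2])


class TestRenderDescription:
    def test_reference_sentence(self):
        cs = make_charset()
        td = TaxonDescription(
            taxon_id="sp1",
            charset_id="cs1",
            entries={
                "c-col": {"blue": 2, "violet": 1},
                "c-len": AggregatedQuantitative(
                    min=3.5, max=6.0, mean=4.8333333, n_values=3, n_specimens=3
                ),
            },
        )
        assert render_description(td, cs) == (
            "Corolla colour blue, violet. Petal length 3.5–6.0 mm (mean 4.83, n = 3)."
        )

    def test_empty_description(self):
        td = TaxonDescription(taxon_id="sp1", charset_id="cs1")
        assert render_description(td, make_charset()) == ""

    def test_deterministic(self, store):
        add_specimen(store, "sp1", states={"blue", "white"}, values=[4.0])
        td = aggregate_taxon(store, "sp1", store.charsets["cs1"])
        a = render_description(td, store.charsets["cs1"])
        b = render_description(td, store.charsets["cs1"])
        assert a == b and a
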