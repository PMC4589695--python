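# samplegraph

Specimen-based data management for systematic biology: persistent linkage
of character data to individual preserved specimens, reversible taxon
assignment, and automatic re-aggregation of specimen-based character and
occurrence data into taxon characterizations at any rank.

## The problem

A taxon characterization ("description") is always derived from a limited
set of sampled individuals. Whenever a new specimen is examined or a taxon
is re-delimited, the characterization should change with it — but common
practice links character data only collectively to a taxon, so every
revision means re-examining specimens. `samplegraph` keeps every datum
anchored to the individual unit it was measured on, which makes taxon
characterizations *additive* and *reproducible*: they can be regenerated at
any time from the current sample set, and every aggregated value is
traceable back to specimens.

The package is a library plus a thin `sg` command line for taxonomists,
collection managers and biodiversity informaticians who need:

* **Derivative hierarchies** — every gathering is a *field unit*, the
  obligatory root of a rooted tree of derivatives (specimen → tissue
  sample → DNA isolate → trace file / consensus sequence; intermediate
  levels may be skipped or lost without breaking rootedness).
* **Inherited, reversible determinations** — a taxon assignment made on any
  unit is effective for the entire hierarchy. Inheritance is computed as a
  view, never copied, so retracting an assignment reverts the whole tree.
* **Additive aggregation** — categorical character data aggregate by
  *appending* (state sets are unioned with per-specimen support counts,
  inputs unchanged); quantitative data aggregate by *merging* into
  statistics. For a taxon *t* with contributing specimens *S(t)* (its own
  plus those of all subtaxa) and measurements *x*:

  - categorical: support(state) = |{s ∈ S(t) : s exhibits state}|
  - quantitative: min/max over all exact values and label ranges,
    mean = arithmetic mean of pooled exact values, with n_values and
    n_specimens

  Aggregating a genus directly from its specimens equals aggregating it
  from its species (additivity); re-running an aggregation *replaces* the
  previous result for that (taxon, character set).
* **An occurrence transmission engine** — the status of a taxon in an area
  is the highest-priority status among all records of the taxon or its
  subtaxa in the area or its subareas (default priority: native >
  naturalized > introduced > cultivated > present-doubtful > absent).
* **Core-copy / enrichment versioning** — imported provider records keep an
  immutable snapshot under the provider's identifier; edits live in an
  ordered enrichment layer with field-level diff, revert-by-compensation
  and three-way resynchronization against fresh provider snapshots.
* **Exchange formats** — Darwin Core occurrence CSV, a documented ABCD
  2.x-style XML subset (whole hierarchies, with character data in
  `MeasurementsOrFacts`), character matrices as CSV + JSON descriptor,
  Nexus, GeoJSON dot maps and FASTA.

## Worked example

```python
from samplegraph import *

store = Store()
store.classification = Classification(("family", "genus", "species"))
store.classification.add(TaxonNode("fam", "Campanulaceae", "family", None))
store.classification.add(TaxonNode("gen", "Campanula", "genus", "fam"))
store.classification.add(TaxonNode("sp", "Campanula alpina", "species", "gen"))

charset = CharacterSet("floral", [
    CharacterDef("col", "corolla colour", "categorical",
                 states=["blue", "violet", "white"]),
    CharacterDef("len", "petal length", "quantitative", unit_label="mm"),
])
store.charsets["floral"] = charset

# three gatherings, each with one specimen scored on the charset
for states, values, rng in [({"blue"}, [4.0, 5.0], None),
                            ({"blue", "violet"}, None, (3.5, 6.0)),
                            ({"white"}, [5.5], None)]:
    fu = create_field_unit(store, GatheringEvent(collectors=["Kilian"],
                                                 country="AT",
                                                 latitude=47.2, longitude=11.4))
    specimen = derive(store, fu.unit_id, "specimen", event_type="accessioning")
    assign_taxon(store, fu.unit_id, "sp", determiner="N. Kilian")
    desc = SpecimenDescription(subject_unit_id=specimen.unit_id, charset_id="floral")
    record_categorical(desc, charset, "col", states)
    if values:
        record_quantitative(desc, charset, "len", values=values)
    else:
        record_quantitative(desc, charset, "len", range_min=rng[0], range_max=rng[1])
    link_description(store, desc, specimen.unit_id)

td = aggregate_taxon(store, "sp", charset)
print(td.entries["col"])
print(render_description(td, charset))
```

prints

```
{'blue': 2, 'violet': 1, 'white': 1}
Corolla colour blue, violet, white. Petal length 3.5–6.0 mm (mean 4.83, n = 3).
```

`blue` has support 2 because two of the three specimens exhibit it; the
petal-length minimum 3.5 comes from the second specimen's label range, the
mean 4.83 from the three pooled exact measurements (4.0, 5.0, 5.5). Running
`aggregate_taxon(store, "gen", charset)` yields the identical entries — the
genus contains only this species, and aggregation is additive. After moving
specimens to another species or uniting taxa, re-running `aggregate_taxon`
replaces the stored description with one matching the new delimitation.

The same workflow from the shell:

```bash
sg fixtures --seed 1 --out demo/        # synthetic store + DwC/matrix exports
sg aggregate --taxon t-sp-0-0 --charset cs-fixture
sg distribution --taxon t-family --area area-root
sg export --format nexus --out demo/matrix.nex
```

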