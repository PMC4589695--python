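# Methods

## Data model

The store is an in-memory container of plain domain objects, persisted as
one JSON document. Its invariant core:

* **GatheringEvent** — collectors, field number, partial ISO date, country,
  locality, WGS84 decimal-degree coordinates (both present or both absent;
  latitude ∈ [−90, 90], longitude ∈ [−180, 180]), uncertainty in metres
  (≥ 0), elevation in metres.
* **FieldUnit** — one gathering of one (possibly undetermined) taxon; the
  obligatory root of a derivative hierarchy. Units representing taxa that
  turn out to be outside the gathering's scope (epiphytes, parasites,
  multi-taxon gatherings) are split off with
  `detach_to_new_field_unit`, which copies the gathering data — the
  collecting event really was shared — and re-parents the subtree.
* **DerivedUnit** — specimen, tissue sample, DNA isolate, media, sequence
  or other; any kind may parent any kind, so lost or never-recorded
  intermediates are simply skipped without placeholder nodes. Sequence
  payloads are restricted to IUPAC nucleotide symbols.
* **Determination** — stored on the unit where it was made; at most one is
  current per unit. The determination *effective* for a unit is the latest
  current determination anywhere in its hierarchy (ties on equal or absent
  dates break by insertion order, latest wins). Because inheritance is a
  computed view rather than a copy, retraction is one deletion and the
  whole hierarchy reverts — partial dates compare by their earliest
  possible interpretation.
* **Classification** — one rooted tree per store; child rank strictly below
  parent rank (the check can be disabled for rank-less working
  classifications). Identifiers everywhere are UUIDv4 strings minted at
  creation and never reused; provider identifiers are kept separately by
  the versioning layer.

`validate_store` re-checks every structural invariant (dangling parents,
cycles, duplicate accessions, multiple current determinations, vocabulary
violations) and returns a report instead of raising, so a store can always
be inspected.

## Aggregation semantics

Specimen descriptions bind entries of one character set to exactly one
unit. A character is categorical (ordered state vocabulary, ≥ 2 states,
polymorphism allowed) or quantitative (exact values and/or a label range,
with a unit label and an optional sample size). An absent entry means "not
scored"; recording an empty state set deletes the entry. "Not applicable"
is not modelled separately.

`aggregate_taxon(taxon, charset)` collects the descriptions of every unit
whose effective determination lies in the taxon's subtree, then per
character:

* categorical (*appending*): union of state sets; the support count of a
  state is the number of distinct contributing units exhibiting it; inputs
  are never mutated.
* quantitative (*merging*): min and max over all exact values and label
  range endpoints; mean = unweighted arithmetic mean of pooled exact
  values only. Label-derived sample sizes are stored verbatim but do not
  weight the mean — weighting by unverifiable label statistics would
  double-count; ranges therefore contribute to the extremes only, and the
  mean is absent when no exact values exist.

Higher taxa are recomputed from specimen level rather than from child
taxon descriptions. Under additivity the two are mathematically equal
(the property suite enforces this), but recomputation can never see a
stale child cache. Each run replaces the previous aggregated description
for that (taxon, character set) and stores per-character provenance (the
contributing unit ids); manually entered taxon descriptions are never
overwritten.

Character sets are compatible when no shared character id differs in kind,
state vocabulary or measurement unit; aggregation refuses incompatible
contributors, naming the offending units. Unit mismatches between
quantitative characters are treated as incompatibility rather than
auto-converted — unit conversion is considered a deliberate editing step,
not something to guess during aggregation. State labels match
case-sensitively by exact string; ontology-backed matching is out of
scope.

The occurrence **transmission engine** is a pure maximum: candidate
records are those whose taxon lies in the query taxon's subtree and whose
area lies in the query area's subtree; the result is the candidate status
of highest priority, `None` without candidates. The default vocabulary
[native > naturalized > introduced > cultivated > present-doubtful >
absent] is fully configurable; priorities are a strict order, so ties
cannot occur. The construction makes the engine order-independent and
monotone (adding a record can only raise or keep the result's priority).

Natural-language rendering is deterministic: characters in character-set
order, categorical states by descending support (ties keep vocabulary
order), quantitative entries as `min–max unit (mean m, n = k)` with the
mean rounded to two decimals; unscored characters are omitted.

## Restructuring and audit

`move_taxon` and `rename_taxon` never touch specimen links. `unite_taxa`
re-points determinations, descriptions and occurrence records to the
target, appends the source's accepted name to the target's synonymy,
re-parents the source's children and keeps the dissolved name string in
each affected determination's note. `reassign_specimens` validates all
preconditions before mutating. Every restructuring writes append-only
audit entries with the former placement; `replay_audit` applies the log to
the initial classification and placement map and reproduces the current
state, which the tests use as the completeness criterion.

## Versioning

An imported provider record is a **core copy** (immutable snapshot under
the provider's record identifier; immutability is hash-checked in the
tests) plus an ordered **enrichment** layer of field-level edits with the
six editing categories (label completion, external source addition,
standardization, parsing correction, georeferencing, typification).
Versions are commit points; `materialize(v)` is always recomputed as
base + edits up to the commit. Field paths are flat dotted keys, which
keeps diffs well-defined; nested exchange structures are flattened
deterministically on import.

Revert appends compensating edits instead of truncating history; a
compensating edit reuses the category of the last edit it undoes
(standardization when the field was never edited locally), since the
category vocabulary has no dedicated "revert" class. Resynchronization
stores the fresh provider snapshot as a new core copy and replays the net
local enrichment on it with a per-field three-way merge: provider
unchanged → edit replayed; provider made the same change → edit dropped
as redundant; both changed differently → conflict, listed in the report,
provider value materialized and the local edit parked. Diffs are
field-level only.

## Exchange formats

* **Darwin Core CSV** — one occurrence row per field unit with its first
  specimen; `occurrenceID` is preserved as the provider record id. Import
  is row-tolerant: malformed rows go to an error report, valid rows are
  kept. UTF-8, comma-delimited, RFC 4180 quoting.
* **ABCD-style XML** — a documented subset dialect (fixed namespace
  `urn:samplegraph:abcd-subset:1.0`), not full schema coverage: one `Unit`
  per field unit, derivatives as flat elements referencing parents by id
  (arbitrary depth), determination histories, and character data atomized
  into the `MeasurementsOrFacts` container (one text per component:
  state label, exact value, `min–max unit`, `n=k`). Units backed by a
  versioned record carry an `EditTrail` distinguishing original from
  edited values. Descriptions re-imported from the container are merged
  per (unit, character set).
* **Matrix CSV + JSON** — rows keyed by unit id, cells encode state sets
  (`|`-joined), exact values, ranges and sample sizes; the JSON descriptor
  defines the character set.
* **Nexus** — categorical columns only, symbols in vocabulary order,
  missing `?`, polymorphism `{..}`; quantitative characters are excluded
  with a logged notice (they have no standard symbol coding).
* **GeoJSON / FASTA** — dot-map points in `[longitude, latitude]` order
  (Darwin Core columns are latitude then longitude; both stated explicitly
  to preclude the classic axis swap); FASTA headers
  `>unit_id|taxon_name|marker`, 80-column wrap.
* Exports honour the publish flag when `publish_only` is set; the flag
  defaults to false so nothing is published accidentally.

Inherited determinations are exported only as stored (unit-level) records
plus computed attributes; they are never materialized onto each
derivative.

## Synthetic data

The fixtures module emulates a small revisionary study: a family with
`n_genera × n_species_per_genus` species, per-species gatherings with
coordinates uniform in a central-European bounding box (lat 40–55,
lon 5–15), full derivative chains (specimen → tissue → DNA → trace media +
consensus sequence), specimen descriptions drawn from per-species ground
truth (categorical states sampled from a species-specific subset with
inclusion probability 0.7, at least one state; quantitative values uniform
on the species' true range), and occurrence records over a nested area
tree. Defaults (2 genera × 2 species × 5 specimens, 2 categorical
characters with 3 states, 1 quantitative character, 80 % georeferenced,
occurrence density 0.5) are sized so a whole store remains
human-inspectable; recovery checks scale specimens up per test. All draws
flow through one seeded generator — identical seeds give byte-identical
serialized stores — and the ground truth is written to a sidecar so tests
never re-derive it from the store.

What the generator does *not* emulate: label OCR noise, geographic
structure beyond a bounding box, missing-data patterns, determiner
disagreement, or real nomenclature. Passing tests therefore demonstrate
the correctness of the data management and aggregation logic, not
robustness to dirty real-world collection data.

## Problem sizes and verification

The property suite and the acceptance script use: 1000 random derivative
trees of up to 50 nodes for rootedness/inheritance against naive
whole-tree scans; a 4-rank, 13-taxon, 72-specimen store for additivity at
every classification node (exact for counts and extremes, mean agreement
to 1e−9); 500 random occurrence instances (≤ 20 taxa, ≤ 30 areas, ≤ 200
records) against exhaustive search; 500 random edit sequences (≤ 20
edits) against patch application; 100 random stores per format for
round-trips; and parameter recovery at 200 specimens/species (uniform
truth [3, 6]; expected extreme gap (b−a)/(n+1) = 0.015, asserted with a
10× slack bound of 0.15) and 30 specimens/species over 20 seeds for
categorical subsets (≥ 95 % of (species, character) pairs). Everything is
seeded and runs in seconds on one CPU.

## Known limitations

* One classification and one area tree per store; no concurrent taxon
  concept networks.
* No nomenclatural rule checking (ICN/ICZN) and no homotypic grouping of
  synonyms.
* Character data below the unit level (single structure instances) are not
  modelled.
* Statistical aggregation is limited to min/max/mean/n by design; anything
  richer belongs downstream.
* The annotated-export round trip cannot distinguish a field whose
  original value is `None` from an absent field; exchange values are
  expected to be strings.
* ABCD subset: reading merges multiple descriptions of the same (unit,
  character set) into one; the edit trail is export-only.
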