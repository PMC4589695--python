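import random

import pytest

from samplegraph.core import ValidationError
from samplegraph.versioning import (
    MISSING,
    apply_edit,
    apply_patch,
    commit_version,
    diff_versions,
    export_annotated,
    import_annotated,
    import_core_copy,
    materialize,
    refresh_core_copy,
    revert_to,
)


@pytest.fixture
def record(store):
    return import_core_copy(
        store, "BGBM", "B-2001", {"collector": "Mill.", "country": "ES"}
    )


class TestImport:
    def test_version_one_is_identity(self, record):
        assert materialize(record, 1) == {"collector": "Mill.", "country": "ES"}

    def test_duplicate_import_conflicts(self, store, record):
        with pytest.raises(ValidationError):
            import_core_copy(store, "BGBM", "B-2001", {"country": "DE"})

    def test_zero_edit_commit_has_empty_diff(self, record):
        commit_version(record)
        assert diff_versions(record, 1, 2) == []


class TestApplyEdit:
    def test_edit_layers_over_immutable_core(self, record):
        apply_edit(record, "country", "Spain", "standardization", author="NK")
        assert materialize(record)["country"] == "Spain"
        assert record.current_base.snapshot["country"] == "ES"

    def test_georeferencing_adds_fields_only_in_enrichment(self, record):
        apply_edit(record, "decimalLatitude", "40.1", "georeferencing")
        apply_edit(record, "decimalLongitude", "-3.7", "georeferencing")
        assert materialize(record)["decimalLatitude"] == "40.1"
        assert "decimalLatitude" not in record.current_base.snapshot

    def test_successive_edits_keep_both_entries(self, record):
        apply_edit(record, "country", "Espana", "parsing_correction")
        apply_edit(record, "country", "Spain", "standardization")
        assert materialize(record)["country"] == "Spain"
        assert [e.new_value for e in record.pending_edits] == ["Espana", "Spain"]
        assert record.pending_edits[1].old_value == "Espana"

    def test_unknown_category_rejected(self, record):
        with pytest.raises(ValidationError):
            apply_edit(record, "country", "Spain", "vandalism")


class TestDiffRevertPatch:
    def test_single_change_diff(self, record):
        apply_edit(record, "country", "Spain", "standardization")
        commit_version(record)
        changes = diff_versions(record, 1, 2)
        assert [(c.field_path, c.value_a, c.value_b) for c in changes] == [
            ("country", "ES", "Spain")
        ]

    def test_revert_restores_snapshot_exactly(self, record):
        apply_edit(record, "country", "Spain", "standardization")
        apply_edit(record, "habitat", "meadow", "label_completion")
        commit_version(record)
        revert_to(record, 1)
        assert materialize(record) == record.bases[0].snapshot
        # history grows, never shrinks
        assert len(record.pending_edits) == 4

    def test_revert_is_self_inverse_on_materialized_state(self, record):
        apply_edit(record, "country", "Spain", "standardization")
        v2 = commit_version(record)
        apply_edit(record, "collector", "Miller", "standardization")
        pre = materialize(record)
        v3 = commit_version(record)
        revert_to(record, 1)
        revert_to(record, v3.version_id)
        assert materialize(record) == pre

    def test_patch_oracle_on_random_edit_sequences(self, store):
        rng = random.Random(42)
        fields = ["collector", "country", "locality", "habitat", "lat"]
        for case in range(50):
            record = import_core_copy(
                store, "P", f"r{case}",
                {f: f"v{rng.randint(0, 3)}" for f in rng.sample(fields, 3)},
            )
            versions = [1]
            for _ in range(rng.randint(1, 15)):
                if rng.random() < 0.25:
                    apply_edit(record, rng.choice(fields), MISSING, "parsing_correction")
                else:
                    apply_edit(record, rng.choice(fields),
                               f"v{rng.randint(0, 9)}", "standardization")
                if rng.random() < 0.4:
                    versions.append(commit_version(record).version_id)
            vk = versions[-1]
            patched = apply_patch(materialize(record, 1), diff_versions(record, 1, vk))
            assert patched == materialize(record, vk)

    def test_unknown_version(self, record):
        with pytest.raises(ValidationError):
            materialize(record, 99)


class TestCoreCopyImmutability:
    def test_digest_stable_under_all_operations(self, record):
        digest = record.current_base.digest()
        apply_edit(record, "country", "Spain", "standardization")
        commit_version(record)
        revert_to(record, 1)
        snap = record.current_base.snapshot
        snap["country"] = "HACKED"  # mutating the returned copy must not leak
        assert record.current_base.digest() == digest


class TestRefreshCoreCopy:
    def test_provider_unchanged_replays_everything(self, record):
        apply_edit(record, "country", "Spain", "standardization")
        report = refresh_core_copy(record, {"collector": "Mill.", "country": "ES"})
        assert report.clean and report.replayed == ["country"]
        assert materialize(record)["country"] == "Spain"

    def test_identical_provider_fix_drops_redundant_edit(self, record):
        apply_edit(record, "country", "Spain", "standardization")
        report = refresh_core_copy(record, {"collector": "Mill.", "country": "Spain"})
        assert report.clean and report.dropped_redundant == ["country"]
        assert materialize(record)["country"] == "Spain"
        assert record.pending_edits == []

    def test_conflicting_change_parks_local_edit(self, record):
        apply_edit(record, "collector", "Mill. (J.)", "standardization")
        report = refresh_core_copy(record, {"collector": "Miller", "country": "ES"})
        assert report.conflicts == [("collector", "Mill.", "Mill. (J.)", "Miller")]
        assert materialize(record)["collector"] == "Miller"  # provider wins

    def test_three_way_merge_matches_per_field_bruteforce(self, store):
        rng = random.Random(7)
        fields = [f"f{i}" for i in range(6)]
        for case in range(50):
            base = {f: f"b{rng.randint(0, 2)}" for f in fields}
            record = import_core_copy(store, "Q", f"r{case}", base)
            for _ in range(rng.randint(0, 6)):
                apply_edit(record, rng.choice(fields), f"l{rng.randint(0, 2)}",
                           "standardization")
            local = materialize(record)
            new = {
                f: (f"p{rng.randint(0, 2)}" if rng.random() < 0.5 else base[f])
                for f in fields
            }
            report = refresh_core_copy(record, new)
            expect_conflicts = sorted(
                f for f in fields
                if local[f] != base[f] and new[f] != base[f] and new[f] != local[f]
            )
            assert sorted(f for f, *_ in report.conflicts) == expect_conflicts
            # materialized state: provider value on conflicts, local elsewhere
            final = materialize(record)
            for f in fields:
                if f in expect_conflicts or local[f] == base[f] == new[f]:
                    assert final[f] == new[f]
                elif local[f] != base[f]:
                    assert final[f] == local[f]


class TestAnnotatedExport:
    def test_edited_field_shows_both_values(self, record):
        apply_edit(record, "country", "Spain", "standardization", author="NK")
        out = export_annotated(record)
        assert out["fields"]["country"]["original"] == "ES"
        assert out["fields"]["country"]["current"] == "Spain"
        assert out["fields"]["country"]["edits"][0]["category"] == "standardization"
        assert out["fields"]["collector"]["edits"] == []

    def test_unedited_record_has_empty_trail(self, record):
        out = export_annotated(record)
        assert all(v["edits"] == [] for v in out["fields"].values())
        assert {f: v["current"] for f, v in out["fields"].items()} == materialize(record)

    def test_roundtrip_reconstructs_materialized_state(self, record):
        apply_edit(record, "country", "Spain", "standardization")
        apply_edit(record, "habitat", "meadow", "label_completion")
        rebuilt = import_annotated(export_annotated(record))
        assert materialize(rebuilt) == materialize(record)
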