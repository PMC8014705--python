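"""Session semantics: modalities, events, table invariants, browsing."""

import numpy as np
import pytest

from qualiannot import (
    AT_END,
    AnnotationRecord,
    ConfigurationError,
    ImageLocator,
    Measurement,
    Modality,
    Roi,
    SessionConfig,
    UnmappedSlotError,
    UnsupportedOperationError,
    ValidationError,
    add_category,
    advance,
    create_session,
    delete_row,
    record_event,
    shortcut_to_keyword,
)
from qualiannot.annotation_model import BrowseMode


class TestSessionCreation:
    def test_single_session_has_four_category_labels(self, single_config):
        session = create_session(single_config)
        assert session.config.keywords == ("interphase", "prophase", "metaphase", "anaphase")
        assert len(session.table) == 0

    def test_features_session_has_three_feature_columns(self, features_config):
        session = create_session(features_config)
        assert session.config.feature_labels == ("texture", "shape", "pigmentation")

    @pytest.mark.parametrize("modality", [Modality.SINGLE, Modality.MULTI])
    def test_empty_keyword_list_rejected(self, modality):
        with pytest.raises(ConfigurationError):
            SessionConfig(modality, keywords=())

    def test_duplicate_keyword_rejected_and_named(self):
        with pytest.raises(ConfigurationError, match="prophase"):
            SessionConfig(Modality.SINGLE, keywords=("prophase", "prophase"))

    def test_whitespace_trimmed_duplicates_rejected(self):
        with pytest.raises(ConfigurationError):
            SessionConfig(Modality.MULTI, keywords=("a", " a "))

    def test_fingerprint_distinguishes_schemas(self, single_config, one_hot_config):
        assert single_config.fingerprint() != one_hot_config.fingerprint()
        same = SessionConfig(Modality.SINGLE, keywords=single_config.keywords)
        assert same.fingerprint() == single_config.fingerprint()


class TestAddCategory:
    def test_keyword_appended_at_end(self, single_config):
        session = create_session(single_config)
        add_category(session, "telophase")
        assert session.config.keywords[-1] == "telophase"

    def test_prior_multi_rows_read_false_for_new_keyword(self, multi_config):
        session = create_session(multi_config)
        record_event(session, ImageLocator(".", "w.tif"), {"cystic": True})
        record_event(session, ImageLocator(".", "x.tif"), {"normal": True})
        add_category(session, "dead")
        assert all(record.flags["dead"] is False for record in session.table.records)
        assert all(set(record.flags) == set(session.config.keywords)
                   for record in session.table.records)

    def test_duplicate_keyword_rejected(self, single_config):
        session = create_session(single_config)
        with pytest.raises(ConfigurationError):
            add_category(session, "prophase")

    def test_features_modality_unsupported(self, features_config):
        session = create_session(features_config)
        with pytest.raises(UnsupportedOperationError):
            add_category(session, "anything")


class TestRecordEvent:
    def test_single_event_without_roi_appends_one_row(self, single_config):
        session = create_session(single_config)
        records = record_event(session, ImageLocator(".", "m.tif"), "metaphase")
        assert len(records) == 1 and len(session.table) == 1
        assert records[0].category == "metaphase"
        assert records[0].roi_names == ()

    def test_unknown_category_rejected(self, single_config):
        session = create_session(single_config)
        with pytest.raises(ValidationError):
            record_event(session, ImageLocator(".", "m.tif"), "cytokinesis")

    def test_unknown_feature_choice_rejected(self, features_config):
        session = create_session(features_config)
        with pytest.raises(ValidationError):
            record_event(session, ImageLocator(".", "e.tif"),
                         {"texture": "rough", "shape": "circle", "pigmentation": "dark"})

    def test_event_with_k_rois_appends_k_rows_sharing_values(self, features_config):
        session = create_session(features_config)
        rois = [Roi.rectangle(i * 10, 0, 5, 5) for i in range(3)]
        choices = {"texture": "granular", "shape": "ellipse", "pigmentation": "dark"}
        records = record_event(session, ImageLocator(".", "e.tif"), choices, rois=rois)
        assert len(records) == 3 and len(session.table) == 3
        assert all(r.choices == choices for r in records)
        assert len(session.rois) == 3

    def test_roi_property_map_carries_feature_pairs(self, features_config):
        session = create_session(features_config)
        roi = Roi.polygon([(0, 0), (10, 0), (5, 8)], name="embryo")
        record_event(session, ImageLocator(".", "e.tif"),
                     {"texture": "granular", "pigmentation": "dark", "shape": "ellipse"},
                     rois=[roi])
        props = session.rois["embryo"].properties_dict()
        assert props == {"qa.texture": "granular", "qa.shape": "ellipse",
                         "qa.pigmentation": "dark"}

    def test_run_measure_without_pixels_rejected(self):
        config = SessionConfig(Modality.SINGLE, keywords=("a",), run_measure=True)
        session = create_session(config)
        with pytest.raises(ValidationError):
            record_event(session, ImageLocator(".", "a.tif"), "a")

    def test_run_measure_reports_roi_statistics(self):
        config = SessionConfig(
            Modality.SINGLE, keywords=("a",), run_measure=True,
            measure_spec=frozenset({Measurement.MEAN, Measurement.AREA}),
        )
        session = create_session(config)
        pixels = np.arange(100.0).reshape(10, 10)
        roi = Roi.rectangle(0, 0, 2, 2, name="r")
        (record,) = record_event(session, ImageLocator(".", "a.tif"), "a",
                                 rois=[roi], pixels=pixels)
        assert record.measurements["Area"] == 4
        assert record.measurements["Mean"] == pytest.approx(pixels[:2, :2].mean())

    def test_multi_flags_always_cover_full_keyword_set(self, multi_config):
        session = create_session(multi_config)
        (record,) = record_event(session, ImageLocator(".", "w.tif"), {"cystic": True})
        assert set(record.flags) == set(multi_config.keywords)
        assert record.flags["cystic"] is True and record.flags["normal"] is False


class TestDeleteRow:
    def _table_with(self, config, n):
        session = create_session(config)
        for i in range(n):
            record_event(session, ImageLocator(".", f"{i}.tif"), "interphase")
        return session.table

    def test_middle_deletion_preserves_order(self, single_config):
        table = self._table_with(single_config, 3)
        delete_row(table, 1)
        assert [r.image for r in table.records] == ["0.tif", "2.tif"]

    def test_deleting_only_row_empties_table(self, single_config):
        table = self._table_with(single_config, 1)
        delete_row(table, 0)
        assert len(table) == 0

    def test_out_of_range_rejected(self, single_config):
        table = self._table_with(single_config, 3)
        with pytest.raises(IndexError):
            delete_row(table, 5)


class TestShortcuts:
    def test_slots_map_to_keywords_in_button_order(self, single_config):
        for i, keyword in enumerate(single_config.keywords, start=1):
            assert shortcut_to_keyword(single_config, i) == keyword

    def test_slot_one_is_leftmost_button(self, single_config):
        assert shortcut_to_keyword(single_config, 1) == "interphase"

    def test_slot_beyond_keyword_count_unmapped(self, single_config):
        with pytest.raises(UnmappedSlotError):
            shortcut_to_keyword(single_config, 5)

    @pytest.mark.parametrize("slot", [0, 13, -1])
    def test_slot_outside_f_key_range_rejected(self, single_config, slot):
        with pytest.raises(ValidationError):
            shortcut_to_keyword(single_config, slot)


class TestAdvance:
    def test_stack_mode_increments_selected_dimension_only(self):
        config = SessionConfig(Modality.SINGLE, keywords=("a",),
                               browse_mode=BrowseMode.STACK, advance_dimension="t")
        session = create_session(config, stack_sizes={"t": 51})
        nxt = advance(session, ImageLocator.of(".", "s.tif", t=3, z=2))
        assert nxt.slices() == {"t": 4, "z": 2}

    def test_directory_mode_steps_to_next_sorted_file(self):
        config = SessionConfig(Modality.SINGLE, keywords=("a",),
                               browse_mode=BrowseMode.DIRECTORY)
        session = create_session(config, file_listing=["c.tif", "a.tif", "b.tif"])
        nxt = advance(session, ImageLocator(".", "b.tif"))
        assert nxt.image == "c.tif"

    def test_end_of_listing_signals_without_wrapping(self):
        config = SessionConfig(Modality.SINGLE, keywords=("a",),
                               browse_mode=BrowseMode.DIRECTORY)
        session = create_session(config, file_listing=["a.tif", "b.tif", "c.tif"])
        assert advance(session, ImageLocator(".", "c.tif")) is AT_END

    def test_repeated_advance_visits_every_file_once(self):
        files = [f"{c}.tif" for c in "fcadbe"]
        config = SessionConfig(Modality.SINGLE, keywords=("a",),
                               browse_mode=BrowseMode.DIRECTORY)
        session = create_session(config, file_listing=files)
        visited = [session.file_listing[0]]
        locator = ImageLocator(".", visited[0])
        while (locator := advance(session, locator)) is not AT_END:
            visited.append(locator.image)
        assert visited == sorted(files)

    def test_unknown_file_rejected(self):
        config = SessionConfig(Modality.SINGLE, keywords=("a",),
                               browse_mode=BrowseMode.DIRECTORY)
        session = create_session(config, file_listing=["a.tif"])
        with pytest.raises(ValidationError):
            advance(session, ImageLocator(".", "zz.tif"))

    def test_stack_end_signals_at_last_slice(self):
        config = SessionConfig(Modality.SINGLE, keywords=("a",),
                               browse_mode=BrowseMode.STACK, advance_dimension="t")
        session = create_session(config, stack_sizes={"t": 4})
        assert advance(session, ImageLocator.of(".", "s.tif", t=4)) is AT_END


class TestRecordValidation:
    def test_record_needs_exactly_one_value_kind(self):
        with pytest.raises(ValidationError):
            AnnotationRecord(folder=".", image="a.tif")
        with pytest.raises(ValidationError):
            AnnotationRecord(folder=".", image="a.tif", category="x", flags={"x": True})
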