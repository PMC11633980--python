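import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from buscurate.image_model import ScanImage
from buscurate.knowledge_extraction import (Laterality, Orientation,
                                            StubOCRBackend, TextDetection,
                                            extract_fields, extract_text,
                                            load_vocabulary, match_axilla,
                                            match_clock_position, match_distance,
                                            match_laterality, match_measurement,
                                            match_orientation, match_procedural)


class TestLaterality:
    @pytest.mark.parametrize("text,expected", [
        ("LEFT BREAST", Laterality.LEFT),
        ("LT BREAST 10:00", Laterality.LEFT),
        ("RT BREAST 10:00", Laterality.RIGHT),
        ("RIGHT AXILLA", Laterality.RIGHT),
        ("L BREAST", Laterality.LEFT),
        ("R AXILLA", Laterality.RIGHT),
        ("HELLO", Laterality.NONE),
        ("PLATE", Laterality.NONE),       # LT must be its own token
        ("L ALONE", Laterality.NONE),     # bare L needs BREAST/AX context
        ("LEFT AND RIGHT", Laterality.CONFLICT),
    ])
    def test_grammar(self, text, expected):
        assert match_laterality(text) is expected


class TestOrientation:
    @pytest.mark.parametrize("text,expected", [
        ("RAD", Orientation.RAD),
        ("ARAD", Orientation.ARAD),
        ("ANTIRAD", Orientation.ARAD),
        ("ANTI-RAD", Orientation.ARAD),
        ("TRANS", Orientation.TRANS),
        ("TRV", Orientation.TRANS),
        ("LONG", Orientation.LONG),
        ("SAG", Orientation.SAG),
        ("OBL", Orientation.OBL),
        ("", Orientation.NONE),
        ("RADIOLOGY", Orientation.NONE),  # word boundary
    ])
    def test_grammar(self, text, expected):
        assert match_orientation(text) is expected


class TestClockPosition:
    @pytest.mark.parametrize("text,expected", [
        ("3:00", (3, 0)),
        ("12:45", (12, 45)),
        ("RT BREAST 10:15 RAD", (10, 15)),
        ("10 O'CLOCK", (10, 0)),
        ("2 OCLOCK", (2, 0)),
        ("15:00", None),    # invalid hour
        ("0:30", None),
        ("NO CLOCK", None),
    ])
    def test_grammar(self, text, expected):
        assert match_clock_position(text) == expected


class TestDistanceAndMeasurement:
    @pytest.mark.parametrize("text,expected", [
        ("2 CM FN", 2.0),
        ("3CMFN", 3.0),
        ("1.5 CM FROM NIPPLE", 1.5),
        ("2 CM", None),  # a measurement, not a distance
        ("NOTHING", None),
    ])
    def test_distance(self, text, expected):
        assert match_distance(text) == expected

    @pytest.mark.parametrize("text,expected", [
        ("1.2 CM", [1.2]),
        ("0.8 X 1.1 CM", [0.8, 1.1]),
        ("2 CM FN", []),  # claimed by the distance field
        ("LUMP", []),
    ])
    def test_measurement(self, text, expected):
        assert match_measurement(text) == expected

    @given(st.floats(0.1, 9.9).map(lambda v: round(v, 1)))
    def test_number_cm_group_claimed_by_exactly_one_field(self, value):
        as_distance = f"{value:g} CM FN"
        as_measurement = f"{value:g} CM"
        assert match_distance(as_distance) == pytest.approx(value)
        assert match_measurement(as_distance) == []
        assert match_distance(as_measurement) is None
        assert match_measurement(as_measurement) == pytest.approx([value])


class TestAxillaProcedural:
    @pytest.mark.parametrize("text,expected", [
        ("LT AXILLA", True), ("AXILLARY NODE", True), ("AX TAIL", True),
        ("MAX", False), ("RELAX", False), ("", False),
    ])
    def test_axilla(self, text, expected):
        assert match_axilla(text) is expected

    @pytest.mark.parametrize("text,expected", [
        ("US GUIDED BIOPSY", True), ("CLIP PLACED", True), ("POST BX", True),
        ("FNA", True), ("COIL", True), ("MARKER", True),
        ("LEFT BREAST 3:00", False), ("", False),
    ])
    def test_procedural(self, text, expected):
        assert match_procedural(text) is expected


class TestExtractText:
    def test_empty_backend(self):
        scan = ScanImage(np.zeros((10, 10), dtype=np.uint8), source_id="s")
        assert extract_text(scan, StubOCRBackend()) == []

    def test_stub_round_trip_with_normalisation(self):
        scan = ScanImage(np.zeros((10, 10), dtype=np.uint8), source_id="s")
        backend = StubOCRBackend({"s": ["rt  breast\t10:00"]})
        dets = extract_text(scan, backend)
        assert [d.text for d in dets] == ["RT BREAST 10:00"]

    def test_low_confidence_dropped(self):
        scan = ScanImage(np.zeros((10, 10), dtype=np.uint8), source_id="s")

        class LowConf:
            def read(self, scan):
                return [TextDetection("HELLO", confidence=0.1),
                        TextDetection("WORLD", confidence=0.9)]

        assert [d.text for d in extract_text(scan, LowConf())] == ["WORLD"]


class TestExtractFields:
    def test_empty_detections_all_none(self):
        out = extract_fields([])
        assert out.laterality is Laterality.NONE
        assert out.orientation is Orientation.NONE
        assert out.clock_position is None and out.distance_from_nipple_cm is None
        assert not out.axilla and not out.procedural and not out.text_present
        assert out.measurements_cm == [] and out.matched_tokens == []

    def test_composed_annotation_line(self):
        out = extract_fields([TextDetection("RT BREAST 10:00 3 CM FN RAD")])
        assert out.laterality is Laterality.RIGHT
        assert out.orientation is Orientation.RAD
        assert out.clock_position == (10, 0)
        assert out.distance_from_nipple_cm == 3.0
        assert out.measurements_cm == []
        assert out.text_present

    def test_left_right_across_detections_conflicts(self):
        out = extract_fields([TextDetection("LEFT"), TextDetection("RIGHT")])
        assert out.laterality is Laterality.CONFLICT

    def test_matched_tokens_record_source_strings(self):
        out = extract_fields([TextDetection("LT AXILLA"), TextDetection("0.8 X 1.1 CM")])
        assert ("laterality", "LT AXILLA") in out.matched_tokens
        assert ("axilla", "LT AXILLA") in out.matched_tokens
        assert ("measurement", "0.8 X 1.1 CM") in out.matched_tokens

    @given(st.text(alphabet=st.characters(codec="ascii"), max_size=40))
    def test_matchers_are_pure_and_total(self, text):
        upper = text.upper()
        assert match_laterality(upper) is match_laterality(upper)
        match_orientation(upper)
        match_clock_position(upper)
        match_distance(upper)
        match_measurement(upper)


class TestVocabulary:
    def test_custom_vocabulary_file(self, tmp_path):
        path = tmp_path / "vocab.yaml"
        path.write_text("laterality_left:\n  - '\\bGAUCHE\\b'\n")
        vocab = load_vocabulary(str(path))
        assert match_laterality("GAUCHE", vocab) is Laterality.LEFT
        assert match_laterality("LEFT", vocab) is Laterality.NONE

    def test_quadrant_notation_rejected(self):
        out = extract_fields([TextDetection("LOQ"), TextDetection("RIQ")])
        assert out.clock_position is None
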