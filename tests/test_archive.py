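"""Archive persistence: round-trip identity, determinism, cross-representation
consistency of the three mask encodings."""

import io
import zipfile

import numpy as np
import pytest

from segont import (
    AnnotationDocument,
    ArchiveFormatError,
    UnsupportedVersionError,
    decode_rle,
    documents_field_equal,
    encode_rle,
    export_html,
    fill_polygons,
    form_segment,
    get_term,
    assign_term,
    load_archive,
    save_archive,
    validate_archive,
)
from segont.archive import _mask_to_png, _png_to_mask

from conftest import random_document


def save_bytes(doc):
    buf = io.BytesIO()
    save_archive(doc, buf)
    return buf.getvalue()


class TestRle:
    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(1, 20, 2)
        mask = (rng.random((h, w)) < rng.uniform(0.1, 0.9)).astype(np.uint8)
        text = f"{h} {w}\n{encode_rle(mask)}"
        assert np.array_equal(decode_rle(text, (h, w)), mask)

    def test_all_ones_starts_with_zero_run(self):
        assert encode_rle(np.ones((2, 2), np.uint8)) == "0 4"

    def test_run_sum_mismatch_detected(self):
        with pytest.raises(ArchiveFormatError):
            decode_rle("2 2\n1 2", (2, 2))


class TestRoundTrip:
    def test_empty_document(self):
        doc = AnnotationDocument.from_array(np.linspace(0, 1, 12).reshape(3, 4))
        assert documents_field_equal(doc, load_archive(io.BytesIO(save_bytes(doc))))

    @pytest.mark.parametrize("seed", range(25))
    def test_randomized_documents_field_equal(self, seed, po):
        rng = np.random.default_rng(4000 + seed)
        doc = random_document(rng, po)
        loaded = load_archive(io.BytesIO(save_bytes(doc)))
        assert documents_field_equal(doc, loaded)

    def test_original_image_bytes_stored_verbatim(self, po):
        rng = np.random.default_rng(8)
        doc = random_document(rng, po)
        data = save_bytes(doc)
        with zipfile.ZipFile(io.BytesIO(data)) as zf:
            stored = zf.read(f"image/{doc.image_filename}")
        assert stored == doc.image_bytes

    def test_identical_documents_serialize_identically(self, po):
        rng1 = np.random.default_rng(99)
        rng2 = np.random.default_rng(99)
        assert save_bytes(random_document(rng1, po)) == save_bytes(
            random_document(rng2, po)
        )


class TestXmlContent:
    def test_term_id_and_name_recorded(self, po):
        doc = AnnotationDocument.from_array(np.full((4, 4), 0.4))
        mask = np.zeros((4, 4), np.uint8)
        mask[1:3, 1:3] = 1
        form_segment(doc, mask)
        assign_term(doc, 1, get_term(po, "PO:0009033"))
        with zipfile.ZipFile(io.BytesIO(save_bytes(doc))) as zf:
            xml = zf.read("annotation.xml").decode()
        assert 'id="PO:0009033"' in xml and 'name="tepal"' in xml


class TestCrossRepresentation:
    def test_rle_png_and_polygons_agree_for_every_segment(self, po):
        rng = np.random.default_rng(15)
        doc = random_document(rng, po, max_layers=3)
        while not doc.layers:
            doc = random_document(rng, po, max_layers=3)
        data = save_bytes(doc)
        with zipfile.ZipFile(io.BytesIO(data)) as zf:
            for lyr in doc.layers:
                rle = decode_rle(
                    zf.read(f"masks/segment_{lyr.segment_id:03d}.rle").decode(),
                    doc.image.shape,
                )
                png = _png_to_mask(zf.read(f"masks/segment_{lyr.segment_id:03d}.png"))
                poly = fill_polygons([list(p) for p in lyr.boundary], doc.image.shape)
                assert np.array_equal(rle, png)
                assert np.array_equal(rle, poly)
                assert np.array_equal(rle, lyr.mask)
        assert validate_archive(io.BytesIO(data)) == []

    def test_png_codec_roundtrip(self):
        rng = np.random.default_rng(2)
        mask = (rng.random((9, 7)) < 0.5).astype(np.uint8)
        assert np.array_equal(_png_to_mask(_mask_to_png(mask)), mask)


class TestErrorHandling:
    def _tampered(self, doc, drop=None, replace=None):
        data = save_bytes(doc)
        out = io.BytesIO()
        with zipfile.ZipFile(io.BytesIO(data)) as zin, zipfile.ZipFile(out, "w") as zout:
            for name in zin.namelist():
                if name == drop:
                    continue
                payload = zin.read(name)
                if replace and name == replace[0]:
                    payload = replace[1]
                zout.writestr(name, payload)
        out.seek(0)
        return out

    @pytest.fixture
    def one_segment_doc(self):
        doc = AnnotationDocument.from_array(np.full((5, 5), 0.6))
        mask = np.zeros((5, 5), np.uint8)
        mask[1:4, 1:4] = 1
        form_segment(doc, mask)
        return doc

    def test_missing_metadata_entry(self, one_segment_doc):
        bad = self._tampered(one_segment_doc, drop="annotation.xml")
        with pytest.raises(ArchiveFormatError, match="metadata_entry missing"):
            load_archive(bad)

    def test_missing_mask_entry_named(self, one_segment_doc):
        bad = self._tampered(one_segment_doc, drop="masks/segment_001.rle")
        with pytest.raises(ArchiveFormatError, match="segment_001.rle"):
            load_archive(bad)

    def test_truncated_mask_entry_reported_by_validate(self, one_segment_doc):
        bad = self._tampered(
            one_segment_doc, replace=("masks/segment_001.rle", b"5 5\n1 2\n")
        )
        failures = validate_archive(bad)
        assert failures
        assert any("segment_001.rle" in f for f in failures)

    def test_unknown_newer_version_rejected(self, one_segment_doc):
        data = save_bytes(one_segment_doc)
        xml = None
        with zipfile.ZipFile(io.BytesIO(data)) as zf:
            xml = zf.read("annotation.xml").replace(
                b'format_version="1.0"', b'format_version="9.9"'
            )
        bad = self._tampered(one_segment_doc, replace=("annotation.xml", xml))
        with pytest.raises(UnsupportedVersionError):
            load_archive(bad)


class TestHtmlExport:
    def test_document_without_segments_has_image_but_no_overlays(self, tmp_path):
        doc = AnnotationDocument.from_array(np.full((4, 6), 0.5), "plain.png")
        out = export_html(doc, tmp_path)
        text = out.read_text()
        assert "data:image/png;base64," in text
        assert "<polygon" not in text

    def test_hover_text_carries_term_name(self, tmp_path, po):
        doc = AnnotationDocument.from_array(np.full((6, 6), 0.5), "flower.png")
        mask = np.zeros((6, 6), np.uint8)
        mask[2:5, 2:5] = 1
        form_segment(doc, mask)
        assign_term(doc, 1, get_term(po, "PO:0009029"))
        text = export_html(doc, tmp_path).read_text()
        assert "<title>stamen (PO:0009029)</title>" in text

    def test_polygon_coordinates_match_layer_boundary(self, tmp_path):
        doc = AnnotationDocument.from_array(np.full((6, 6), 0.5), "sq.png")
        mask = np.zeros((6, 6), np.uint8)
        mask[1:4, 2:5] = 1
        layer = form_segment(doc, mask)
        text = export_html(doc, tmp_path).read_text()
        expected = " ".join(f"{c},{r}" for r, c in layer.boundary[0])
        assert f'points="{expected}"' in text
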