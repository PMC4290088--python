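"""Archive persistence and HTML export.

A saved annotation is a ZIP archive containing

* the original image bytes, verbatim (never re-encoded),
* per segment: a 1-bit PNG mask image and a run-length-encoded text mask,
* ``annotation.xml`` with the format version, image dimensions, taxon,
  curation metadata and, per segment, its id, color, optional ontology term
  and boundary polygon coordinates.

Serialization is deterministic: entries are written in a fixed order
(image, then masks in id order, then XML) with fixed epoch timestamps, so
identical documents produce byte-identical archives.  The XML schema is this
package's own, versioned via ``format_version`` (see docs/FORMAT.md).

The RLE text format is row-major: a header line ``height width`` followed by
alternating run lengths, starting with the count of leading zeros.
"""

from __future__ import annotations

import base64
import io
import xml.etree.ElementTree as ET
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .boundary import fill_polygons
from .errors import (
    ArchiveFormatError,
    SegontError,
    UnsupportedVersionError,
    ValidationError,
)
from .image import decode_image
from .ontology import OntologyTerm, TaxonRecord
from .session import (
    AnnotationDocument,
    CurationMetadata,
    SegmentLayer,
    palette_color,
)

FORMAT_VERSION = "1.0"
METADATA_ENTRY = "annotation.xml"
_EPOCH = (1980, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class ArchiveManifest:
    """Entry names of one archive: image, per-segment mask pair, metadata."""

    original_image_entry: str
    segment_entries: tuple[tuple[str, str], ...]  # (rle entry, png entry) per id
    metadata_entry: str = METADATA_ENTRY
    format_version: str = FORMAT_VERSION


# ---------------------------------------------------------------------------
# RLE codec
# ---------------------------------------------------------------------------


def encode_rle(mask: np.ndarray) -> str:
    """Row-major run-length encoding; first run counts zeros (may be 0)."""
    mask = np.asarray(mask, dtype=np.uint8).ravel()
    if mask.size == 0:
        raise SegontError("cannot RLE-encode an empty mask")
    changes = np.flatnonzero(np.diff(mask)) + 1
    bounds = np.concatenate(([0], changes, [mask.size]))
    runs = np.diff(bounds).tolist()
    if mask[0] == 1:
        runs = [0] + runs
    return " ".join(str(r) for r in runs)


def decode_rle(text: str, shape: tuple[int, int]) -> np.ndarray:
    lines = text.strip().split("\n")
    header = lines[0].split()
    h, w = int(header[0]), int(header[1])
    if (h, w) != tuple(shape):
        raise ArchiveFormatError(f"RLE header {h}x{w} != expected {shape}")
    runs = [int(tok) for tok in " ".join(lines[1:]).split()]
    total = sum(runs)
    if total != h * w:
        raise ArchiveFormatError(
            f"RLE runs sum to {total}, expected {h * w} pixels"
        )
    flat = np.zeros(h * w, dtype=np.uint8)
    pos, value = 0, 0
    for run in runs:
        if value:
            flat[pos : pos + run] = 1
        pos += run
        value ^= 1
    return flat.reshape(h, w)


def _rle_entry_text(mask: np.ndarray) -> str:
    h, w = mask.shape
    return f"{h} {w}\n{encode_rle(mask)}\n"


# ---------------------------------------------------------------------------
# PNG mask codec
# ---------------------------------------------------------------------------


def _mask_to_png(mask: np.ndarray) -> bytes:
    im = Image.fromarray((np.asarray(mask, dtype=np.uint8) * 255)).convert("1")
    buf = io.BytesIO()
    im.save(buf, format="PNG", optimize=False)
    return buf.getvalue()


def _png_to_mask(data: bytes) -> np.ndarray:
    with Image.open(io.BytesIO(data)) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


# ---------------------------------------------------------------------------
# XML metadata
# ---------------------------------------------------------------------------


def _color_hex(color: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*color)


def _hex_color(text: str) -> tuple[int, int, int]:
    text = text.lstrip("#")
    return tuple(int(text[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def _poly_text(poly: tuple[tuple[int, int], ...]) -> str:
    return " ".join(f"{r},{c}" for r, c in poly)


def _text_poly(text: str) -> tuple[tuple[int, int], ...]:
    return tuple(
        (int(r), int(c)) for r, c in (pair.split(",") for pair in text.split())
    )


def _segment_entries(segment_id: int) -> tuple[str, str]:
    return (
        f"masks/segment_{segment_id:03d}.rle",
        f"masks/segment_{segment_id:03d}.png",
    )


def build_metadata_xml(doc: AnnotationDocument) -> bytes:
    root = ET.Element("annotation", format_version=FORMAT_VERSION)
    ET.SubElement(
        root,
        "image",
        filename=doc.image_filename,
        entry=f"image/{doc.image_filename}",
        height=str(doc.image.height),
        width=str(doc.image.width),
        format=doc.image.source_format,
    )
    if doc.taxon is not None:
        attrs = {"name": doc.taxon.name, "source": doc.taxon.source}
        if doc.taxon.namebank_id:
            attrs["namebank_id"] = doc.taxon.namebank_id
        ET.SubElement(root, "taxon", attrs)
    cur = ET.SubElement(root, "curation")
    for key in ("curator", "collection", "comments"):
        el = ET.SubElement(cur, key)
        el.text = getattr(doc.curation, key) or None
    segments = ET.SubElement(root, "segments")
    for lyr in doc.layers:
        rle_entry, png_entry = _segment_entries(lyr.segment_id)
        seg = ET.SubElement(
            segments,
            "segment",
            id=str(lyr.segment_id),
            color=_color_hex(lyr.color),
            mask_rle=rle_entry,
            mask_image=png_entry,
        )
        if lyr.term is not None:
            term = ET.SubElement(
                seg, "term", id=lyr.term.term_id, name=lyr.term.name,
                ontology=lyr.term.ontology,
            )
            if lyr.term.definition:
                ET.SubElement(term, "definition").text = lyr.term.definition
            for syn in lyr.term.synonyms:
                ET.SubElement(term, "synonym").text = syn
        boundary = ET.SubElement(seg, "boundary")
        for poly in lyr.boundary:
            ET.SubElement(boundary, "polygon", points=_poly_text(poly))
    ET.indent(root)
    return ET.tostring(root, encoding="utf-8", xml_declaration=True)


def _parse_metadata_xml(data: bytes) -> dict:
    try:
        root = ET.fromstring(data)
    except ET.ParseError as exc:
        raise ArchiveFormatError(f"cannot parse {METADATA_ENTRY}: {exc}")
    version = root.get("format_version", "")
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"archive format_version {version!r} is not supported "
            f"(this reader supports {FORMAT_VERSION})"
        )
    image_el = root.find("image")
    if image_el is None:
        raise ArchiveFormatError("annotation.xml lacks an <image> element")
    taxon_el = root.find("taxon")
    taxon = None
    if taxon_el is not None:
        taxon = TaxonRecord(
            name=taxon_el.get("name", ""),
            namebank_id=taxon_el.get("namebank_id"),
            source=taxon_el.get("source", "local-list"),
        )
    cur = CurationMetadata()
    cur_el = root.find("curation")
    if cur_el is not None:
        for key in ("curator", "collection", "comments"):
            el = cur_el.find(key)
            setattr(cur, key, (el.text or "") if el is not None else "")
    segments = []
    for seg in root.iter("segment"):
        term_el = seg.find("term")
        term = None
        if term_el is not None:
            term = OntologyTerm(
                term_id=term_el.get("id", ""),
                name=term_el.get("name", ""),
                definition=(
                    term_el.find("definition").text
                    if term_el.find("definition") is not None
                    else None
                ),
                synonyms=tuple(s.text or "" for s in term_el.findall("synonym")),
                ontology=term_el.get("ontology", ""),
            )
        boundary = tuple(
            _text_poly(p.get("points", "")) for p in seg.iter("polygon")
        )
        segments.append(
            {
                "id": int(seg.get("id", "0")),
                "color": _hex_color(seg.get("color", "#000000")),
                "mask_rle": seg.get("mask_rle", ""),
                "mask_image": seg.get("mask_image", ""),
                "term": term,
                "boundary": boundary,
            }
        )
    return {
        "version": version,
        "image_filename": image_el.get("filename", ""),
        "image_entry": image_el.get("entry", ""),
        "height": int(image_el.get("height", "0")),
        "width": int(image_el.get("width", "0")),
        "taxon": taxon,
        "curation": cur,
        "segments": segments,
    }


# ---------------------------------------------------------------------------
# Save / load / validate
# ---------------------------------------------------------------------------


def save_archive(doc: AnnotationDocument, destination) -> ArchiveManifest:
    """Write the document as a deterministic ZIP archive.

    ``destination`` may be a path or a writable binary file object.
    """
    failures = doc.validate()
    if failures:
        raise ValidationError(failures)
    image_entry = f"image/{doc.image_filename}"
    seg_entries = []

    def _write(zf: zipfile.ZipFile, name: str, data: bytes) -> None:
        info = zipfile.ZipInfo(name, date_time=_EPOCH)
        info.compress_type = zipfile.ZIP_DEFLATED
        zf.writestr(info, data)

    def _write_all(zf: zipfile.ZipFile) -> None:
        _write(zf, image_entry, doc.image_bytes)
        for lyr in doc.layers:
            rle_entry, png_entry = _segment_entries(lyr.segment_id)
            _write(zf, png_entry, _mask_to_png(lyr.mask))
            _write(zf, rle_entry, _rle_entry_text(lyr.mask).encode())
            seg_entries.append((rle_entry, png_entry))
        _write(zf, METADATA_ENTRY, build_metadata_xml(doc))

    if hasattr(destination, "write"):
        with zipfile.ZipFile(destination, "w") as zf:
            _write_all(zf)
    else:
        with zipfile.ZipFile(Path(destination), "w") as zf:
            _write_all(zf)
    return ArchiveManifest(image_entry, tuple(seg_entries))


def _read_entry(zf: zipfile.ZipFile, name: str) -> bytes:
    try:
        return zf.read(name)
    except KeyError:
        raise ArchiveFormatError(f"archive entry missing: {name}")
    except Exception as exc:
        raise ArchiveFormatError(f"archive entry unreadable: {name} ({exc})")


def load_archive(source) -> AnnotationDocument:
    """Re-open a saved archive for continued editing.

    ``load_archive(save_archive(doc))`` is field-equal to ``doc``.
    """
    with zipfile.ZipFile(source) as zf:
        names = set(zf.namelist())
        if METADATA_ENTRY not in names:
            raise ArchiveFormatError(f"metadata_entry missing: {METADATA_ENTRY}")
        meta = _parse_metadata_xml(zf.read(METADATA_ENTRY))
        image_bytes = _read_entry(zf, meta["image_entry"])
        doc = AnnotationDocument.from_file_bytes(image_bytes, meta["image_filename"])
        if doc.image.shape != (meta["height"], meta["width"]):
            raise ValidationError(
                [
                    f"image dimensions {doc.image.shape} != XML "
                    f"({meta['height']}, {meta['width']})"
                ]
            )
        doc.taxon = meta["taxon"]
        doc.curation = meta["curation"]
        for seg in meta["segments"]:
            mask = decode_rle(
                _read_entry(zf, seg["mask_rle"]).decode(), doc.image.shape
            )
            png_mask = _png_to_mask(_read_entry(zf, seg["mask_image"]))
            if not np.array_equal(mask, png_mask):
                raise ValidationError(
                    [f"segment {seg['id']}: RLE and PNG masks disagree"]
                )
            doc.layers.append(
                SegmentLayer(
                    segment_id=seg["id"],
                    mask=mask,
                    color=seg["color"],
                    term=seg["term"],
                    boundary=seg["boundary"],
                )
            )
    failures = doc.validate()
    if failures:
        raise ValidationError(failures)
    return doc


def validate_archive(source) -> list[str]:
    """Full invariant report for an archive; empty list means valid.

    Checks entry presence, XML consistency, and for every segment the
    three-way agreement RLE mask == PNG mask == filled boundary polygons.
    """
    failures: list[str] = []
    try:
        zf = zipfile.ZipFile(source)
    except Exception as exc:
        return [f"not a readable ZIP archive: {exc}"]
    with zf:
        names = set(zf.namelist())
        if METADATA_ENTRY not in names:
            return [f"metadata_entry missing: {METADATA_ENTRY}"]
        try:
            meta = _parse_metadata_xml(zf.read(METADATA_ENTRY))
        except (ArchiveFormatError, UnsupportedVersionError) as exc:
            return [str(exc)]
        if meta["image_entry"] not in names:
            failures.append(f"archive entry missing: {meta['image_entry']}")
        else:
            try:
                img = decode_image(zf.read(meta["image_entry"]))
                if img.shape != (meta["height"], meta["width"]):
                    failures.append("image dimensions disagree with XML")
            except Exception as exc:
                failures.append(f"original image undecodable: {exc}")
        shape = (meta["height"], meta["width"])
        expected_ids = list(range(1, len(meta["segments"]) + 1))
        if [s["id"] for s in meta["segments"]] != expected_ids:
            failures.append("segment ids are not consecutive from 1")
        for seg in meta["segments"]:
            sid = seg["id"]
            missing = [
                seg[key] for key in ("mask_rle", "mask_image") if seg[key] not in names
            ]
            for entry in missing:
                failures.append(f"archive entry missing: {entry}")
            if missing:
                continue
            try:
                rle_mask = decode_rle(zf.read(seg["mask_rle"]).decode(), shape)
            except (ArchiveFormatError, ValueError) as exc:
                failures.append(f"segment {sid}: bad RLE entry {seg['mask_rle']}: {exc}")
                continue
            png_mask = _png_to_mask(zf.read(seg["mask_image"]))
            if not np.array_equal(rle_mask, png_mask):
                failures.append(f"segment {sid}: RLE and PNG masks disagree")
            try:
                filled = fill_polygons([list(p) for p in seg["boundary"]], shape)
            except SegontError as exc:
                failures.append(f"segment {sid}: bad boundary polygons: {exc}")
                continue
            if not np.array_equal(filled, rle_mask):
                failures.append(
                    f"segment {sid}: filled boundary polygons disagree with mask"
                )
            if seg["color"] != palette_color(sid):
                failures.append(f"segment {sid}: color is not the preset palette color")
    return failures


# ---------------------------------------------------------------------------
# HTML export
# ---------------------------------------------------------------------------

_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
.annotated-image {{ position: relative; display: inline-block; }}
.annotated-image img, .annotated-image svg {{ display: block; }}
.annotated-image svg {{ position: absolute; top: 0; left: 0; }}
.segment polygon {{ fill-opacity: 0.35; stroke-width: 1; }}
.segment:hover polygon {{ fill-opacity: 0.6; }}
figcaption {{ font-family: sans-serif; font-size: 14px; }}
</style>
</head>
<body>
<figure class="annotated-image">
<img src="data:{mime};base64,{image_b64}" width="{width}" height="{height}" alt="{title}">
<svg width="{width}" height="{height}" viewBox="0 0 {width} {height}" xmlns="http://www.w3.org/2000/svg">
{overlays}
</svg>
<figcaption>{caption}</figcaption>
</figure>
</body>
</html>
"""

_MIME = {"JPEG": "image/jpeg", "PNG": "image/png", "GIF": "image/gif", "BMP": "image/bmp"}


def _svg_overlays(doc: AnnotationDocument) -> str:
    parts = []
    for lyr in doc.layers:
        if lyr.term is not None:
            hover = f"{lyr.term.name} ({lyr.term.term_id})"
        else:
            hover = f"segment {lyr.segment_id}"
        color = _color_hex(lyr.color)
        polys = "\n".join(
            '  <polygon points="{}" fill="{}" stroke="{}"/>'.format(
                " ".join(f"{c},{r}" for r, c in poly), color, color
            )
            for poly in lyr.boundary
        )
        parts.append(
            f'<g class="segment" id="segment-{lyr.segment_id}">\n'
            f"  <title>{hover}</title>\n{polys}\n</g>"
        )
    return "\n".join(parts)


def export_html(doc: AnnotationDocument, destination: str | Path) -> Path:
    """Write a self-contained HTML view of the annotated image.

    The original image is embedded as a data URI; each segment boundary is
    an inline SVG polygon in the layer's preset color, with the assigned
    term shown on hover.  Returns the path of the written file.
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    caption_bits = [doc.image_filename]
    if doc.taxon is not None:
        caption_bits.append(f"<i>{doc.taxon.name}</i>")
    caption_bits.append(f"{len(doc.layers)} segment(s)")
    html = _HTML_TEMPLATE.format(
        title=doc.image_filename,
        mime=_MIME[doc.image.source_format],
        image_b64=base64.b64encode(doc.image_bytes).decode(),
        width=doc.image.width,
        height=doc.image.height,
        overlays=_svg_overlays(doc),
        caption=" &mdash; ".join(caption_bits),
    )
    out = destination / (Path(doc.image_filename).stem + "_annotated.html")
    out.write_text(html)
    return out
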