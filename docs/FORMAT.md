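# Annotation archive format, version 1.0

A saved annotation is a standard ZIP archive (deflate compression) with a
fixed entry order and fixed (epoch, 1980-01-01) entry timestamps, so that
identical documents serialize to byte-identical archives.

## Entries, in order

| entry | content |
|---|---|
| `image/<filename>` | the original image bytes, **verbatim** — never re-encoded |
| `masks/segment_NNN.png` | 1-bit PNG of segment NNN's binary mask |
| `masks/segment_NNN.rle` | the same mask, run-length encoded text |
| `annotation.xml` | all metadata (below) |

`NNN` is the zero-padded segment id; segments appear in id order (1..n,
consecutive).

## RLE text format

```
<height> <width>
<run> <run> <run> ...
```

Runs are row-major pixel counts of alternating value, **starting with the
count of leading zeros** (which may be `0` when the first pixel is
foreground).  The runs must sum to `height * width`.

## Coordinates

All coordinates are 0-based `(row, col)`.  Boundary polygon vertices lie on
the **pixel-corner grid**: corner `(r, c)` is the top-left corner of pixel
`(r, c)`, and pixel `(r, c)` covers the half-open square
`[r, r+1) × [c, c+1)`.  Polygons are closed (the last vertex connects back
to the first, which is not repeated) and rectilinear.  A mask with holes has
one polygon per boundary loop; filling all polygons with the even-odd rule
reproduces the mask exactly.

## annotation.xml

```xml
<?xml version='1.0' encoding='utf-8'?>
<annotation format_version="1.0">
  <image filename="flower.png" entry="image/flower.png"
         height="72" width="72" format="PNG" />
  <taxon name="Galanthus elwesii" source="local-list" namebank_id="tx:0001" />
  <curation>
    <curator>Example Curator</curator>
    <collection />
    <comments />
  </curation>
  <segments>
    <segment id="1" color="#e6194b"
             mask_rle="masks/segment_001.rle"
             mask_image="masks/segment_001.png">
      <term id="PO:0009030" name="carpel" ontology="PO">
        <definition>...</definition>
        <synonym>...</synonym>
      </term>
      <boundary>
        <polygon points="8,10 8,14 9,14 ..." />
      </boundary>
    </segment>
  </segments>
</annotation>
```

* `format_version` — readers must reject versions they do not support.
* `<taxon>` and `<term>` are optional; a segment has at most one term, a
  document at most one taxon.
* `color` is the preset palette color implied by the segment id; it is
  stored for self-containedness and checked on validation.
* `points` is a space-separated list of `row,col` corner vertices.
* Unknown extra elements are ignored by the reader (forward-compatible
  extensions).

## Consistency requirements

For every segment the three mask representations must agree pixel-for-pixel:
the RLE entry, the PNG entry, and the even-odd fill of the boundary
polygons.  `validate_archive` (CLI: `segont validate`) checks all of this
plus entry presence, consecutive ids, image decodability and dimension
agreement.
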