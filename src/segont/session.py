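"""The editing workflow: form segments, label them, assemble the document.

Mirrors the two-mode annotation loop of the original tool: in segmentation
mode the user accumulates foreground/background scribbles and runs or refines
the graph cut; once satisfied they *form* the segment, which fixes the
current mask as an immutable layer with a preset color.  In labeling mode
each formed layer may be given one ontology term, and the whole document one
taxon plus free-text curation metadata.  The original image is never
modified by any operation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import graphcut
from .boundary import trace_boundaries
from .errors import SegontError, ShapeMismatchError
from .image import ImageGrid, decode_image, encode_png
from .ontology import OntologyTerm, TaxonRecord
from .seeds import SeedSet

#: Preset overlay palette: a fixed 12-color maximally-distinct cycle.
#: A layer's color is (segment_id - 1) mod 12 into this table, so the color
#: is a pure function of the id.
PALETTE: tuple[tuple[int, int, int], ...] = (
    (230, 25, 75),    # red
    (60, 180, 75),    # green
    (255, 225, 25),   # yellow
    (67, 99, 216),    # blue
    (245, 130, 48),   # orange
    (145, 30, 180),   # purple
    (70, 240, 240),   # cyan
    (240, 50, 230),   # magenta
    (188, 246, 12),   # lime
    (250, 190, 190),  # pink
    (0, 128, 128),    # teal
    (154, 99, 36),    # brown
)


def palette_color(segment_id: int) -> tuple[int, int, int]:
    """Preset display color for a segment id (ids start at 1)."""
    if segment_id < 1:
        raise SegontError("segment ids start at 1")
    return PALETTE[(segment_id - 1) % len(PALETTE)]


@dataclass(frozen=True)
class SegmentLayer:
    """A formed, immutable binary mask layer with color and optional term."""

    segment_id: int
    mask: np.ndarray
    color: tuple[int, int, int]
    term: OntologyTerm | None = None
    boundary: tuple[tuple[tuple[int, int], ...], ...] = ()

    def __post_init__(self):
        mask = np.ascontiguousarray(self.mask, dtype=np.uint8)
        if mask.ndim != 2:
            raise SegontError("segment mask must be 2-D")
        if not mask.any():
            raise SegontError("segment mask must contain at least one foreground pixel")
        if not np.isin(mask, (0, 1)).all():
            raise SegontError("segment mask values must be 0 or 1")
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)
        if self.color != palette_color(self.segment_id):
            raise SegontError("layer color must be the preset palette color for its id")

    def field_equal(self, other: "SegmentLayer") -> bool:
        return (
            self.segment_id == other.segment_id
            and np.array_equal(self.mask, other.mask)
            and self.color == other.color
            and self.term == other.term
            and self.boundary == other.boundary
        )


@dataclass
class CurationMetadata:
    """Free-text curation details: curator, collection, comments."""

    curator: str = ""
    collection: str = ""
    comments: str = ""


@dataclass
class AnnotationDocument:
    """Image + ordered segment layers + taxon + curation: the unit of persistence.

    ``image_bytes`` are the verbatim bytes of the original file; archives
    store them unchanged, and no operation may touch them.
    """

    image: ImageGrid
    image_bytes: bytes
    image_filename: str
    layers: list[SegmentLayer] = field(default_factory=list)
    taxon: TaxonRecord | None = None
    curation: CurationMetadata = field(default_factory=CurationMetadata)

    @classmethod
    def from_file_bytes(cls, data: bytes, filename: str) -> "AnnotationDocument":
        return cls(image=decode_image(data), image_bytes=data, image_filename=filename)

    @classmethod
    def from_array(cls, values: np.ndarray, filename: str = "image.png") -> "AnnotationDocument":
        """Wrap an in-memory array; its deterministic PNG encoding becomes
        the original bytes."""
        image = ImageGrid(values)
        return cls(image=image, image_bytes=encode_png(image), image_filename=filename)

    def image_hash(self) -> str:
        return hashlib.sha256(self.image_bytes).hexdigest()

    def layer(self, segment_id: int) -> SegmentLayer:
        for lyr in self.layers:
            if lyr.segment_id == segment_id:
                return lyr
        raise SegontError(f"no segment with id {segment_id}")

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        failures = []
        for i, lyr in enumerate(self.layers, start=1):
            if lyr.segment_id != i:
                failures.append(f"segment ids not consecutive at position {i}")
            if lyr.mask.shape != self.image.shape:
                failures.append(f"segment {lyr.segment_id} mask shape != image shape")
        return failures


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def form_segment(doc: AnnotationDocument, mask: np.ndarray) -> SegmentLayer:
    """Fix a mask as the next immutable layer; returns the new layer.

    The layer gets the next consecutive id, the preset palette color for
    that id, and boundary polygons traced from the mask (whose filled
    rasterization reproduces the mask exactly).
    """
    mask = np.asarray(mask, dtype=np.uint8)
    if mask.shape != doc.image.shape:
        raise ShapeMismatchError("mask shape does not match document image")
    if not mask.any():
        raise SegontError("cannot form a segment from an empty mask")
    segment_id = len(doc.layers) + 1
    boundary = tuple(tuple(p) for p in trace_boundaries(mask))
    layer = SegmentLayer(
        segment_id=segment_id,
        mask=mask,
        color=palette_color(segment_id),
        boundary=boundary,
    )
    doc.layers.append(layer)
    return layer


def assign_term(doc: AnnotationDocument, segment_id: int, term: OntologyTerm) -> AnnotationDocument:
    """Set (or replace) the ontology term of one segment; last write wins."""
    lyr = doc.layer(segment_id)
    doc.layers[doc.layers.index(lyr)] = replace(lyr, term=term)
    return doc


def assign_taxon(doc: AnnotationDocument, taxon: TaxonRecord) -> AnnotationDocument:
    """Set the document-level taxon (one per document; replaces any previous)."""
    doc.taxon = taxon
    return doc


def delete_segment(doc: AnnotationDocument, segment_id: int) -> AnnotationDocument:
    """Remove a layer; remaining layers are renumbered consecutively and
    their colors re-derived from the new ids.  Terms travel with their layer."""
    doc.layer(segment_id)  # raises for unknown id
    kept = [lyr for lyr in doc.layers if lyr.segment_id != segment_id]
    doc.layers = [
        SegmentLayer(
            segment_id=i,
            mask=lyr.mask,
            color=palette_color(i),
            term=lyr.term,
            boundary=lyr.boundary,
        )
        for i, lyr in enumerate(kept, start=1)
    ]
    return doc


def documents_field_equal(a: AnnotationDocument, b: AnnotationDocument) -> bool:
    """Field-wise equality over image bytes, filename, layers, taxon, curation."""
    return (
        a.image_bytes == b.image_bytes
        and a.image_filename == b.image_filename
        and a.taxon == b.taxon
        and a.curation == b.curation
        and len(a.layers) == len(b.layers)
        and all(x.field_equal(y) for x, y in zip(a.layers, b.layers))
    )


# ---------------------------------------------------------------------------
# Interactive-style session
# ---------------------------------------------------------------------------


class EditingSession:
    """Scripted equivalent of the two-mode GUI loop.

    Scribbles accumulate in :attr:`seeds`; :meth:`run_segmentation` computes
    the working mask from all seeds so far (re-running after new scribbles
    *is* refinement); :meth:`form` fixes the working mask as a layer and
    clears the scribbles for the next segment.
    """

    def __init__(
        self,
        doc: AnnotationDocument,
        params: graphcut.EnergyParams | None = None,
    ):
        self.doc = doc
        self.params = params or graphcut.default_params(doc.image)
        self.seeds = SeedSet(doc.image.shape)
        self.working_mask: np.ndarray | None = None

    def add_scribble(self, vertices, label) -> None:
        self.seeds.add_stroke(vertices, label)

    def add_scribble_points(self, points) -> None:
        for row, col, label in points:
            self.seeds.add_point(row, col, label)

    def clear_seeds(self) -> None:
        self.seeds.clear()
        self.working_mask = None

    def run_segmentation(self) -> np.ndarray:
        self.working_mask = graphcut.segment(self.doc.image, self.seeds, self.params)
        return self.working_mask

    def form(self) -> SegmentLayer:
        if self.working_mask is None:
            self.run_segmentation()
        layer = form_segment(self.doc, self.working_mask)
        self.clear_seeds()
        return layer

    def label(self, segment_id: int, term: OntologyTerm) -> None:
        assign_term(self.doc, segment_id, term)

    def set_taxon(self, taxon: TaxonRecord) -> None:
        assign_taxon(self.doc, taxon)

    def set_curation(self, **fields: str) -> None:
        for key, value in fields.items():
            if not hasattr(self.doc.curation, key):
                raise SegontError(f"unknown curation field {key!r}")
            setattr(self.doc.curation, key, value)
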