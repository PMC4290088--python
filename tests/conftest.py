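import numpy as np
import pytest

from segont import (
    AnnotationDocument,
    CurationMetadata,
    TaxonRecord,
    form_segment,
    get_term,
    mini_plant_ontology,
)

TERM_IDS = (
    "PO:0009058",  # perianth
    "PO:0009066",  # anther
    "PO:0009033",  # tepal
    "PO:0009074",  # style
    "PO:0009072",  # plant ovary
    "PO:0009029",  # stamen
    "PO:0009030",  # carpel
)


@pytest.fixture(scope="session")
def po():
    return mini_plant_ontology()


def random_mask(rng, shape):
    """A random nonempty binary mask (blob-ish via threshold on smoothed noise)."""
    mask = (rng.random(shape) < rng.uniform(0.2, 0.7)).astype(np.uint8)
    if not mask.any():
        mask[rng.integers(shape[0]), rng.integers(shape[1])] = 1
    return mask


def random_document(rng, provider, max_layers=3):
    """A randomized small annotation document, for round-trip property tests."""
    h, w = int(rng.integers(3, 12)), int(rng.integers(3, 12))
    if rng.random() < 0.5:
        values = rng.random((h, w))
    else:
        values = rng.random((h, w, 3))
    doc = AnnotationDocument.from_array(values, f"img_{rng.integers(1e6)}.png")
    for _ in range(int(rng.integers(0, max_layers + 1))):
        layer = form_segment(doc, random_mask(rng, (h, w)))
        if rng.random() < 0.7:
            term = get_term(provider, TERM_IDS[int(rng.integers(len(TERM_IDS)))])
            from segont import assign_term

            assign_term(doc, layer.segment_id, term)
    if rng.random() < 0.6:
        doc.taxon = TaxonRecord(
            name="Galanthus elwesii", namebank_id="tx:0001", source="local-list"
        )
    if rng.random() < 0.6:
        doc.curation = CurationMetadata(
            curator=f"curator-{rng.integers(100)}",
            collection="test shelf",
            comments="randomized fixture document",
        )
    return doc
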