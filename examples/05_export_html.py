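"""Export an annotated document as a self-contained HTML page.

The page embeds the original image as a data URI and each segment boundary
as an inline SVG polygon in its preset color; hovering a segment shows its
ontology term.
"""

from pathlib import Path

from segont import (
    AnnotationDocument,
    assign_term,
    export_html,
    five_region_scene,
    form_segment,
    get_term,
    mini_plant_ontology,
)

scene = five_region_scene(seed=42)
doc = AnnotationDocument.from_array(scene.image.values, "flower.png")
form_segment(doc, scene.region_mask(3))
assign_term(doc, 1, get_term(mini_plant_ontology(), "PO:0009033"))

out = export_html(doc, Path("scratch") if Path("scratch").is_dir() else Path("."))
text = out.read_text()
print(f"wrote {out} ({len(text)} characters)")
print("contains hover text 'tepal (PO:0009033)':", "tepal (PO:0009033)" in text)
print("SVG polygons:", text.count("<polygon"))
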