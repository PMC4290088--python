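format-version: 1.2
data-version: segont/mini-po-subset-1.0
ontology: po
remark: Synthetic mini subset of Plant Ontology anatomy terms packaged for offline term lookup and tests. Definitions are paraphrased; not an official PO release.

[Term]
id: PO:0009046
name: flower
def: "Reproductive shoot system of an angiosperm, typically bearing perianth, androecium and gynoecium." []
synonym: "floral structure" RELATED []

[Term]
id: PO:0009058
name: perianth
def: "Collective structure of the outer floral organs, comprising the calyx and corolla or the tepals." []
synonym: "perigone" EXACT []
synonym: "perigonium" EXACT []
is_a: PO:0009046 ! flower

[Term]
id: PO:0009033
name: tepal
def: "A perianth organ not differentiated into sepal or petal." []
is_a: PO:0009058 ! perianth

[Term]
id: PO:0009032
name: petal
def: "A corolla organ, usually colored, of the inner perianth whorl." []
is_a: PO:0009058 ! perianth

[Term]
id: PO:0009031
name: sepal
def: "A calyx organ of the outer perianth whorl, usually green." []
is_a: PO:0009058 ! perianth

[Term]
id: PO:0009061
name: androecium
def: "Collective structure of the stamens of a flower." []
synonym: "stamen whorl" RELATED []
is_a: PO:0009046 ! flower

[Term]
id: PO:0009029
name: stamen
def: "Male reproductive organ of a flower, consisting of an anther and usually a filament." []
is_a: PO:0009061 ! androecium

[Term]
id: PO:0009066
name: anther
def: "The pollen-bearing portion of a stamen." []
is_a: PO:0009029 ! stamen

[Term]
id: PO:0009067
name: filament
def: "The stalk portion of a stamen supporting the anther." []
synonym: "stamen filament" EXACT []
is_a: PO:0009029 ! stamen

[Term]
id: PO:0009062
name: gynoecium
def: "Collective structure of the carpels of a flower." []
synonym: "carpel whorl" RELATED []
synonym: "pistil" RELATED []
is_a: PO:0009046 ! flower

[Term]
id: PO:0009030
name: carpel
def: "Female reproductive organ of a flower, bearing ovules; one unit of the gynoecium." []
is_a: PO:0009062 ! gynoecium

[Term]
id: PO:0009072
name: plant ovary
def: "The basal, ovule-bearing portion of the gynoecium." []
synonym: "ovary" EXACT []
is_a: PO:0009062 ! gynoecium

[Term]
id: PO:0009074
name: style
def: "The portion of the gynoecium between ovary and stigma." []
is_a: PO:0009062 ! gynoecium

[Term]
id: PO:0009073
name: stigma
def: "The pollen-receptive portion of the gynoecium, usually at the tip of the style." []
is_a: PO:0009062 ! gynoecium

[Term]
id: PO:0020003
name: plant ovule
def: "The structure in the ovary containing the female gametophyte; develops into the seed." []
synonym: "ovule" EXACT []
is_a: PO:0009072 ! plant ovary

[Term]
id: PO:0009025
name: vascular leaf
def: "A leaf of a vascular plant." []
synonym: "leaf" BROAD []

[Term]
id: PO:0020039
name: leaf lamina
def: "The expanded, usually flat, portion of a leaf." []
synonym: "leaf blade" EXACT []
is_a: PO:0009025 ! vascular leaf

[Term]
id: PO:0020038
name: petiole
def: "The stalk of a leaf, attaching the lamina to the stem." []
is_a: PO:0009025 ! vascular leaf

[Term]
id: PO:0009047
name: stem
def: "The main axis of the shoot system, bearing leaves and buds." []

[Term]
id: PO:0009005
name: root
def: "The usually descending axis of a plant, normally below ground." []

[Term]
id: PO:0009006
name: shoot system
def: "The above-ground system of stems, leaves and reproductive structures." []

[Term]
id: PO:0009049
name: inflorescence
def: "A shoot system bearing a group of flowers." []
is_a: PO:0009006 ! shoot system

[Term]
id: PO:0009001
name: fruit
def: "The ripened ovary (or ovaries) with adherent parts, containing the seeds." []

[Term]
id: PO:0009010
name: seed
def: "The ripened ovule, containing the embryo." []

[Term]
id: PO:0000999
name: dummy obsolete organ
def: "Retired placeholder term; retained to exercise obsolete-term filtering." []
is_obsolete: true
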