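{
 "service": "segont mini term service fixture",
 "note": "Recorded JSON mirror of the packaged mini ontology; fixture schema is this package's own.",
 "terms": [
  {
   "id": "PO:0009001",
   "name": "fruit",
   "definition": "The ripened ovary (or ovaries) with adherent parts, containing the seeds.",
   "synonyms": []
  },
  {
   "id": "PO:0009005",
   "name": "root",
   "definition": "The usually descending axis of a plant, normally below ground.",
   "synonyms": []
  },
  {
   "id": "PO:0009006",
   "name": "shoot system",
   "definition": "The above-ground system of stems, leaves and reproductive structures.",
   "synonyms": []
  },
  {
   "id": "PO:0009010",
   "name": "seed",
   "definition": "The ripened ovule, containing the embryo.",
   "synonyms": []
  },
  {
   "id": "PO:0009025",
   "name": "vascular leaf",
   "definition": "A leaf of a vascular plant.",
   "synonyms": [
    "leaf"
   ]
  },
  {
   "id": "PO:0009029",
   "name": "stamen",
   "definition": "Male reproductive organ of a flower, consisting of an anther and usually a filament.",
   "synonyms": []
  },
  {
   "id": "PO:0009030",
   "name": "carpel",
   "definition": "Female reproductive organ of a flower, bearing ovules; one unit of the gynoecium.",
   "synonyms": []
  },
  {
   "id": "PO:0009031",
   "name": "sepal",
   "definition": "A calyx organ of the outer perianth whorl, usually green.",
   "synonyms": []
  },
  {
   "id": "PO:0009032",
   "name": "petal",
   "definition": "A corolla organ, usually colored, of the inner perianth whorl.",
   "synonyms": []
  },
  {
   "id": "PO:0009033",
   "name": "tepal",
   "definition": "A perianth organ not differentiated into sepal or petal.",
   "synonyms": []
  },
  {
   "id": "PO:0009046",
   "name": "flower",
   "definition": "Reproductive shoot system of an angiosperm, typically bearing perianth, androecium and gynoecium.",
   "synonyms": [
    "floral structure"
   ]
  },
  {
   "id": "PO:0009047",
   "name": "stem",
   "definition": "The main axis of the shoot system, bearing leaves and buds.",
   "synonyms": []
  },
  {
   "id": "PO:0009049",
   "name": "inflorescence",
   "definition": "A shoot system bearing a group of flowers.",
   "synonyms": []
  },
  {
   "id": "PO:0009058",
   "name": "perianth",
   "definition": "Collective structure of the outer floral organs, comprising the calyx and corolla or the tepals.",
   "synonyms": [
    "perigone",
    "perigonium"
   ]
  },
  {
   "id": "PO:0009061",
   "name": "androecium",
   "definition": "Collective structure of the stamens of a flower.",
   "synonyms": [
    "stamen whorl"
   ]
  },
  {
   "id": "PO:0009062",
   "name": "gynoecium",
   "definition": "Collective structure of the carpels of a flower.",
   "synonyms": [
    "carpel whorl",
    "pistil"
   ]
  },
  {
   "id": "PO:0009066",
   "name": "anther",
   "definition": "The pollen-bearing portion of a stamen.",
   "synonyms": []
  },
  {
   "id": "PO:0009067",
   "name": "filament",
   "definition": "The stalk portion of a stamen supporting the anther.",
   "synonyms": [
    "stamen filament"
   ]
  },
  {
   "id": "PO:0009072",
   "name": "plant ovary",
   "definition": "The basal, ovule-bearing portion of the gynoecium.",
   "synonyms": [
    "ovary"
   ]
  },
  {
   "id": "PO:0009073",
   "name": "stigma",
   "definition": "The pollen-receptive portion of the gynoecium, usually at the tip of the style.",
   "synonyms": []
  },
  {
   "id": "PO:0009074",
   "name": "style",
   "definition": "The portion of the gynoecium between ovary and stigma.",
   "synonyms": []
  },
  {
   "id": "PO:0020003",
   "name": "plant ovule",
   "definition": "The structure in the ovary containing the female gametophyte; develops into the seed.",
   "synonyms": [
    "ovule"
   ]
  },
  {
   "id": "PO:0020038",
   "name": "petiole",
   "definition": "The stalk of a leaf, attaching the lamina to the stem.",
   "synonyms": []
  },
  {
   "id": "PO:0020039",
   "name": "leaf lamina",
   "definition": "The expanded, usually flat, portion of a leaf.",
   "synonyms": [
    "leaf blade"
   ]
  }
 ]
}
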