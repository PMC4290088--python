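"""Term autocomplete and taxon lookup against the offline providers.

The same search code runs against the packaged mini Plant Ontology OBO file
and against a recorded JSON mirror of a term web service; both give the
same answers.
"""

from segont import (
    get_term,
    mini_plant_ontology,
    mini_taxon_list,
    mini_term_service,
    search_taxa,
    search_terms,
)

for provider in (mini_plant_ontology(), mini_term_service()):
    hits = search_terms(provider, "sta", limit=5)
    print(f"{type(provider).__name__}: 'sta' ->",
          ", ".join(f"{t.name} ({t.term_id})" for t in hits))

term = get_term(mini_plant_ontology(), "PO:0009058")
print(f"\n{term.term_id} {term.name}")
print(f"  definition: {term.definition}")
print(f"  synonyms: {', '.join(term.synonyms)}")

print("\ntaxon search 'Galanthus':")
for taxon in search_taxa(mini_taxon_list(), "Galanthus"):
    print(f"  {taxon.name} [{taxon.namebank_id}]")
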