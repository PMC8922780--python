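"""Tour of the bundled CDE catalogue.

Loads the 16 common data elements and 11 model templates, shows which
models cover which element, and how controlled labels are bound to
ontology IRIs.
"""

from cdefair import load_catalog

catalog = load_catalog()

print(f"{len(catalog.elements)} common data elements, {len(catalog.models)} model templates\n")

for eid, element in sorted(catalog.elements.items()):
    models = ", ".join(catalog.models_for_element(eid))
    print(f"  {eid}  {element.name:45s} -> {models}")

print("\nControlled values of element 3.1 (Patient Status):")
for value in catalog.get_element("3.1").allowed_values:
    print(f"  {value.label:20s} {value.term_iri}")

template = catalog.get_model("patient_status")
print(f"\nCSV contract for '{template.model_name}':")
for column in template.column_specs:
    req = "required" if column.required else "optional"
    print(f"  {column.name:12s} {column.datatype:10s} {req}")
# The listing above is what a registry export for this model must follow:
# one row per observation, the pseudonym (pid) linking rows across files.
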