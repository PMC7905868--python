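"""Term-level semantic distance on a hand-built phenotype ontology.

Builds a seven-term DAG, computes the normalized common-ancestor-path
distance between a few term pairs, and shows how the normalization constant
d_max is obtained.
"""

from rdmap import OntologyDAG, Term, compute_d_max, term_distance

dag = OntologyDAG(terms={
    "HP:0": Term("HP:0", "phenotypic abnormality", ()),
    "HP:1": Term("HP:1", "nervous system", ("HP:0",)),
    "HP:2": Term("HP:2", "eye", ("HP:0",)),
    "HP:3": Term("HP:3", "seizure", ("HP:1",)),
    "HP:4": Term("HP:4", "ataxia", ("HP:1",)),
    "HP:5": Term("HP:5", "cataract", ("HP:2",)),
    "HP:6": Term("HP:6", "nuclear cataract", ("HP:5",)),
})

d_max = compute_d_max(dag, mode="exact")
print(f"d_max (exact, all pairs) = {d_max}")

for a, b in [("HP:3", "HP:4"), ("HP:3", "HP:5"), ("HP:3", "HP:6"), ("HP:3", "HP:3")]:
    raw = dag.path_length(a, b)
    print(f"dist({dag.terms[a].name!r}, {dag.terms[b].name!r}) "
          f"= {raw}/{d_max} = {term_distance(dag, a, b):.2f}")

# Sibling phenotypes (seizure/ataxia) meet at their shared parent two edges
# up, so they are far closer (0.33) than phenotypes of different organ
# systems, which must route through the ontology root (0.67-0.83).
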