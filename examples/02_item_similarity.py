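"""Item-item similarity from an ontology and from feature vectors.

Scores chemistry-style items with Lin semantic similarity over a small
is_a hierarchy (information content from the topology), scores
astronomy-style items with cosine over mean feature vectors, and
materialises a top-n neighbour table - the input the enrichment
transform consumes.
"""

import io

from seenrec import (
    build_similarity_table,
    cosine_similarity,
    information_content,
    parse_obo,
    semantic_similarity,
)
from seenrec.similarity import feature_similarity_table
from seenrec.synthetic import gen_feature_matrix

OBO = """format-version: 1.2
ontology: demo

[Term]
id: CHEBI:1
name: chemical entity

[Term]
id: CHEBI:2
name: amine
is_a: CHEBI:1

[Term]
id: CHEBI:3
name: monoamine
is_a: CHEBI:2

[Term]
id: CHEBI:4
name: noradrenaline
is_a: CHEBI:3

[Term]
id: CHEBI:5
name: polyketide
is_a: CHEBI:1
"""

dag = parse_obo(io.StringIO(OBO))
ic = information_content(dag)  # intrinsic: from descendant counts
for a, b in [("CHEBI:4", "CHEBI:3"), ("CHEBI:4", "CHEBI:5")]:
    lin = semantic_similarity(dag, ic, a, b, "lin")
    print(f"lin({dag.names[a]}, {dag.names[b]}) = {lin:.3f}")
print("A compound is far more similar to its parent class than to an")
print("unrelated branch - the MICA's information content drives the score.")

table = build_similarity_table(
    sorted(dag.terms), lambda a, b: semantic_similarity(dag, ic, a, b, "lin"), top_n=2)
print("\nnoradrenaline's top-2 neighbours:", table.top_neighbors("CHEBI:4", 2))

# astronomy-style: cosine over per-cluster mean features (position, parallax)
features = gen_feature_matrix(n_items=20, n_groups=4, noise_sd=0.05, seed=1)
cos_table = feature_similarity_table(features, top_n=3)
item = features.items[0]
print(f"\ncosine neighbours of {item}:", cos_table.top_neighbors(item, 3))
print("cosine(v, v) =", cosine_similarity(features.vector(item), features.vector(item)))
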