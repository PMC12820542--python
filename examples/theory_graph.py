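"""Build the TAM adoption-model graph from weight + pooling results and
export it as DOT."""

from metaweight import (
    build_theory_graph,
    export_graph,
    group_paths,
    load_pe_bi_effects,
    load_theory_vocabulary,
    pool_random,
    records_from_counts,
    weight_table,
)

weights = weight_table(group_paths(records_from_counts()))
pools = {
    ("performance expectancy", "behavioral intention"): pool_random(
        load_pe_bi_effects()
    )
}
vocab = load_theory_vocabulary()["TAM"]
graph = build_theory_graph("TAM", [tuple(e) for e in vocab["edges"]], weights, pools)

print(export_graph(graph, "dot"))
print(
    "// Thick edges (penwidth > 3.1) are paths with weight >= 0.700;"
    "\n// dashed edges have a weight but no pooled effect in this demo."
)
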