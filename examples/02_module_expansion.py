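"""Expanding a module with interaction partners from a weighted edge table.

Partners with at least two edges into the module are ranked by summed edge
weight and appended; enrichment against the assessment sets is compared
before and after.
"""

from neuromark.gene_sets import GeneSet
from neuromark.expansion import enrichment_improvement, expand_module
from neuromark.screen import derive_duration_set
from neuromark.synthetic import SimConfig, generate_edge_table, generate_study

study = generate_study(SimConfig(n_transcripts=1000, module_sizes=(65, 50, 45), seed=4))
module = GeneSet("immune module", study.truth["immune_like_genes"])
edges = generate_edge_table(study, n_partners=12, noise_edges=60)

expanded = expand_module(module, edges, min_edges=2, max_added=12)
print(f"module of {len(module)} genes expanded to {len(expanded.expanded_set)} "
      f"({len(expanded.added_members)} interaction partners added)")
for gene in expanded.added_members[:5]:
    count, weight = expanded.support[gene]
    print(f"  {gene}: {count} edges into the module, summed weight {weight:.2f}")

universe = GeneSet("measured", study.cns.measured_genes)
duration_set = derive_duration_set(study.cns)
for row in enrichment_improvement(module, expanded.expanded_set, [duration_set], universe):
    print(f"{row['set_name']}: p {row['p_before']:.2e} -> {row['p_after']:.2e} "
          f"({'improved' if row['improved'] else 'not improved'}) "
          "- whether added partners strengthen the progression association")
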