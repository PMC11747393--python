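"""Build a mean concept graph from simulated pairwise similarity ratings.

Ratings on the -7..+7 scale are mapped to edge weights in [0, 1]
(0 = maximally related, 1 = maximally opposed); averaging the weights over
participants gives one weighted graph over the 16 concepts.
"""

from pramnet import EdgeWeightMatrix, mean_graph, rating_to_edge_weight
from pramnet.simulate import default_scenarios, simulate_cohort

cohort = simulate_cohort(default_scenarios()["paper_like"], seed=0)
print(f"cohort: {cohort.n_participants} participants, "
      f"{cohort.ratings.n_pairs} concept pairs")

print("rating +7 ->", rating_to_edge_weight(7), " (identical concepts, zero distance)")
print("rating -7 ->", rating_to_edge_weight(-7), "(opposed concepts, maximal distance)")

graph = mean_graph(EdgeWeightMatrix.from_ratings(cohort.ratings))
edge_list = graph.to_edge_list().sort_values("weight")
print("\nfive most strongly associated concept pairs (smallest mean distance):")
print(edge_list.head(5).to_string(index=False))
print("\nfive least associated pairs (largest mean distance):")
print(edge_list.tail(5).to_string(index=False))
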