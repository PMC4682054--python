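"""Parsimony pathway inference and directional permutation enrichment.

First removes pathways explainable purely through shared multi-pathway
ortholog groups (minimum set cover), then tests whether any pathway
holds more consistently-increasing KOs than random subsets of the same
size would (permutation test with an exact hypergeometric cross-check).
"""

import numpy as np

from catgut import parsimony_pathways
from catgut.enrichment import enrich_directions
from catgut.simulate import generate_kegg_hierarchy

hier = generate_kegg_hierarchy(n_ko=300, n_pathway=20, mean_multiplicity=2.5,
                               seed=2)
observed = hier.kos[:250]

cover = parsimony_pathways(observed, hier, solver="greedy")
print(f"candidate pathways: {len(cover.retained) + len(cover.removed)}, "
      f"retained after parsimony: {len(cover.retained)} "
      f"({cover.solver} solver)")

# positive control: every KO of one pathway moves up, plus random extras
rng = np.random.default_rng(2)
members = hier.pathway_to_kos()
target = cover.retained[0]
packed = sorted(members[target] & set(observed))
up = packed + list(
    rng.choice([k for k in observed if k not in members[target]], 15,
               replace=False))
enr = enrich_directions(observed, up, [], hier, n_perm=1000, seed=2)

hits = enr.up[enr.up["enriched"]]
print(f"up-enriched pathways: {list(hits.index)} (target was {target})")
print(enr.up.loc[[target], ["total", "significant", "p_perm",
                            "p_hypergeom"]].to_string())
for note in enr.notes:
    print("note:", note)

print("\nThe packed pathway reaches permutation p = 0 (exact "
      "hypergeometric tail agrees); with 1,000 permutations only p = 0 "
      "can clear the Sidak cutoff.")
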