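"""Build a combined gene-pair background: curated edges plus random pairs.

The background a pathway is ranked against should not consist of curated
pathway edges alone — curated pairs are systematically more co-regulated
than arbitrary pairs, which biases the ranking.  This example pools the
edges of a few toy pathways (the observed part), samples an equal number of
random gene pairs from a larger gene universe, and merges the two with
single inclusion for the overlap.
"""

from dyspia import (
    PathwayPairSet,
    build_observed_background,
    canonical_pair,
    combine_backgrounds,
    sample_random_background,
)

universe = [f"GENE{i:03d}" for i in range(200)]

pathways = []
for k in range(5):
    block = universe[20 * k : 20 * k + 12]
    pairs = frozenset(
        canonical_pair(block[i], block[j])
        for i in range(len(block))
        for j in range(i + 1, len(block))
        if (i + j + k) % 3  # sparse, pathway-specific edge pattern
    )
    pathways.append(PathwayPairSet(f"pw{k}", f"toy pathway {k}", pairs))

observed = build_observed_background(pathways)
random_part = sample_random_background(universe, n_pairs=len(observed), seed=42)
background = combine_backgrounds(observed, random_part, universe_size=len(universe))

n_both = sum(1 for f in background.provenance if f == "both")
print(f"observed edges:        {len(observed)}")
print(f"random pairs sampled:  {len(random_part)}")
print(f"shared by both parts:  {n_both}")
print(f"combined background:   {len(background)} pairs "
      f"(= {len(observed)} + {len(random_part)} - {n_both})")
print("\nEach pair is stored once, in canonical (ascending) symbol order,")
print("with a provenance flag saying which part(s) contributed it.")
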