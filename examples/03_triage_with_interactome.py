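"""Triage screen hits against an interactome protein list.

The screen ranking alone is long and noisy; intersecting the enriched genes
with an orthogonal protein list (here a synthetic stand-in for an IP-MS
interactome) narrows the candidates, as in a Venn-overlap triage.
"""

import screenrank as sr

lib_cfg, screen_cfg = sr.scaled_invivo_scenario(seed=1)
manifest = sr.generate_library(lib_cfg)
counts, sheet = sr.simulate_invivo_screen(manifest, screen_cfg)
ranking, _ = sr.rank_genes_invivo(counts, manifest, sheet)

# synthetic interactome: the five drivers plus 45 unrelated genes
interactome = set(screen_cfg.driver_genes) | {
    f"GENE{i:06d}" for i in range(1, 46)
}

enriched = sr.select_enriched(ranking, top_n=25)
result = sr.intersect_sets(enriched, interactome, parameters={"top_n": 25})

print(f"enriched set (top 25) ∩ interactome ({len(interactome)} proteins):")
print(f"overlap, in screen-rank order: {result.overlap_genes}")
print(f"venn regions: {result.venn_counts}")
# The overlap keeps the screen's rank order, so the first overlap gene is
# the strongest candidate; venn region sizes sum to the union of both sets.
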