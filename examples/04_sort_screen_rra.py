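"""Score a sorted fluorescence-reporter stability screen with alpha-RRA.

Cells carry a ratio reporter tracking a substrate protein's stability and
are sorted into ratio-high and ratio-low 5% gates. Guides enriched in the
low gate destabilized the substrate; alpha-RRA aggregates guide ranks into
a gene-level rho with a permutation p-value and BH FDR.
"""

import screenrank as sr

lib_cfg, sort_cfg = sr.scaled_sort_scenario(seed=1)
manifest = sr.generate_library(lib_cfg)
counts, sheet = sr.simulate_sorted_gates(manifest, sort_cfg)

scores = sr.score_guides_sorted(counts, sheet)
config = sr.SortScreenConfig(alpha=0.25, n_permutations=10_000, seed=1)
result = sr.alpha_rra(scores, manifest, config)

print(result.head(10).to_string(index=False))
effects = set(sort_cfg.effect_genes)
print(f"\nseeded effect genes in top 10: {len(effects & set(result['gene'].head(10)))}/5")
# rho is the minimum beta order-statistic probability over a gene's
# top-ranked guides (smaller = guides sit improbably high); p_value is its
# permutation tail probability, floored at 1/(n_permutations + 1).
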