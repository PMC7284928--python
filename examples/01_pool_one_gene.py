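"""Pool one gene's per-study log2 fold-changes by hand.

Builds four study-level effects, pools them under the fixed-effects model,
assesses heterogeneity, and shows the DerSimonian-Laird random-effects fit.
"""

from megapath import GeneEffect, fixed_effects, heterogeneity, pool_gene, random_effects

effects = [
    GeneEffect("PPARG", "STUDY1", lfc=-0.61, var=0.040, n_case=34, n_control=4),
    GeneEffect("PPARG", "STUDY2", lfc=-0.48, var=0.025, n_case=49, n_control=48),
    GeneEffect("PPARG", "STUDY3", lfc=-0.55, var=0.060, n_case=31, n_control=21),
    GeneEffect("PPARG", "STUDY4", lfc=-0.44, var=0.030, n_case=84, n_control=14),
]

pooled, se = fixed_effects(effects)
q, df, i_sq, p_q = heterogeneity(effects, pooled)
pooled_r, se_r, tau_sq = random_effects(effects)
result = pool_gene(effects)

print(f"fixed-effects pooled LFC = {pooled:+.3f} (se {se:.3f})")
print(f"heterogeneity: Q = {q:.3f} on df = {df}, I^2 = {i_sq:.1f}%, p_Q = {p_q:.3f}")
print(f"random-effects pooled LFC = {pooled_r:+.3f} (se {se_r:.3f}), tau^2 = {tau_sq:.4f}")
print(f"selected model: {result.model}  ->  p = {result.p_value:.2e}")

# Q below its expectation df means the studies look homogeneous, so the
# common-effect (fixed) model is selected; the pooled LFC is the
# inverse-variance weighted mean and its p-value uses z = LFC/se.
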