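"""Rating entropy per concept pair and its relation to news-bias effects.

High-entropy pairs (participants disagree widely) are the ones most
associated with the partisan bias of consumed news; the relation is
summarized with an offset sigmoid fit of |news coefficient| against
entropy in bits.
"""

from pramnet import entropy_effect_analysis, run_edgewise
from pramnet.simulate import default_scenarios, simulate_cohort

cohort = simulate_cohort(default_scenarios()["paper_like"], seed=0)
edges = run_edgewise(cohort, predictors=("news_bias",), n_perm=1000, seed=0)
ana = entropy_effect_analysis(edges, cohort.ratings, seed=0)

f = ana.fit
print(f"offset sigmoid fit 1/(1+exp(-a(x-b)))+c of |beta_news| vs entropy:")
print(f"  a = {f.a:.3f}, b = {f.b:.3f}, c = {f.c:.4f}, R^2 = {f.r_squared:.3f}")

t = ana.table.sort_values("entropy")
print(f"\nentropy range: {t.entropy.min():.2f} to {t.entropy.max():.2f} bits "
      "(max possible log2(15) = 3.91)")
print("\nmean |news effect| for the 10 lowest- vs 10 highest-entropy pairs:")
print(f"  lowest:  {t.head(10).abs_beta.mean():.4f}")
print(f"  highest: {t.tail(10).abs_beta.mean():.4f}")
print("\nlow-uncertainty anchor pairs are untouched by news bias; "
      "uncertain pairs carry the largest effects.")
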