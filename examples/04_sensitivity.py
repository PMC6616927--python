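"""Sensitivity analysis of a fitted model.

Computes first-order Sobol indices (share of prediction variance explained by
each predictor alone) and a one-at-a-time profile sweeping one predictor over
0 +/- 2 sigma with the others at their mean.
"""

import beeftradeoff as bt
from beeftradeoff.modelsel import compare_families, fit_model, importance, make_tasks, select_predictors
from beeftradeoff.sensitivity import first_order_si, oat_profile

herd = bt.generate_herd(bt.default_config(seed=42))
indicators, _ = bt.pretreat_herd(herd)
task = next(t for t in make_tasks(indicators) if t.response == "PUFA/MUFA")
scores = compare_families(task, indicators, n_splits=20, seed=0, rf_trees=200)
subset = select_predictors(importance(task, indicators, scores.champion, 20, 0, 200))
model = fit_model(task, indicators, scores.champion, subset, seed=0, rf_trees=200)

res = first_order_si(model, n_base=50_000, seed=0)
print(f"model for {model.response!r} ({model.family}):")
for name, si in res.si.sort_values(ascending=False).items():
    print(f"  Si[{name}] = {si:.3f}")
print(f"  sum of Si = {res.sum_si:.3f} (< 1 indicates interaction effects)")

top = res.si.idxmax()
curve = oat_profile(model, top)
print(f"\nOAT profile of {top!r} (predictor swept over [-2, 2], others at 0):")
for i in range(0, len(curve.grid), 10):
    print(f"  x = {curve.grid[i]:+.1f} -> prediction {curve.prediction[i]:+.3f}")
print("  -> the slope/shape shows how the indicator responds across the trait range")
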