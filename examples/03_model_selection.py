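"""Champion-model selection for a single indicator.

Races the five regression families (lm, ridge, rf, plsr, sir) over shared
train/test splits for one indicator, screens predictors against a random
probe, refits the champion and reports apparent vs optimism-corrected
adjusted R-squared — the gap estimates how much the model overfits 30 animals.
"""

import beeftradeoff as bt
from beeftradeoff.modelsel import (
    apparent_adj_r2,
    compare_families,
    corrected_adj_r2,
    fit_model,
    importance,
    make_tasks,
    select_predictors,
)

herd = bt.generate_herd(bt.default_config(seed=42))
indicators, _ = bt.pretreat_herd(herd)

task = next(t for t in make_tasks(indicators) if t.response == "PUFA/MUFA")
print(f"response: {task.response}  ({len(task.candidates)} cross-group candidates)")

scores = compare_families(task, indicators, n_splits=20, seed=0, rf_trees=200)
print("median test MSE per family:")
for fam, mse in scores.mse.median().items():
    marker = "  <- champion" if fam == scores.champion else ""
    print(f"  {fam:>5s}: {mse:.3f}{marker}")

imps = importance(task, indicators, scores.champion, n_splits=20, seed=0, rf_trees=200)
subset = select_predictors(imps)
print(f"\npredictors kept (importance above the random probe): {subset}")

model = fit_model(task, indicators, scores.champion, subset, seed=0, rf_trees=200)
quality = corrected_adj_r2(task, indicators, scores.champion, subset, B=50, seed=0,
                           rf_trees=200)
print(f"adjusted R2: apparent {apparent_adj_r2(model, indicators):.3f}, "
      f"optimism-corrected {quality.adjR2_corrected:.3f}")
print("  -> the corrected value estimates out-of-sample fit; a large gap = overfitting")
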