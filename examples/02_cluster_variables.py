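"""Cluster the variables of each parameter of interest and summarize them.

Standardizes the herd, runs hierarchical clustering of variables around
latent components within each group (CP at k=6, fatty acids at k=6, flavor
descriptors at k=5), prints the cohesiveness of each solution, and shows the
24-indicator table the modeling stage consumes.
"""

import beeftradeoff as bt

herd = bt.generate_herd(bt.default_config(seed=42))
indicators, solutions = bt.pretreat_herd(herd)

for group, sol in solutions.items():
    print(f"{group}: {sol.k} clusters, cohesiveness {sol.homogeneity_pct:.1f}%")
    for cid in range(sol.k):
        members = sol.members(cid)
        loads = ", ".join(f"{m} ({sol.loadings[m]:+.2f})" for m in members[:4])
        more = "..." if len(members) > 4 else ""
        print(f"   cluster {cid}: {loads}{more}")

print(f"\nindicator table: {indicators.values.shape[0]} animals x "
      f"{indicators.values.shape[1]} indicators")
print("  cohesiveness = % of variable variance captured by the cluster latents;")
print("  each indicator is a cluster latent, a kept representative, or a passthrough.")
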