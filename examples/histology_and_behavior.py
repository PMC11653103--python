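"""Striatal interneuron densities, percent decreases, and behavior stats.

Recomputes the worked percent-decrease examples from the published
density means, generates a synthetic per-animal count table at those
means, runs the group t tests and rostrocaudal gradients, and rebuilds
the social-interaction t test from printed mean/SEM/n summaries.
"""

import numpy as np
import pandas as pd

from costria import histology, reference
from costria.stats import SummaryStat, t_from_summary
from costria.synthetic import simulate_histology

# worked examples straight from the published group means
chat = reference.TOTAL_CELLS["ChAT"]
print("ChAT total decrease: "
      f"{histology.percent_decrease(chat['control'][0], chat['VPA'][0]):.1f}% "
      "(2,335 -> 1,443 cells per brain)")
for _, row in reference.TOTAL_DENSITY.iterrows():
    d = histology.percent_decrease(row["control_mean"], row["vpa_mean"])
    print(f"  {row['marker']:>4} {row['region']:<5} {d:5.1f}% decrease "
          f"({row['control_mean']:.2f} -> {row['vpa_mean']:.2f} cells/mm^2)")

# synthetic per-animal table at the published means, n = 7 brains per group
means = pd.concat([
    reference.TOTAL_DENSITY.rename(columns={"control_mean": "density"})
    .assign(group="control")[["group", "region", "marker", "density"]],
    reference.TOTAL_DENSITY.rename(columns={"vpa_mean": "density"})
    .assign(group="VPA")[["group", "region", "marker", "density"]],
])
table = simulate_histology(means, noise_sd=6.0, n_animals=7, seed=0)
dens = histology.density_per_region(table)
comp = histology.regional_comparison(dens)
print("\ngroup comparisons on the synthetic table (t test, n = 7 animals):")
print(comp[["marker", "region", "mean_a", "mean_b", "t", "p"]]
      .round(4).to_string(index=False))

grad = histology.rostrocaudal_gradient(
    histology.density_per_region(
        simulate_histology(
            reference.SLICE_DENSITY_CHAT.rename(columns={"mean": "density"})
            .assign(marker="ChAT")[["group", "region", "marker", "slice", "density"]],
            noise_sd=0.0, n_animals=2, seed=0,
        )
    )
)
print("\nChAT rostrocaudal gradients (slices 1 rostral -> 4 caudal):")
print(grad.query("group == 'control'").round(2).to_string(index=False))

res = t_from_summary(SummaryStat(352.8, 12.26, 18), SummaryStat(314.1, 10.68, 18))
print(f"\nsocial interaction, compartment time: t({res.df:.0f}) = "
      f"{res.statistic:.3f}, p = {res.p:.4f} "
      "(rebuilt from printed mean +/- SEM, n = 18 per group)")
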