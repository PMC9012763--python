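"""Aggregate multi-group expert estimates and map their disagreement.

A protocol-shaped CPT is jittered into four synthetic expert groups,
the groups are averaged back into a definitive table, and each element's
between-group relative range (max - min over mean; 0 = exact agreement)
is banded. The worked single-element case: estimates of 0% and 5%
disagree by exactly twice their mean, relative range 2.00.
"""

import numpy as np

from esbbn import (
    ElicitationModel, GroupNoiseModel, NodeSpec,
    aggregate_groups, disagreement_map, generate_cpt, perturb_groups, relative_range,
)

print(f"worked case, estimates 0% and 5%: relative range = "
      f"{relative_range([0.0, 0.05]):.2f}")

child = NodeSpec("DissolvedOxygen", ("High", "Medium", "Low"))
parents = [NodeSpec("WaterTemp", ("Low", "Medium", "High")),
           NodeSpec("BOD", ("Low", "Medium", "High"))]
base = generate_cpt(child, parents, ElicitationModel(seed=5))
groups = perturb_groups(base, GroupNoiseModel(n_groups=4, seed=5))
definitive = aggregate_groups(groups)
err = float(np.max(np.abs(definitive.table - base.table)))
print(f"4-group aggregation: max element error vs base CPT = {err:.4f}")

dm = disagreement_map(groups)
frame = dm.to_dataframe()
print(frame.groupby("band", observed=True)["relative_range"].agg(["count", "mean"]))
print("high-band (poor agreement) elements sit at the low-probability "
      "entries, which barely influence posteriors.")
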