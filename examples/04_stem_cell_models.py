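"""Equipotent vs hierarchical limbal stem cells: clone-number dynamics.

In the equipotent model every limbal cell is a stem cell and neutral drift
steadily coarsens the limbal clones. In the hierarchical model rare,
irreplaceable stem cells pin the clone count at the stem-cell number.
"""

import numpy as np

from corneasim import stats
from corneasim.engine import ModelConfig, run

common = dict(R_total=21, m=3, rls=20, seed=2, lambda_s=1.0, a=0.5,
              checkpoint_interval=2.0)

eq = ModelConfig(stem_model="equipotent", **common)
tr_eq = run(eq, stop="time", tau_max=60, record_snapshots=True)
limbal_eq = stats.clone_counts(tr_eq, "LIMBUS")

hier = ModelConfig(stem_model="hierarchical", stem_fraction=0.1, **common)
tr_h = run(hier, stop="time", tau_max=60, record_snapshots=True)
limbal_h = stats.clone_counts(tr_h, "LIMBUS")
n_s = int(np.sum(tr_h.final_state.cell_type == 0))

print("tau   equipotent clones   hierarchical clones")
for i in range(0, len(limbal_eq), 5):
    print(f"{limbal_eq['tau'].iloc[i]:5.0f} {limbal_eq['n_clones'].iloc[i]:>12} "
          f"{limbal_h['n_clones'].iloc[min(i, len(limbal_h)-1)]:>18}")
print(f"\nhierarchical stem-cell count: {n_s} (clone count is pinned there);")
print("equipotent clones keep coarsening by neutral drift.")
css = stats.clone_size_stats(tr_eq, "LIMBUS")
print(f"equipotent scaled clone sizes, late-time KS distance: "
      f"{css.ks_statistic:.2f} (scale invariance)")
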