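"""Coupled replication-removal with strong centripetal bias: stripes.

Runs the locally-coupled model (removal within m cells of the divider,
inward-facing sector) on a small tissue until every corneal site holds a
limbus-derived cell, then reports the renewal time against the analytic
bound 2R/(m+1) and the stripe order of the final pattern.
"""

from corneasim import stats, theory
from corneasim.engine import ModelConfig, run

cfg = ModelConfig(R_total=31, m=5, rls=60, seed=1,
                  lambda_s=1 / 3, a=1.0)  # saturated limbal output
print(f"coupled model, bias={cfg.bias:.2f}, RLS={cfg.rls}, R={cfg.R:.0f}")

tr = run(cfg, stop="renewal", tau_max=300)
st = tr.final_state
limit = theory.renewal_time_limit_coupled(cfg.R, cfg.m)
print(f"full renewal after {tr.renewal_tau:.1f} corneal replication times "
      f"(analytic lower limit {limit:.1f})")
print(f"front depth: {stats.front_depth(st):.1f} cells (= R when renewed)")
um = stats.unmixing(st, (5, 15))
print(f"clonal unmixing at mid-depth: {um:.2f} "
      "(1 = perfect centripetal stripes)")
print("Strong local bias renews the tissue near the analytic speed limit "
      "and organizes clones into radial stripes.")
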