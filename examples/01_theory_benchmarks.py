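"""Closed-form benchmarks for the default geometry (R=100, m=5).

Prints the analytic limits the simulator is checked against: the minimal
progenitor lifespan and renewal-time bound of the locally-coupled model,
the zero-lifespan renewal times of the uncoupled model (stem cells only),
and the tenfold penalty of removing the centripetal bias.
"""

from corneasim import theory as T
from corneasim.engine import ModelConfig

cfg = ModelConfig()  # physiological defaults
R, m = int(cfg.R), int(cfg.m)

print(f"geometry: corneal radius R={R} cells, interaction radius m={m}")
print(f"rates: lambda_s={cfg.lambda_s:.3f}/d, lambda_p={cfg.lambda_p:.3f}/d,"
      f" asymmetric fraction a={cfg.a}")
print()
print(f"min RLS, coupled + ideal bias (R/m):        "
      f"{T.min_rls_ideal_bias(R, m)} replications")
print(f"renewal-time limit, coupled (2R/(m+1)):     "
      f"{T.renewal_time_limit_coupled(R, m):.1f} replication times")
print(f"min renewal, uncoupled ideal bias (log2 R): "
      f"{T.min_renewal_time_uncoupled(R):.2f} "
      f"(ceil {T.min_renewal_time_uncoupled(R, integer=True):.0f})")
tw = T.renewal_time_uncoupled_rls0(R, cfg.lambda_s, cfg.lambda_p, cfg.a,
                                   "ideal")
tn = T.renewal_time_uncoupled_rls0(R, cfg.lambda_s, cfg.lambda_p, cfg.a,
                                   "none")
print(f"zero-RLS renewal, uncoupled ideal bias:     {tw:.0f} replication times")
print(f"zero-RLS renewal, uncoupled no bias:        {tn:.0f} replication times")
print(f"no-bias / ideal-bias ratio (2 H_R R/(R+1)): "
      f"{T.uncoupled_bias_ratio(R):.2f}")
p = T.front_advance_probability(R, m, n_samples=200_000)
print(f"front-advance probability, no bias:         {p:.3f} (~3/8)")
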