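"""Conditional dependence and model comparison.

Shows the two remaining inferential tools: evolution *partial* correlations
(conditional trend dependence, from inverted covariance draws) and DIC for
choosing the number of seasonal harmonics.
"""

import numpy as np

import sutse
from sutse.inference import MCMCConfig

# three series: 0-1 strongly coupled, 2 independent
spec = sutse.build_model(3, 1)
evo_corr = np.eye(3)
evo_corr[0, 1] = evo_corr[1, 0] = 0.8
params = sutse.CovParams([0.05] * 3, np.eye(3), [0.01] * 3, evo_corr)
init = np.zeros(spec.state_dim)
for c in range(3):
    init[c * spec.block_dim] = 7.0 + 0.3 * c
    init[c * spec.block_dim + 2] = 0.20  # clear annual cycle (+-20% of the level)
    init[c * spec.block_dim + 3] = 0.10
config = sutse.SimulationConfig(spec=spec, params=params, init_state=init,
                                n_months=120, seed=21)
data = sutse.simulate(config).log_series

posterior = sutse.sample_posterior(
    data, spec, config=MCMCConfig(n_chains=2, n_warmup=300, n_keep=600, seed=4)
)

part = sutse.correlation_summary(posterior, kind="partial-evolution")
print("P(partial evolution correlation > 0 | Y), upper triangle:")
print(part.to_frame().to_string())

out = sutse.dic(posterior, data, spec, thin=4)
print(f"\nDIC (q=1 model): {out['dic']:.1f}  (mean deviance {out['mean_deviance']:.1f}, "
      f"effective parameters p_D {out['p_d']:.1f})")

spec0 = sutse.build_model(3, 0)
post0 = sutse.sample_posterior(
    data, spec0, config=MCMCConfig(n_chains=2, n_warmup=300, n_keep=600, seed=4)
)
out0 = sutse.dic(post0, data, spec0, thin=4)
print(f"DIC (trend-only): {out0['dic']:.1f}")
print(
    "\nLower DIC is better; with a real annual cycle in the data the "
    "seasonal model should win. Partial correlations near +-1 with peaked "
    "posteriors indicate direct (conditional) coupling between trends."
)
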