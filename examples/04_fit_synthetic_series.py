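"""Generate synthetic monthly series and refit the model to them.

The generator integrates the system at the reference parameters and
samples January-November of each year (the national statistics skip
December).  A noiseless refit recovers the trajectory-identifiable
parameter combinations exactly; with 2% observation noise the fitted
trajectory still explains the data, but several parameter
combinations become ambiguous at this window length.
"""

import numpy as np

from hospflow import (
    GeneratorConfig,
    ModelParams,
    REFERENCE_PARAMS,
    fit,
    generate_series,
    identifiable_combinations,
    predict,
)

guess = ModelParams.from_array(REFERENCE_PARAMS.to_array() * 1.2)

# --- noiseless series: the estimator inverts the generator exactly ---
clean = generate_series(GeneratorConfig(noise_sd=0.0, seed=1))
res = fit(clean, guess, n_starts=1)
print(f"noiseless refit: SSE = {res.sse:.3g}, R^2 = {res.r_squared:.6f}")
print("identifiable combination     estimate        truth")
truth = identifiable_combinations(REFERENCE_PARAMS)
est = identifiable_combinations(res.params)
for key in truth:
    print(f"  {key:24s} {est[key]:12.6g} {truth[key]:12.6g}")

# --- 2% noise: the trajectory is still recovered, parameters blur ---
cfg = GeneratorConfig(noise_sd=0.02, seed=1)
noisy = generate_series(cfg)
res_n = fit(noisy, guess, n_starts=1)
fitted = predict(res_n.params, res_n.initial_state, noisy.times)
ideal = predict(cfg.params, cfg.initial, noisy.times)
traj_err = np.mean(np.abs(fitted - ideal) / ideal)
print(f"\nnoisy refit (2% noise, 8 years x 11 months x 3 tiers):")
print(f"  pooled R^2 = {res_n.r_squared:.4f}")
print(f"  mean relative distance of fitted trajectory from the")
print(f"  noiseless generating trajectory: {traj_err:.3%}")

print("""
The trajectory pins down nine parameter combinations (per-tier
crowding r/m and net linear rate, plus the transfer rates); a tier's
growth/churn/capacity triple is never separately identifiable from
visit counts.  With observation noise even some of the nine blur:
different transfer structures reproduce an 88-month window almost
equally well, although the fitted trajectory itself stays within a
percent of the truth.""")
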