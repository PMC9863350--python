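"""Single-trial spatial analysis with AR1 x AR1 residuals.

Simulates one p-rep field trial with known spatial correlation, runs the
forward model-selection ladder, and prints the recovered correlations,
variance components, and any flagged outlier plots.
"""

import numpy as np

from breedgain.simulate import SimConfig, TraitArchitecture, simulate_founders, simulate_trial
from breedgain.spatial import TrialLayout, flag_outliers, sample_variogram, select_spatial_model

arch = TraitArchitecture(rho_range=0.5, rho_row=0.4, spatial_share=0.7)
cfg = SimConfig(ranges=16, rows=20, single_rep_fraction=0.5)
truth, _ = simulate_founders(arch, SimConfig(founders_per_pool=80), seed=4)
rng = np.random.default_rng(4)
trial = simulate_trial(truth[:120], "DEMO", arch, cfg, rng)

layout = TrialLayout.from_frame(trial)
fit = select_spatial_model(layout, trial["GY"].to_numpy())

print(f"Selected terms: {fit.terms}")
print(f"Fitted AR1 correlations: range {fit.rho_range:.2f}, row {fit.rho_row:.2f} "
      "(truth: 0.50, 0.40 diluted by the nugget share)")
print(f"Variance components: genotype {fit.sigma2_g:.3f}, residual {fit.sigma2_e:.3f}")
print(f"REML log-likelihood {fit.rll:.1f}, AIC {fit.aic:.1f}")

out = flag_outliers(fit)
print(f"Outlier plots at |z| > 3.5: {len(out)} of {fit.n}")

v = sample_variogram(fit.residuals, layout, max_lag=3)
face = v[v["row_lag"] == 0]
print("\nVariogram range-face (rising semivariance = spatial trend captured):")
print(face[["range_lag", "semivariance", "count"]].to_string(index=False))
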