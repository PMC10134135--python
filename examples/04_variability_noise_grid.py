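"""Biological variability vs measurement noise.

Scales the standard deviations of the biological coefficients (beta) and
the measurement-noise vector (eps) independently on a factorial grid.
Biological variability dominates: beta x 0 gives near-perfect separation at
any tested noise level, while the within-person scenario (beta x 0.5 —
within-person variability is about a factor 2 below between-person) lifts
the AUC well above the calibration point (1, 1).
"""

from irsim import (
    FixtureSpec,
    calibrate_descriptive,
    calibrate_noise,
    generate_reference_cohorts,
    noise_grid_sweep,
)

spec = FixtureSpec(
    grid_start=1000.0, grid_stop=1240.0, r_components=60,
    n_per_class=150, n_blanks=40, signal_amplitude=0.035, seed=8,
)
controls, cases, blanks, _ = generate_reference_cohorts(spec)
result = noise_grid_sweep(
    calibrate_descriptive(controls),
    calibrate_descriptive(cases),
    calibrate_noise(blanks),
    beta_scales=[0.0, 0.5, 1.0, 2.0],
    eps_scales=[0.0, 1.0],
    n_controls=150, n_cases=150, replicates=3, seed=9, k=5,
)
print("beta x   eps x   mean AUC")
for _, cell in result.cells.iterrows():
    print(f"{cell['beta_scale']:6.1f}  {cell['eps_scale']:6.1f}   {cell['mean_auc']:.3f}")
print("(rows: AUC falls as biological variability grows; the eps columns show")
print(" measurement noise matters far less than biological variability)")
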