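"""Compute residual feed intake (RFI) on a synthetic herd.

RFI is the residual of DMI regressed on milk energy, metabolic BW, BW
change and management classes (DIM, lactation, cohort); a more negative
RFI means the cow eats less than her production predicts.
"""

import warnings

import thermofeed as tf

warnings.simplefilter("ignore")

cfg = tf.SimConfig(n_cows=300, seed=4)  # truth: b1=0.37, b2=0.10, b3=0.30
ds = tf.simulate_herd(cfg)
records = tf.build_efficiency_records(
    ds.dmi_daily, ds.milk_weekly, ds.bw, ds.cows, cfg.trial_days
)
fit = tf.compute_rfi(records)

print(f"cows in model: {fit.n_cows}, design rank: {fit.rank}")
for name, truth in zip(("milke", "mbw", "delta_bw"), cfg.rfi_true_coefs):
    print(f"  b[{name}] = {fit.coef(name):.3f} +- {fit.se(name):.3f}   (generated with {truth})")
print(f"adjusted R2: {fit.adj_r2:.2f}")
print(f"RFI mean: {fit.residuals.mean():.1e} (zero by construction), SD {fit.residuals.std():.2f} kg/d")
print(
    "\nThe partial regression coefficients recover the energy-sink"
    " coefficients the herd was generated with; the residuals are the"
    " per-cow RFI values."
)
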