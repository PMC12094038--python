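"""Associate temperature phenotypes with feed-efficiency traits.

Trial-level OLS (cohort + THI adjusted), a cohort-controlled partial
correlation, and the adjusted-R2 comparison of the RFI model with and
without a temperature trait.
"""

import warnings

import thermofeed as tf
from thermofeed.association import regress_trait
from thermofeed.pipeline import trial_association_frame

warnings.simplefilter("ignore")

cfg = tf.SimConfig(n_cows=300, seed=5)  # injected slope: -2.5 kg/d per degC
ds = tf.simulate_herd(cfg)
frame = trial_association_frame(ds)

res = regress_trait(
    frame.rename(columns={"mean_temp": "temp_trait", "dmi": "response"}), "dmi", "mean_temp"
)
print(f"DMI on mean body temperature: slope {res.slope:.2f} +- {res.se:.2f} kg/d per degC "
      f"(p={res.p_value:.3f}, n={res.n}; injected {cfg.dmi_temp_slope})")

pc = tf.partial_correlation(frame["mean_temp"], frame["dmi"], frame["cohort"])
print(f"partial correlation (cohort-controlled): r = {pc.r:.2f}, p = {pc.p_value:.3f}")

records = tf.build_efficiency_records(ds.dmi_daily, ds.milk_weekly, ds.bw, ds.cows, cfg.trial_days)
cmp_res = tf.compare_rfi_models(records, frame.set_index("cow_id")["mean_temp"], "mean_temp")
print(cmp_res.display())
print(
    "\nA negative slope means hotter cows eat less; the tiny adjusted-R2"
    " change shows mean temperature adds little to the RFI model beyond the"
    " energy sinks, mirroring what such models show on real herds."
)
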