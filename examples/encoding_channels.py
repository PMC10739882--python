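"""Window-wise encoding models and channel classification.

Generates a synthetic cohort whose channels code RPE variables with known
gains, fits the competing encoding models (RPE value / salience /
asymmetric) at the response-kernel peak, and classifies each channel into
the four-category coding taxonomy from its conditional (channel-level)
coefficients plus channel-own significance tests.
"""

import pandas as pd

from asymrpe import encoding, synth

cfg = synth.CohortConfig(n_subjects=3, channels_per_region=3)
cohort = synth.generate_cohort(cfg, seed=4)
windows = encoding.envelope_windows(cohort)
truth = cohort.channel_table
truth["chan"] = truth.subject + ":" + truth.channel

# model comparison at the windows spanning the INS kernel peak (~275 ms)
res = encoding.fit_window_models(
    windows, cohort.trials, truth, region="INS", window_indices=[10, 11]
)
print("AIC comparison at the kernel-peak windows (INS):")
print(encoding.compare_models_aic(res).round(1).to_string())

# channel classification from the asymmetric model, all windows
res_full = encoding.fit_window_models(
    windows, cohort.trials, truth, region="INS", models=("asymmetric",)
)
coefs = encoding.extract_channel_coefficients(res_full)
ins_windows = {
    k: v for k, v in windows.items() if k[1].startswith("ins")
}
tests = encoding.channel_ols_tests(ins_windows, cohort.trials)
cats = encoding.classify_all_channels(coefs, tests)

merged = cats.merge(
    truth[["chan", "category", "polarity"]], on="chan",
    suffixes=("_estimated", "_true"),
)
print("\nChannel classification vs ground truth (INS):")
print(merged[["chan", "category_true", "category_estimated",
              "polarity_true", "polarity_estimated",
              "prpe_peak", "nrpe_peak"]].round(2).to_string(index=False))
n_ok = (merged.category_true == merged.category_estimated).sum()
print(
    f"\n{n_ok}/{len(merged)} channels recovered. The asymmetric model's "
    "lower AIC at the peak reflects channels whose positive- and "
    "negative-RPE gains differ; peak coefficients are in baseline z-units "
    "per unit RPE magnitude."
)
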