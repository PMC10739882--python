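"""Lagged directed connectivity between INS and dMPFC.

Couples synthetic channel pairs at a +75 ms lag (INS leading) with a
coupling strength that grows with positive-RPE magnitude, then runs the
full connectivity analysis: per-trial lagged cross-correlation, per-lag
mixed models, peak-lag extraction, and pair categorization.
"""

from asymrpe import connectivity, synth

cfg = synth.CohortConfig(
    n_subjects=2, channels_per_region=1,
    couplings_per_subject=2, null_couplings_per_subject=1,
    coupling_lag_ms=75.0, coupling_m_p=0.25, coupling_m_sd=0.05,
    time_span_s=(0.0, 1.0),
)
cohort = synth.generate_cohort(cfg, seed=8)

xcorr = {
    key: connectivity.trial_lagged_xcorr(ins, dmpfc)[0]
    for key, (ins, dmpfc) in cohort.pair_envelopes.items()
}
results = connectivity.fit_lag_models(xcorr, cohort.trials)

prpe = results.table[results.table.term == "prpe"].set_index("lag_ms")
peak_lag = prpe["estimate"].abs().idxmax()
print("Region-level pRPE effect on INS->dMPFC correlation by lag (subset):")
print(prpe.loc[[-100.0, 0.0, 50.0, 75.0, 100.0, 200.0],
               ["estimate", "se", "q"]].round(4).to_string())
print(f"\nFixed-effect pRPE peak at {peak_lag:+.0f} ms "
      "(positive lag = INS precedes dMPFC).")

pair_coefs = connectivity.extract_pair_coefficients(results)
pair_tests = connectivity.pair_ols_tests(xcorr, cohort.trials)
categories = connectivity.classify_all_pairs(pair_coefs, pair_tests)
truth = {
    f"{c.subject}:{c.ins_channel}->{c.dmpfc_channel}":
        "pRPE-coupled" if c.m_p != 0 else "unmodulated"
    for c in cohort.couplings
}
categories["ground_truth"] = categories["chan"].map(truth)
print("\nPair classification:")
print(categories[["chan", "ground_truth", "category", "polarity",
                  "prpe_peak_lag_ms"]].to_string(index=False))
print(
    "\npRPE-coupled pairs should be recovered as category pRPE with a peak "
    "lag near +75 ms; unmodulated pairs (coupled, but with constant "
    "strength) should stay 'none'."
)
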