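"""Trial-level RPEs and the RT-adaptation model ladder.

Simulates a cohort of adaptive agents on the staircased interval-timing
task with a planted post-positive-RPE slowing of 0.02 s per unit pRPE,
derives expected value and RPEs from each agent's fitted logistic value
model, and runs the hierarchical mixed-model comparison (intercept-only
up to the asymmetric-RPE model).
"""

from asymrpe import behavior, synth
from asymrpe.lmm import likelihood_ratio_test

frames = synth.generate_behavior_cohort(
    n_subjects=6, seed=11,
    agent=synth.AdaptiveAgentConfig(prpe_slowing=0.02),
)
one = next(iter(frames.values()))
print(f"{len(frames)} subjects, {len(one)} cleaned trials for the first one")
print("\nFirst subject, first 5 trials (pipeline-derived RL variables):")
print(one[["condition", "tolerance_ms", "outcome", "p_win", "ev",
           "prpe", "nrpe"]].head().round(3).to_string(index=False))

table = behavior.rt_adaptation_table(frames)
res = behavior.run_model_ladder(table)

print("\nModel comparison (each model vs its designated null):")
print(res["lrt"].round(4).to_string(index=False))
print("\nAIC per model (lower is better):")
print(res["aic"][["label", "aic"]].round(1).to_string())

b6 = res["fits"]["b6"]
lrt = likelihood_ratio_test(res["fits"]["b3"], res["fits"]["b6"])
print("\nAsymmetric-RPE model coefficients:")
print(b6.fixed.round(4).to_string())
print(
    f"\nThe prev_prpe coefficient (~0.02 s per unit positive-RPE magnitude) "
    f"recovers the planted slowing; the b6-vs-b3 test "
    f"(chi2={lrt.chi2:.1f}, df={lrt.df}, p={lrt.p:.2g}) shows RPEs explain "
    f"RT changes beyond previous RT and outcome. prev_rt near -0.75 is the "
    f"agents' mean reversion toward the 1 s target."
)
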