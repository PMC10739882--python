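"""From raw broadband voltage to baseline-normalized HFA windows.

Renders a known z-unit envelope into a 70–150 Hz-modulated voltage trace,
then runs the spectral pipeline: multitaper sub-band log power, bootstrap
baseline z-scoring, sub-band averaging, and 50 ms sliding-window means.
"""

import numpy as np

from asymrpe import hfa, synth

rng = np.random.default_rng(2)
time_grid = np.round(np.arange(-0.4, 1.4001, 0.025), 3)

channel = synth.make_channel_ground_truth(
    "pRPE", "regular", 1.0, rng, region="INS"
)
import pandas as pd

n_trials = 120
rl = pd.DataFrame({
    "ev": rng.normal(0, 0.4, n_trials),
    "prpe": np.abs(rng.normal(0, 0.6, n_trials)),
    "nrpe": np.abs(rng.normal(0, 0.6, n_trials)),
})
envelope = synth.simulate_hfa_envelopes(channel, rl, time_grid, rng)
raw, times = synth.envelope_to_raw_trace(envelope, time_grid, 1000.0, rng)
print(f"raw epochs: {raw.shape[0]} trials x {raw.shape[1]} samples at 1 kHz")

log_power, grid = hfa.extract_hfa_power(raw, 1000.0, times)
print(f"sub-band log power: {log_power.shape} "
      "(trials x 9 sub-bands x 25 ms grid)")

baseline = (grid >= -0.25) & (grid <= -0.05)
feedback = (grid >= -0.25) & (grid <= 1.2)
z = hfa.bootstrap_baseline_normalize(
    log_power[:, :, feedback], log_power[:, :, baseline], n_boot=500, rng=0
)
windows, starts = hfa.window_average(z, grid[feedback])
print(f"{windows.shape[1]} analysis windows from "
      f"{starts[0]*1000:.0f} to {starts[-1]*1000:.0f} ms post-feedback")

true_windows, _ = hfa.window_average(envelope, time_grid)
profile_r = np.corrcoef(windows.mean(axis=0), true_windows.mean(axis=0))[0, 1]
print(f"trial-averaged recovered-vs-true window profile: r = {profile_r:.3f}")
print(
    "The recovered profile peaks at the channel's response-kernel latency "
    f"(~{channel.kernel_peak_s*1000:.0f} ms); r near 1 confirms the "
    "spectral pipeline linearly recovers the embedded envelope on average "
    "(single-trial 50 ms power estimates are intrinsically noisy)."
)
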