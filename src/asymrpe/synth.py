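"""Synthetic cohorts with known ground truth.

Two generators live here:

* **Behavioral cohorts** — adaptive agents whose response time reverts
  toward the target and carries tunable previous-trial RPE effects, used
  to validate the RT-adaptation model ladder (power, sign recovery, null
  calibration).
* **Neural cohorts** — channels whose feedback-locked high-frequency
  activity (HFA) envelope is a kernel-shaped linear function of expected
  value and positive/negative RPE magnitude plus autocorrelated noise,
  optionally rendered down to broadband voltage traces; and channel pairs
  whose lagged coupling gain is modulated trial-by-trial by the same RL
  variables.

Ground-truth quantities (per-channel gains, coding categories, coupling
lags) are stored alongside the data so recovery by the analysis pipeline
can be scored exactly. Envelopes are generated directly in baseline
z-units, which makes ground-truth gains commensurate with fitted
regression coefficients; the raw-trace path exists to exercise the
spectral extraction pipeline and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm

from . import rl, task

__all__ = [
    "ChannelGroundTruth",
    "CouplingSpec",
    "CohortConfig",
    "SyntheticCohort",
    "AdaptiveAgentConfig",
    "generate_behavior_cohort",
    "make_channel_ground_truth",
    "simulate_hfa_envelopes",
    "envelope_to_raw_trace",
    "simulate_coupled_pair",
    "generate_cohort",
    "stationary_win_probability",
    "response_kernel",
    "CATEGORIES",
]

CATEGORIES = ("pRPE", "nRPE", "sRPE", "uRPE", "none")
REGIONS = ("dMPFC", "INS")

#: region-specific synthetic electrode clouds (MNI-like mm): mean, SD
_REGION_CLOUDS = {"dMPFC": ((6.0, 20.0, 40.0), 8.0), "INS": ((-38.0, 5.0, 2.0), 6.0)}
#: HFA response kernel peak latency per region (s)
_KERNEL_PEAK = {"dMPFC": 0.300, "INS": 0.275}


# ---------------------------------------------------------------------------
# behavioral cohorts with RT adaptation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdaptiveAgentConfig:
    """Agent with trial-to-trial RT dynamics.

    rt_i = target + bias + ar_coef*(rt_{i-1} - target - bias)
           + prpe_slowing*prpe_{i-1} + nrpe_slowing*nrpe_{i-1} + noise.

    ``ar_coef`` of 0.25 makes the previous-RT fixed effect on RT change
    approximately -0.75, the value seen in patient behavior. The RPE terms
    use the agent's *generative* expected value (closed-form win
    probability of a Gaussian timer), so planted effects are exact.
    """

    timing_bias: float = 0.0
    timing_sd: float = 0.06
    ar_coef: float = 0.25
    prpe_slowing: float = 0.0  # s per unit positive-RPE magnitude
    nrpe_slowing: float = 0.0
    lapse_rate: float = 0.0


def stationary_win_probability(
    tolerance_ms, timing_sd: float, timing_bias: float = 0.0
) -> np.ndarray:
    """Closed-form win probability of a Gaussian timer: P(|error| <= t)
    for error ~ N(bias, sd^2), tolerances in ms, timings in s."""
    t = np.asarray(tolerance_ms, float) / 1000.0
    return norm.cdf((t - timing_bias) / timing_sd) - norm.cdf(
        (-t - timing_bias) / timing_sd
    )


def _simulate_adaptive_session(
    config: task.TaskConfig, agent: AdaptiveAgentConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """One adaptive-agent session; returns the trial frame augmented with
    *generative* RL variables (columns prefixed gen_)."""
    # effective error SD of the AR process, used for the generative EV
    sd_eff = agent.timing_sd / np.sqrt(1.0 - agent.ar_coef**2)
    level = dict(config.initial_tolerance)
    conditions = sorted(set(config.block_order))
    center = config.target_interval + agent.timing_bias

    def play(tol_ms: float, prev_dev: float, prev_prpe: float, prev_nrpe: float):
        noise = rng.normal(0.0, agent.timing_sd)
        lapse = rng.random() < agent.lapse_rate
        neutral = rng.random() < config.neutral_rate
        if lapse:
            return None, "missing", prev_dev
        dev = agent.ar_coef * prev_dev + noise
        rt = (center + dev + agent.prpe_slowing * prev_prpe
              + agent.nrpe_slowing * prev_nrpe)
        err = rt - config.target_interval
        if neutral:
            outcome = "neutral"
        else:
            outcome = "win" if abs(err) * 1000.0 <= tol_ms else "loss"
        return float(rt), outcome, dev

    # staircase burn-in per condition
    for cond in conditions:
        prev_dev = 0.0
        for _ in range(config.staircase_burnin):
            tol = task.effective_tolerance(level[cond], config)
            _, outcome, prev_dev = play(tol, prev_dev, 0.0, 0.0)
            level[cond] = task.staircase_level_update(cond, level[cond], outcome, config)

    rows = []
    idx = 0
    prev_dev, prev_prpe, prev_nrpe = 0.0, 0.0, 0.0
    for block_index, cond in enumerate(config.block_order):
        for _ in range(config.trials_per_block):
            tol = task.effective_tolerance(level[cond], config)
            rt, outcome, prev_dev = play(tol, prev_dev, prev_prpe, prev_nrpe)
            p = float(stationary_win_probability(tol, sd_eff, agent.timing_bias))
            ev = 2.0 * p - 1.0
            reward = task.REWARD[outcome]
            srpe = reward - ev if np.isfinite(reward) else np.nan
            if np.isfinite(srpe):
                prev_prpe, prev_nrpe = max(srpe, 0.0), max(-srpe, 0.0)
            else:
                prev_prpe, prev_nrpe = 0.0, 0.0
            rows.append(
                {
                    "trial_index": idx, "block_index": block_index,
                    "condition": cond, "tolerance_ms": tol,
                    "rt_s": rt if rt is not None else np.nan,
                    "outcome": outcome, "reward": reward,
                    "gen_p_win": p, "gen_ev": ev, "gen_srpe": srpe,
                    "gen_prpe": prev_prpe if np.isfinite(srpe) else np.nan,
                    "gen_nrpe": prev_nrpe if np.isfinite(srpe) else np.nan,
                }
            )
            level[cond] = task.staircase_level_update(cond, level[cond], outcome, config)
            idx += 1
    return pd.DataFrame(rows)


def generate_behavior_cohort(
    n_subjects: int,
    seed: int,
    agent: AdaptiveAgentConfig | None = None,
    config: task.TaskConfig | None = None,
    bias_sd: float = 0.01,
    ar_sd: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Simulate a cohort of adaptive agents (subject-level heterogeneity in
    timing bias and RT autocorrelation) and return per-subject trial
    frames augmented with pipeline-fitted RL variables, ready for
    :func:`asymrpe.behavior.rt_adaptation_table`."""
    agent = agent or AdaptiveAgentConfig()
    config = config or task.TaskConfig()
    master = np.random.default_rng(seed)
    frames: dict[str, pd.DataFrame] = {}
    for i in range(n_subjects):
        rng = np.random.default_rng(master.integers(2**31))
        subj_agent = replace(
            agent,
            timing_bias=agent.timing_bias + rng.normal(0.0, bias_sd),
            ar_coef=float(np.clip(agent.ar_coef + rng.normal(0.0, ar_sd), 0.0, 0.9)),
        )
        frame = _simulate_adaptive_session(config, subj_agent, rng)
        cleaned = task.trials_to_frame(
            task.reject_trials(task.frame_to_trials(frame))
        )
        merged = frame[frame["trial_index"].isin(cleaned["trial_index"])]
        frames[f"S{i:02d}"] = rl.augment_trials(merged.reset_index(drop=True))
    return frames


# ---------------------------------------------------------------------------
# channel ground truth and HFA envelopes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelGroundTruth:
    """Generative description of one channel's RPE coding."""

    subject: str
    channel: str
    region: str
    xyz: tuple[float, float, float]
    g_ev: float
    g_p: float
    g_n: float
    kernel_peak_s: float
    kernel_width_s: float
    noise_sd: float
    ar1: float
    category: str
    polarity: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not 0.0 <= self.kernel_peak_s <= 0.6:
            raise ValueError("kernel peak must lie within the 0-0.6 s window")
        _check_gain_signs(self.category, self.g_p, self.g_n)


def _check_gain_signs(category: str, g_p: float, g_n: float) -> None:
    ok = {
        "pRPE": g_p != 0 and g_n == 0,
        "nRPE": g_n != 0 and g_p == 0,
        "sRPE": g_p * g_n < 0,
        "uRPE": g_p * g_n > 0,
        "none": g_p == 0 and g_n == 0,
    }[category]
    if not ok:
        raise ValueError(
            f"gains (g_p={g_p}, g_n={g_n}) inconsistent with category {category}"
        )


#: polarity -> sign of (g_p, g_n); None marks an unused gain.
#: "regular" nRPE coding means HFA *decreases* with negative-RPE magnitude.
_POLARITY_SIGNS = {
    ("pRPE", "regular"): (1, None), ("pRPE", "inverted"): (-1, None),
    ("nRPE", "regular"): (None, -1), ("nRPE", "inverted"): (None, 1),
    ("sRPE", "regular"): (1, -1), ("sRPE", "inverted"): (-1, 1),
    ("uRPE", "increasing"): (1, 1), ("uRPE", "decreasing"): (-1, -1),
    ("none", "none"): (None, None),
}


def make_channel_ground_truth(
    category: str,
    polarity: str,
    gain_scale: float,
    rng: np.random.Generator,
    *,
    subject: str = "S00",
    channel: str = "ch00",
    region: str = "dMPFC",
    noise_sd: float = 1.0,
    ar1: float = 0.5,
    gain_jitter: float = 0.2,
) -> ChannelGroundTruth:
    """Draw one channel's generative gains for a category/polarity.

    Gain magnitudes are ``gain_scale`` jittered by ±``gain_jitter``
    (relative); signs follow the coding taxonomy: e.g. a regular sRPE
    channel has g_p > 0 and g_n < 0, an increasing uRPE channel g_p > 0
    and g_n > 0. The EV gain is drawn at half scale with random sign for
    any responsive channel.
    """
    if (category, polarity) not in _POLARITY_SIGNS:
        raise ValueError(f"invalid category/polarity: {category}/{polarity}")
    sign_p, sign_n = _POLARITY_SIGNS[(category, polarity)]

    def mag() -> float:
        return gain_scale * float(rng.uniform(1.0 - gain_jitter, 1.0 + gain_jitter))

    g_p = sign_p * mag() if sign_p is not None else 0.0
    g_n = sign_n * mag() if sign_n is not None else 0.0
    g_ev = 0.0
    if category != "none":
        g_ev = float(rng.choice([-1.0, 1.0])) * 0.5 * mag()
    center, sd = _REGION_CLOUDS[region]
    xyz = tuple(float(v) for v in rng.normal(center, sd))
    return ChannelGroundTruth(
        subject=subject, channel=channel, region=region, xyz=xyz,
        g_ev=g_ev, g_p=g_p, g_n=g_n,
        kernel_peak_s=_KERNEL_PEAK[region], kernel_width_s=0.075,
        noise_sd=noise_sd, ar1=ar1, category=category, polarity=polarity,
    )


def response_kernel(time_grid: np.ndarray, peak_s: float, width_s: float) -> np.ndarray:
    """Unit-peak Gaussian bump at the channel's response latency; zero
    before feedback onset."""
    k = np.exp(-0.5 * ((time_grid - peak_s) / width_s) ** 2)
    k[time_grid < 0] = 0.0
    return k


def _ar1_noise(shape: tuple[int, int], ar1: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Trial x time AR(1) noise with stationary SD ``sd``."""
    n_trials, n_time = shape
    innov_sd = sd * np.sqrt(1.0 - ar1**2)
    out = np.empty(shape)
    out[:, 0] = rng.normal(0.0, sd, n_trials)
    for j in range(1, n_time):
        out[:, j] = ar1 * out[:, j - 1] + rng.normal(0.0, innov_sd, n_trials)
    return out


def simulate_hfa_envelopes(
    channel: ChannelGroundTruth,
    rl_table: pd.DataFrame,
    time_grid: np.ndarray,
    rng: np.random.Generator,
    ev_col: str = "ev",
    prpe_col: str = "prpe",
    nrpe_col: str = "nrpe",
) -> np.ndarray:
    """Trials x time HFA envelope in z-units:
    (g_EV*ev + g_p*prpe + g_n*nrpe) * K(t) + AR(1) noise."""
    amp = (
        channel.g_ev * rl_table[ev_col].to_numpy(float)
        + channel.g_p * rl_table[prpe_col].to_numpy(float)
        + channel.g_n * rl_table[nrpe_col].to_numpy(float)
    )
    kernel = response_kernel(time_grid, channel.kernel_peak_s, channel.kernel_width_s)
    env = amp[:, None] * kernel[None, :]
    if channel.noise_sd > 0:
        env = env + _ar1_noise(env.shape, channel.ar1, channel.noise_sd, rng)
    return env


# ---------------------------------------------------------------------------
# raw broadband rendering
# ---------------------------------------------------------------------------

def envelope_to_raw_trace(
    envelope: np.ndarray,
    env_time: np.ndarray,
    fs: float,
    rng: np.random.Generator,
    *,
    epoch_span: tuple[float, float] = (-0.5, 1.4),
    mod_depth: float = 0.25,
    pink_sd: float = 1.0,
    white_sd: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Render trials x time envelopes into voltage-like broadband traces.

    Each trial's trace is ``(1 + mod_depth*env) * carrier + background``
    where the carrier is unit-SD 70-150 Hz band-limited noise, so the
    log band power is approximately linear in the envelope for small
    ``mod_depth*env``. Outside the envelope's time support (e.g. the
    pre-stimulus baseline) the modulation is zero. Returns (traces,
    sample_times).
    """
    if fs < 300.0:
        raise ValueError("sampling rate too low to carry the 150 Hz band edge")
    t0, t1 = epoch_span
    n_samp = int(round((t1 - t0) * fs))
    times = t0 + np.arange(n_samp) / fs
    n_trials = envelope.shape[0]
    env_up = np.zeros((n_trials, n_samp))
    inside = (times >= env_time[0]) & (times <= env_time[-1])
    for i in range(n_trials):
        env_up[i, inside] = np.interp(times[inside], env_time, envelope[i])
    sos = signal.butter(4, [70.0, 150.0], btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, rng.normal(0.0, 1.0, (n_trials, n_samp)), axis=1)
    carrier /= carrier.std(axis=1, keepdims=True)
    gain = np.clip(1.0 + mod_depth * env_up, 0.05, None)
    pink = _pink_noise((n_trials, n_samp), rng) * pink_sd
    white = rng.normal(0.0, white_sd, (n_trials, n_samp))
    return gain * carrier + pink + white, times


def _pink_noise(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f-amplitude background via spectral shaping."""
    n_trials, n = shape
    spec = np.fft.rfft(rng.normal(0.0, 1.0, shape), axis=1)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    out = np.fft.irfft(spec, n=n, axis=1)
    return out / out.std(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# coupled pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingSpec:
    """Directed coupling between an INS and a dMPFC channel at a fixed lag
    (ms, positive = INS leads), with trial-varying coupling strength
    base_gain + m_EV*ev + m_p*prpe + m_n*nrpe."""

    subject: str
    ins_channel: str
    dmpfc_channel: str
    lag_ms: float
    base_gain: float = 0.5
    m_ev: float = 0.0
    m_p: float = 0.0
    m_n: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.lag_ms) > 400 or self.lag_ms % 25 != 0:
            raise ValueError("lag must sit on the 25 ms grid within ±400 ms")


def simulate_coupled_pair(
    spec: CouplingSpec,
    rl_table: pd.DataFrame,
    time_grid: np.ndarray,
    rng: np.random.Generator,
    smooth_samples: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (ins, dmpfc) trials x time envelopes coupled at the
    configured lag with trial-varying strength.

    The dMPFC series mixes the lag-shifted latent with fresh noise at a
    trial-specific mixing coefficient ``a = base_gain + m·X`` under a
    unit-variance constraint (``a·latent + sqrt(1−a²)·noise``), so the
    per-trial lagged correlation is *linear* in the modulators — a
    variance-scaling gain instead would couple correlation to the
    modulators through a saturating nonlinearity and leak planted
    modulation of one RPE term into the others. The latent decorrelates
    over ~25 ms (default smoothing), keeping per-trial correlation windows
    rich in effective samples.
    """
    step_ms = 25.0
    lag_k = int(round(spec.lag_ms / step_ms))
    n_trials = len(rl_table)
    n_time = len(time_grid)
    pad = abs(lag_k) + 8
    latent = rng.normal(0.0, 1.0, (n_trials, n_time + 2 * pad))
    latent = gaussian_filter1d(latent, smooth_samples, axis=1)
    latent /= latent.std(axis=1, keepdims=True)
    a = (
        spec.base_gain
        + spec.m_ev * rl_table["ev"].to_numpy(float)
        + spec.m_p * rl_table["prpe"].to_numpy(float)
        + spec.m_n * rl_table["nrpe"].to_numpy(float)
    )
    a = np.clip(a, -0.98, 0.98)
    ins = latent[:, pad: pad + n_time] + rng.normal(
        0.0, spec.noise_sd, (n_trials, n_time)
    )
    # positive lag: dMPFC reproduces INS activity lag_k samples later
    shifted = latent[:, pad - lag_k: pad - lag_k + n_time]
    dmpfc = a[:, None] * shifted + np.sqrt(1.0 - a[:, None] ** 2) * rng.normal(
        0.0, 1.0, (n_trials, n_time)
    )
    return ins, dmpfc


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Defaults mirror the study conditions: 4 blocks x 75 trials per
    subject (2 easy, 2 hard), channel gains of 0.5 z at the kernel peak,
    unit-SD AR(1) channel noise, and a category mix dominated by positive
    and unsigned RPE coding."""

    n_subjects: int = 4
    channels_per_region: int = 4
    task: task.TaskConfig = field(default_factory=task.TaskConfig)
    timing_sd: float = 0.06
    gain_scale: float = 0.5
    noise_sd: float = 1.0
    ar1: float = 0.5
    category_mix: dict[str, float] = field(
        default_factory=lambda: {
            "pRPE": 0.30, "uRPE": 0.30, "nRPE": 0.10, "sRPE": 0.10, "none": 0.20
        }
    )
    #: probability of regular (pRPE/nRPE/sRPE) or increasing (uRPE) coding;
    #: inverted nRPE coding dominates, as observed
    regular_prob: dict[str, float] = field(
        default_factory=lambda: {"pRPE": 0.95, "nRPE": 0.33, "sRPE": 0.85, "uRPE": 0.95}
    )
    time_step_s: float = 0.025
    time_span_s: tuple[float, float] = (-0.4, 1.4)
    couplings_per_subject: int = 0
    #: additional pairs with zero RPE modulation (coupled, but not
    #: RPE-responsive) mixed into each subject
    null_couplings_per_subject: int = 0
    coupling_lag_ms: float = 75.0
    coupling_m_p: float = 0.0
    coupling_m_n: float = 0.0
    coupling_m_ev: float = 0.0
    #: between-pair SD of the modulation gains (pair heterogeneity)
    coupling_m_sd: float = 0.1
    coupling_noise_sd: float = 1.0
    with_raw: bool = False
    raw_fs: float = 1000.0  # must tile the 25 ms analysis grid

    @property
    def time_grid(self) -> np.ndarray:
        t0, t1 = self.time_span_s
        n = int(round((t1 - t0) / self.time_step_s)) + 1
        return np.round(t0 + np.arange(n) * self.time_step_s, 6)


@dataclass
class SyntheticCohort:
    """Everything one analysis run needs, plus the generative truth."""

    config: CohortConfig
    trials: dict[str, pd.DataFrame]  # per subject, RL-augmented
    channels: list[ChannelGroundTruth]
    envelopes: dict[tuple[str, str], np.ndarray]  # (subject, channel) -> trials x time
    time_grid: np.ndarray
    couplings: list[CouplingSpec]
    pair_envelopes: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]]
    raw: dict[tuple[str, str], np.ndarray]
    raw_times: np.ndarray | None

    @property
    def channel_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [c.subject for c in self.channels],
                "channel": [c.channel for c in self.channels],
                "region": [c.region for c in self.channels],
                "x": [c.xyz[0] for c in self.channels],
                "y": [c.xyz[1] for c in self.channels],
                "z": [c.xyz[2] for c in self.channels],
                "g_ev": [c.g_ev for c in self.channels],
                "g_p": [c.g_p for c in self.channels],
                "g_n": [c.g_n for c in self.channels],
                "category": [c.category for c in self.channels],
                "polarity": [c.polarity for c in self.channels],
            }
        )


def _jitter(base: float, sd: float, rng: np.random.Generator) -> float:
    """Pair-level heterogeneity on a nonzero modulation gain; gains that
    are exactly zero stay zero (that predictor is truly unmodulated)."""
    return base + rng.normal(0.0, sd) if base != 0.0 else 0.0


def _draw_category(mix: dict[str, float], rng: np.random.Generator) -> str:
    cats = list(mix)
    probs = np.array([mix[c] for c in cats], float)
    return str(rng.choice(cats, p=probs / probs.sum()))


def _draw_polarity(category: str, regular_prob: dict[str, float],
                   rng: np.random.Generator) -> str:
    if category == "none":
        return "none"
    regular = rng.random() < regular_prob[category]
    if category == "uRPE":
        return "increasing" if regular else "decreasing"
    return "regular" if regular else "inverted"


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort, deterministic given ``seed``.

    Behavioral sessions are simulated with stationary timers and run
    through the actual RL pipeline (trial rejection, logistic value-model
    fit, RPE derivation), so the envelope generator consumes exactly the
    trial-level variables the analysis will see. Channel envelopes embed
    the generative gains; couplings (if configured) couple dedicated
    channel pairs at the configured lag.
    """
    config = config or CohortConfig()
    master = np.random.default_rng(seed)
    time_grid = config.time_grid
    trials: dict[str, pd.DataFrame] = {}
    channels: list[ChannelGroundTruth] = []
    envelopes: dict[tuple[str, str], np.ndarray] = {}
    couplings: list[CouplingSpec] = []
    pair_envelopes: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}
    raw: dict[tuple[str, str], np.ndarray] = {}
    raw_times = None

    for i in range(config.n_subjects):
        subject = f"S{i:02d}"
        rng = np.random.default_rng(master.integers(2**31))
        agent = task.AgentConfig(timing_sd=config.timing_sd)
        session = task.run_session(config.task, agent, int(rng.integers(2**31)))
        kept = task.reject_trials(session)
        frame = rl.augment_trials(task.trials_to_frame(kept))
        frame = frame[frame["outcome"] != "missing"].reset_index(drop=True)
        trials[subject] = frame

        for region in REGIONS:
            for j in range(config.channels_per_region):
                name = f"{region.lower()}{j:02d}"
                cat = _draw_category(config.category_mix, rng)
                pol = _draw_polarity(cat, config.regular_prob, rng)
                chan = make_channel_ground_truth(
                    cat, pol, config.gain_scale, rng,
                    subject=subject, channel=name, region=region,
                    noise_sd=config.noise_sd, ar1=config.ar1,
                )
                channels.append(chan)
                env = simulate_hfa_envelopes(chan, frame, time_grid, rng)
                envelopes[(subject, name)] = env
                if config.with_raw:
                    tr, raw_times = envelope_to_raw_trace(
                        env, time_grid, config.raw_fs, rng
                    )
                    raw[(subject, name)] = tr

        n_mod = config.couplings_per_subject
        for k in range(n_mod + config.null_couplings_per_subject):
            modulated = k < n_mod
            jit = config.coupling_m_sd
            spec = CouplingSpec(
                subject=subject,
                ins_channel=f"ins_pair{k:02d}",
                dmpfc_channel=f"dmpfc_pair{k:02d}",
                lag_ms=config.coupling_lag_ms,
                m_ev=_jitter(config.coupling_m_ev, jit, rng) if modulated else 0.0,
                m_p=_jitter(config.coupling_m_p, jit, rng) if modulated else 0.0,
                m_n=_jitter(config.coupling_m_n, jit, rng) if modulated else 0.0,
                noise_sd=config.coupling_noise_sd,
            )
            couplings.append(spec)
            ins_env, dmpfc_env = simulate_coupled_pair(spec, frame, time_grid, rng)
            pair_envelopes[(subject, spec.ins_channel, spec.dmpfc_channel)] = (
                ins_env, dmpfc_env
            )

    return SyntheticCohort(
        config=config, trials=trials, channels=channels, envelopes=envelopes,
        time_grid=time_grid, couplings=couplings,
        pair_envelopes=pair_envelopes, raw=raw, raw_times=raw_times,
    )
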