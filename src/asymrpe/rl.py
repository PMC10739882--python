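"""Trial-level value and reward-prediction-error derivation.

Win probability is modeled per participant as a logistic function of the
error tolerance t (in ms) in effect on each trial,

    p_win = 1 / (1 + exp(-(beta0 + beta1 * t))),

fit by maximum likelihood over the whole session (easy and hard blocks
pooled). Expected value rescales p_win linearly onto the reward range
[-1, 1]; the signed RPE is reward minus expected value, and the
valence-split magnitudes are its positive and negative parts. Neutral
outcomes (reward 0) are excluded from the fit — they are delivered at
random and carry no performance information — but still receive RPEs,
which makes a neutral outcome a negative surprise in easy blocks (EV > 0)
and a positive one in hard blocks (EV < 0).

No temporal-difference learning is involved: the tolerance cue is visible
on every trial, so value is a static function of tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .task import BehavioralTrial, trials_to_frame

__all__ = [
    "ValueModelFit",
    "fit_value_model",
    "win_probability",
    "expected_value",
    "compute_rpes",
    "augment_trials",
]

#: |coefficient| clamp applied when the logistic fit is separated
_CLAMP = 50.0


@dataclass(frozen=True)
class ValueModelFit:
    """Logistic win-probability model: log-odds intercept and slope per
    millisecond of tolerance."""

    beta0: float
    beta1: float
    n_trials_fit: int
    degenerate: bool = False


def fit_value_model(trials: list[BehavioralTrial] | pd.DataFrame) -> ValueModelFit:
    """Maximum-likelihood logistic regression of win (1) / loss (0) on
    tolerance (ms) across the session; neutral and missing trials excluded.

    Complete separation (e.g., every trial above some tolerance won) leaves
    the MLE unbounded; the fit is then flagged degenerate and coefficients
    are clamped to finite values.
    """
    frame = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    valenced = frame[frame["outcome"].isin(["win", "loss"])]
    y = (valenced["outcome"] == "win").to_numpy(float)
    t = valenced["tolerance_ms"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both wins and losses among valenced trials")
    X = sm.add_constant(t)
    degenerate = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            beta0, beta1 = res.params
            # perfect classification -> the MLE is unbounded (separation)
            if np.all(np.abs(res.fittedvalues - y) < 1e-4):
                degenerate = True
        except Exception:
            degenerate = True
            beta0, beta1 = 0.0, 0.0
    if not degenerate and (
        not np.isfinite([beta0, beta1]).all() or max(abs(beta0), abs(beta1)) > _CLAMP
    ):
        degenerate = True
    if degenerate:
        warnings.warn(
            "logistic value model is separated/non-identified; "
            "coefficients clamped", RuntimeWarning, stacklevel=2
        )
        beta0 = float(np.clip(beta0, -_CLAMP, _CLAMP))
        beta1 = float(np.clip(beta1, -_CLAMP, _CLAMP))
    return ValueModelFit(float(beta0), float(beta1), int(len(y)), degenerate)


def win_probability(fit: ValueModelFit, tolerance_ms) -> np.ndarray | float:
    """p_win = expit(beta0 + beta1 * t); strictly increasing in t when
    beta1 > 0."""
    t = np.asarray(tolerance_ms, float)
    out = expit(fit.beta0 + fit.beta1 * t)
    return float(out) if out.ndim == 0 else out


def expected_value(p_win) -> np.ndarray | float:
    """EV = 2*p_win − 1, the linear rescaling of win probability onto the
    reward range [−1, 1]."""
    p = np.asarray(p_win, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_win must lie in [0, 1]")
    ev = 2.0 * p - 1.0
    return float(ev) if ev.ndim == 0 else ev


def compute_rpes(reward, ev) -> pd.DataFrame:
    """Signed RPE and its decomposition.

    srpe = reward − EV; urpe = |srpe|; prpe = max(srpe, 0);
    nrpe = max(−srpe, 0). By construction prpe − nrpe = srpe,
    prpe + nrpe = urpe and prpe·nrpe = 0 on every trial.
    """
    r = np.asarray(reward, float)
    v = np.asarray(ev, float)
    srpe = r - v
    return pd.DataFrame(
        {
            "srpe": srpe,
            "urpe": np.abs(srpe),
            "prpe": np.maximum(srpe, 0.0),
            "nrpe": np.maximum(-srpe, 0.0),
        }
    )


def augment_trials(
    frame: pd.DataFrame, fit: ValueModelFit | None = None
) -> pd.DataFrame:
    """Add p_win, ev, srpe, urpe, prpe, nrpe columns to a trial table.

    Missing-outcome trials get NaN RL variables (they are excluded from all
    downstream models). If no fit is supplied one is estimated from the
    table itself.
    """
    if fit is None:
        fit = fit_value_model(frame)
    out = frame.copy()
    p = win_probability(fit, out["tolerance_ms"].to_numpy(float))
    ev = expected_value(p)
    rpes = compute_rpes(out["reward"].to_numpy(float), ev)
    out["p_win"] = p
    out["ev"] = ev
    for col in ("srpe", "urpe", "prpe", "nrpe"):
        out[col] = rpes[col].to_numpy()
    missing = out["outcome"] == "missing"
    out.loc[missing, ["p_win", "ev", "srpe", "urpe", "prpe", "nrpe"]] = np.nan
    return out
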