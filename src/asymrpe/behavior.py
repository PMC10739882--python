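"""Reaction-time adaptation: the hierarchical mixed-model ladder.

Trial-to-trial RT change is modeled as a function of the previous trial's
RT, its outcome, and its reward-prediction error, with by-subject random
intercepts and previous-RT random slopes:

====== ==================== ==========================================================
model  name                 fixed effects (random: 1 + prev_rt | subject, b1 up)
====== ==================== ==========================================================
b0     intercept only       1                     (random: 1 | subject)
b1     previous RT          prev_rt
b2     outcome              prev_rt + prev_outcome
b3     interaction          prev_rt * prev_outcome
b4     RPE value            prev_rt * prev_outcome + srpe
b5     RPE salience         prev_rt * prev_outcome + urpe
b6     asymmetric RPE       prev_rt * prev_outcome + prpe + nrpe
====== ==================== ==========================================================

Each model is compared with the null that omits its parameter of interest
(b1 vs b0, b2 vs b1, b3 vs b2, b4/b5/b6 vs b3) by a one-sided
likelihood-ratio test on ML fits; b4 and b5 have equal parameter counts
and are compared by AIC only. The outcome factor is treatment-coded with
"win" as the reference level, so the prev_rt:loss interaction directly
measures the extra mean reversion after losses.
"""

from __future__ import annotations

import logging

import pandas as pd

from .lmm import LmmFit, LrtResult, fit_lmm, likelihood_ratio_test
from .task import frame_to_trials, rt_change_table

logger = logging.getLogger(__name__)

__all__ = ["LADDER_SPECS", "rt_adaptation_table", "run_model_ladder"]

_OUTCOME = "C(prev_outcome, Treatment('win'))"

#: Wilkinson fixed-effect formulas of the ladder; random structure is
#: (1 | subject) for b0 and (1 + prev_rt | subject) for b1 and above.
LADDER_SPECS: dict[str, dict] = {
    "b0": {"label": "Intercept only", "formula": "rt_change ~ 1",
           "re": "1", "null": None},
    "b1": {"label": "Previous RT", "formula": "rt_change ~ prev_rt",
           "re": "1 + prev_rt", "null": "b0"},
    "b2": {"label": "Outcome",
           "formula": f"rt_change ~ prev_rt + {_OUTCOME}",
           "re": "1 + prev_rt", "null": "b1"},
    "b3": {"label": "Interaction",
           "formula": f"rt_change ~ prev_rt * {_OUTCOME}",
           "re": "1 + prev_rt", "null": "b2"},
    "b4": {"label": "RPE value",
           "formula": f"rt_change ~ prev_rt * {_OUTCOME} + prev_srpe",
           "re": "1 + prev_rt", "null": "b3"},
    "b5": {"label": "RPE salience",
           "formula": f"rt_change ~ prev_rt * {_OUTCOME} + prev_urpe",
           "re": "1 + prev_rt", "null": "b3"},
    "b6": {"label": "Asymmetric RPE",
           "formula": f"rt_change ~ prev_rt * {_OUTCOME} + prev_prpe + prev_nrpe",
           "re": "1 + prev_rt", "null": "b3"},
}


def rt_adaptation_table(subject_frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Build the pooled ladder table from per-subject augmented trial frames.

    Each frame must carry the trial-table columns plus the RL variables
    (p_win, ev, srpe, urpe, prpe, nrpe) from :func:`asymrpe.rl.augment_trials`.
    RT-change rows follow the within-block adjacency rules of
    :func:`asymrpe.task.rt_change_table`; the previous trial's RL variables
    are joined on ``prev_trial_index``.
    """
    parts = []
    for subject, frame in subject_frames.items():
        changes = rt_change_table(frame_to_trials(frame))
        if changes.empty:
            logger.warning("subject %s contributes no RT-change rows", subject)
            continue
        rl_prev = frame.set_index("trial_index")[
            ["p_win", "ev", "srpe", "urpe", "prpe", "nrpe"]
        ].add_prefix("prev_")
        merged = changes.join(rl_prev, on="prev_trial_index")
        merged.insert(0, "subject", subject)
        parts.append(merged)
    if not parts:
        return pd.DataFrame()
    table = pd.concat(parts, ignore_index=True)
    return table.dropna(subset=["rt_change", "prev_rt", "prev_srpe"])


def run_model_ladder(
    table: pd.DataFrame,
    models: list[str] | None = None,
    robust: bool = False,
) -> dict:
    """Fit the ladder on a pooled RT-adaptation table.

    Returns ``{"fits": {name: LmmFit}, "lrt": DataFrame, "aic": DataFrame}``.
    LRT rows compare each model with its designated null; the AIC table
    covers every fitted model (the only comparison available for the
    equal-complexity b4 vs b5 pair).
    """
    required = {"subject", "rt_change", "prev_rt", "prev_outcome",
                "prev_srpe", "prev_urpe", "prev_prpe", "prev_nrpe"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ladder table is missing columns: {sorted(missing)}")

    names = models or list(LADDER_SPECS)
    if table["prev_outcome"].nunique() < 2:
        # outcome factor degenerates; drop it from the formulas
        raise ValueError("prev_outcome must have at least two levels")

    fits: dict[str, LmmFit] = {}
    for name in names:
        spec = LADDER_SPECS[name]
        null = spec["null"]
        warm = fits.get(null) if null else None
        if warm is not None and LADDER_SPECS[null]["re"] != spec["re"]:
            warm = None  # different random structure; no warm start
        fits[name] = fit_lmm(
            spec["formula"], table, groups="subject",
            re_formula=spec["re"], name=name, robust=robust,
            start_from=warm, multi_start=True,
        )

    lrt_rows = []
    for name in names:
        null = LADDER_SPECS[name]["null"]
        if null is None or null not in fits:
            continue
        res: LrtResult = likelihood_ratio_test(fits[null], fits[name])
        lrt_rows.append(
            {"model": name, "null": null, "df": res.df,
             "chi2": res.chi2, "p": res.p}
        )
    aic = pd.DataFrame(
        {"model": names,
         "label": [LADDER_SPECS[n]["label"] for n in names],
         "aic": [fits[n].aic for n in names],
         "loglik": [fits[n].loglik for n in names],
         "n_params": [fits[n].n_params for n in names]}
    ).set_index("model")
    return {"fits": fits, "lrt": pd.DataFrame(lrt_rows), "aic": aic}
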