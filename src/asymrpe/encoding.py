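"""Window-wise encoding models of HFA and channel classification.

For each brain region and each 50 ms analysis window, single-trial HFA
power is predicted from trial-level RL variables with linear mixed models
using subject and channel-within-subject as nested random effects:

* RPE value:      HFA ~ sRPE + EV
* RPE salience:   HFA ~ uRPE + EV
* asymmetric RPE: HFA ~ nRPE + pRPE + EV

each with the same terms as random slopes at both grouping levels
(channel-level effects enter as independent variance components). Model
comparison uses AIC; fixed-effect p-values are FDR-corrected across
windows per term (Benjamini–Hochberg), while channel-level conditional
coefficients (fixed effect + subject + channel BLUP deviations) keep
uncorrected p-values — mixed-model shrinkage already regularizes them.

Channels are then classified by which RPE-magnitude terms reach
significance and the signs of their peak (largest-|coefficient|)
significant windows. Per-term significance is judged on each channel's
own trials (single-channel regression per window, BH step-up across the
23 windows), gated by a joint F test of the two RPE-magnitude terms —
conditional (BLUP) p-values collapse onto the region fixed effect
wherever between-channel variance vanishes and would inherit its chance
significances across windows; peak windows and coefficient signs are
still read from the conditional series. The categories:

* only pRPE significant → pRPE channel (regular if the peak coefficient
  is positive, inverted if negative);
* only nRPE significant → nRPE channel (regular if negative — HFA falls
  as negative surprises grow — inverted if positive);
* both significant with opposite peak signs → signed-RPE channel;
* both significant with matching peak signs → unsigned-RPE channel
  (increasing/decreasing);
* neither → unresponsive.

The same decision table is reused verbatim for connectivity channel
pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.discrete.discrete_model import MNLogit
from statsmodels.stats.multitest import multipletests

from . import hfa as hfa_mod
from .lmm import LmmFit, fit_lmm

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_TERMS",
    "WindowModelResults",
    "ChannelCategory",
    "envelope_windows",
    "window_table",
    "channel_ols_tests",
    "classify_units",
    "fit_window_models",
    "compare_models_aic",
    "fdr_correct",
    "extract_channel_coefficients",
    "classify_profile",
    "classify_channel",
    "classify_all_channels",
    "category_proportion_stats",
    "spatial_gradient_test",
    "rankit_transform",
]

#: predictor sets of the three competing models
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "value": ("srpe", "ev"),
    "salience": ("urpe", "ev"),
    "asymmetric": ("nrpe", "prpe", "ev"),
}


def _model_formulas(model: str) -> tuple[str, str, dict[str, str]]:
    terms = MODEL_TERMS[model]
    fixed = "hfa ~ " + " + ".join(terms)
    re_formula = "1 + " + " + ".join(terms)
    vc = {"ch": "0 + C(chan)"}
    for t in terms:
        vc[f"ch_{t}"] = f"0 + C(chan):{t}"
    return fixed, re_formula, vc


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------

def envelope_windows(cohort) -> dict[tuple[str, str], np.ndarray]:
    """Sliding-window means of each channel's z-unit envelope
    (trials × 23 windows on the 0–0.6 s grid)."""
    out = {}
    for key, env in cohort.envelopes.items():
        win, _ = hfa_mod.window_average(env, cohort.time_grid)
        out[key] = win
    return out


def window_table(
    windows: dict[tuple[str, str], np.ndarray],
    rl_tables: dict[str, pd.DataFrame],
    channels: pd.DataFrame,
    region: str,
    window_index: int,
) -> pd.DataFrame:
    """Long table for one region and window: one row per
    subject × channel × trial with HFA and RL predictors. Channel ids are
    made globally unique as ``subject:channel``."""
    parts = []
    sel = channels[channels["region"] == region]
    for row in sel.itertuples(index=False):
        key = (row.subject, row.channel)
        if key not in windows:
            continue
        rl = rl_tables[row.subject]
        parts.append(
            pd.DataFrame(
                {
                    "subject": row.subject,
                    "chan": f"{row.subject}:{row.channel}",
                    "hfa": windows[key][:, window_index],
                    "ev": rl["ev"].to_numpy(float),
                    "srpe": rl["srpe"].to_numpy(float),
                    "urpe": rl["urpe"].to_numpy(float),
                    "prpe": rl["prpe"].to_numpy(float),
                    "nrpe": rl["nrpe"].to_numpy(float),
                }
            )
        )
    if not parts:
        raise ValueError(f"no channels found for region {region!r}")
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# window-wise model fits
# ---------------------------------------------------------------------------

@dataclass
class WindowModelResults:
    """Fixed-effect summaries and fits per region × window × model."""

    region: str
    window_starts: np.ndarray
    table: pd.DataFrame  # window, model, term, estimate, se, ci, p, q, aic
    fits: dict[tuple[int, str], LmmFit] = field(repr=False, default_factory=dict)


def fit_window_models(
    windows: dict[tuple[str, str], np.ndarray],
    rl_tables: dict[str, pd.DataFrame],
    channels: pd.DataFrame,
    region: str,
    models: tuple[str, ...] = ("value", "salience", "asymmetric"),
    window_indices: list[int] | None = None,
    robust: bool = False,
) -> WindowModelResults:
    """Fit the competing encoding models for every analysis window of one
    region; FDR-correct fixed-effect p across windows per model × term."""
    starts = hfa_mod.window_starts()
    idxs = list(range(len(starts))) if window_indices is None else list(window_indices)
    rows = []
    fits: dict[tuple[int, str], LmmFit] = {}
    for w in idxs:
        data = window_table(windows, rl_tables, channels, region, w)
        for model in models:
            fixed, re_formula, vc = _model_formulas(model)
            fit = fit_lmm(
                fixed, data, groups="subject", re_formula=re_formula,
                vc_formula=vc, name=f"{region}:{model}:w{w}", robust=robust,
            )
            fits[(w, model)] = fit
            for term in MODEL_TERMS[model]:
                r = fit.fixed.loc[term]
                rows.append(
                    {
                        "window": w, "window_start_s": starts[w], "model": model,
                        "term": term, "estimate": r["estimate"], "se": r["se"],
                        "ci_lo": r["ci_lo"], "ci_hi": r["ci_hi"], "p": r["p"],
                        "aic": fit.aic, "converged": fit.converged,
                    }
                )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for (model, term), grp in table.groupby(["model", "term"]):
        table.loc[grp.index, "q"] = fdr_correct(grp["p"].to_numpy())
    return WindowModelResults(
        region=region, window_starts=starts[idxs], table=table, fits=fits
    )


def compare_models_aic(results: WindowModelResults) -> pd.DataFrame:
    """Per-window model ranking: AIC per model, winner, and ΔAIC of each
    model relative to the per-window minimum."""
    aic = (
        results.table.groupby(["window", "model"])["aic"].first().unstack("model")
    )
    out = aic.add_prefix("aic_")
    out["winner"] = aic.idxmin(axis=1)
    for m in aic.columns:
        out[f"delta_{m}"] = aic[m] - aic.min(axis=1)
    return out


def fdr_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# channel-level conditional coefficients
# ---------------------------------------------------------------------------

def _conditional_rows(fit: LmmFit, terms: tuple[str, ...]) -> pd.DataFrame:
    """Per-channel conditional coefficients for one fitted window.

    conditional estimate = fixed + subject BLUP + channel BLUP;
    conditional SE combines the fixed-effect SE with the conditional
    covariance of both BLUP deviations (normal approximation).
    """
    res = fit.result
    re = fit.random_effects
    re_cov = fit.random_effects_cov
    rows = []
    for subject, blups in re.items():
        cov = re_cov[subject]
        names = list(blups.index)
        chan_keys = [n for n in names if n.startswith("ch[")]
        chans = [k[k.index("[C(chan)[") + 9: -2] for k in chan_keys]
        for chan in chans:
            for term in terms:
                sel = np.zeros(len(names))
                if term in names:
                    sel[names.index(term)] = 1.0
                ch_name = f"ch_{term}[C(chan)[{chan}]:{term}]"
                if ch_name in names:
                    sel[names.index(ch_name)] = 1.0
                dev = float(np.dot(sel, blups.to_numpy()))
                var_dev = float(sel @ cov.to_numpy() @ sel)
                est = float(fit.fixed.loc[term, "estimate"]) + dev
                se = float(np.sqrt(fit.fixed.loc[term, "se"] ** 2 + max(var_dev, 0.0)))
                p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else 1.0
                rows.append(
                    {"subject": subject, "chan": chan, "term": term,
                     "estimate": est, "se": se, "p": p}
                )
    return pd.DataFrame(rows)


def extract_channel_coefficients(
    results: WindowModelResults, model: str = "asymmetric"
) -> pd.DataFrame:
    """Channel × window × term conditional coefficient series (uncorrected
    p-values) from the chosen model's window fits."""
    parts = []
    for (w, m), fit in results.fits.items():
        if m != model:
            continue
        rows = _conditional_rows(fit, MODEL_TERMS[model])
        rows["window"] = w
        rows["window_start_s"] = hfa_mod.window_starts()[w]
        parts.append(rows)
    if not parts:
        raise ValueError(f"no fitted windows for model {model!r}")
    return pd.concat(parts, ignore_index=True).sort_values(
        ["chan", "term", "window"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelCategory:
    """Channel responsiveness category plus coding polarity."""

    chan: str
    category: str  # pRPE / nRPE / sRPE / uRPE / none
    polarity: str  # regular / inverted / increasing / decreasing / none
    prpe_peak: float
    nrpe_peak: float
    prpe_peak_window: int
    nrpe_peak_window: int


def classify_profile(
    p_sig: bool, n_sig: bool, p_peak: float, n_peak: float
) -> tuple[str, str]:
    """Four-category decision table on (significance, peak sign) of the
    positive/negative RPE-magnitude coefficients; shared between HFA
    channels and connectivity pairs."""
    if p_sig and n_sig:
        if p_peak * n_peak < 0:
            return "sRPE", "regular" if p_peak > 0 else "inverted"
        return "uRPE", "increasing" if p_peak > 0 else "decreasing"
    if p_sig:
        return "pRPE", "regular" if p_peak > 0 else "inverted"
    if n_sig:
        return "nRPE", "regular" if n_peak < 0 else "inverted"
    return "none", "none"


def _peak(series: pd.DataFrame, alpha: float) -> tuple[bool, float, int]:
    """(any window significant, coefficient at the peak significant window,
    its window index); peak = max |estimate| among significant windows."""
    sig = series[series["p"] < alpha]
    if sig.empty:
        return False, 0.0, -1
    k = sig["estimate"].abs().idxmax()
    return True, float(sig.loc[k, "estimate"]), int(sig.loc[k, "window"])


def classify_channel(coef_series: pd.DataFrame, alpha: float = 0.05) -> ChannelCategory:
    """Classify one channel from its conditional coefficient series
    (rows: window × term for a single channel)."""
    chan = coef_series["chan"].iloc[0]
    p_sig, p_peak, p_w = _peak(coef_series[coef_series["term"] == "prpe"], alpha)
    n_sig, n_peak, n_w = _peak(coef_series[coef_series["term"] == "nrpe"], alpha)
    category, polarity = classify_profile(p_sig, n_sig, p_peak, n_peak)
    return ChannelCategory(chan, category, polarity, p_peak, n_peak, p_w, n_w)


def channel_ols_tests(
    windows: dict[tuple[str, str], np.ndarray],
    rl_tables: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Single-channel regression tests: per channel × window, OLS of that
    channel's windowed HFA on (nrpe, prpe, ev), with per-term t-tests and
    a joint F test of the two RPE-magnitude terms (term ``joint_rpe``)."""
    import statsmodels.api as sm

    terms = MODEL_TERMS["asymmetric"]
    joint = np.zeros((2, 4))
    joint[0, 1] = joint[1, 2] = 1.0  # nrpe, prpe columns
    rows = []
    for (subject, channel), win in windows.items():
        rl = rl_tables[subject]
        X = sm.add_constant(rl[list(terms)].to_numpy(float))
        chan = f"{subject}:{channel}"
        for w in range(win.shape[1]):
            res = sm.OLS(win[:, w], X).fit()
            for t_i, term in enumerate(terms, start=1):
                rows.append(
                    {"subject": subject, "chan": chan, "term": term, "window": w,
                     "estimate": res.params[t_i], "se": res.bse[t_i],
                     "p": res.pvalues[t_i]}
                )
            rows.append(
                {"subject": subject, "chan": chan, "term": "joint_rpe",
                 "window": w, "estimate": np.nan, "se": np.nan,
                 "p": float(res.f_test(joint).pvalue)}
            )
    return pd.DataFrame(rows)


def classify_units(
    cond_series: pd.DataFrame,
    own_tests: pd.DataFrame | None = None,
    alpha: float = 0.05,
    axis_col: str = "window",
) -> pd.DataFrame:
    """Four-category classification of channels or channel pairs.

    ``cond_series`` carries conditional (mixed-model) coefficients per
    unit × term × axis point (window index or lag); ``own_tests`` the
    unit-own regression p-values on the same axis, including ``joint_rpe``
    rows. A unit is responsive only if its joint RPE F test survives a BH
    step-up across the axis; each term is significant if its own p-values
    survive the same step-up. Peak coefficients (value, axis location)
    come from the conditional series, restricted to axis points where the
    unit's own term test has p < alpha when own tests are available.
    Without ``own_tests`` significance falls back to the conditional
    p-values (any point < alpha), as for a single fitted window.
    """
    min_q = sig_axis = None
    if own_tests is not None:
        min_q = (
            own_tests.groupby(["chan", "term"])["p"]
            .apply(lambda p: float(np.min(fdr_correct(p.to_numpy()))))
        )
        sig_axis = (
            own_tests[own_tests["p"] < alpha]
            .set_index(["chan", "term"]).sort_index()
        )

    rows = []
    for chan, grp in cond_series.groupby("chan"):
        info = {"chan": chan, "subject": grp["subject"].iloc[0]}
        flags, peaks, locs = {}, {}, {}
        for term in ("prpe", "nrpe"):
            series = grp[grp["term"] == term].sort_values(axis_col)
            if own_tests is None:
                sig = series[series["p"] < alpha]
                flags[term] = not sig.empty
            else:
                flags[term] = bool(min_q.get((chan, term), np.inf) < alpha)
                try:
                    ok_axis = set(np.atleast_1d(
                        sig_axis.loc[(chan, term), axis_col]
                    ).tolist())
                except KeyError:
                    ok_axis = set()
                sig = series[series[axis_col].isin(ok_axis)]
            use = sig if not sig.empty else series
            k = use["estimate"].abs().to_numpy().argmax()
            peaks[term] = float(use["estimate"].iloc[k])
            locs[term] = use[axis_col].iloc[k]
        responsive = True
        if own_tests is not None:
            responsive = bool(min_q.get((chan, "joint_rpe"), 0.0) < alpha)
        if not responsive:
            category, polarity = "none", "none"
        else:
            category, polarity = classify_profile(
                flags["prpe"], flags["nrpe"], peaks["prpe"], peaks["nrpe"]
            )
            if own_tests is not None and category == "none":
                # jointly responsive but neither term alone survives:
                # label by the stronger peak coefficient
                if abs(peaks["prpe"]) >= abs(peaks["nrpe"]):
                    category, polarity = classify_profile(
                        True, False, peaks["prpe"], 0.0
                    )
                else:
                    category, polarity = classify_profile(
                        False, True, 0.0, peaks["nrpe"]
                    )
        info.update(
            category=category, polarity=polarity,
            prpe_peak=peaks["prpe"], nrpe_peak=peaks["nrpe"],
            prpe_sig=bool(flags["prpe"]), nrpe_sig=bool(flags["nrpe"]),
        )
        info[f"prpe_peak_{axis_col}"] = locs["prpe"]
        info[f"nrpe_peak_{axis_col}"] = locs["nrpe"]
        rows.append(info)
    return pd.DataFrame(rows)


def classify_all_channels(
    coef_table: pd.DataFrame,
    channel_tests: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every channel from its conditional coefficient series,
    with channel-own regression tests (:func:`channel_ols_tests`)
    providing the significance decisions when supplied."""
    out = classify_units(coef_table, channel_tests, alpha, axis_col="window")
    return out.rename(columns={
        "prpe_peak_window": "prpe_peak_window", "nrpe_peak_window": "nrpe_peak_window"
    })


# ---------------------------------------------------------------------------
# category statistics
# ---------------------------------------------------------------------------

_RESPONSIVE = ("pRPE", "nRPE", "sRPE", "uRPE")


def category_proportion_stats(categories: pd.DataFrame) -> dict:
    """Group-level tests on per-subject category proportions.

    ``categories`` needs columns subject, region, category. Subjects
    missing a region are excluded. Returns per-subject proportions, the
    per-category between-region signed-rank tests (FDR over the four
    categories), and — after region averaging — a Kruskal–Wallis test
    across categories with FDR-corrected pairwise signed-rank contrasts.
    """
    both = [
        s for s, grp in categories.groupby("subject")
        if grp["region"].nunique() >= 2
    ]
    data = categories[categories["subject"].isin(both)]
    if data.empty or (data["category"] != "none").sum() == 0:
        warnings.warn("no responsive channels; category tests skipped")
        return {"proportions": pd.DataFrame(), "region_tests": pd.DataFrame(),
                "kruskal": None, "pairwise": pd.DataFrame()}
    props = (
        data.groupby(["subject", "region"])["category"]
        .value_counts(normalize=True).rename("prop").reset_index()
        .pivot_table(index=["subject", "region"], columns="category",
                     values="prop", fill_value=0.0)
        .reindex(columns=_RESPONSIVE, fill_value=0.0).reset_index()
    )
    region_rows = []
    regions = sorted(props["region"].unique())
    if len(regions) == 2:
        a = props[props["region"] == regions[0]].set_index("subject")
        b = props[props["region"] == regions[1]].set_index("subject")
        common = a.index.intersection(b.index)
        for cat in _RESPONSIVE:
            d = a.loc[common, cat] - b.loc[common, cat]
            if np.allclose(d, 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(d)
            region_rows.append({"category": cat, "stat": stat, "p": p})
    region_tests = pd.DataFrame(region_rows)
    if not region_tests.empty:
        region_tests["q"] = fdr_correct(region_tests["p"].to_numpy())

    avg = props.groupby("subject")[list(_RESPONSIVE)].mean()
    groups = [avg[c].to_numpy() for c in _RESPONSIVE]
    if all(np.allclose(g, g[0]) for g in groups) and len({g[0] for g in groups}) == 1:
        kw = None
        warnings.warn("degenerate category proportions; Kruskal-Wallis skipped")
    else:
        kw_stat, kw_p = stats.kruskal(*groups)
        kw = {"stat": float(kw_stat), "p": float(kw_p), "df": len(groups) - 1}
    pair_rows = []
    for i in range(len(_RESPONSIVE)):
        for j in range(i + 1, len(_RESPONSIVE)):
            d = avg[_RESPONSIVE[i]] - avg[_RESPONSIVE[j]]
            if np.allclose(d, 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(d)
            pair_rows.append(
                {"a": _RESPONSIVE[i], "b": _RESPONSIVE[j], "stat": stat, "p": p}
            )
    pairwise = pd.DataFrame(pair_rows)
    if not pairwise.empty:
        pairwise["q"] = fdr_correct(pairwise["p"].to_numpy())
    return {"proportions": props, "region_tests": region_tests,
            "kruskal": kw, "pairwise": pairwise}


def spatial_gradient_test(
    categories: pd.DataFrame, min_members: int = 2
) -> pd.DataFrame | None:
    """Multinomial logistic regression of responsive-channel category on
    electrode coordinates (x, y, z), with uRPE as the reference category.

    Needs columns category, x, y, z. Categories with fewer than
    ``min_members`` channels are dropped (logged). Returns a tidy frame of
    coefficients and Wald p per category × coordinate, or None when fewer
    than two categories remain.
    """
    data = categories[categories["category"].isin(_RESPONSIVE)].copy()
    counts = data["category"].value_counts()
    small = counts[counts < min_members].index.tolist()
    if small:
        logger.warning("dropping sparse categories from gradient test: %s", small)
        data = data[~data["category"].isin(small)]
    cats = data["category"].unique().tolist()
    if len(cats) < 2:
        warnings.warn("fewer than two categories present; no gradient test")
        return None
    order = (["uRPE"] if "uRPE" in cats else []) + sorted(c for c in cats if c != "uRPE")
    code = pd.Categorical(data["category"], categories=order)
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(float) for c in ("x", "y", "z")]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MNLogit(code.codes, X).fit(disp=0, maxiter=200)
    rows = []
    coord_names = ["const", "x", "y", "z"]
    params = np.asarray(res.params)  # (k_coords, n_cats-1)
    bse = np.asarray(res.bse)
    for j, cat in enumerate(order[1:]):
        for i, coord in enumerate(coord_names):
            est, se = params[i, j], bse[i, j]
            p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
            rows.append(
                {"category": cat, "reference": order[0], "coord": coord,
                 "estimate": est, "se": se, "p": p}
            )
    return pd.DataFrame(rows)


def rankit_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (rankit) transform:
    Phi^{-1}((rank − 0.5)/n) with average ranks for ties."""
    v = np.asarray(values, float)
    if v.size == 0:
        return v.copy()
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / v.size)
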