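"""Lagged directed connectivity between INS and dMPFC channels.

For every INS–dMPFC channel pair, each trial's HFA time series are
cross-correlated at lags from −400 to +400 ms in 25 ms steps (positive
lag = INS activity precedes dMPFC activity). The trials × lags
correlation coefficients are then modeled per lag with the asymmetric RPE
predictors (EV, pRPE, nRPE) in mixed models with subject and channel-pair
as nested random effects. Fixed-effect p-values are FDR-corrected across
lags per predictor; pair-level conditional coefficients stay uncorrected.
Per pair and predictor, the peak lag is the lag maximizing the absolute
conditional coefficient, and pairs are classified into the same four
RPE-coding categories used for channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import _conditional_rows, classify_profile, fdr_correct
from .lmm import LmmFit, fit_lmm

__all__ = [
    "lag_grid",
    "trial_lagged_xcorr",
    "LagModelResults",
    "fit_lag_models",
    "extract_pair_coefficients",
    "extract_peak_lag",
    "classify_pair",
    "classify_all_pairs",
    "connectivity_category_stats",
]

STEP_MS = 25.0
CONNECTIVITY_TERMS = ("ev", "prpe", "nrpe")


def lag_grid(max_lag_ms: float = 400.0) -> np.ndarray:
    """Symmetric lag grid in ms, 25 ms steps (33 lags for ±400 ms);
    positive lags mean INS leads dMPFC."""
    n = int(round(max_lag_ms / STEP_MS))
    return np.arange(-n, n + 1) * STEP_MS


def trial_lagged_xcorr(
    hfa_ins: np.ndarray,
    hfa_dmpfc: np.ndarray,
    lags_ms: np.ndarray | None = None,
    min_overlap: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial Pearson correlation between dMPFC(t) and INS(t − lag).

    Both inputs are trials × time on the 25 ms grid. Returns
    ``(r, n_overlap)`` with r shaped trials × lags; lags whose overlap is
    below ``min_overlap`` samples, or trials with a zero-variance segment,
    yield NaN.
    """
    lags_ms = lag_grid() if lags_ms is None else np.asarray(lags_ms, float)
    n_trials, n_time = hfa_ins.shape
    if hfa_dmpfc.shape != hfa_ins.shape:
        raise ValueError("INS and dMPFC series must share the trial x time grid")
    r = np.full((n_trials, len(lags_ms)), np.nan)
    n_overlap = np.zeros(len(lags_ms), int)
    for j, lag in enumerate(lags_ms):
        k = int(round(lag / STEP_MS))
        if k >= 0:
            a, b = hfa_dmpfc[:, k:], hfa_ins[:, : n_time - k]
        else:
            a, b = hfa_dmpfc[:, : n_time + k], hfa_ins[:, -k:]
        n_overlap[j] = a.shape[1]
        if a.shape[1] < min_overlap:
            continue
        am = a - a.mean(axis=1, keepdims=True)
        bm = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((am**2).sum(axis=1) * (bm**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r[:, j] = np.where(denom > 0, (am * bm).sum(axis=1) / denom, np.nan)
    return r, n_overlap


@dataclass
class LagModelResults:
    """Per-lag fixed effects (with FDR across lags) and the fits."""

    lags_ms: np.ndarray
    table: pd.DataFrame  # lag_ms, term, estimate, se, p, q, aic
    fits: dict[float, LmmFit] = field(repr=False, default_factory=dict)


def fit_lag_models(
    xcorr_by_pair: dict[tuple[str, str, str], np.ndarray],
    rl_tables: dict[str, pd.DataFrame],
    lags_ms: np.ndarray | None = None,
    robust: bool = False,
) -> LagModelResults:
    """Mixed model ``r ~ ev + prpe + nrpe`` at each lag.

    ``xcorr_by_pair`` maps (subject, ins_channel, dmpfc_channel) to a
    trials × lags correlation array aligned with the subject's RL table.
    Random structure: subject random intercept, pair-within-subject
    intercept and slopes as independent variance components (pair-level
    slopes carry the conditional inference; subject-level slopes are not
    identifiable at the few-subject scale this runs at).
    """
    lags_ms = lag_grid() if lags_ms is None else np.asarray(lags_ms, float)
    vc = {"ch": "0 + C(chan)"}
    for t in CONNECTIVITY_TERMS:
        vc[f"ch_{t}"] = f"0 + C(chan):{t}"
    rows, fits = [], {}
    for j, lag in enumerate(lags_ms):
        parts = []
        for (subject, ins, dmpfc), r in xcorr_by_pair.items():
            rl = rl_tables[subject]
            parts.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "chan": f"{subject}:{ins}->{dmpfc}",
                        "r": r[:, j],
                        "ev": rl["ev"].to_numpy(float),
                        "prpe": rl["prpe"].to_numpy(float),
                        "nrpe": rl["nrpe"].to_numpy(float),
                    }
                )
            )
        data = pd.concat(parts, ignore_index=True).dropna(subset=["r"])
        if data.empty:
            continue
        fit = fit_lmm(
            "r ~ ev + prpe + nrpe", data, groups="subject",
            re_formula="1", vc_formula=vc,
            name=f"lag{lag:+.0f}ms", robust=robust,
        )
        fits[float(lag)] = fit
        for term in CONNECTIVITY_TERMS:
            fr = fit.fixed.loc[term]
            rows.append(
                {"lag_ms": float(lag), "term": term, "estimate": fr["estimate"],
                 "se": fr["se"], "ci_lo": fr["ci_lo"], "ci_hi": fr["ci_hi"],
                 "p": fr["p"], "aic": fit.aic, "converged": fit.converged}
            )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for term, grp in table.groupby("term"):
        table.loc[grp.index, "q"] = fdr_correct(grp["p"].to_numpy())
    return LagModelResults(lags_ms=lags_ms, table=table, fits=fits)


def extract_pair_coefficients(results: LagModelResults) -> pd.DataFrame:
    """Pair × lag × term conditional coefficients (uncorrected p)."""
    parts = []
    for lag, fit in results.fits.items():
        rows = _conditional_rows(fit, CONNECTIVITY_TERMS)
        rows["lag_ms"] = lag
        parts.append(rows)
    return pd.concat(parts, ignore_index=True).sort_values(
        ["chan", "term", "lag_ms"], ignore_index=True
    )


def pair_ols_tests(
    xcorr_by_pair: dict[tuple[str, str, str], np.ndarray],
    rl_tables: dict[str, pd.DataFrame],
    lags_ms: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-pair regression tests: per pair × lag, OLS of that pair's
    trial correlations on (ev, prpe, nrpe), with per-term t-tests and a
    joint F test of the two RPE-magnitude terms (rows with term
    ``joint_rpe``).

    These are the pair-level significance tests (each pair judged on its
    own trials); the mixed model's conditional estimates are still what
    peak lags and coefficient signs are read from.
    """
    import statsmodels.api as sm

    lags_ms = lag_grid() if lags_ms is None else np.asarray(lags_ms, float)
    joint = np.zeros((2, 4))
    joint[0, 2] = joint[1, 3] = 1.0  # prpe, nrpe columns
    rows = []
    for (subject, ins, dmpfc), r in xcorr_by_pair.items():
        rl = rl_tables[subject]
        X = sm.add_constant(rl[list(CONNECTIVITY_TERMS)].to_numpy(float))
        chan = f"{subject}:{ins}->{dmpfc}"
        for j, lag in enumerate(lags_ms):
            y = r[:, j]
            ok = np.isfinite(y)
            if ok.sum() < X.shape[1] + 2:
                continue
            res = sm.OLS(y[ok], X[ok]).fit()
            for t_i, term in enumerate(CONNECTIVITY_TERMS, start=1):
                rows.append(
                    {"subject": subject, "chan": chan, "term": term,
                     "lag_ms": float(lag), "estimate": res.params[t_i],
                     "se": res.bse[t_i], "p": res.pvalues[t_i]}
                )
            rows.append(
                {"subject": subject, "chan": chan, "term": "joint_rpe",
                 "lag_ms": float(lag), "estimate": np.nan, "se": np.nan,
                 "p": float(res.f_test(joint).pvalue)}
            )
    return pd.DataFrame(rows)


def extract_peak_lag(pair_series: pd.DataFrame) -> pd.DataFrame:
    """Per pair × term: the lag maximizing |conditional estimate|.

    Ties resolve to the earliest (most negative) lag. Returns one row per
    pair × term with the peak estimate, its lag, and its p-value.
    """
    rows = []
    for (chan, term), grp in pair_series.groupby(["chan", "term"]):
        grp = grp.sort_values("lag_ms")
        mags = grp["estimate"].abs().to_numpy()
        k = int(np.argmax(mags))  # first occurrence = most negative lag
        rows.append(
            {
                "chan": chan, "subject": grp["subject"].iloc[0], "term": term,
                "peak_estimate": float(grp["estimate"].iloc[k]),
                "peak_lag_ms": float(grp["lag_ms"].iloc[k]),
                "peak_p": float(grp["p"].iloc[k]),
            }
        )
    return pd.DataFrame(rows)


def classify_pair(peaks: pd.DataFrame, alpha: float = 0.05) -> tuple[str, str]:
    """Classify one pair from its per-term peak rows (uncorrected p < alpha
    at the peak lag), using the shared four-category decision table."""
    def get(term):
        row = peaks[peaks["term"] == term]
        if row.empty:
            return False, 0.0
        return bool(row["peak_p"].iloc[0] < alpha), float(row["peak_estimate"].iloc[0])

    p_sig, p_peak = get("prpe")
    n_sig, n_peak = get("nrpe")
    return classify_profile(p_sig, n_sig, p_peak, n_peak)


def classify_all_pairs(
    pair_series: pd.DataFrame,
    pair_tests: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Peak extraction + categorization for every pair; returns one row per
    pair with category, polarity, and per-term peak estimates/lags.

    Uses the four-category machinery shared with channel classification
    (:func:`asymrpe.encoding.classify_units`): responsiveness gated by the
    pair-own joint RPE F test with a BH step-up across lags, per-term
    significance by the same step-up on the term's own p-values, peak lags
    and signs from the conditional series. Testing only at the
    conditionally selected peak would be max-selected over 33 lags, and
    the BLUP conditional p of an unmodulated predictor collapses onto the
    region-level fixed effect and inherits its chance significances.
    """
    from .encoding import classify_units

    return classify_units(pair_series, pair_tests, alpha, axis_col="lag_ms")


def connectivity_category_stats(pair_categories: pd.DataFrame) -> dict:
    """Kruskal–Wallis + FDR-corrected pairwise rank-sum tests on
    per-subject category proportions, and on per-term peak-lag
    distributions across categories (significant pairs only)."""
    responsive = ("pRPE", "nRPE", "sRPE", "uRPE")
    props = (
        pair_categories.groupby("subject")["category"]
        .value_counts(normalize=True).rename("prop").reset_index()
        .pivot_table(index="subject", columns="category", values="prop",
                     fill_value=0.0)
        .reindex(columns=responsive, fill_value=0.0)
    )
    out: dict = {"proportions": props}
    groups = [props[c].to_numpy() for c in responsive]
    if len(pair_categories["category"].unique()) < 2:
        out["kruskal"] = None
        out["pairwise"] = pd.DataFrame()
    else:
        stat, p = stats.kruskal(*groups)
        out["kruskal"] = {"stat": float(stat), "p": float(p), "df": 3}
        rows = []
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = props[responsive[i]], props[responsive[j]]
                if np.allclose(a.to_numpy(), b.to_numpy()):
                    s, pv = 0.0, 1.0
                else:
                    s, pv = stats.ranksums(a, b)
                rows.append({"a": responsive[i], "b": responsive[j],
                             "stat": s, "p": pv})
        pw = pd.DataFrame(rows)
        pw["q"] = fdr_correct(pw["p"].to_numpy())
        out["pairwise"] = pw

    for term in ("prpe", "nrpe"):
        col, sig_col = f"{term}_peak_lag_ms", f"{term}_sig"
        if col not in pair_categories or sig_col not in pair_categories:
            continue
        sel = pair_categories[
            pair_categories[sig_col].fillna(False).astype(bool)
            & pair_categories["category"].isin(responsive)
        ]
        summ = sel.groupby("category")[col].describe()[["count", "25%", "50%", "75%"]]
        res = {"summary": summ}
        cats = [c for c in responsive if (sel["category"] == c).sum() > 0]
        if len(cats) >= 2:
            stat, p = stats.kruskal(*[sel.loc[sel["category"] == c, col] for c in cats])
            res["kruskal"] = {"stat": float(stat), "p": float(p), "df": len(cats) - 1}
            rows = []
            for i in range(len(cats)):
                for j in range(i + 1, len(cats)):
                    s, pv = stats.ranksums(
                        sel.loc[sel["category"] == cats[i], col],
                        sel.loc[sel["category"] == cats[j], col],
                    )
                    rows.append({"a": cats[i], "b": cats[j], "stat": s, "p": pv})
            pw = pd.DataFrame(rows)
            pw["q"] = fdr_correct(pw["p"].to_numpy())
            res["pairwise"] = pw
        out[f"lag_{term}"] = res
    return out
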