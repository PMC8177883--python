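"""Hierarchical response->cue->attack inference analysis.

Participants report, on a 0-100 likelihood scale, how often each response
triggers each cue (R->CS), how often each cue ends in an attack (CS->Attack),
and — directly — how often each response leads to an attack (R->Attack).  If
direct beliefs are assembled from the mediating links, the direct report
should match the *chained* estimate

    chain(R) = min(100, R->CS+ x CS+->Attack / 100  +  R->CS- x CS-->Attack / 100)

with products taken on the probability scale and the sum capped at 100%.
This module computes chained estimates, regresses direct on chained
inferences (per block and phase-averaged, split by cluster and response),
and quantifies what omitting either single path does to the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import stepwise_linear


@dataclass
class ChainEstimate:
    overall: float       # capped sum of both paths, percent
    path_plus: float     # R->CS+->Attack component, percent
    path_minus: float    # R->CS-->Attack component, percent


def chain_estimate(r_to_csplus, csplus_to_attack, r_to_csminus, csminus_to_attack):
    """Chained response->attack estimate (percent) from four component
    inferences on the 0-100 scale.  Scalar in, :class:`ChainEstimate` out;
    array-likes broadcast and return arrays of the three quantities."""
    arrs = [np.asarray(a, dtype=float) for a in
            (r_to_csplus, csplus_to_attack, r_to_csminus, csminus_to_attack)]
    for a in arrs:
        with np.errstate(invalid="ignore"):
            if np.any((a < 0) | (a > 100)):
                raise ValueError("component inferences must be within [0, 100]")
    plus = arrs[0] * arrs[1] / 100.0
    minus = arrs[2] * arrs[3] / 100.0
    overall = np.minimum(100.0, plus + minus)
    if overall.ndim == 0:
        return ChainEstimate(float(overall), float(plus), float(minus))
    return overall, plus, minus


def chain_table(reports: pd.DataFrame) -> pd.DataFrame:
    """Long table of direct vs chained inferences from a self-report frame.

    Expects punishment-phase rows with columns ``inf_{R}_{CSplus,CSminus}``,
    ``inf_{CSplus,CSminus}_attack`` and ``inf_{R}_attack`` for R in R1, R2.
    Returns one row per participant x block x response.
    """
    punish = reports[reports["phase"] == "punish"]
    rows = []
    for r in punish.itertuples(index=False):
        for planet in ("R1", "R2"):
            a = getattr(r, f"inf_{planet}_CSplus")
            b = getattr(r, "inf_CSplus_attack")
            c = getattr(r, f"inf_{planet}_CSminus")
            d = getattr(r, "inf_CSminus_attack")
            if any(pd.isna(v) for v in (a, b, c, d)):
                continue
            est = chain_estimate(a, b, c, d)
            rows.append({
                "participant_id": r.participant_id,
                "block": r.block,
                "response": planet,
                "direct": getattr(r, f"inf_{planet}_attack"),
                "chained": est.overall,
                "path_plus": est.path_plus,
                "path_minus": est.path_minus,
            })
    return pd.DataFrame(rows)


def _ols_fit(y: np.ndarray, x: np.ndarray) -> dict:
    if np.ptp(x) == 0:
        return {"slope": np.nan, "intercept": np.nan, "r2": np.nan,
                "F": np.nan, "p": np.nan, "n": len(y)}
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {"slope": float(model.params[1]), "intercept": float(model.params[0]),
            "r2": float(model.rsquared), "F": float(model.fvalue),
            "p": float(model.f_pvalue), "n": int(model.nobs)}


def regress_direct_vs_chained(table: pd.DataFrame, labels: pd.Series | None = None,
                              level: str = "block",
                              predictor: str = "chained") -> pd.DataFrame:
    """OLS of direct R->Attack inferences on chained estimates.

    ``level='block'`` pools participant x block observations; ``level='phase'``
    first averages each participant's punishment blocks.  If cluster
    ``labels`` are given, fits are reported per cluster x response, else per
    response.  Groups with fewer than 3 pairs or a constant predictor report
    missing statistics.
    """
    if level not in ("block", "phase"):
        raise ValueError("level must be 'block' or 'phase'")
    df = table.copy()
    df["cluster"] = (df["participant_id"].map(labels) if labels is not None else "all")
    value_cols = ["direct", "chained", "path_plus", "path_minus"]
    if level == "phase":
        df = (df.groupby(["participant_id", "cluster", "response"], as_index=False)
                [value_cols].mean())
    df = df.dropna(subset=["direct", predictor])
    out = []
    for (cluster, response), g in df.groupby(["cluster", "response"], sort=True):
        row = {"cluster": cluster, "response": response, "level": level,
               "predictor": predictor}
        if len(g) < 3:
            row.update({"slope": np.nan, "intercept": np.nan, "r2": np.nan,
                        "F": np.nan, "p": np.nan, "n": len(g)})
        else:
            row.update(_ols_fit(g["direct"].to_numpy(float),
                                g[predictor].to_numpy(float)))
        out.append(row)
    return pd.DataFrame(out)


def omission_analysis(table: pd.DataFrame, labels: pd.Series | None = None,
                      p_enter: float = 0.05, p_remove: float = 0.10) -> dict:
    """What happens to the prediction when one mediating path is dropped.

    Returns, per response: the full-model regression, single-path
    regressions (CS+ only, CS- only), mean signed prediction error of each
    single path (estimate - direct; negative = underprediction), and the
    stepwise entry path of the two single-path estimates as predictors of
    the direct inference.
    """
    df = table.dropna(subset=["direct", "chained", "path_plus", "path_minus"])
    out = {"full": regress_direct_vs_chained(df, labels, predictor="chained"),
           "cs_plus_only": regress_direct_vs_chained(df, labels, predictor="path_plus"),
           "cs_minus_only": regress_direct_vs_chained(df, labels, predictor="path_minus"),
           "bias": {}, "stepwise": {}}
    for response, g in df.groupby("response", sort=True):
        direct = g["direct"].to_numpy(float)
        out["bias"][response] = {
            "omit_CSminus_mean_error": float(np.mean(g["path_plus"] - direct)),
            "omit_CSplus_mean_error": float(np.mean(g["path_minus"] - direct)),
        }
        X = g[["path_plus", "path_minus"]].rename(
            columns={"path_plus": "CSplus_path", "path_minus": "CSminus_path"})
        out["stepwise"][response] = stepwise_linear(
            pd.Series(direct), X.reset_index(drop=True),
            p_enter=p_enter, p_remove=p_remove)
    return out
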