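"""End-to-end orchestration: simulate a cohort, then run the full analysis
(exclusions -> behavioural metrics -> clustering -> chain-inference analysis
-> cohort statistics) into a results directory of tidy CSVs.

Outputs are deterministic given (config, seed); the run log carries no
timestamps so re-runs are byte-identical.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import causal, clustering, metrics, stats
from .cohort import generate_cohort, read_cohort_dir
from .config import RunConfig
from .events import EventLog


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate and write a synthetic cohort directory."""
    cohort = generate_cohort(
        n=config.n_participants,
        sensitive_fraction=config.sensitive_fraction,
        param_dispersion=config.param_dispersion,
        seed=config.seed,
        config=config.task,
    )
    return cohort.write(out_dir)


def _event_logs(events: pd.DataFrame) -> list[EventLog]:
    return [EventLog.from_dataframe(df, pid)
            for pid, df in events.groupby("participant_id", sort=True)]


def _attack_inference_ratio(row) -> float:
    a, b = row.get("inf_R1_attack"), row.get("inf_R2_attack")
    if pd.isna(a) or pd.isna(b) or (a + b) == 0:
        return math.nan
    return a / (a + b)


def _reward_inference_ratio(row) -> float:
    a, b = row.get("inf_R1_reward"), row.get("inf_R2_reward")
    if pd.isna(a) or pd.isna(b) or (a + b) == 0:
        return math.nan
    return a / (a + b)


def run_analyze(cohort_dir: str | Path, out_dir: str | Path,
                config: RunConfig | None = None) -> Path:
    """Analyse a cohort directory; writes all stage outputs and a run log."""
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    data = read_cohort_dir(cohort_dir)
    reports, quests = data["self_reports"], data["questionnaires"]
    block_dur = float(data["manifest"]["config"]["block_duration_s"])

    # 1. exclusions
    excl = metrics.apply_exclusions(reports, quests)
    excl.excluded.to_csv(out / "excluded.csv", index=False)
    retained = excl.retained_ids
    log_lines.append(f"retained {len(retained)} participants; "
                     f"excluded {len(excl.excluded)}")
    reports = reports[reports["participant_id"].isin(retained)]

    # 2. behavioural metrics
    logs = [lg for lg in _event_logs(data["events"]) if lg.participant_id in retained]
    block_summary = pd.concat(
        [metrics.summarise_blocks(lg, block_dur) for lg in logs], ignore_index=True) \
        if logs else pd.DataFrame()
    collapsed = metrics.collapse_pre(block_summary) if len(block_summary) else block_summary
    collapsed.to_csv(out / "participant_summary.csv", index=False)
    pav = pd.DataFrame([metrics.summarise_pavlovian(lg, block_dur,
                                                    config.suppression_formula)
                        for lg in logs])
    pav.to_csv(out / "pavlovian_summary.csv", index=False)

    if not logs:
        log_lines.append("empty cohort after exclusions; analysis stages skipped")
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        return out

    # 3. clustering on final punishment-block ratios
    punish_blocks = sorted(collapsed[collapsed["phase"] == "punish"]["block"].unique(),
                           key=lambda b: int(b))
    final_block = punish_blocks[-1] if punish_blocks else None
    labels = None
    if final_block is not None:
        final = (collapsed[collapsed["block"] == final_block]
                 .dropna(subset=["preference_ratio"])
                 .sort_values("participant_id"))
        try:
            result = clustering.cluster_sensitivity(
                final["preference_ratio"].to_numpy(), seed=config.seed,
                k_values=config.k_values)
            cl = result.to_frame(final["preference_ratio"].to_numpy(),
                                 final["participant_id"])
            cl.to_csv(out / "clusters.csv", index=False)
            labels = cl.set_index("participant_id")["cluster_label"]
            mean_sil = result.mean_silhouette[result.chosen_k]
            sizes = {k: int(v) for k, v in
                     pd.Series(result.labels).value_counts().items()}
            log_lines.append(
                f"clustering: k={result.chosen_k}, mean silhouette {mean_sil:.3f}, "
                f"separation {result.separation:.2f}, sizes {sizes}")
            min_size = min(sizes.values())
            if mean_sil < 0.5 or result.separation < 4.0 or \
                    min_size < max(3, 0.05 * len(final)):
                log_lines.append("WARNING: weak cluster separation, low "
                                 "silhouette or near-singleton cluster; cohort "
                                 "may not be bimodal in punishment sensitivity")
        except clustering.DegenerateDataError as e:
            log_lines.append(f"WARNING: clustering degenerate ({e})")

    # 4. chain-inference analysis
    table = causal.chain_table(reports)
    table.to_csv(out / "chain_estimates.csv", index=False)
    if len(table):
        reg_block = causal.regress_direct_vs_chained(table, labels, level="block")
        reg_phase = causal.regress_direct_vs_chained(table, labels, level="phase")
        pd.concat([reg_block, reg_phase], ignore_index=True) \
            .to_csv(out / "chain_regression.csv", index=False)
        om = causal.omission_analysis(table, labels,
                                      p_enter=config.p_enter, p_remove=config.p_remove)
        bias_rows = [{"response": r, **v} for r, v in om["bias"].items()]
        pd.DataFrame(bias_rows).to_csv(out / "chain_omission_bias.csv", index=False)

    # 5. cohort statistics
    stat_rows = []
    for block in ["Pre"] + [str(b) for b in punish_blocks]:
        vals = collapsed[collapsed["block"] == block]["preference_ratio"].dropna()
        if len(vals) >= 2:
            r = stats.one_sample_ratio_test(vals)
            stat_rows.append({"analysis": "preference_vs_0.5", "effect": f"block {block}",
                              "statistic": r.t, "df1": r.df, "df2": np.nan, "p": r.p})
    for col in ("suppression_CSplus", "suppression_CSminus"):
        vals = pav[col].dropna()
        if len(vals) >= 2:
            r = stats.one_sample_ratio_test(vals)
            stat_rows.append({"analysis": "suppression_vs_0.5", "effect": col,
                              "statistic": r.t, "df1": r.df, "df2": np.nan, "p": r.p})

    # block-linear contrast on punishment preference ratios, by cluster
    wide = collapsed[collapsed["phase"] == "punish"].pivot(
        index="participant_id", columns="block", values="preference_ratio")
    wide = wide.reindex(columns=[str(b) for b in punish_blocks]).dropna()
    if wide.shape[0] >= 3 and wide.shape[1] >= 2:
        k = wide.shape[1]
        lin = np.arange(k, dtype=float) - (k - 1) / 2.0
        grp = labels.reindex(wide.index) if labels is not None else None
        if grp is not None and grp.isna().any():
            grp = None
        anova = stats.contrast_anova(wide, {"block_linear": lin}, groups=grp)
        for r in anova.itertuples(index=False):
            stat_rows.append({"analysis": "contrast_anova_preference",
                              "effect": r.effect, "statistic": r.F,
                              "df1": r.df1, "df2": r.df2, "p": r.p})
    pd.DataFrame(stat_rows).to_csv(out / "anova_results.csv", index=False)

    # inference-bias ratios feed stepwise models of behaviour and cluster
    phase_rep = (reports[reports["phase"] == "punish"]
                 .groupby("participant_id", sort=True).mean(numeric_only=True))
    phase_rep["attack_ratio"] = phase_rep.apply(_attack_inference_ratio, axis=1)
    phase_rep["reward_ratio"] = phase_rep.apply(_reward_inference_ratio, axis=1)
    pref = (collapsed[collapsed["phase"] == "punish"]
            .groupby("participant_id")["preference_ratio"].mean())
    model_df = pd.concat([phase_rep[["attack_ratio", "reward_ratio"]], pref], axis=1).dropna()
    path_rows = []
    if len(model_df) > 5:
        lin_res = stats.stepwise_linear(model_df["preference_ratio"],
                                        model_df[["attack_ratio", "reward_ratio"]],
                                        p_enter=config.p_enter, p_remove=config.p_remove)
        for s in lin_res.steps:
            path_rows.append({"model": "preference~inference_ratios", "action": s.action,
                              "variable": s.variable, "statistic": s.F, "p": s.p,
                              "r2": s.r2, "delta_r2": s.delta_r2})
        log_lines.append(f"stepwise linear: included {lin_res.included}, "
                         f"r2={lin_res.r2:.3f}")
        if labels is not None:
            cl_df = model_df.join(labels, how="inner").dropna()
            y = (cl_df["cluster_label"] == "sensitive").astype(int)
            if y.nunique() == 2:
                log_res = stats.stepwise_logistic(
                    y, cl_df[["attack_ratio", "reward_ratio"]],
                    p_enter=config.p_enter, p_remove=config.p_remove)
                for action, var, lr, p in log_res.steps:
                    path_rows.append({"model": "cluster~inference_ratios",
                                      "action": action, "variable": var,
                                      "statistic": lr, "p": p, "r2": np.nan,
                                      "delta_r2": np.nan})
                log_lines.append(
                    f"stepwise logistic: included {log_res.included}, "
                    f"Nagelkerke r2={log_res.nagelkerke_r2:.3f}, "
                    f"accuracy {100 * log_res.accuracy:.1f}%")
    pd.DataFrame(path_rows).to_csv(out / "regression_paths.csv", index=False)

    # 6. PCA over instrumental items (pre vs punishment phase aggregates)
    pre_rep = (reports[reports["phase"] == "pre"]
               .groupby("participant_id", sort=True).mean(numeric_only=True))
    items = pd.DataFrame(index=model_df.index)
    rate = (collapsed.groupby(["participant_id", "phase"])["overall_iti_rate"]
            .mean().unstack())
    items["rate_pre"] = rate.get("pre")
    items["rate_pun"] = rate.get("punish")
    items["pref_pre"] = (collapsed[collapsed["block"] == "Pre"]
                         .set_index("participant_id")["preference_ratio"])
    items["pref_pun"] = pref
    items["attack_ratio"] = phase_rep["attack_ratio"]
    items["reward_ratio"] = phase_rep["reward_ratio"]
    items = items.dropna()
    if len(items) > items.shape[1] + 2:
        try:
            pca = stats.pca_varimax(items)
            pca.loadings.round(4).to_csv(out / "pca_loadings.csv")
            log_lines.append(f"PCA: {pca.n_components} components, "
                             f"{100 * pca.total_variance_explained:.1f}% of variance")
        except ValueError as e:
            log_lines.append(f"WARNING: PCA skipped ({e})")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
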