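"""End-to-end orchestration: simulate (or load) a cohort, compute SL
matrices, small-world metrics across threshold and degree grids, and
group statistics, writing a plain-text output bundle.

Outputs per run (all TSV / key-value text, bit-identical under a fixed
seed): per-subject time-series and SL matrices, group-mean SL matrices,
a long-format metrics table, a study-summary table (whole-brain mean
synchronization S, corrected cluster coefficient gamma and corrected
path length lambda per group, with two-sample t-tests), per-level
t statistics, the cluster-based permutation test report, the regional
SL difference map and its block-level summary, and a run manifest.

Since the synchronization likelihood is a bivariate measure, the
cerebellum-excluded analysis set is the row/column subset of each
subject's full SL matrix; it does not require recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as slio
from .graphs import corrected_metrics, graph_from_degree, graph_from_threshold
from .registry import exclude_cerebellum, load_registry, make_registry
from .sl import SlParams, SyncMatrix, global_sync_mean, sl_matrix
from .stats import (block_summary, cluster_permutation_test, level_tstats,
                    regional_difference_map)
from .synthetic import CohortConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]

VERSION = "0.1.0"

DEFAULT_T_LEVELS = (0.01, 0.02, 0.03, 0.04, 0.05)
DEFAULT_K_LEVELS = tuple(range(5, 16))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    sl_params: SlParams = field(default_factory=SlParams)
    t_levels: tuple = DEFAULT_T_LEVELS
    k_levels: tuple = DEFAULT_K_LEVELS
    n_surrogates: int = 50
    reference_k: float = 10.0
    alpha: float = 0.05
    n_permutations: int = 5000
    cluster_metric: str = "lam"
    seed: int = 0
    use_bundled_registry: bool = True
    write_subjects: bool = True

    def __post_init__(self) -> None:
        if self.cluster_metric not in ("C", "L", "gamma", "lam"):
            raise ValueError(f"unknown cluster_metric {self.cluster_metric!r}")


def _submatrix(m: SyncMatrix, keep: np.ndarray) -> SyncMatrix:
    labels = tuple(np.asarray(m.region_labels)[keep])
    return SyncMatrix(values=m.values[np.ix_(keep, keep)], region_labels=labels)


def _metrics_table(matrices, subjects, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for si, (subj, mat) in enumerate(zip(subjects, matrices)):
        for mode, levels, builder in (
                ("T", cfg.t_levels, graph_from_threshold),
                ("K", cfg.k_levels, graph_from_degree)):
            for li, level in enumerate(levels):
                g = builder(mat, level)
                rec = corrected_metrics(
                    g, n_surrogates=cfg.n_surrogates,
                    seed=[cfg.seed, 7, si, 0 if mode == "T" else 1, li],
                    subject_id=subj.subject_id, mode=mode, level=level)
                rows.append({
                    "subject_id": subj.subject_id, "group": subj.group,
                    "mode": mode, "level": level, "C": rec.C, "L": rec.L,
                    "C_s": rec.C_s, "L_s": rec.L_s, "gamma": rec.gamma,
                    "lambda": rec.lam,
                    "n_inf_surrogates": rec.n_inf_surrogates,
                })
    return pd.DataFrame(rows)


def _group_pivot(metrics: pd.DataFrame, mode: str, column: str):
    """Per-group (n_subjects x n_levels) arrays for one metric column."""
    sub = metrics[metrics["mode"] == mode]
    piv = sub.pivot_table(index=["group", "subject_id"], columns="level",
                          values=column, sort=True)
    levels = tuple(piv.columns)
    g1 = piv.loc["patient"].to_numpy()
    g2 = piv.loc["control"].to_numpy()
    return g1, g2, levels


def _summary_table(matrices, subjects, metrics: pd.DataFrame,
                   cfg: RunConfig, roi_set: str) -> pd.DataFrame:
    from scipy import stats as sps

    s_vals = {"control": [], "patient": []}
    for subj, mat in zip(subjects, matrices):
        s_vals[subj.group].append(global_sync_mean(mat))
    ref = metrics[(metrics["mode"] == "K") &
                  (np.isclose(metrics["level"], cfg.reference_k))]
    rows = []
    for name, col in (("S", None), ("gamma", "gamma"), ("lambda", "lambda")):
        if col is None:
            pat = np.array(s_vals["patient"])
            ctl = np.array(s_vals["control"])
        else:
            pat = ref[ref["group"] == "patient"][col].to_numpy()
            ctl = ref[ref["group"] == "control"][col].to_numpy()
        t, p = sps.ttest_ind(pat, ctl, equal_var=True)
        rows.append({"roi_set": roi_set, "parameter": name,
                     "patient_mean": pat.mean(), "patient_sd": pat.std(ddof=1),
                     "control_mean": ctl.mean(), "control_sd": ctl.std(ddof=1),
                     "t": t, "p": p})
    return pd.DataFrame(rows)


def _analyse_roi_set(tag: str, registry, subjects, matrices,
                     cfg: RunConfig, out: Path) -> dict:
    res: dict = {}
    # group-mean SL matrices
    for group in ("control", "patient"):
        vals = np.mean([m.values for s, m in zip(subjects, matrices)
                        if s.group == group], axis=0)
        np.fill_diagonal(vals, 1.0)
        mean_mat = SyncMatrix(values=np.clip(0.5 * (vals + vals.T), 0, 1),
                              region_labels=matrices[0].region_labels)
        slio.write_sync_matrix(mean_mat, out / f"mean_sl_{group}_{tag}.tsv")

    metrics = _metrics_table(matrices, subjects, cfg)
    metrics.to_csv(out / f"metrics_{tag}.tsv", sep="\t", index=False,
                   float_format="%.10g")
    res["metrics"] = metrics

    summary = _summary_table(matrices, subjects, metrics, cfg, tag)
    res["summary"] = summary

    # per-level t statistics for C and L on both grids
    t_rows = []
    for mode in ("T", "K"):
        for col in ("C", "L", "gamma", "lambda"):
            g1, g2, levels = _group_pivot(metrics, mode, col)
            ls = level_tstats(g1, g2, levels=levels)
            for lev, t in zip(ls.levels, ls.t_values):
                t_rows.append({"mode": mode, "metric": col, "level": lev,
                               "t": t, "df": ls.df})
    pd.DataFrame(t_rows).to_csv(out / f"level_tstats_{tag}.tsv", sep="\t",
                                index=False, float_format="%.10g")

    # cluster-based permutation test on the chosen metric over K levels
    colname = {"lam": "lambda"}.get(cfg.cluster_metric, cfg.cluster_metric)
    g1, g2, levels = _group_pivot(metrics, "K", colname)
    cluster = cluster_permutation_test(
        g1, g2, levels=levels, n_permutations=cfg.n_permutations,
        seed=[cfg.seed, 11])
    res["cluster"] = cluster
    report = {
        "metric": colname, "mode": "K", "p_value": cluster.p_value,
        "max_stat": cluster.max_stat, "method": cluster.method,
        "n_permutations": cluster.n_permutations,
        "threshold_lo": cluster.threshold[0],
        "threshold_hi": cluster.threshold[1],
        "clusters": "; ".join(
            f"levels {c.levels[0]}..{c.levels[-1]} sign {c.sign:+d} "
            f"sum {c.stat:.4f}" for c in cluster.clusters) or "none",
    }
    slio.write_keyvalue(report, out / f"cluster_test_{tag}.txt")

    # regional difference map (patient vs control) and block summary
    pat = [m for s, m in zip(subjects, matrices) if s.group == "patient"]
    ctl = [m for s, m in zip(subjects, matrices) if s.group == "control"]
    dmap = regional_difference_map(pat, ctl, alpha=cfg.alpha)
    res["diff_map"] = dmap
    pd.DataFrame(dmap.signs, index=list(dmap.region_labels),
                 columns=list(dmap.region_labels)).to_csv(
        out / f"regional_diff_{tag}.tsv", sep="\t")
    blocks = block_summary(dmap, registry)
    blocks.to_csv(out / f"block_summary_{tag}.tsv", sep="\t", index=False)
    res["block_summary"] = blocks
    return res


def run_pipeline(config: RunConfig, out_dir, registry=None,
                 subjects=None) -> dict:
    """Run the full analysis and write the output bundle to ``out_dir``.

    ``registry`` and ``subjects`` default to the bundled AAL registry
    and a cohort simulated from ``config.cohort``.  Returns a dict with
    the in-memory results (metrics tables, summary, cluster results,
    difference maps) keyed by ROI-set tag.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort_cfg = config.cohort
    if registry is None:
        if config.use_bundled_registry and cohort_cfg.n_regions == 116:
            registry = load_registry()
            if cohort_cfg.region_labels is None:
                cohort_cfg = replace(
                    cohort_cfg, region_labels=tuple(registry["region"]),
                    block_map=tuple(registry["block"]))
        else:
            registry = make_registry(cohort_cfg.block_map,
                                     cohort_cfg.region_labels)
    if subjects is None:
        subjects = simulate_cohort(cohort_cfg)
    if subjects[0].n_regions != len(registry):
        raise ValueError("registry does not cover the subjects' regions")

    if config.write_subjects:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for s in subjects:
            slio.write_subject_tsv(s, ts_dir / f"{s.subject_id}.tsv")
    slio.write_manifest_tsv(subjects, out / "cohort_manifest.tsv")
    registry.to_csv(out / "registry.tsv", sep="\t", index=False)

    matrices = [sl_matrix(s, config.sl_params) for s in subjects]
    sl_dir = out / "sl_matrices"
    sl_dir.mkdir(exist_ok=True)
    for s, m in zip(subjects, matrices):
        slio.write_sync_matrix(m, sl_dir / f"{s.subject_id}.tsv")

    results: dict = {}
    tag_full = f"roi{len(registry)}"
    results[tag_full] = _analyse_roi_set(tag_full, registry, subjects,
                                         matrices, config, out)

    if registry["cerebellum"].astype(bool).any():
        reg90, subj90 = exclude_cerebellum(registry, subjects)
        keep = ~registry["cerebellum"].astype(bool).to_numpy()
        mats90 = [_submatrix(m, keep) for m in matrices]
        tag90 = f"roi{len(reg90)}"
        results[tag90] = _analyse_roi_set(tag90, reg90, subj90, mats90,
                                          config, out)

    summary = pd.concat([r["summary"] for r in results.values()],
                        ignore_index=True)
    summary.to_csv(out / "summary_table.tsv", sep="\t", index=False,
                   float_format="%.10g")
    results["summary_table"] = summary

    manifest = {
        "slnet_version": VERSION,
        "seed": config.seed,
        "n_control": cohort_cfg.n_control,
        "n_patient": cohort_cfg.n_patient,
        "n_regions": cohort_cfg.n_regions,
        "n_timepoints": cohort_cfg.n_timepoints,
        "sl_lag": config.sl_params.lag,
        "sl_dim": config.sl_params.dim,
        "sl_theiler": config.sl_params.theiler,
        "sl_pref": config.sl_params.pref,
        "t_levels": ",".join(str(t) for t in config.t_levels),
        "k_levels": ",".join(str(k) for k in config.k_levels),
        "n_surrogates": config.n_surrogates,
        "reference_k": config.reference_k,
        "alpha": config.alpha,
        "n_permutations": config.n_permutations,
        "cluster_metric": config.cluster_metric,
    }
    slio.write_keyvalue(manifest, out / "run_manifest.txt")
    results["manifest"] = manifest
    return results
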