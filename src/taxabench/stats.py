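"""Aggregation of per-sample metrics and cross-pipeline significance tests.

Per-sample metrics are summarized as mean +/- SD per (community,
pipeline, metric); replicate communities aggregate over their technical
replicates, one-to-one communities contribute a single value (no SD).
Pipelines are then compared with a Kruskal-Wallis test followed by
post-hoc pairwise Wilcoxon tests under Benjamini-Hochberg FDR control.

The sampling unit for the cross-pipeline tests is configurable: the
per-community mean (default; one value per community per pipeline) or
the individual sample.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

METRIC_COLUMNS = {"AD": "ad", "Sensitivity": "sensitivity_pct", "FPRA": "fpra_pct"}


@dataclass
class TestResult:
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    adjusted_p: Optional[float] = None


def summarize(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/n per (community, pipeline, metric) from a long metrics table.

    Input columns: sample_id, pipeline_id, community_id, ad,
    sensitivity_pct, fpra_pct [, unclassified_pct].  SD is NaN for n=1.
    """
    rows = []
    for (community, pipeline), sub in metrics.groupby(
        ["community_id", "pipeline_id"], sort=False
    ):
        for metric, col in METRIC_COLUMNS.items():
            values = sub[col].dropna().to_numpy()
            if values.size == 0:
                continue
            rows.append(
                {
                    "community_id": community,
                    "pipeline_id": pipeline,
                    "metric": metric,
                    "mean": float(values.mean()),
                    "sd": float(values.std(ddof=1)) if values.size > 1 else math.nan,
                    "n": int(values.size),
                }
            )
    return pd.DataFrame(rows)


def community_average(means: Sequence[float]) -> float:
    """Community 'difficulty': mean of the pipelines' community means."""
    if len(means) < 2:
        raise ValidationError("community average needs >= 2 pipelines")
    return float(np.mean(means))


def pipeline_average(means: Sequence[float]) -> tuple[float, float]:
    """Unweighted grand mean and SD of a pipeline's per-community means."""
    if len(means) < 2:
        raise ValidationError("pipeline average needs >= 2 communities")
    arr = np.asarray(means, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def metric_table(summaries: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Publication-shaped summary table for one metric.

    Community rows x (pipeline mean, sd) columns, plus an ``Average``
    column (community difficulty) and an ``Average`` row (per-pipeline
    grand mean over communities).
    """
    sub = summaries[summaries.metric == metric]
    if sub.empty:
        raise ValidationError(f"no summaries for metric {metric!r}")
    mean_tbl = sub.pivot(index="community_id", columns="pipeline_id", values="mean")
    sd_tbl = sub.pivot(index="community_id", columns="pipeline_id", values="sd")
    out = pd.DataFrame(index=mean_tbl.index)
    for pipeline in mean_tbl.columns:
        out[f"{pipeline}_mean"] = mean_tbl[pipeline]
        out[f"{pipeline}_sd"] = sd_tbl[pipeline]
    out["Average"] = mean_tbl.mean(axis=1)
    grand = {}
    for pipeline in mean_tbl.columns:
        vals = mean_tbl[pipeline].dropna().tolist()
        if len(vals) > 1:
            g_mean, g_sd = pipeline_average(vals)
        else:  # single community: grand mean degenerates to that value
            g_mean, g_sd = vals[0], math.nan
        grand[f"{pipeline}_mean"] = g_mean
        grand[f"{pipeline}_sd"] = g_sd
    grand["Average"] = math.nan
    out.loc["Average"] = pd.Series(grand)
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups (tie-corrected ranks,
    chi-square approximation with k-1 degrees of freedom).

    If every value in every group is identical the test is degenerate:
    H = 0, p = 1.
    """
    names = tuple(groups)
    if len(names) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for name, arr in zip(names, arrays):
        if arr.size == 0:
            raise ValidationError(f"group {name!r} is empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(names, 0.0, 1.0)
    stat, p = sps.kruskal(*arrays)
    return TestResult(names, float(stat), float(p))


def pairwise_wilcoxon_bh(
    groups: Mapping[str, Sequence[float]],
    paired: bool = False,
) -> pd.DataFrame:
    """All pairwise two-sample rank tests with Benjamini-Hochberg FDR.

    Unpaired rank-sum (Mann-Whitney U) by default; the paired signed-rank
    variant is available when samples correspond one-to-one across
    groups.  Exact p-values are used for small samples (total n <= 10),
    the tie-corrected normal approximation otherwise.  A pair whose test
    cannot be computed is recorded with NaN rather than aborting the
    whole comparison.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("pairwise comparison needs >= 2 groups")
    rows = []
    for a, b in itertools.combinations(names, 2):
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        try:
            if x.size < 2 or y.size < 2:
                raise ValidationError("group size < 2")
            if paired:
                if x.size != y.size:
                    raise ValidationError("paired test needs equal sizes")
                if np.all(x == y):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = sps.wilcoxon(x, y)
            else:
                method = "exact" if (x.size + y.size) <= 10 and not _has_ties(x, y) else "asymptotic"
                stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
            rows.append({"group_a": a, "group_b": b, "statistic": float(stat), "p_value": float(p)})
        except ValidationError as exc:
            rows.append(
                {"group_a": a, "group_b": b, "statistic": math.nan, "p_value": math.nan,
                 "error": str(exc)}
            )
    out = pd.DataFrame(rows)
    ok = out.p_value.notna()
    adjusted = np.full(len(out), math.nan)
    if ok.any():
        adjusted[ok.to_numpy()] = multipletests(
            out.loc[ok, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["adjusted_p"] = adjusted
    return out


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def compare_pipelines(
    metrics: pd.DataFrame,
    metric: str = "AD",
    unit: str = "community",
    paired: bool = False,
) -> tuple[TestResult, pd.DataFrame]:
    """Cross-pipeline significance testing for one metric.

    ``unit='community'`` tests per-community means (the fully printed
    summary level); ``unit='sample'`` tests individual sample values.
    """
    col = METRIC_COLUMNS[metric]
    if unit == "community":
        summaries = summarize(metrics)
        sub = summaries[summaries.metric == metric]
        groups = {
            p: g["mean"].tolist() for p, g in sub.groupby("pipeline_id", sort=False)
        }
    elif unit == "sample":
        groups = {
            p: g[col].dropna().tolist()
            for p, g in metrics.groupby("pipeline_id", sort=False)
        }
    else:
        raise ValueError("unit must be 'community' or 'sample'")
    return kruskal_wallis(groups), pairwise_wilcoxon_bh(groups, paired=paired)
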