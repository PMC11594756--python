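"""Group-comparison statistics and the qPCR relative-expression utility.

Group differences in the activity parameters are assessed with the
Kruskal-Wallis rank test (tie-corrected H, chi-square p with k-1 degrees of
freedom, via scipy); an exact permutation p-value is available for very
small samples.  Relative mRNA levels use the standard ddCt method,
``fold = 2**(-ddCt)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class ValidationError(ValueError):
    pass


@dataclass
class GroupSamples:
    """Named groups of a per-recording statistic."""

    labels: list[str]
    values: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValidationError("labels and values differ in length")
        if len(self.labels) < 2:
            raise ValidationError("need at least 2 groups")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for lab, v in zip(self.labels, self.values):
            if v.size == 0:
                raise ValidationError(f"group {lab!r} is empty")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str, value_col: str):
        labels, values = [], []
        for lab, sub in df.groupby(group_col):
            labels.append(str(lab))
            values.append(sub[value_col].dropna().to_numpy())
        return cls(labels=labels, values=values)


def kruskal_wallis(
    g: GroupSamples, permutation: bool = False
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its p-value.

    The p-value uses the chi-square approximation with ``k - 1`` degrees of
    freedom; with ``permutation=True`` (intended for total N <= 10) the exact
    permutation distribution of H over all group relabellings is used
    instead.
    """
    n_total = sum(v.size for v in g.values)
    if n_total < 3:
        raise ValidationError("need at least 3 observations in total")
    pooled = np.concatenate(g.values)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # scipy rejects the all-identical degenerate case
    h, p = sps.kruskal(*g.values)
    if permutation:
        p = _permutation_pvalue(g, h)
    return float(h), float(p)


def _h_statistic(pooled_ranks: np.ndarray, sizes: list[int], tie_term: float) -> float:
    n = pooled_ranks.size
    h = 0.0
    start = 0
    for sz in sizes:
        r = pooled_ranks[start : start + sz].sum()
        h += r * r / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _permutation_pvalue(g: GroupSamples, h_obs: float) -> float:
    pooled = np.concatenate(g.values)
    n = pooled.size
    if n > 12:
        raise ValidationError("exact permutation p-value only for small N")
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    sizes = [v.size for v in g.values]
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if _h_statistic(ranks[list(perm)], sizes, tie_term) >= h_obs - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# ddCt


def delta_delta_ct(
    table: pd.DataFrame,
    control_label: str = "control",
    sample_col: str = "sample",
    condition_col: str = "condition",
    ct_target_col: str = "ct_target",
    ct_reference_col: str = "ct_reference",
) -> pd.DataFrame:
    """Relative expression per sample by the ddCt method.

    ``dCt = Ct_target - Ct_reference`` per sample; ``ddCt`` subtracts the
    mean dCt of the control condition; relative expression is ``2**(-ddCt)``.
    """
    for col in (sample_col, condition_col, ct_target_col, ct_reference_col):
        if col not in table.columns:
            raise ValidationError(f"ddCt table lacks column {col!r}")
    ct_t = table[ct_target_col].astype(float)
    ct_r = table[ct_reference_col].astype(float)
    if not (np.isfinite(ct_t).all() and np.isfinite(ct_r).all()):
        raise ValidationError("Ct values must be finite")
    if (ct_t <= 0).any() or (ct_r <= 0).any():
        raise ValidationError("Ct values must be > 0")
    dct = ct_t - ct_r
    control = dct[table[condition_col] == control_label]
    if control.empty:
        raise ValidationError(f"no rows with control condition {control_label!r}")
    ddct = dct - control.mean()
    out = table[[sample_col, condition_col]].copy()
    out["delta_ct"] = dct
    out["delta_delta_ct"] = ddct
    out["relative_expression"] = np.power(2.0, -ddct)
    return out


# ---------------------------------------------------------------------------
# longitudinal fold changes and omnibus tests


def fold_change_report(
    summary: pd.DataFrame,
    metrics: list[str] | None = None,
    baseline_div: int = 14,
) -> pd.DataFrame:
    """Group-mean fold change of each metric vs the group's baseline DIV.

    ``summary`` is the per-recording longitudinal table (columns ``group``,
    ``div`` plus metric columns).  Zero or missing baselines yield NaN.
    """
    from .bursts import METRIC_COLUMNS

    if metrics is None:
        metrics = [m for m in METRIC_COLUMNS if m in summary.columns]
    rows = []
    for group, sub in summary.groupby("group"):
        base = sub[sub["div"] == baseline_div]
        for div, per_div in sub.groupby("div"):
            row = {"group": group, "div": div}
            for metric in metrics:
                base_mean = base[metric].mean() if not base.empty else math.nan
                div_mean = per_div[metric].mean()
                row[f"fold_{metric}"] = (
                    div_mean / base_mean
                    if np.isfinite(base_mean) and base_mean != 0
                    else math.nan
                )
            rows.append(row)
    return pd.DataFrame(rows).sort_values(["group", "div"]).reset_index(drop=True)


def group_comparison_table(
    summary: pd.DataFrame,
    metrics: list[str] | None = None,
    posthoc: bool = False,
) -> pd.DataFrame:
    """Per-DIV omnibus Kruskal-Wallis across groups for each metric.

    With ``posthoc=True``, pairwise two-group rank tests with Holm-adjusted
    p-values are appended (the omnibus rows carry ``comparison='omnibus'``).
    """
    from .bursts import METRIC_COLUMNS

    if metrics is None:
        metrics = [m for m in METRIC_COLUMNS if m in summary.columns]
    rows = []
    for div, sub in summary.groupby("div"):
        for metric in metrics:
            clean = sub.dropna(subset=[metric])
            groups = [g for g, s in clean.groupby("group") if len(s) > 0]
            if len(groups) < 2:
                continue
            gs = GroupSamples.from_frame(clean, "group", metric)
            try:
                h, p = kruskal_wallis(gs)
            except ValidationError:
                continue
            rows.append(
                {
                    "div": div,
                    "metric": metric,
                    "comparison": "omnibus",
                    "statistic": h,
                    "df": len(gs.labels) - 1,
                    "p": p,
                    "p_adjusted": p,
                }
            )
            if posthoc:
                rows.extend(_pairwise(clean, div, metric))
    return pd.DataFrame(
        rows,
        columns=["div", "metric", "comparison", "statistic", "df", "p", "p_adjusted"],
    )


def _pairwise(clean: pd.DataFrame, div, metric: str) -> list[dict]:
    by_group = {g: s[metric].to_numpy() for g, s in clean.groupby("group")}
    pairs = list(itertools.combinations(sorted(by_group), 2))
    raw = []
    for a, b in pairs:
        gs = GroupSamples(labels=[a, b], values=[by_group[a], by_group[b]])
        h, p = kruskal_wallis(gs)
        raw.append((a, b, h, p))
    adjusted = holm_adjust([p for *_ , p in raw])
    return [
        {
            "div": div,
            "metric": metric,
            "comparison": f"{a} vs {b}",
            "statistic": h,
            "df": 1,
            "p": p,
            "p_adjusted": padj,
        }
        for (a, b, h, p), padj in zip(raw, adjusted)
    ]


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjustment, monotone and capped at 1."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
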