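"""Group summaries and Mann-Whitney U comparisons between conditions.

Per-recording metrics are summarized as mean ± SD (sample SD) per condition,
and each treated condition is compared against the control with a two-sided
Mann-Whitney U test — exact by full enumeration for small tie-free samples,
otherwise the normal approximation with tie-corrected variance and
continuity correction.  No multiple-testing correction is applied; panels
are reported individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "ConditionSummary", "mann_whitney_u",
           "summarize_conditions", "replicate_density_comparison"]


@dataclass
class TestResult:
    U: float            # U statistic of the first sample
    n1: int
    n2: int
    p_value: float      # two-sided
    method: str         # "exact" or "asymptotic"

    def __post_init__(self) -> None:
        assert 0.0 <= self.U <= self.n1 * self.n2 + 1e-9
        assert 0.0 <= self.p_value <= 1.0


@dataclass
class ConditionSummary:
    condition: str
    n: int
    metrics: pd.DataFrame  # index: metric; columns: mean, sd, min, max, n


def mann_whitney_u(x, y, exact_max_n: int = 8) -> TestResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    U is computed from midrank sums.  The p-value is exact (full enumeration
    of rank assignments) when ``max(n1, n2) <= exact_max_n`` and the pooled
    sample is tie-free, and otherwise uses the normal approximation with
    tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = max(x.size, y.size) <= exact_max_n and not ties
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return TestResult(U=float(res.statistic), n1=x.size, n2=y.size,
                      p_value=float(res.pvalue),
                      method="exact" if exact else "asymptotic")


def replicate_density_comparison(cond_a: str = "control",
                                 cond_b: str = "suramin",
                                 n_replicates: int = 100,
                                 seed: int = 0) -> np.ndarray:
    """Monte-Carlo twin of the between-condition density comparison.

    For each replicate, per-recording active-cell densities are drawn from
    the two conditions' truncated-normal distributions at their study group
    sizes, and the two-sided Mann-Whitney U p-value is computed.  Returns
    the array of p-values (one per replicate).
    """
    from .simulate import condition_preset, truncated_normal

    a, b = condition_preset(cond_a), condition_preset(cond_b)
    ma, sa = a.metric_distributions["density"]
    mb, sb = b.metric_distributions["density"]
    rng = np.random.default_rng(seed)
    ps = np.empty(n_replicates)
    for i in range(n_replicates):
        x = truncated_normal(ma, sa, rng, a.n_recordings)
        y = truncated_normal(mb, sb, rng, b.n_recordings)
        ps[i] = mann_whitney_u(x, y).p_value
    return ps


def summarize_conditions(
    metrics: pd.DataFrame,
    control: str = "control",
    metric_columns: list[str] | None = None,
    exact_max_n: int = 8,
) -> tuple[list[ConditionSummary], dict[tuple[str, str], TestResult]]:
    """Per-condition mean ± SD summaries and tests vs control.

    ``metrics`` has one row per recording with a ``condition`` column plus
    numeric metric columns.  Missing values (e.g. undefined speeds of failed
    waves) are excluded pairwise; the per-metric n in the summaries reports
    how many recordings contributed.  Returns the summaries and a dict of
    ``(condition, metric) -> TestResult`` for every non-control condition.
    """
    if "condition" not in metrics.columns:
        raise ValueError("metrics table needs a 'condition' column")
    if metric_columns is None:
        metric_columns = [c for c in metrics.columns
                          if c != "condition"
                          and np.issubdtype(metrics[c].dtype, np.number)]
    conditions = list(dict.fromkeys(metrics["condition"]))
    if len(conditions) >= 2 and control not in conditions:
        raise ValueError(f"no condition labeled {control!r}")

    summaries = []
    for cond in conditions:
        sub = metrics.loc[metrics["condition"] == cond, metric_columns]
        tab = pd.DataFrame({
            "mean": sub.mean(), "sd": sub.std(ddof=1),
            "min": sub.min(), "max": sub.max(), "n": sub.count(),
        })
        summaries.append(ConditionSummary(cond, len(sub), tab))

    tests: dict[tuple[str, str], TestResult] = {}
    if len(conditions) < 2:
        warnings.warn("single condition: summaries only, no tests", stacklevel=2)
        return summaries, tests
    ctrl = metrics[metrics["condition"] == control]
    for cond in conditions:
        if cond == control:
            continue
        other = metrics[metrics["condition"] == cond]
        for m in metric_columns:
            a = ctrl[m].dropna().to_numpy()
            b = other[m].dropna().to_numpy()
            if a.size and b.size:
                tests[(cond, m)] = mann_whitney_u(a, b, exact_max_n)
    return summaries, tests
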