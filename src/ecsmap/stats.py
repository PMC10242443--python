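"""Nonparametric group comparisons shared by the diffusion and width analyses.

Two-group designs use the two-sided Mann-Whitney U test, k-group designs use
Kruskal-Wallis followed by Dunn's pairwise post-hoc test with Bonferroni
adjustment, and distribution comparisons use the two-sample
Kolmogorov-Smirnov test.  Dunn's z statistics are computed from mean ranks of
the pooled sample with the standard tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestReport", "compare_groups", "dunn_posthoc", "summarize"]


@dataclass
class TestReport:
    test: str
    statistic: float
    pvalue: float
    n_per_group: dict[str, int]
    degenerate: bool = False
    posthoc: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def summarize(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    n = values.size
    return {
        "n": int(n),
        "mean": float(values.mean()),
        "sem": float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "median": float(np.median(values)),
    }


def dunn_posthoc(samples: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise comparisons on pooled mean ranks with tie correction."""
    labels = list(samples)
    values = [np.asarray(samples[k], dtype=float) for k in labels]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks, sizes = {}, {}
    offset = 0
    for lab, v in zip(labels, values):
        mean_ranks[lab] = float(ranks[offset : offset + v.size].mean())
        sizes[lab] = v.size
        offset += v.size
    rows = []
    m = len(labels) * (len(labels) - 1) // 2
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
            rows.append({"group_a": a, "group_b": b, "z": z, "p": p, "p_adj": p_adj})
    return pd.DataFrame(rows)


def compare_groups(samples: dict[str, np.ndarray], design: str = "two_group") -> TestReport:
    """Compare labeled value lists with the design-appropriate rank test.

    design: "two_group" (Mann-Whitney U, two-sided), "k_group"
    (Kruskal-Wallis + Dunn's/Bonferroni), or "distribution" (two-sample KS).
    Groups that are all tied to a single constant are degenerate and reported
    with p = 1.
    """
    samples = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for k, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    n_per = {k: int(v.size) for k, v in samples.items()}
    summary = {k: summarize(v) for k, v in samples.items()}
    pooled = np.concatenate(list(samples.values()))
    if np.all(pooled == pooled[0]):
        return TestReport(design, float("nan"), 1.0, n_per, degenerate=True,
                          summary=summary)
    vals = list(samples.values())
    if design == "two_group":
        if len(samples) != 2:
            raise ValueError("two_group design requires exactly two groups")
        res = sps.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        return TestReport("mann-whitney", float(res.statistic), float(res.pvalue),
                          n_per, summary=summary)
    if design == "distribution":
        if len(samples) != 2:
            raise ValueError("distribution design requires exactly two groups")
        res = sps.ks_2samp(vals[0], vals[1])
        return TestReport("kolmogorov-smirnov", float(res.statistic),
                          float(res.pvalue), n_per, summary=summary)
    if design == "k_group":
        res = sps.kruskal(*vals)
        return TestReport("kruskal-wallis", float(res.statistic), float(res.pvalue),
                          n_per, posthoc=dunn_posthoc(samples), summary=summary)
    raise ValueError(f"unknown design {design!r}")
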