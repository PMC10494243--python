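"""Group-comparison statistics used in the cohort reports.

Two groups are compared with the Mann-Whitney U test; three or more with the
Kruskal-Wallis test followed by Dunn's pairwise post-hoc comparisons (rank
sums with tie correction), reported both unadjusted and Holm-adjusted.
Distributions are summarized as Q1/median/Q3 with linear-interpolation
quartiles.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def summarize_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """(Q1, median, Q3) with linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to summarize")
    q1, m, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(q1), float(m), float(q3)


def quartile_table(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for label, v in groups.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        q1, m, q3 = summarize_quartiles(v)
        rows.append({"group": label, "n": v.size, "q1": q1, "median": m, "q3": q3})
    return pd.DataFrame(rows)


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on rank sums after a Kruskal-Wallis design.

    For groups i, j with mean ranks Rbar_i, Rbar_j over the pooled ranking
    of N observations, z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) *
    (1/n_i + 1/n_j)) with the tie correction T = sum(t^3 - t) / (12(N-1)).
    Two-sided p-values are reported raw and Holm-adjusted.
    """
    labels = list(groups)
    clean = {k: np.asarray(v, float)[np.isfinite(np.asarray(v, float))]
             for k, v in groups.items()}
    pooled = np.concatenate([clean[k] for k in labels])
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    sizes = {}
    i0 = 0
    for k in labels:
        n_k = clean[k].size
        mean_rank[k] = float(ranks[i0 : i0 + n_k].mean())
        sizes[k] = n_k
        i0 += n_k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p_unadjusted": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = multipletests(df["p_unadjusted"], method="holm")[1]
    return df


def group_compare(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Omnibus + pairwise comparison table for two or more groups.

    Two groups: a single Mann-Whitney U row.  More: one Kruskal-Wallis row
    followed by Dunn rows with raw and Holm-adjusted p-values.  Degenerate
    groups (n < 3 or all ties) are flagged rather than tested.
    """
    clean = {k: np.asarray(v, float)[np.isfinite(np.asarray(v, float))]
             for k, v in groups.items()}
    if len(clean) < 2:
        raise ValueError("need at least two groups")
    flags = {
        k: ("n<3" if v.size < 3 else "all-ties" if np.ptp(v) == 0 else "")
        for k, v in clean.items()
    }
    degenerate = [k for k, f in flags.items() if f]
    rows = []
    if degenerate:
        rows.append(
            {
                "test": "degenerate",
                "group1": ";".join(f"{k}({flags[k]})" for k in degenerate),
                "group2": "",
                "statistic": np.nan,
                "p_value": np.nan,
                "p_holm": np.nan,
            }
        )
        return pd.DataFrame(rows)
    labels = list(clean)
    if len(labels) == 2:
        a, b = labels
        res = sps.mannwhitneyu(clean[a], clean[b], alternative="two-sided")
        rows.append(
            {
                "test": "mann-whitney-u",
                "group1": a,
                "group2": b,
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "p_holm": float(res.pvalue),
            }
        )
    else:
        kw = sps.kruskal(*[clean[k] for k in labels])
        rows.append(
            {
                "test": "kruskal-wallis",
                "group1": "all",
                "group2": "",
                "statistic": float(kw.statistic),
                "p_value": float(kw.pvalue),
                "p_holm": np.nan,
            }
        )
        for _, r in dunn_test(clean).iterrows():
            rows.append(
                {
                    "test": "dunn",
                    "group1": r["group1"],
                    "group2": r["group2"],
                    "statistic": float(r["z"]),
                    "p_value": float(r["p_unadjusted"]),
                    "p_holm": float(r["p_holm"]),
                }
            )
    return pd.DataFrame(rows)
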