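"""Group comparison for kinetics metrics.

Kruskal–Wallis omnibus test followed by Dunn's pairwise z-tests on mean
ranks (with tie correction), Holm-adjusted, summarized as a compact letter
display: groups sharing a letter are not significantly different at the
chosen alpha.
"""

from __future__ import annotations

import itertools
import logging
import math
import string

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["dunn_test", "compact_letter_display", "compare_groups"]


def dunn_test(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on mean ranks, Holm-adjusted.

    Returns a table with columns (group_a, group_b, z, p_raw, p_adjusted).
    The z statistic for groups i, j is
    (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)), where T is
    the tie correction sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {g: len(samples[g]) for g in names}
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def compact_letter_display(
    groups: list[str], significant_pairs: set[frozenset], medians: dict[str, float] | None = None
) -> dict[str, str]:
    """Assign letters so that two groups share a letter iff their pair is
    not in ``significant_pairs``.

    Classic insert-and-absorb construction; deterministic for a fixed group
    order (groups are ordered by median when medians are supplied).
    """
    order = sorted(groups, key=lambda g: medians[g]) if medians else list(groups)
    letters: list[set[str]] = [set(order)]
    for a, b in itertools.combinations(order, 2):
        if frozenset((a, b)) not in significant_pairs:
            continue
        for s in list(letters):
            if a in s and b in s:
                letters.remove(s)
                letters.append(s - {a})
                letters.append(s - {b})
        # absorb subsets
        letters = [s for s in letters if s and not any(s < o for o in letters if o is not s)]
    # drop exact duplicates, keep deterministic order
    unique: list[set[str]] = []
    for s in letters:
        if s not in unique:
            unique.append(s)
    unique.sort(key=lambda s: min(order.index(g) for g in s))
    if len(unique) > len(string.ascii_lowercase):
        raise ValueError("more letter groups than letters")
    out = {g: "" for g in order}
    for letter, s in zip(string.ascii_lowercase, unique):
        for g in order:
            if g in s:
                out[g] += letter
    return out


def compare_groups(
    records: pd.DataFrame,
    metric: str,
    group_column: str = "group",
    alpha: float = 0.01,
) -> dict:
    """Kruskal–Wallis omnibus + Dunn posthoc + compact letters for one metric.

    Groups with fewer than 2 observations are excluded with a warning.
    Returns {"kruskal_p", "pairwise" (DataFrame), "letters" (group -> str)}.
    """
    samples: dict[str, np.ndarray] = {}
    for g, sub in records.groupby(group_column, sort=False):
        vals = sub[metric].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            logger.warning("group %r has n < 2 for %s; excluded", g, metric)
            continue
        samples[g] = vals
    if len(samples) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    kw_stat, kw_p = sps.kruskal(*samples.values())
    pairwise = dunn_test(samples)
    sig = {
        frozenset((r.group_a, r.group_b))
        for r in pairwise.itertuples()
        if r.p_adjusted < alpha
    }
    medians = {g: float(np.median(v)) for g, v in samples.items()}
    letters = compact_letter_display(list(samples), sig, medians)
    return {
        "kruskal_statistic": float(kw_stat),
        "kruskal_p": float(kw_p),
        "pairwise": pairwise,
        "letters": letters,
        "alpha": alpha,
    }
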