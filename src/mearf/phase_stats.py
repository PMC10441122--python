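"""Nonparametric comparison of the protocol phases.

Each normalized metric is compared across the five phases with the
Kruskal–Wallis omnibus test (rank-based H with tie correction, chi-square
reference with k-1 degrees of freedom) followed by the Conover–Iman
all-pairs post-hoc on the same pooled ranks (t statistics with N-k degrees
of freedom), Holm-adjusted over the phase pairs.  Effect sizes are reported
as median percent changes between phases.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mearf")

DEFAULT_P_ADJUST = "holm"


# ---------------------------------------------------------------------------
# omnibus
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: dict) -> tuple[float, float]:
    """Kruskal–Wallis H and p over named groups of values.

    All-identical data (zero rank variance) are a degenerate case reported
    as H = 0, p = 1 rather than an error.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Conover–Iman all-pairs post-hoc
# ---------------------------------------------------------------------------

def conover_all_pairs(
    groups: dict, p_adjust: str | None = DEFAULT_P_ADJUST
) -> pd.DataFrame:
    """Two-sided Conover–Iman pairwise p-values from pooled ranks.

    The statistic for a pair (i, j) is
    ``(Rbar_i - Rbar_j) / sqrt(S2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))``
    where ranks are pooled with ties averaged, ``S2`` is the pooled rank
    variance (tie-corrected) and ``H`` the Kruskal–Wallis statistic; the
    reference distribution is Student's t with N-k degrees of freedom.
    P-values are adjusted over the k(k-1)/2 pairs (Holm by default;
    ``p_adjust=None`` disables adjustment).  Groups with fewer than two
    values yield NaN for their pairs.  Returns a symmetric labeled matrix
    with 1.0 on the diagonal.
    """
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    usable = [k for k in labels if len(arrays[k]) >= 2]
    for k in labels:
        if len(arrays[k]) < 2:
            logger.warning("group %s has <2 values; its pairs are undefined", k)
    k_grp = len(usable)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    np.fill_diagonal(mat.values, 1.0)
    if k_grp < 2:
        return mat

    pooled = np.concatenate([arrays[k] for k in usable])
    n = np.array([len(arrays[k]) for k in usable])
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    splits = np.split(ranks, np.cumsum(n)[:-1])
    rbar = np.array([s.mean() for s in splits])

    if np.all(pooled == pooled[0]):
        for a, b in itertools.combinations(usable, 2):
            mat.loc[a, b] = mat.loc[b, a] = 1.0
        return mat

    h, _ = kruskal_wallis({k: arrays[k] for k in usable})
    s2 = (np.sum(ranks**2) - n_tot * (n_tot + 1) ** 2 / 4.0) / (n_tot - 1)
    df = n_tot - k_grp
    scale = s2 * max(n_tot - 1 - h, 0.0) / df

    pairs = list(itertools.combinations(range(k_grp), 2))
    pvals = []
    for i, j in pairs:
        denom = np.sqrt(scale * (1.0 / n[i] + 1.0 / n[j]))
        t = (rbar[i] - rbar[j]) / denom if denom > 0 else 0.0
        pvals.append(2.0 * stats.t.sf(abs(t), df) if denom > 0 else 1.0)
    pvals = np.minimum(np.asarray(pvals), 1.0)
    if p_adjust:
        pvals = multipletests(pvals, method=p_adjust)[1]
    for (i, j), p in zip(pairs, pvals):
        a, b = usable[i], usable[j]
        mat.loc[a, b] = mat.loc[b, a] = float(p)
    return mat


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def median_percent_change(values_a, values_b) -> float:
    """``100 * (median_a - median_b) / median_b``; negative = decrease in a."""
    med_a = float(np.median(np.asarray(values_a, dtype=float)))
    med_b = float(np.median(np.asarray(values_b, dtype=float)))
    if med_b == 0:
        raise ValueError("reference median is zero; percent change undefined")
    return 100.0 * (med_a - med_b) / med_b


# ---------------------------------------------------------------------------
# report over a normalized metrics table
# ---------------------------------------------------------------------------

@dataclass
class StatsReport:
    """Per-metric omnibus + post-hoc + effect sizes over one condition."""

    metrics: dict = field(default_factory=dict)
    n_cultures: int = 0
    p_adjust: str = DEFAULT_P_ADJUST

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, entry in self.metrics.items():
            pw = entry["pairwise_p"]
            for a, b in itertools.combinations(pw.index, 2):
                rows.append(
                    (
                        metric,
                        a,
                        b,
                        pw.loc[a, b],
                        entry["median_change_pct"].get((a, b), np.nan),
                    )
                )
        return pd.DataFrame(
            rows, columns=["metric", "phase_a", "phase_b", "p_adj", "median_change_pct"]
        )

    def to_json(self, path=None):
        payload = {
            "n_cultures": self.n_cultures,
            "p_adjust": self.p_adjust,
            "metrics": {
                m: {
                    "H": e["H"],
                    "p_omnibus": e["p_omnibus"],
                    "pairwise_p": {
                        f"{a}|{b}": _nan_to_none(e["pairwise_p"].loc[a, b])
                        for a in e["pairwise_p"].index
                        for b in e["pairwise_p"].columns
                        if a != b
                    },
                    "median_change_pct": {
                        f"{a}|{b}": _nan_to_none(v)
                        for (a, b), v in e["median_change_pct"].items()
                    },
                }
                for m, e in self.metrics.items()
            },
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return None


def _nan_to_none(v):
    v = float(v)
    return None if not np.isfinite(v) else v


def compare_phases(
    normalized: pd.DataFrame,
    phases: tuple[str, ...] | None = None,
    p_adjust: str = DEFAULT_P_ADJUST,
) -> StatsReport:
    """Build a :class:`StatsReport` from a normalized tidy metrics table.

    ``normalized`` must carry columns ``culture``, ``phase``, ``metric`` and
    ``normalized_pct`` (see :func:`mearf.metrics.normalize_metrics`).  Each
    metric is treated as its own test family: Kruskal–Wallis across phases,
    Conover–Iman pairs Holm-adjusted within the metric, plus the median
    percent change for every ordered phase pair (a vs b, b the reference).
    """
    if phases is None:
        phases = tuple(pd.unique(normalized["phase"]))
    report = StatsReport(
        n_cultures=int(normalized["culture"].nunique()), p_adjust=p_adjust
    )
    for metric, grp in normalized.groupby("metric", sort=False):
        groups = {}
        for ph in phases:
            vals = grp.loc[grp["phase"] == ph, "normalized_pct"].dropna().to_numpy()
            if len(vals):
                groups[ph] = vals
        if len(groups) < 2:
            logger.warning("metric %s: fewer than two phases with data", metric)
            continue
        h, p = kruskal_wallis(groups)
        pw = conover_all_pairs(groups, p_adjust=p_adjust)
        changes = {}
        for a, b in itertools.permutations(groups, 2):
            try:
                changes[(a, b)] = median_percent_change(groups[a], groups[b])
            except ValueError:
                changes[(a, b)] = np.nan
        report.metrics[metric] = {
            "H": h,
            "p_omnibus": p,
            "pairwise_p": pw,
            "median_change_pct": changes,
        }
    return report
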