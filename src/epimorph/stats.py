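"""Spatial group statistics: normalized AP coordinate, cluster position
tests, vertical/horizontal orientation classes and symmetry tests.

The anterior–posterior coordinate is normalized per sample to [−1, 1] with +1
at the arterial-pole (anterior, low-y) end and −1 at the venous-pole end:
y_norm = −2(y − y_mid)/(Y_max − Y_min) with y_mid the midrange.  Cluster
positions are compared with one-sided Mann–Whitney U tests and deviations
from AP symmetry with one-sample Wilcoxon signed-rank tests; both use full
enumeration for small samples and the usual normal approximation with tie
correction otherwise.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .angles import axial_distance
from .errors import StatisticsError

__all__ = [
    "normalize_ap",
    "mann_whitney",
    "cluster_position_test",
    "orientation_class",
    "symmetry_test",
    "boxplot_summary",
]

# full-enumeration thresholds (beyond these the normal approximation is used)
_MW_EXACT_MAX_N = 16
_WILCOXON_EXACT_MAX_N = 20


def normalize_ap(y: np.ndarray) -> np.ndarray:
    """Per-sample normalized AP coordinate in [−1, 1].

    −1 at the venous-pole end (max y) and +1 at the arterial-pole end (min y);
    the midrange maps to 0 so the range is exactly [−1, 1].
    """
    y = np.asarray(y, dtype=float)
    ymin, ymax = y.min(), y.max()
    if ymax <= ymin:
        raise StatisticsError("constant y; AP normalization undefined")
    mid = (ymax + ymin) / 2.0
    return -2.0 * (y - mid) / (ymax - ymin)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann–Whitney U of sample a (ties counted half)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2.0)


def _mw_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided P(U_A ≥ u_obs) by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na = len(a)
    offset = na * (na + 1) / 2.0
    u_obs = ranks[:na].sum() - offset
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), na):
        total += 1
        if ranks[list(idx)].sum() - offset >= u_obs - 1e-9:
            count += 1
    return count / total


def mann_whitney(a, b, alternative: str = "greater"):
    """One-sided Mann–Whitney U test of a against b.

    alternative="greater" tests whether a tends to exceed b.  Full
    enumeration (inclusive p, tie-aware midranks) when n_a + n_b ≤ 16,
    otherwise the normal approximation with tie correction (scipy).
    Returns (U of a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatisticsError("empty group in Mann-Whitney test")
    if alternative not in ("greater", "less"):
        raise StatisticsError("alternative must be 'greater' or 'less'")
    if alternative == "less":
        u_b, p = mann_whitney(b, a, "greater")
        return _u_statistic(a, b), p
    u = _u_statistic(a, b)
    if a.size + b.size <= _MW_EXACT_MAX_N:
        return u, _mw_exact_p(a, b)
    res = sps.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def cluster_position_test(
    y_norm: np.ndarray,
    labels: np.ndarray,
    cluster_a,
    cluster_b,
    side: str = "A>B",
):
    """Is cluster A located more anterior (higher y_norm) than cluster B?

    One-sided Mann–Whitney U on the normalized AP coordinates of the two
    clusters; side "A>B" (default) tests anterior enrichment of A.
    Returns (U, p).
    """
    y_norm = np.asarray(y_norm, dtype=float)
    labels = np.asarray(labels)
    a = y_norm[labels == cluster_a]
    b = y_norm[labels == cluster_b]
    if a.size == 0 or b.size == 0:
        raise StatisticsError("empty cluster in position test")
    if side not in ("A>B", "B>A"):
        raise StatisticsError("side must be 'A>B' or 'B>A'")
    return mann_whitney(a, b, "greater" if side == "A>B" else "less")


def orientation_class(theta, width: float = 10.0):
    """Classify axial angles: 'vertical' within ``width``° of the AP axis,
    'horizontal' within ``width``° of the LR axis, else 'other'."""
    t = np.atleast_1d(np.asarray(theta, dtype=float))
    out = np.full(t.shape, "other", dtype=object)
    out[axial_distance(t, 90.0) <= width] = "vertical"
    out[axial_distance(t, 0.0) <= width] = "horizontal"
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return str(out[0])
    return out


def _wilcoxon_exact_p(d: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact signed-rank p by enumeration of all 2^n sign assignments."""
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    n = len(d)
    # distribution of W+ over all sign patterns
    totals = np.zeros(1)
    for r in ranks:
        totals = np.concatenate([totals, totals + r])
    p_ge = float(np.mean(totals >= w_obs - 1e-9))
    p_le = float(np.mean(totals <= w_obs + 1e-9))
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return w_obs, p


def symmetry_test(values, alternative: str = "two-sided"):
    """One-sample Wilcoxon signed-rank test of the values against 0.

    Used on normalized AP coordinates of cell subsets (vertical cells,
    horizontal cells, anisotropic cells) to test whether their spatial
    distribution deviates from AP symmetry.  Zero values are dropped
    (Wilcoxon's convention).  Exact enumeration for n ≤ 20, otherwise the
    normal approximation with tie correction.  Returns (W+, p).
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0.0]
    if v.size == 0:
        raise StatisticsError("no nonzero values; symmetry test undefined")
    if alternative not in ("two-sided", "greater", "less"):
        raise StatisticsError(f"unknown alternative {alternative!r}")
    if v.size <= _WILCOXON_EXACT_MAX_N:
        return _wilcoxon_exact_p(v, alternative)
    res = sps.wilcoxon(v, alternative=alternative, method="approx",
                       zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def boxplot_summary(values: np.ndarray, by: np.ndarray) -> pd.DataFrame:
    """Median, quartiles and min/max whiskers per group."""
    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(by)})
    rows = []
    for g, grp in df.groupby("group", sort=True):
        v = grp["value"].to_numpy()
        rows.append(
            {
                "group": g,
                "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
                "min": float(v.min()),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(rows)
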