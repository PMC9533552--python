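"""Donor-level aggregation, outlier removal, and nonparametric tests.

The unit of statistical analysis is the *data point*: one donor's mean
over the images contributing to a (region, layer) cell. Group contrasts
(AD vs control) use the two-sided Wilcoxon rank-sum (Mann-Whitney) test;
the within-image colocalization contrast (red percentage inside vs
outside the marker footprint) is paired by construction and uses the
Wilcoxon signed-rank test on donor-level differences.

Small samples get exact p-values by enumeration *conditional on the
observed midranks*, which stays exact in the presence of ties; larger
samples fall back to the tie-corrected normal approximation. Midranks
are doubled to integers so every comparison in the enumeration is exact
integer arithmetic.

Outlier removal uses the modified z-score (Iglewicz-Hoaglin): a value is
excluded when 0.6745·|x − median| / MAD exceeds 3.5, with a
mean-absolute-deviation fallback when the MAD vanishes; the rule is
iterated to convergence so it is idempotent, and it is skipped entirely
below n = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .layers import layer_group as _layer_group

__all__ = [
    "rank_sum_test",
    "signed_rank_test",
    "detect_outliers",
    "aggregate",
    "compare_groups",
    "paired_coloc_test",
    "significance_summary",
    "ComparisonResult",
    "stars",
]

#: combined-n limit for exact rank-sum enumeration (C(20,10) ≈ 1.8e5)
RANK_SUM_EXACT_MAX = 20
#: n limit for exact signed-rank enumeration (2^15 sign patterns)
SIGNED_RANK_EXACT_MAX = 15

MODIFIED_Z_CUTOFF = 3.5
OUTLIER_MIN_N = 3


# ---------------------------------------------------------------------------
# exact nonparametric tests
# ---------------------------------------------------------------------------

def _double_ranks(values: np.ndarray) -> np.ndarray:
    """Midranks scaled by 2 so they are exact integers."""
    r2 = 2.0 * sps.rankdata(values)
    out = np.rint(r2).astype(np.int64)
    assert np.allclose(r2, out)
    return out


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Returns ``(W, p)`` where W is the rank sum of ``x`` in the combined
    sample.  For combined n <= 20 the p-value is exact: every assignment
    of the observed (mid)ranks to the first group is enumerated and
    p = P(|W - E[W]| >= |w - E[W]|).  Ties are handled exactly because
    the enumeration conditions on the observed midranks.  Larger samples
    use the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks2 = _double_ranks(combined)
    w2 = int(ranks2[:n].sum())
    w = w2 / 2.0
    mu2 = n * (n + m + 1)  # 2 * E[W]
    if n + m <= RANK_SUM_EXACT_MAX:
        idx = np.array(list(combinations(range(n + m), n)), dtype=np.intp)
        sums = ranks2[idx].sum(axis=1)
        p = float(np.mean(np.abs(sums - mu2) >= abs(w2 - mu2)))
    else:
        # scipy's U statistic: U = W - n(n+1)/2
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
    return w, min(p, 1.0)


def signed_rank_test(diffs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of paired differences.

    Zero differences are dropped (classic convention); if every
    difference is zero the test is uninformative and p = 1.  Returns
    ``(T, p)`` with T the sum of signed ranks of |d|.  For n <= 15 the
    p-value is exact over all 2^n sign patterns of the observed midranks
    (tie-exact); otherwise the tie-corrected normal approximation is
    used.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    n = d.size
    ranks2 = _double_ranks(np.abs(d))
    t2 = int((np.sign(d).astype(np.int64) * ranks2).sum())
    if n <= SIGNED_RANK_EXACT_MAX:
        signs = np.where(
            (np.arange(2**n)[:, None] >> np.arange(n)) & 1, 1, -1
        ).astype(np.int64)
        tsums = signs @ ranks2
        p = float(np.mean(np.abs(tsums) >= abs(t2)))
    else:
        _, p = sps.wilcoxon(d, alternative="two-sided", correction=True, method="approx")
        p = float(p)
    return t2 / 2.0, min(p, 1.0)


# ---------------------------------------------------------------------------
# outlier removal
# ---------------------------------------------------------------------------

def _modified_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    dev = np.abs(values - med)
    mad = np.median(dev)
    if mad > 0:
        scale = mad / 0.6745
    else:
        meanad = float(np.mean(dev))
        if meanad == 0:
            return np.zeros_like(values)
        scale = meanad / 0.7979  # E|Z| for a standard normal
    return dev / scale


def detect_outliers(values, cutoff: float = MODIFIED_Z_CUTOFF) -> np.ndarray:
    """Boolean keep-mask over ``values`` under the modified z-score rule.

    The criterion is re-applied to the surviving values until it is a
    fixed point, so the rule is idempotent by construction.  With fewer
    than 3 values nothing is ever excluded.
    """
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    while True:
        kept = values[keep]
        if kept.size < OUTLIER_MIN_N:
            break
        z = _modified_z(kept)
        bad = z > cutoff
        if not bad.any():
            break
        keep_idx = np.flatnonzero(keep)
        keep[keep_idx[bad]] = False
    return keep


# ---------------------------------------------------------------------------
# aggregation into data points and group comparison
# ---------------------------------------------------------------------------

def aggregate(
    rows: pd.DataFrame,
    value_cols: str | list[str],
    mode: str = "layer",
) -> pd.DataFrame:
    """Pool image-level rows into donor-level data points.

    One output row per donor x (region, layer) — or (region, layer
    group) in ``layer-group`` mode — holding the arithmetic mean of the
    contributing image values and the number of images.  Rows whose
    value is missing (undefined ratio, excluded layer) simply do not
    contribute.
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    rows = rows.copy()
    if mode == "layer":
        key_col = "layer"
    elif mode == "layer-group":
        key_col = "layer_group"
        if "layer_group" not in rows.columns:
            rows["layer_group"] = rows["layer"].map(_layer_group)
    else:
        raise ValueError(f"unknown grouping mode {mode!r}")
    out = (
        rows.groupby(["donor_id", "group", "region", key_col], sort=True, observed=True)
        .agg(**{c: (c, "mean") for c in value_cols}, n_images=(value_cols[0], "count"))
        .reset_index()
    )
    out = out[out["n_images"] >= 1]
    return out.rename(columns={key_col: "key"})


@dataclass
class ComparisonResult:
    """Outcome of one nonparametric test on one geo-layer."""

    region: str
    key: str  # layer or layer group
    test: str
    statistic: float | None
    p_value: float | None
    computable: bool
    group_stats: dict[str, dict] = field(default_factory=dict)  # group -> mean/sem/n
    excluded: dict[str, list[float]] = field(default_factory=dict)
    note: str = ""

    def row(self) -> dict:
        r = {
            "region": self.region,
            "key": self.key,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "computable": self.computable,
            "note": self.note,
        }
        for g, s in self.group_stats.items():
            tag = g.replace("-", "_")
            r[f"mean_{tag}"] = s.get("mean")
            r[f"sem_{tag}"] = s.get("sem")
            r[f"n_{tag}"] = s.get("n")
            r[f"excluded_{tag}"] = ";".join(f"{v:g}" for v in self.excluded.get(g, []))
        return r


def _summary(vals: np.ndarray) -> dict:
    n = vals.size
    return {
        "mean": float(np.mean(vals)) if n else None,
        "sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else None,
        "n": int(n),
    }


def compare_groups(
    points: pd.DataFrame,
    region: str,
    key: str,
    value_col: str = "percent",
    groups: tuple[str, str] = ("AD", "control"),
    remove_outliers: bool = True,
) -> ComparisonResult:
    """AD-vs-control rank-sum comparison for one geo-layer.

    Outliers are removed per group first; group means, standard errors
    and post-removal n are reported for plotting.  With an empty group
    the result is flagged not-computable.
    """
    sel = points[(points["region"] == region) & (points["key"] == key)]
    samples: dict[str, np.ndarray] = {}
    excluded: dict[str, list[float]] = {}
    stats_by_group: dict[str, dict] = {}
    for g in groups:
        vals = sel.loc[sel["group"] == g, value_col].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if remove_outliers:
            keep = detect_outliers(vals)
            excluded[g] = [float(v) for v in vals[~keep]]
            vals = vals[keep]
        else:
            excluded[g] = []
        samples[g] = vals
        stats_by_group[g] = _summary(vals)
    if any(samples[g].size == 0 for g in groups):
        return ComparisonResult(
            region=region, key=key, test="rank-sum", statistic=None, p_value=None,
            computable=False, group_stats=stats_by_group, excluded=excluded,
            note="empty group after exclusions",
        )
    w, p = rank_sum_test(samples[groups[0]], samples[groups[1]])
    return ComparisonResult(
        region=region, key=key, test="rank-sum", statistic=w, p_value=p,
        computable=True, group_stats=stats_by_group, excluded=excluded,
    )


def paired_coloc_test(
    points: pd.DataFrame,
    region: str,
    key: str,
    group: str,
    alpha: float = 0.05,
    remove_outliers: bool = True,
) -> ComparisonResult:
    """Signed-rank test of p_pos − p_neg within one group and geo-layer.

    ``points`` must carry donor-level ``p_pos`` and ``p_neg`` columns
    (from :func:`aggregate`).  Significant colocalization is declared at
    p < alpha with a positive median difference; fewer than 3 paired
    points make the result not-computable.
    """
    sel = points[
        (points["region"] == region) & (points["key"] == key) & (points["group"] == group)
    ]
    d = (sel["p_pos"] - sel["p_neg"]).to_numpy(dtype=float)
    d = d[~np.isnan(d)]
    excluded: dict[str, list[float]] = {group: []}
    if remove_outliers:
        keep = detect_outliers(d)
        excluded[group] = [float(v) for v in d[~keep]]
        d = d[keep]
    stats_by_group = {group: _summary(d)}
    if d.size < 3:
        return ComparisonResult(
            region=region, key=key, test="signed-rank", statistic=None, p_value=None,
            computable=False, group_stats=stats_by_group, excluded=excluded,
            note="fewer than 3 paired data points",
        )
    t, p = signed_rank_test(d)
    res = ComparisonResult(
        region=region, key=key, test="signed-rank", statistic=t, p_value=p,
        computable=True, group_stats=stats_by_group, excluded=excluded,
    )
    if np.all(d == 0):
        res.note = "all paired differences zero"
    elif p < alpha and np.median(d) > 0:
        res.note = "significant colocalization"
    return res


# ---------------------------------------------------------------------------
# significance summary
# ---------------------------------------------------------------------------

def stars(p: float | None) -> str:
    """Star annotation tiers: * p<0.05, ** p<0.01, *** p<0.001."""
    if p is None or np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def significance_summary(results: list[ComparisonResult], alpha: float = 0.05) -> pd.DataFrame:
    """Plot-ready table: one row per result with star tiers and counts.

    The returned frame carries a ``significant`` flag per geo-layer; the
    attribute ``df.attrs["n_significant"]`` / ``["n_total"]`` give the
    "k out of N geo-layers" headline counts.
    """
    rows = []
    for r in results:
        row = r.row()
        row["stars"] = stars(r.p_value) if r.computable else ""
        row["significant"] = bool(r.computable and r.p_value is not None and r.p_value < alpha)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_total"] = len(results)
    df.attrs["n_significant"] = int(df["significant"].sum()) if len(df) else 0
    return df
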