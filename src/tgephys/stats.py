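"""Group-level statistics: mean ± SEM summaries, one-way ANOVA with post hoc
comparisons, and immunohistochemistry (IHC) marker-percentage composition.

Values are summarized as mean ± SEM (SD/sqrt(n)).  Between-group differences
use classical one-way ANOVA; post hoc pairwise comparisons are Tukey HSD by
default, with a Bonferroni-corrected pooled-variance alternative.  IHC
composition works on per-section counts: percentages per section, averaged
into biological replicates (one replicate = one animal's ganglion), with
marginal marker percentages as sums of the joint classes containing the
marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import IHCCounts


class StatsError(ValueError):
    pass


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    method: Optional[str] = None
    pairwise: dict = field(default_factory=dict)  # (g1, g2) -> adjusted p


def group_summary(
    values: pd.DataFrame,
    labels: Sequence,
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-group n, mean and SEM for each numeric parameter column.

    Single-member groups carry SEM = NaN (a spread cannot be estimated).
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=values.index, name="group")
    known = set(labels.dropna().unique())
    if columns is None:
        columns = [c for c in values.columns if pd.api.types.is_numeric_dtype(values[c])]
    df = values[list(columns)].copy()
    df["group"] = labels
    rows = []
    for g, sub in df.groupby("group", sort=True):
        for c in columns:
            x = sub[c].dropna()
            n = len(x)
            rows.append(
                dict(
                    group=g,
                    parameter=c,
                    n=n,
                    mean=float(x.mean()) if n else np.nan,
                    sem=float(x.sem(ddof=1)) if n >= 2 else np.nan,
                )
            )
    return pd.DataFrame(rows)


def _groups_from(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape[0] != labels.shape[0]:
        raise StatsError("values and labels must align")
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    out = {}
    for g in pd.unique(labels):
        out[g] = values[labels == g]
    return out


def anova_posthoc(
    values: Sequence[float],
    labels: Sequence,
    method: Optional[str] = "tukey",
) -> AnovaResult:
    """Classical one-way ANOVA with optional post hoc pairwise comparisons.

    ``method`` is "tukey" (default), "bonferroni" (pooled-variance pairwise
    t tests with p multiplied by the number of pairs), or None (omnibus
    only).  Identical values in every group give F = 0, p = 1 rather than
    an error.
    """
    groups = _groups_from(values, labels)
    arrays = [v for v in groups.values() if v.size >= 2]
    if len(arrays) < 2:
        raise StatsError("ANOVA needs >= 2 groups with >= 2 members")
    names = [g for g, v in groups.items() if v.size >= 2]
    k = len(arrays)
    n_tot = sum(v.size for v in arrays)
    dfb, dfw = k - 1, n_tot - k
    grand = np.concatenate(arrays)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in arrays)
    ssb = sum(v.size * (v.mean() - grand.mean()) ** 2 for v in arrays)
    if ssb <= 1e-12 * max(1.0, grand.var() * n_tot, abs(grand.mean())):
        if ssw <= 0:
            result = AnovaResult(0.0, dfb, dfw, 1.0, method)
            if method is not None:
                result.pairwise = {
                    pair: 1.0 for pair in combinations(names, 2)
                }
            return result
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrays)
    if not np.isfinite(f):  # zero within-group variance but distinct means
        f, p = np.inf, 0.0
    result = AnovaResult(float(f), dfb, dfw, float(p), method)
    if method is None:
        return result
    if method == "tukey":
        res = sps.tukey_hsd(*arrays)
        for (i, a), (j, b) in combinations(enumerate(names), 2):
            result.pairwise[(a, b)] = float(res.pvalue[i, j])
    elif method == "bonferroni":
        msw = ssw / dfw if dfw > 0 else 0.0
        n_pairs = k * (k - 1) // 2
        for (i, a), (j, b) in combinations(enumerate(names), 2):
            va, vb = arrays[i], arrays[j]
            se = np.sqrt(msw * (1 / va.size + 1 / vb.size))
            if se == 0:
                p_raw = 1.0 if va.mean() == vb.mean() else 0.0
            else:
                t = (va.mean() - vb.mean()) / se
                p_raw = 2 * sps.t.sf(abs(t), dfw)
            result.pairwise[(a, b)] = float(min(1.0, p_raw * n_pairs))
    else:
        raise StatsError(f"unknown post hoc method {method!r}")
    return result


# ---------------------------------------------------------------------------
# IHC composition


def marker_marginals(joint_percent: dict) -> dict:
    """Marginal CGRP and trpV1 percentages from joint-class percentages.

    CGRP marginal = CGRP+/trpV1- plus CGRP+/trpV1+; trpV1 marginal =
    CGRP+/trpV1+ plus CGRP-/trpV1+.  Pure arithmetic, exact.
    """
    return {
        "CGRP": joint_percent["cgrp_only"] + joint_percent["cgrp_trpv1"],
        "trpV1": joint_percent["cgrp_trpv1"] + joint_percent["trpv1_only"],
    }


def ihc_marginals(counts: IHCCounts) -> pd.DataFrame:
    """Mean ± SEM percentages per joint class and marker marginal.

    Per-section percentages are averaged within each biological replicate;
    the mean and SEM are taken across replicates.  Zero-total sections are
    excluded with a warning.
    """
    df = counts.table.copy()
    zero = df["total"] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-total section(s)")
        df = df[~zero]
    if df.empty:
        raise StatsError("no usable sections")
    classes = list(counts.class_names)
    pct = df[classes].div(df["total"], axis=0) * 100.0
    pct["replicate_id"] = df["replicate_id"].values
    rep = pct.groupby("replicate_id").mean()
    rep_marg = pd.DataFrame(
        {
            "CGRP": rep["cgrp_only"] + rep["cgrp_trpv1"]
            if "cgrp_only" in rep
            else np.nan,
            "trpV1": rep["cgrp_trpv1"] + rep["trpv1_only"]
            if "trpv1_only" in rep
            else np.nan,
        }
    )
    table = pd.concat([rep, rep_marg], axis=1)
    out = pd.DataFrame(
        {
            "mean_percent": table.mean(),
            "sem_percent": table.sem(ddof=1) if len(table) >= 2 else np.nan,
            "n_replicates": len(table),
        }
    )
    out.index.name = "marker_class"
    return out.reset_index()
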