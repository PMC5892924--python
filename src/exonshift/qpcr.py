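"""ΔΔCt relative quantification with outlier screening and group comparison.

Workflow for isoform-specific qPCR assays (e.g. tau 0N/1N/2N/4R panels):
technical replicates are averaged to one Ct per (sample, target); each
target is normalized to a reference gene (ΔCt = Ct_target − Ct_reference);
relative expression is then expressed against a calibrator target
(ΔΔCt = ΔCt_target − ΔCt_calibrator, relative level 2^−ΔΔCt — classic
100%-efficiency assumption). Outliers within (group × target) strata are
screened with a two-sided single-pass Grubbs test and groups are compared
with a Mann-Whitney U test (exact for small samples).

Runs are capped at ``CT_CEILING`` cycles; a Ct at the ceiling is a
non-detect and propagates a ``censored`` flag rather than a number
pretending to be a measurement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DomainError,
    InsufficientDataError,
    ValidationError,
)

log = logging.getLogger(__name__)

CT_CEILING = 40.0
DEFAULT_REFERENCE = "GAPDH"
DEFAULT_CALIBRATOR = "total_tau"


def validate_qpcr_table(table: pd.DataFrame, reference: str = DEFAULT_REFERENCE) -> pd.DataFrame:
    """Validate a long-format Ct table; adds a ``non_detect`` flag column."""
    required = {"sample_id", "group", "target", "ct"}
    if not required.issubset(table.columns):
        raise ValidationError(f"qPCR table must have columns {sorted(required)}")
    t = table.copy()
    ct = t["ct"].astype(float)
    if ((ct <= 0) | (ct > CT_CEILING)).any():
        bad = t.loc[(ct <= 0) | (ct > CT_CEILING)]
        raise ValidationError(
            f"Ct values outside (0, {CT_CEILING}]: samples {list(bad['sample_id'])[:5]}"
        )
    t["non_detect"] = ct >= CT_CEILING
    if t["non_detect"].any():
        log.warning("%d Ct values at the %g-cycle ceiling flagged as non-detects",
                    int(t["non_detect"].sum()), CT_CEILING)
    have_ref = set(t.loc[t["target"] == reference, "sample_id"])
    missing = set(t["sample_id"]) - have_ref
    if missing:
        log.warning("samples without reference (%s) Ct: %s", reference, sorted(missing)[:5])
    return t


def delta_delta_ct(
    table: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE,
    calibrator: str = DEFAULT_CALIBRATOR,
    per_group_calibrator: bool = False,
) -> pd.DataFrame:
    """Relative expression by the ΔΔCt method.

    Replicates are averaged (arithmetic mean of Ct) before any subtraction.
    By default the calibrator ΔCt is the *same sample's* calibrator-target
    ΔCt, so the calibrator's own relative level is exactly 1 everywhere;
    ``per_group_calibrator`` instead subtracts the group-mean calibrator
    ΔCt. Samples lacking a reference Ct are excluded with a warning;
    any non-detect involved marks the result ``censored``.
    """
    t = validate_qpcr_table(table, reference)
    mean_ct = (
        t.groupby(["sample_id", "group", "target"], sort=True)
        .agg(ct=("ct", "mean"), non_detect=("non_detect", "any"))
        .reset_index()
    )
    wide_ct = mean_ct.pivot(index="sample_id", columns="target", values="ct")
    wide_nd = mean_ct.pivot(index="sample_id", columns="target", values="non_detect")
    groups = mean_ct.drop_duplicates("sample_id").set_index("sample_id")["group"]
    for tgt in (reference, calibrator):
        if tgt not in wide_ct.columns:
            raise ValidationError(f"target {tgt!r} absent from the table")

    usable = wide_ct[reference].notna()
    if (~usable).any():
        log.warning("excluding samples without reference Ct: %s",
                    list(wide_ct.index[~usable])[:5])
    wide_ct = wide_ct[usable]
    wide_nd = wide_nd[usable]

    delta = wide_ct.sub(wide_ct[reference], axis=0)
    if per_group_calibrator:
        cal = delta[calibrator].groupby(groups.loc[delta.index]).transform("mean")
    else:
        cal = delta[calibrator]
    ddct = delta.sub(cal, axis=0)

    rows = []
    for sample in delta.index:
        for target in wide_ct.columns:
            if target == reference:
                continue
            dct = delta.at[sample, target]
            dd = ddct.at[sample, target]
            censored = bool(
                wide_nd.at[sample, target]
                or wide_nd.at[sample, reference]
                or wide_nd.at[sample, calibrator]
            )
            rows.append(
                {
                    "sample_id": sample,
                    "group": groups.at[sample],
                    "target": target,
                    "delta_ct": float(dct) if np.isfinite(dct) else float("nan"),
                    "delta_delta_ct": float(dd) if np.isfinite(dd) else float("nan"),
                    "rel_to_calibrator": float(2.0 ** -dd) if np.isfinite(dd) else float("nan"),
                    "censored": censored,
                }
            )
    return pd.DataFrame(rows)


def grubbs_test(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[Optional[int], float, float]:
    """Two-sided single-pass Grubbs outlier test.

    Returns ``(outlier_index or None, G, G_crit)`` with
    G = max|x_i − mean| / sd and the critical value from the t distribution:
    G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) quantile on
    n−2 df. Ties in |deviation| resolve to the first maximal index.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise InsufficientDataError(f"Grubbs test needs n >= 3, got {x.size}")
    if not np.isfinite(x).all():
        raise DomainError("Grubbs test requires finite values")
    sd = x.std(ddof=1)
    n = x.size
    t_q = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    g_crit = ((n - 1) / math.sqrt(n)) * math.sqrt(t_q**2 / (n - 2 + t_q**2))
    if sd == 0:
        log.warning("zero standard deviation; no outlier detectable")
        return None, 0.0, g_crit
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    return (idx if g > g_crit else None), g, g_crit


def remove_outliers(
    table: pd.DataFrame, value_col: str, by: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Drop at most one Grubbs outlier per stratum (single pass, two-sided)."""
    kept = []
    for _, sub in table.groupby(list(by), sort=False):
        vals = sub[value_col].to_numpy(float)
        if len(vals) >= 3 and np.nanstd(vals) > 0:
            idx, _, _ = grubbs_test(vals[np.isfinite(vals)], alpha)
            if idx is not None:
                finite_pos = np.flatnonzero(np.isfinite(vals))
                drop_label = sub.index[finite_pos[idx]]
                log.info("Grubbs outlier removed: %s", dict(sub.loc[drop_label]))
                sub = sub.drop(index=drop_label)
        kept.append(sub)
    return pd.concat(kept).sort_index()


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p; exact for small untied samples.

    The exact null distribution of U is used when n_a + n_b <= 20 and there
    are no ties; otherwise the normal approximation with continuity and tie
    correction. The reported U is the larger of the two one-sided U
    statistics (max convention; the p-value does not depend on it). With
    every value tied across both groups, p = 1 by convention.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return a.size * b.size / 2.0, 1.0
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size + b.size <= 20
    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        u_a, p = float(res.statistic), float(res.pvalue)
    elif small and math.comb(a.size + b.size, a.size) <= 20_000:
        # exact by enumeration; permits ties, which scipy's exact path rejects
        gt = (a[:, None] > b[None, :]).sum()
        eq = (a[:, None] == b[None, :]).sum()
        u_a = float(gt + 0.5 * eq)
        p = mann_whitney_exact_p(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u_a, p = float(res.statistic), float(res.pvalue)
    u_b = a.size * b.size - u_a
    return max(u_a, u_b), float(p)


def mann_whitney_exact_p(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Exact two-sided p by complete enumeration of group assignments.

    Brute-force reference: enumerates all C(n_a+n_b, n_a) splits of the
    pooled values and counts splits whose U is at least as extreme (in
    two-sided min-U terms) as observed. Intended for small n in tests and
    cross-checks; cost grows combinatorially.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    pooled = np.concatenate([a, b])
    n_a = a.size

    def u_min(idx_a: tuple[int, ...]) -> float:
        mask = np.zeros(pooled.size, bool)
        mask[list(idx_a)] = True
        xa, xb = pooled[mask], pooled[~mask]
        gt = (xa[:, None] > xb[None, :]).sum()
        eq = (xa[:, None] == xb[None, :]).sum()
        ua = gt + 0.5 * eq
        return min(ua, xa.size * xb.size - ua)

    observed = u_min(tuple(range(n_a)))
    total = 0
    extreme = 0
    for combo in combinations(range(pooled.size), n_a):
        total += 1
        if u_min(combo) <= observed + 1e-12:
            extreme += 1
    return extreme / total


def group_comparison(
    relative: pd.DataFrame,
    group_a: str,
    group_b: str,
    value_col: str = "rel_to_calibrator",
    grubbs_alpha: Optional[float] = 0.05,
) -> pd.DataFrame:
    """Per-target group comparison of relative expression (U, p).

    Censored measurements are excluded; optional Grubbs screening runs
    within (group × target) strata before the test.
    """
    data = relative[~relative["censored"]].copy()
    if grubbs_alpha is not None:
        data = remove_outliers(data, value_col, ["group", "target"], grubbs_alpha)
    rows = []
    for target, sub in data.groupby("target", sort=True):
        va = sub.loc[sub["group"] == group_a, value_col].dropna().to_numpy()
        vb = sub.loc[sub["group"] == group_b, value_col].dropna().to_numpy()
        if va.size == 0 or vb.size == 0:
            log.warning("target %s: a group is empty after filtering; skipped", target)
            continue
        u, p = mann_whitney(va, vb)
        rows.append(
            {
                "target": target,
                f"n_{group_a}": int(va.size),
                f"n_{group_b}": int(vb.size),
                f"mean_{group_a}": float(va.mean()),
                f"mean_{group_b}": float(vb.mean()),
                "U": u,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
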