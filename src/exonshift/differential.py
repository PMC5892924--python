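"""Pre-/post-natal differential analysis and cross-dataset replication.

For each gene in a user-supplied gene set the table carries one gene-level
record (all-probe gene mean) and one record per named exon (splicing index
by default, raw exon expression optionally). Records are compared between
prenatal and postnatal samples with a two-sample t-test, fold changes are
postnatal/prenatal means, and p-values are Bonferroni-corrected over all
records in the run — the volcano-plot screen. Replication across datasets
requires, in *every* dataset, adjusted significance together with at least
a 1.5-fold increase or decrease.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    GENE_LEVEL,
    FeatureExpression,
    SampleRecord,
    SplicingIndexMatrix,
    sample_frame,
)
from .errors import DomainError, InsufficientDataError, ValidationError

log = logging.getLogger(__name__)

TTestVariant = Literal["welch", "pooled"]
ExonStatistic = Literal["splicing_index", "exon_expression"]

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05


def two_group_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: TTestVariant = "welch",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    ``welch`` (unequal variances, Welch–Satterthwaite df) is the default,
    matching R's ``t.test``; ``pooled`` gives the classical equal-variance
    test with df = n_a + n_b - 2.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"each group needs >= 2 values, got {a.size} and {b.size}"
        )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = a.size + b.size - 2.0
        if a.mean() == b.mean():
            log.warning("both groups constant and equal; p = 1 by convention")
            return 0.0, df, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def fold_change(mean_pre: float, mean_post: float) -> tuple[float, float]:
    """Postnatal/prenatal ratio and its log2. Requires a positive prenatal mean."""
    if not np.isfinite(mean_pre) or mean_pre <= 0:
        raise DomainError(f"fold change undefined for prenatal mean {mean_pre!r}")
    fc = float(mean_post) / float(mean_pre)
    return fc, (math.log2(fc) if fc > 0 else float("nan"))


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Multiply each p by the family size, capping at 1."""
    p = np.asarray(p_values, float)
    finite = p[np.isfinite(p)]
    if ((finite < 0) | (finite > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


@dataclass
class DifferentialOptions:
    exon_statistic: ExonStatistic = "splicing_index"
    t_variant: TTestVariant = "welch"


def differential_table(
    si: SplicingIndexMatrix,
    features: FeatureExpression,
    samples: "Sequence[SampleRecord] | pd.DataFrame",
    gene_set: Sequence[str],
    exon_statistic: ExonStatistic = "splicing_index",
    t_variant: TTestVariant = "welch",
) -> pd.DataFrame:
    """Prenatal-vs-postnatal differential table for a gene set.

    Returns one row per gene (gene-level expression) and per named exon
    (configured exon statistic), with Bonferroni correction over all rows
    of the run. Rows where the prenatal mean is non-positive keep a missing
    fold change but still carry the test result.
    """
    if not gene_set:
        raise ValidationError("gene_set must be non-empty")
    meta = sample_frame(samples)
    shared = [s for s in features.sample_ids if s in meta.index]
    if len(shared) < len(features.sample_ids):
        log.warning("%d samples lack metadata and are dropped",
                    len(features.sample_ids) - len(shared))
    meta = meta.loc[shared]
    pre_ids = meta.index[~meta["postnatal"].astype(bool)]
    post_ids = meta.index[meta["postnatal"].astype(bool)]
    if len(pre_ids) < 2 or len(post_ids) < 2:
        raise InsufficientDataError(
            f"need >= 2 prenatal and >= 2 postnatal samples, got "
            f"{len(pre_ids)} prenatal / {len(post_ids)} postnatal"
        )

    rows: list[dict] = []
    known_genes = {g for g, _ in features.feature_keys}
    for gene in gene_set:
        if gene not in known_genes:
            log.warning("gene %s absent from feature table; skipped", gene)
            continue
        rows.append(
            _one_record(gene, GENE_LEVEL, "gene",
                        features.gene_expression(gene), pre_ids, post_ids, t_variant)
        )
        for g, exon in si.exon_keys:
            if g != gene:
                continue
            if exon_statistic == "splicing_index":
                series = si.series(gene, exon)
            else:
                series = features.exon_expression(gene, exon)
            rows.append(
                _one_record(gene, exon, "exon", series, pre_ids, post_ids, t_variant)
            )
    if not rows:
        raise ValidationError("no gene of the gene set found in the data")
    table = pd.DataFrame(rows)
    table["p_adj"] = bonferroni_adjust(table["p_value"].to_numpy())
    table.attrs["t_variant"] = t_variant
    table.attrs["exon_statistic"] = exon_statistic
    table.attrs["m_tests"] = len(table)
    return table


def _one_record(
    gene: str,
    feature: str,
    level: str,
    series: pd.Series,
    pre_ids: pd.Index,
    post_ids: pd.Index,
    t_variant: TTestVariant,
) -> dict:
    pre = series.loc[series.index.intersection(pre_ids)].dropna()
    post = series.loc[series.index.intersection(post_ids)].dropna()
    if len(pre) < 2 or len(post) < 2:
        raise InsufficientDataError(
            f"{gene}/{feature}: a group is empty or too small after filtering "
            f"({len(pre)} prenatal / {len(post)} postnatal)"
        )
    t, df, p = two_group_t_test(pre, post, t_variant)
    mean_pre, mean_post = float(pre.mean()), float(post.mean())
    try:
        fc, lfc = fold_change(mean_pre, mean_post)
    except DomainError:
        log.warning("%s/%s: non-positive prenatal mean; fold change undefined",
                    gene, feature)
        fc, lfc = float("nan"), float("nan")
    return {
        "gene": gene,
        "feature": feature,
        "level": level,
        "mean_pre": mean_pre,
        "mean_post": mean_post,
        "fold_change": fc,
        "log2_fc": lfc,
        "t_stat": t,
        "df": df,
        "p_value": p,
        "n_pre": int(len(pre)),
        "n_post": int(len(post)),
    }


def passes_screen(
    fold_change: float,
    p_adj: float,
    threshold_fc: float = DEFAULT_FC_THRESHOLD,
    threshold_alpha: float = DEFAULT_ALPHA,
) -> bool:
    """Volcano screen: adjusted significance AND >= threshold-fold change either way."""
    if not (np.isfinite(fold_change) and np.isfinite(p_adj)):
        return False
    return bool(
        p_adj < threshold_alpha
        and (fold_change >= threshold_fc or fold_change <= 1.0 / threshold_fc)
    )


def replicate_across_datasets(
    tables: Mapping[str, pd.DataFrame],
    threshold_fc: float = DEFAULT_FC_THRESHOLD,
    threshold_alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Conjunction replication rule over per-dataset differential tables.

    A feature *passes* iff in every dataset it is Bonferroni-significant and
    changes at least ``threshold_fc``-fold up or down. Features absent from
    some dataset are reported with ``testable = False`` and never pass.
    """
    if len(tables) < 2:
        raise ValidationError("replication needs >= 2 datasets")
    keyed = {
        name: t.set_index(["gene", "feature"]) for name, t in tables.items()
    }
    all_keys: set[tuple[str, str]] = set()
    for t in keyed.values():
        all_keys |= set(t.index)
    shared = set.intersection(*(set(t.index) for t in keyed.values()))
    if not shared:
        log.warning("no feature shared across all datasets")

    rows = []
    for key in sorted(all_keys):
        gene, feature = key
        row: dict = {"gene": gene, "feature": feature}
        testable = key in shared
        ok = testable
        for name, t in keyed.items():
            if key in t.index:
                fc = float(t.at[key, "fold_change"])
                padj = float(t.at[key, "p_adj"])
                row[f"fc_{name}"] = fc
                row[f"p_adj_{name}"] = padj
                ok = ok and passes_screen(fc, padj, threshold_fc, threshold_alpha)
            else:
                row[f"fc_{name}"] = float("nan")
                row[f"p_adj_{name}"] = float("nan")
        row["testable"] = testable
        row["passes"] = bool(ok)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["threshold_fc"] = threshold_fc
    out.attrs["threshold_alpha"] = threshold_alpha
    return out


def volcano_data(table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready volcano columns (log2 FC, -log10 adjusted p, level flag)."""
    out = table[["gene", "feature", "level", "log2_fc"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p_adj"] = -np.log10(table["p_adj"].to_numpy(float))
    return out
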