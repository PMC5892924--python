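"""Normalization, probe aggregation and the splicing index.

The splicing index of an exon in a sample is the mean expression of the
probes inside that exon divided by the mean expression of all probes of the
gene. It is a dimensionless proxy for exon inclusion: when an alternative
exon is skipped its probes lose signal relative to the gene body, pulling
the index down. Because the gene mean includes the alternative-exon probes
themselves, the index is a *diluted* inclusion proportion rather than a
percent-spliced-in value; the ``gene_mean="constitutive_only"`` mode removes
that dilution at the cost of deviating from the all-probe gene mean.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd

from .containers import (
    GENE_BODY,
    GENE_LEVEL,
    ExpressionMatrix,
    FeatureExpression,
    ProbeAnnotation,
    SplicingIndexMatrix,
)
from .errors import DegenerateInputError, ValidationError

log = logging.getLogger(__name__)

#: Gene-expression floor below which a splicing index is reported missing.
DENOMINATOR_FLOOR = 1e-8

GeneMeanMode = Literal["inclusive", "constitutive_only"]


def unity_normalize(
    matrix: ExpressionMatrix, per_probe: bool = False
) -> ExpressionMatrix:
    """Affinely rescale expression to [0, 1], eliminating negative values.

    By default the rescaling uses the global minimum and maximum of the
    entire dataset, so relative order is preserved everywhere; ``per_probe``
    rescales each probe row independently (sensitivity-analysis mode).
    """
    values = matrix.values
    if per_probe:
        lo = values.min(axis=1)
        hi = values.max(axis=1)
        span = hi - lo
        if (span.fillna(0) == 0).any():
            raise DegenerateInputError("per-probe normalization hit a constant probe")
        out = values.sub(lo, axis=0).div(span, axis=0)
        return ExpressionMatrix(out)
    finite = values.values[np.isfinite(values.values)]
    if finite.size < 2:
        raise DegenerateInputError("need at least two finite values to normalize")
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        raise DegenerateInputError("constant matrix: unity normalization undefined")
    return ExpressionMatrix((values - lo) / (hi - lo))


def aggregate_features(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    gene_mean: GeneMeanMode = "inclusive",
) -> FeatureExpression:
    """Average probes into exon- and gene-level features.

    For every gene a ``(gene, "gene")`` row holds the mean over *all* of the
    gene's probes (named-exon and gene-body alike, unless
    ``gene_mean="constitutive_only"``); each named exon gets a
    ``(gene, exon)`` row averaging its own probes. Means skip missing
    cells; a feature is missing for a sample only when every contributing
    probe is missing there. Probes absent from the annotation are dropped
    with a logged count.
    """
    values = matrix.values
    annotated = values.index.intersection(annotation.table.index)
    n_dropped = len(values.index) - len(annotated)
    if n_dropped:
        log.warning("dropping %d probes without annotation", n_dropped)
    if len(annotated) == 0:
        raise ValidationError("no probe in the matrix is annotated")
    values = values.loc[annotated]
    ann = annotation.table.loc[annotated]

    rows: list[pd.Series] = []
    keys: list[tuple[str, str]] = []
    n_probes: list[int] = []

    for gene, gene_ann in ann.groupby("gene", sort=True):
        if gene_mean == "constitutive_only":
            gene_probes = gene_ann.index[gene_ann["feature"] == GENE_BODY]
        else:
            gene_probes = gene_ann.index
        if len(gene_probes) == 0:
            log.warning("gene %s has no probes for the gene mean; omitted", gene)
        else:
            rows.append(values.loc[gene_probes].mean(axis=0, skipna=True))
            keys.append((gene, GENE_LEVEL))
            n_probes.append(len(gene_probes))
        for exon, exon_ann in gene_ann[gene_ann["feature"] != GENE_BODY].groupby(
            "feature", sort=True
        ):
            rows.append(values.loc[exon_ann.index].mean(axis=0, skipna=True))
            keys.append((gene, exon))
            n_probes.append(len(exon_ann))

    index = pd.MultiIndex.from_tuples(keys, names=["gene", "feature"])
    out = pd.DataFrame(rows, index=index, columns=values.columns)
    return FeatureExpression(out, pd.Series(n_probes, index=index, name="n_probes"))


def compute_splicing_index(
    features: FeatureExpression, floor: float = DENOMINATOR_FLOOR
) -> SplicingIndexMatrix:
    """Divide each exon's mean expression by its gene's mean expression.

    Indices are reported missing wherever the gene-level denominator is
    missing or does not exceed ``floor`` (never infinite); the count of
    floored cells is logged.
    """
    vals = features.values
    exon_keys = [(g, f) for g, f in vals.index if f != GENE_LEVEL]
    genes_with_level = {g for g, f in vals.index if f == GENE_LEVEL}
    orphans = sorted({g for g, _ in exon_keys} - genes_with_level)
    if orphans:
        raise ValidationError(f"exons without a parent gene mean: {orphans[:5]}")
    if not exon_keys:
        raise ValidationError("no named-exon features present")

    gene_of = pd.Index([g for g, _ in exon_keys])
    exon_vals = vals.loc[exon_keys]
    denom = vals.loc[[(g, GENE_LEVEL) for g in gene_of]].to_numpy(float)
    denom_ok = np.isfinite(denom) & (denom > floor)
    n_floored = int((np.isfinite(denom) & ~denom_ok).sum())
    if n_floored:
        log.warning("%d splicing-index cells floored (gene expression <= %g)",
                    n_floored, floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom_ok, exon_vals.to_numpy(float) / denom, np.nan)
    index = pd.MultiIndex.from_tuples(exon_keys, names=["gene", "exon"])
    return SplicingIndexMatrix(pd.DataFrame(out, index=index, columns=vals.columns))


def maybe_unity_normalize(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, bool]:
    """Apply unity normalization only when the matrix contains negative values.

    Upstream providers deliver data on heterogeneous scales; rescaling to
    [0, 1] is needed only to eliminate negative values (log-ratio style
    data) before ratios are taken.
    """
    finite = matrix.values.values[np.isfinite(matrix.values.values)]
    if finite.size and finite.min() < 0:
        return unity_normalize(matrix), True
    return matrix, False
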