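"""In-memory containers for the pipeline.

Matrices are thin wrappers around :class:`pandas.DataFrame` that enforce the
structural invariants (unique identifiers, aligned axes) once at
construction; all numerics downstream operate on the wrapped frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ages import BIRTH_PCD, is_postnatal
from .errors import ValidationError

#: Sentinel feature label for probes in constitutive exons / the gene body.
GENE_BODY = "gene_body"

#: Feature label under which the aggregated gene-level mean is stored.
GENE_LEVEL = "gene"


def _check_unique(values: Iterable[str], what: str) -> list[str]:
    values = [str(v) for v in values]
    seen: set[str] = set()
    dupes: set[str] = set()
    for v in values:
        if v in seen:
            dupes.add(v)
        seen.add(v)
    if dupes:
        raise ValidationError(f"duplicate {what}: {sorted(dupes)[:5]}")
    return values


@dataclass
class ExpressionMatrix:
    """Probe x sample expression values; NaN marks missing cells."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "probe identifiers")
        _check_unique(self.values.columns, "sample identifiers")
        self.values = self.values.astype(float)
        self.values.index.name = "probe_id"
        self.values.columns.name = None

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def drop_empty(self) -> "ExpressionMatrix":
        """Return a copy without all-missing rows/columns (read-time contract)."""
        v = self.values.dropna(axis=0, how="all").dropna(axis=1, how="all")
        return ExpressionMatrix(v)


@dataclass
class ProbeAnnotation:
    """Mapping probe -> (gene, feature).

    ``feature`` is either a named exon (``"exon2"``, ``"exon10"``, ...) or
    the sentinel :data:`GENE_BODY` for constitutive / gene-level probes.
    """

    table: pd.DataFrame  # index probe_id; columns gene, feature

    def __post_init__(self) -> None:
        t = self.table
        if not {"gene", "feature"}.issubset(t.columns):
            raise ValidationError("probe annotation needs columns gene, feature")
        _check_unique(t.index, "annotated probe identifiers")
        if t["gene"].isna().any() or t["feature"].isna().any():
            raise ValidationError("probe annotation contains missing gene/feature")
        self.table = t[["gene", "feature"]].astype(str)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    def exons_of(self, gene: str) -> list[str]:
        sub = self.table[self.table["gene"] == gene]
        return sorted(f for f in sub["feature"].unique() if f != GENE_BODY)


@dataclass
class SampleRecord:
    """Per-sample covariates on the canonical age axis."""

    sample_id: str
    donor_id: str
    age_pcd: float
    sex: str
    postnatal: Optional[bool] = None
    rin: Optional[float] = None
    race: Optional[str] = None
    region: Optional[str] = None
    dataset: str = "user-defined"

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_pcd) or self.age_pcd <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: age_pcd must be positive, got {self.age_pcd}"
            )
        if self.postnatal is None:
            self.postnatal = is_postnatal(self.age_pcd)

    @classmethod
    def with_birth_threshold(cls, birth_pcd: float = BIRTH_PCD, **kw) -> "SampleRecord":
        rec = cls(postnatal=is_postnatal(kw["age_pcd"], birth_pcd), **kw)
        return rec


def sample_frame(samples: "Sequence[SampleRecord] | pd.DataFrame") -> pd.DataFrame:
    """Normalize a sample collection to a DataFrame indexed by sample_id."""
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                df.index.name = "sample_id"
        return df
    rows = []
    for rec in samples:
        rows.append(
            {
                "sample_id": rec.sample_id,
                "donor_id": rec.donor_id,
                "age_pcd": rec.age_pcd,
                "postnatal": rec.postnatal,
                "sex": rec.sex,
                "rin": rec.rin,
                "race": rec.race,
                "region": rec.region,
                "dataset": rec.dataset,
            }
        )
    df = pd.DataFrame(rows)
    _check_unique(df["sample_id"], "sample identifiers in metadata")
    return df.set_index("sample_id")


@dataclass
class FeatureExpression:
    """Feature x sample means after probe aggregation.

    Rows are a MultiIndex ``(gene, feature)`` where ``feature`` is a named
    exon or :data:`GENE_LEVEL` for the all-probe gene mean. ``n_probes``
    counts the probes contributing to each row.
    """

    values: pd.DataFrame
    n_probes: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.values.index, pd.MultiIndex):
            raise ValidationError("FeatureExpression rows must be (gene, feature) pairs")
        if (self.n_probes < 1).any():
            raise ValidationError("every retained feature needs >= 1 probe")
        self.n_probes = self.n_probes.reindex(self.values.index)

    @property
    def feature_keys(self) -> list[tuple[str, str]]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def gene_expression(self, gene: str) -> pd.Series:
        return self.values.loc[(gene, GENE_LEVEL)]

    def exon_expression(self, gene: str, exon: str) -> pd.Series:
        return self.values.loc[(gene, exon)]


@dataclass
class SplicingIndexMatrix:
    """Exon x sample splicing indices (exon mean / gene mean, dimensionless)."""

    values: pd.DataFrame  # MultiIndex (gene, exon) x samples

    def __post_init__(self) -> None:
        if not isinstance(self.values.index, pd.MultiIndex):
            raise ValidationError("SplicingIndexMatrix rows must be (gene, exon) pairs")

    @property
    def exon_keys(self) -> list[tuple[str, str]]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def series(self, gene: str, exon: str) -> pd.Series:
        return self.values.loc[(gene, exon)]
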