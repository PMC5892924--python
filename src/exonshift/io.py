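"""Readers and writers for the tabular interchange formats.

Formats
-------
Expression TSV
    UTF-8, tab-separated; first column header ``probe_id``, one column per
    sample; missing cells written as ``NA``.
Sample metadata CSV
    RFC-4180; columns ``sample_id, donor_id, age, age_unit, sex`` and
    optionally ``rin, race, region, dataset``. ``age`` may carry an inline
    unit (``"20 pcw"``) when ``age_unit`` is absent or empty.
Probe annotation TSV
    Columns ``probe_id, gene, feature``.
qPCR Ct CSV
    Columns ``sample_id, group, target, ct, replicate``.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ages import BIRTH_PCD, convert_age, parse_age
from .containers import (
    ExpressionMatrix,
    ProbeAnnotation,
    SampleRecord,
    SplicingIndexMatrix,
)
from .errors import ParseError, ValidationError
from .regions import RegionVocabulary, default_vocabulary

log = logging.getLogger(__name__)

MISSING_TOKEN = "NA"


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a probe x sample expression TSV.

    Duplicate probe/sample identifiers and non-numeric cells are rejected
    with errors naming the offending coordinates; ``NA`` cells become NaN
    and are logged.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "probe_id":
        raise ParseError(
            f"{path}: line 1: expression TSV must start with a 'probe_id' header, "
            f"got {header[0]!r}"
        )
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample identifiers in header")

    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValidationError(f"{path}: duplicate probe identifiers: {dupes[:5]}")

    values = raw.replace({MISSING_TOKEN: None, "": None}).apply(
        pd.to_numeric, errors="coerce"
    )
    # coerce turns unparseable text into NaN; distinguish them from real NAs
    bad = values.isna() & raw.notna() & ~raw.isin([MISSING_TOKEN, ""])
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ParseError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at "
            f"(probe {raw.index[r]!r}, sample {raw.columns[c]!r})"
        )
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        log.warning("%s: %d missing expression cells", path, n_missing)

    matrix = ExpressionMatrix(values)
    dropped = matrix.drop_empty()
    if dropped.shape != matrix.shape:
        log.warning(
            "%s: dropped %d all-missing rows and %d all-missing columns",
            path,
            matrix.shape[0] - dropped.shape[0],
            matrix.shape[1] - dropped.shape[1],
        )
    return dropped


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix in the TSV dialect read_expression_matrix accepts."""
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, lineterminator="\n")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe annotation TSV (probe_id, gene, feature)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene", "feature"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: probe annotation must have columns {sorted(required)}"
        )
    if df["probe_id"].duplicated().any():
        dupes = sorted(df.loc[df["probe_id"].duplicated(), "probe_id"].unique())
        raise ValidationError(f"{path}: probe annotated twice: {dupes[:5]}")
    return ProbeAnnotation(df.set_index("probe_id"))


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    df = annotation.table.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


_OPTIONAL_META = ("rin", "race", "region", "dataset")


def read_sample_metadata(
    path: str | Path,
    vocabulary: Optional[RegionVocabulary] = None,
    birth_pcd: float = BIRTH_PCD,
) -> list[SampleRecord]:
    """Read sample metadata CSV into validated :class:`SampleRecord` rows."""
    path = Path(path)
    vocabulary = vocabulary or default_vocabulary()
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty metadata file")
        fields = set(reader.fieldnames)
        for col in ("sample_id", "age", "sex"):
            if col not in fields:
                raise ValidationError(f"{path}: missing mandatory column {col!r}")
        records: list[SampleRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = _record_from_row(row, fields, vocabulary, birth_pcd)
            except (ValidationError, ParseError):
                raise
            except Exception as exc:  # age conversion, float parsing
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample_id values")
    return records


def _record_from_row(
    row: dict,
    fields: set[str],
    vocabulary: RegionVocabulary,
    birth_pcd: float,
) -> SampleRecord:
    unit = (row.get("age_unit") or "").strip()
    age_text = (row.get("age") or "").strip()
    if unit:
        age_pcd = convert_age(float(age_text), unit, birth_pcd)
    else:
        value, parsed_unit = parse_age(age_text)
        age_pcd = convert_age(value, parsed_unit, birth_pcd)

    def opt(name: str) -> Optional[str]:
        v = (row.get(name) or "").strip()
        return v or None

    region = opt("region")
    if region is not None:
        vocabulary.validate(region)
    rin_text = opt("rin")
    rin = float(rin_text) if rin_text is not None else None
    if rin is not None and not (0 <= rin <= 10):
        raise ValidationError(f"sample {row['sample_id']}: RIN {rin} outside [0, 10]")
    return SampleRecord(
        sample_id=row["sample_id"].strip(),
        donor_id=(opt("donor_id") or row["sample_id"].strip()),
        age_pcd=age_pcd,
        postnatal=age_pcd > birth_pcd,
        sex=row["sex"].strip().lower(),
        rin=rin,
        race=opt("race"),
        region=region,
        dataset=opt("dataset") or "user-defined",
    )


def write_sample_metadata(samples: Sequence[SampleRecord], path: str | Path) -> None:
    """Write sample metadata CSV with ages in canonical pcd."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "donor_id", "age", "age_unit", "sex", "rin", "race",
             "region", "dataset"]
        )
        for r in samples:
            writer.writerow(
                [
                    r.sample_id,
                    r.donor_id,
                    repr(float(r.age_pcd)),
                    "pcd",
                    r.sex,
                    "" if r.rin is None else r.rin,
                    r.race or "",
                    r.region or "",
                    r.dataset,
                ]
            )


def write_splicing_index(si: SplicingIndexMatrix, path: str | Path) -> None:
    """Write splicing indices with ``gene:exon`` row labels, expression-TSV dialect."""
    df = si.values.copy()
    df.index = [f"{g}:{e}" for g, e in df.index]
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, lineterminator="\n")


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct CSV; delegated validation lives in :mod:`exonshift.qpcr`."""
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "target": str})
    required = {"sample_id", "group", "target", "ct"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: qPCR table must have columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return df
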