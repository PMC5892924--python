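import numpy as np
import pandas as pd
import pytest

from exonshift import (
    SimulationConfig,
    aggregate_features,
    compute_splicing_index,
    differential_table,
    simulate_dataset,
)


@pytest.fixture()
def tiny_matrix_tsv(tmp_path):
    """Well-formed 3-probe x 2-sample expression TSV."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "probe_id\ts1\ts2\n"
        "p1\t1.0\t2.0\n"
        "p2\t3.5\t4.5\n"
        "p3\t0.25\t6.0\n"
    )
    return path


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated dataset (seed 1)."""
    cfg = SimulationConfig(seed=1)
    matrix, annotation, samples, truth = simulate_dataset(cfg)
    return cfg, matrix, annotation, samples, truth


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Features, splicing indices and differential table for the default sim."""
    cfg, matrix, annotation, samples, _ = default_sim
    features = aggregate_features(matrix, annotation)
    si = compute_splicing_index(features)
    table = differential_table(si, features, samples, cfg.genes)
    return cfg, features, si, samples, table


def brute_force_feature_means(matrix_df: pd.DataFrame, ann_df: pd.DataFrame):
    """Independent loop-based probe aggregation (oracle for aggregate_features)."""
    out: dict[tuple[str, str], list[float]] = {}
    genes = sorted(ann_df["gene"].unique())
    for gene in genes:
        probes = [p for p in matrix_df.index if ann_df.at[p, "gene"] == gene]
        for sample in matrix_df.columns:
            vals = [matrix_df.at[p, sample] for p in probes
                    if np.isfinite(matrix_df.at[p, sample])]
            out.setdefault((gene, "gene"), []).append(
                sum(vals) / len(vals) if vals else np.nan
            )
        exons = sorted(
            f for f in ann_df.loc[probes, "feature"].unique() if f != "gene_body"
        )
        for exon in exons:
            eprobes = [p for p in probes if ann_df.at[p, "feature"] == exon]
            for sample in matrix_df.columns:
                vals = [matrix_df.at[p, sample] for p in eprobes
                        if np.isfinite(matrix_df.at[p, sample])]
                out.setdefault((gene, exon), []).append(
                    sum(vals) / len(vals) if vals else np.nan
                )
    return {k: np.array(v) for k, v in out.items()}
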