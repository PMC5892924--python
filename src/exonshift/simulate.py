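"""Synthetic probe-level datasets with a known perinatal splicing switch.

The generator emulates the structure of developmental brain expression
cohorts: donors spanning fetal-to-adult ages, optional multi-region
sampling with reduced total-gene expression in neurogenic regions, probes
tagged to constitutive gene-body positions or to named alternative exons,
and exon inclusion following a logistic trajectory in log10 age — a rapid
perinatal rise to a stable adult plateau for the exon-10 analogue, a slower
childhood rise for the exon-2 analogue.

Model
-----
For sample *s* (age *t_s*, region *r*) and gene *g* with baseline level
``mu_g`` and region multiplier ``m_r``, a probe's expected intensity is

    expected = mu_g * m_r * psi_e(t_s)      (named-exon probe)
    expected = mu_g * m_r                   (gene-body probe)

with inclusion ``psi_e(t) = psi_pre + (psi_post - psi_pre) /
(1 + exp(-k * (log10 t - log10 t0)))``. Microarray mode emits positive
linear-scale intensities ``expected * 2**(affinity + noise)`` where the
per-probe affinity (drawn once) and the per-cell noise are Gaussian on the
log2-intensity scale; counts mode emits negative-binomial draws with the
same mean. All randomness flows from the single config seed.

The default cohort places 60 donors in a second-trimester fetal stratum
(40–160 pcd) and 60 in a late-infancy-to-adult stratum (500–30947 pcd ≈
84 years), each log-uniform, so the prenatal and postnatal groups sit on
the inclusion plateaus on either side of the perinatal switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ages import BIRTH_PCD, is_postnatal
from .containers import (
    GENE_BODY,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleRecord,
)
from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class SwitchSpec:
    """Logistic inclusion trajectory for one alternative exon."""

    gene: str
    exon: str
    psi_pre: float
    psi_post: float
    t0_pcd: float = BIRTH_PCD
    k: float = 8.0  # steepness per unit log10(age_pcd)

    def __post_init__(self) -> None:
        for name, p in (("psi_pre", self.psi_pre), ("psi_post", self.psi_post)):
            if not 0.0 < p < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {p}")
        if self.t0_pcd <= 0:
            raise ValidationError("t0_pcd must be positive")


def inclusion_at(spec: SwitchSpec, age_pcd: "float | np.ndarray") -> "float | np.ndarray":
    """Inclusion proportion psi at a post-conceptual age (days).

    ``k = 0`` degenerates to the constant mid-level (psi_pre + psi_post)/2;
    large ``k`` approaches a step at ``t0_pcd``.
    """
    age = np.asarray(age_pcd, float)
    if np.any(~np.isfinite(age)) or np.any(age <= 0):
        raise DomainError("age_pcd must be positive and finite")
    z = -spec.k * (np.log10(age) - math.log10(spec.t0_pcd))
    psi = spec.psi_pre + (spec.psi_post - spec.psi_pre) / (1.0 + np.exp(z))
    return float(psi) if np.isscalar(age_pcd) else psi


def flat_exon(gene: str, exon: str, psi: float) -> SwitchSpec:
    """Constant-inclusion exon (null trajectory)."""
    return SwitchSpec(gene, exon, psi, psi, BIRTH_PCD, 0.0)


#: Default switching and null exons: a tau-like gene with an abrupt
#: perinatal exon-10 switch, a slower childhood exon-2 rise and a flat
#: exon 3, next to four paralogous genes with flat alternative exons.
DEFAULT_SWITCHES: tuple[SwitchSpec, ...] = (
    SwitchSpec("MAPT", "exon10", psi_pre=0.2, psi_post=0.6, t0_pcd=266.0, k=8.0),
    SwitchSpec("MAPT", "exon2", psi_pre=0.3, psi_post=0.5, t0_pcd=600.0, k=3.0),
    flat_exon("MAPT", "exon3", 0.15),
    flat_exon("MAP2", "exon9", 0.5),
    flat_exon("MAP4", "exon5", 0.3),
    flat_exon("MAP1A", "exon4", 0.4),
    flat_exon("MAP1B", "exon6", 0.6),
)


@dataclass
class SimulationConfig:
    """Full description of one simulated dataset; the seed determines everything."""

    n_donors: int = 120
    regions: Mapping[str, float] = field(default_factory=lambda: {"DFC": 1.0})
    age_range: tuple[float, float] = (40.0, 30947.0)  # ~5.7 pcw .. 84 y
    fetal_age_max: float = 160.0  # prenatal stratum upper bound (~23 pcw)
    postnatal_age_min: float = 500.0  # postnatal stratum lower bound (~8 months)
    switches: Sequence[SwitchSpec] = DEFAULT_SWITCHES
    probes_per_feature: int = 4
    gene_body_probes: int = 48
    gene_means: Optional[Mapping[str, float]] = None
    noise_sd: float = 0.1  # log2-intensity scale
    probe_affinity_sd: float = 0.25  # log2-intensity scale
    mode: Literal["microarray", "counts"] = "microarray"
    nb_dispersion: float = 10.0
    dataset: str = "sim"
    birth_pcd: float = BIRTH_PCD
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 4:
            raise ValidationError("need at least 4 donors")
        if not self.regions:
            raise ValidationError("at least one region is required")
        if any(m <= 0 for m in self.regions.values()):
            raise ValidationError("region multipliers must be positive")
        lo, hi = self.age_range
        if not (0 < lo < self.fetal_age_max <= self.birth_pcd
                <= self.postnatal_age_min < hi):
            raise ValidationError(
                "require 0 < age_min < fetal_age_max <= birth_pcd "
                "<= postnatal_age_min < age_max"
            )
        if self.noise_sd < 0 or self.probe_affinity_sd < 0:
            raise ValidationError("noise parameters must be non-negative")
        if self.probes_per_feature < 1 or self.gene_body_probes < 1:
            raise ValidationError("probe counts must be >= 1")
        if self.mode not in ("microarray", "counts"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "counts" and self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        seen = set()
        for sw in self.switches:
            if (sw.gene, sw.exon) in seen:
                raise ValidationError(f"duplicate exon spec {(sw.gene, sw.exon)}")
            seen.add((sw.gene, sw.exon))

    @property
    def genes(self) -> list[str]:
        return sorted({sw.gene for sw in self.switches})


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return 10 ** rng.uniform(math.log10(lo), math.log10(hi), n)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation, list[SampleRecord], pd.DataFrame]:
    """Generate (expression, annotation, samples, truth) for one dataset.

    Donors split evenly between the fetal and postnatal age strata; every
    donor contributes one specimen per configured region. The truth table
    records, per named exon and sample, the inclusion psi together with the
    gene baseline and region multiplier actually used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_pre = config.n_donors // 2
    n_post = config.n_donors - n_pre
    ages = np.concatenate(
        [
            _log_uniform(rng, config.age_range[0], config.fetal_age_max, n_pre),
            _log_uniform(rng, config.postnatal_age_min, config.age_range[1], n_post),
        ]
    )
    sexes = rng.choice(["male", "female"], config.n_donors)
    rins = np.clip(rng.normal(7.5, 1.0, config.n_donors), 5.0, 10.0)
    races = rng.choice(["grp1", "grp2", "grp3"], config.n_donors, p=[0.5, 0.3, 0.2])

    region_codes = list(config.regions)
    samples: list[SampleRecord] = []
    for i in range(config.n_donors):
        donor = f"D{i:03d}"
        for region in region_codes:
            sid = f"{donor}_{region}" if len(region_codes) > 1 else donor
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    donor_id=donor,
                    age_pcd=float(ages[i]),
                    postnatal=is_postnatal(ages[i], config.birth_pcd),
                    sex=str(sexes[i]),
                    rin=float(round(rins[i], 1)),
                    race=str(races[i]),
                    region=region,
                    dataset=config.dataset,
                )
            )
    sample_ids = [s.sample_id for s in samples]
    sample_age = np.array([s.age_pcd for s in samples])
    sample_mult = np.array([config.regions[s.region] for s in samples])

    genes = config.genes
    if config.gene_means is not None:
        mu = {g: float(config.gene_means[g]) for g in genes}
    else:
        draws = _log_uniform(rng, 200.0, 5000.0, len(genes))
        mu = dict(zip(genes, draws))

    probe_ids: list[str] = []
    ann_rows: list[dict] = []
    expected_rows: list[np.ndarray] = []
    truth_rows: list[dict] = []
    by_gene = {g: [sw for sw in config.switches if sw.gene == g] for g in genes}
    for gene in genes:
        base = mu[gene] * sample_mult
        for j in range(config.gene_body_probes):
            probe_ids.append(f"{gene}_body_{j:03d}")
            ann_rows.append({"gene": gene, "feature": GENE_BODY})
            expected_rows.append(base)
        for sw in by_gene[gene]:
            psi = inclusion_at(sw, sample_age)
            for j in range(config.probes_per_feature):
                probe_ids.append(f"{gene}_{sw.exon}_{j:02d}")
                ann_rows.append({"gene": gene, "feature": sw.exon})
                expected_rows.append(base * psi)
            for sid, age, p, m in zip(sample_ids, sample_age, psi, sample_mult):
                truth_rows.append(
                    {
                        "gene": gene,
                        "exon": sw.exon,
                        "sample_id": sid,
                        "age_pcd": float(age),
                        "psi": float(p),
                        "mu": mu[gene],
                        "region_multiplier": float(m),
                    }
                )

    expected = np.vstack(expected_rows)
    if config.mode == "microarray":
        affinity = rng.normal(0.0, config.probe_affinity_sd, (expected.shape[0], 1))
        noise = rng.normal(0.0, config.noise_sd, expected.shape)
        values = expected * np.exp2(affinity + noise)
    else:
        r = config.nb_dispersion
        values = rng.negative_binomial(r, r / (r + expected)).astype(float)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    )
    annotation = ProbeAnnotation(
        pd.DataFrame(ann_rows, index=pd.Index(probe_ids, name="probe_id"))
    )
    truth = pd.DataFrame(truth_rows)
    return matrix, annotation, samples, truth


def expected_splicing_index(config: SimulationConfig, gene: str, exon: str,
                            age_pcd: float) -> float:
    """Closed-form noiseless splicing index implied by the inclusive gene mean.

    With gene-body probes at mu and each alternative exon e at mu*psi_e, the
    all-probe gene mean is mu * (n_body + p * sum_e psi_e) / n_total, so the
    recovered index is psi diluted by that factor. Used as the analytic
    oracle for pipeline-inversion tests.
    """
    specs = [sw for sw in config.switches if sw.gene == gene]
    psis = {sw.exon: inclusion_at(sw, age_pcd) for sw in specs}
    if exon not in psis:
        raise ValidationError(f"no spec for {gene}/{exon}")
    n_body = config.gene_body_probes
    p = config.probes_per_feature
    n_total = n_body + p * len(specs)
    dilution = (n_body + p * sum(psis.values())) / n_total
    return psis[exon] / dilution


#: Fig-4-like default truth for the qPCR generator: adult excess of the
#: exon-10 (4R) and exon-2 (1N) products, fetal excess of 0N, scant 2N.
DEFAULT_QPCR_REL: Mapping[str, Mapping[str, float]] = {
    "GAPDH": {"fetal": 1.0, "adult": 1.0},
    "total_tau": {"fetal": 1.0, "adult": 1.0},
    "0N": {"fetal": 3.0, "adult": 1.0},
    "1N": {"fetal": 0.4, "adult": 1.2},
    "2N": {"fetal": 0.05, "adult": 0.3},
    "4R": {"fetal": 0.25, "adult": 2.0},
}

DEFAULT_BASE_CT: Mapping[str, float] = {
    "GAPDH": 19.0,
    "total_tau": 24.0,
    "0N": 26.0,
    "1N": 26.0,
    "2N": 28.0,
    "4R": 26.0,
}


def simulate_qpcr(
    groups: Mapping[str, int] = None,
    true_rel: Mapping[str, Mapping[str, float]] = None,
    ct_noise_sd: float = 0.15,
    n_replicates: int = 3,
    base_ct: Mapping[str, float] = None,
    reference: str = "GAPDH",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format Ct table with known relative expression.

    Ct for a (sample, target) is ``base_ct[target] − log2(true relative
    level) + noise`` per technical replicate, so the ΔΔCt analysis inverts
    the configured levels exactly when ``ct_noise_sd = 0``.
    """
    groups = dict(groups or {"fetal": 7, "adult": 7})
    true_rel = {t: dict(g) for t, g in (true_rel or DEFAULT_QPCR_REL).items()}
    base_ct = dict(base_ct or DEFAULT_BASE_CT)
    if reference not in true_rel:
        raise ValidationError(f"reference target {reference!r} missing from true_rel")
    for group in groups:
        for target, levels in true_rel.items():
            if group not in levels:
                raise ValidationError(f"target {target!r} lacks level for {group!r}")
            if levels[group] <= 0:
                raise DomainError(f"relative level must be positive: {target}/{group}")
        if abs(true_rel[reference][group] - 1.0) > 1e-12:
            raise ValidationError("reference target must have relative level 1")

    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for group, n in groups.items():
        for _ in range(n):
            i += 1
            sid = f"{group[:1].upper()}{i:02d}"
            for target, levels in true_rel.items():
                center = base_ct.get(target, 25.0) - math.log2(levels[group])
                for rep in range(1, n_replicates + 1):
                    ct = center + rng.normal(0.0, ct_noise_sd) if ct_noise_sd else center
                    rows.append(
                        {
                            "sample_id": sid,
                            "group": group,
                            "target": target,
                            "ct": round(float(np.clip(ct, 1.0, 40.0)), 4),
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


def two_dataset_pair(
    base: Optional[SimulationConfig] = None, seed: int = 0
) -> tuple[SimulationConfig, SimulationConfig]:
    """Configs for a replication experiment: a shared switch, a
    dataset-specific switch, and nulls.

    Both datasets carry the tau-like exon-10 switch; only the first carries
    an additional switch in a paralog; the remaining exons are flat.
    """
    shared = SwitchSpec("MAPT", "exon10", 0.2, 0.6, 266.0, 8.0)
    a_only = SwitchSpec("MAP2", "exon9", 0.3, 0.55, 266.0, 8.0)
    nulls = (
        flat_exon("MAPT", "exon2", 0.4),
        flat_exon("MAPT", "exon3", 0.15),
        flat_exon("MAP2", "exon11", 0.5),
        flat_exon("MAP4", "exon5", 0.3),
        flat_exon("MAP4", "exon7", 0.6),
        flat_exon("MAP1A", "exon4", 0.4),
        flat_exon("MAP1A", "exon6", 0.25),
        flat_exon("MAP1B", "exon6", 0.6),
    )
    base = base or SimulationConfig()
    cfg_a = replace(
        base, switches=(shared, a_only) + nulls, dataset="yale_sim", seed=seed
    )
    cfg_b = replace(
        base,
        switches=(shared, flat_exon("MAP2", "exon9", 0.3)) + nulls,
        dataset="lieber_sim",
        seed=seed + 10_000,
    )
    return cfg_a, cfg_b
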