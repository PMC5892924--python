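"""Linear-model fitting, temporal trends and regional contrasts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonshift import (
    SimulationConfig,
    SwitchSpec,
    age_trend,
    aggregate_features,
    build_design,
    compute_splicing_index,
    fit_linear_model,
    flat_exon,
    regional_model,
    sample_frame,
    simulate_dataset,
)
from exonshift.errors import InsufficientDataError, ValidationError
from exonshift.regions import DEFAULT_NEUROGENIC, DEFAULT_REGION_CODES


def normal_equations_oracle(y, X):
    """Closed-form OLS estimates and standard errors."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se


class TestFitLinearModel:
    def test_noiseless_interpolation(self):
        age = np.array([1.0, 2.0, 3.0, 4.0])
        design = pd.DataFrame({"intercept": 1.0, "age": age})
        fit = fit_linear_model(1 + 2 * age, design)
        assert fit.term("intercept")["estimate"] == pytest.approx(1.0, abs=1e-10)
        assert fit.term("age")["estimate"] == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 12, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = X @ rng.normal(size=k) + rng.normal(size=n)
        design = pd.DataFrame(X, columns=["intercept", "x1", "x2"])
        fit = fit_linear_model(y, design)
        beta, se = normal_equations_oracle(y, X)
        np.testing.assert_allclose(fit.coefficients["estimate"], beta, atol=1e-8)
        np.testing.assert_allclose(fit.coefficients["se"], se, atol=1e-8)

    def test_duplicated_covariate_is_rank_deficient(self):
        X = pd.DataFrame({"intercept": np.ones(10), "a": np.arange(10.0),
                          "b": np.arange(10.0)})
        with pytest.raises(ValidationError, match="rank"):
            fit_linear_model(np.arange(10.0), X)

    def test_too_few_observations(self):
        X = pd.DataFrame({"intercept": np.ones(2), "a": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            fit_linear_model([1.0, 2.0], X)

    def test_confidence_interval_coverage(self):
        """95% CIs on the slope cover the true value ~95% of the time."""
        rng = np.random.default_rng(42)
        true_slope = 0.5
        n, n_sims = 30, 500
        covered = 0
        x = rng.normal(size=n)
        design = pd.DataFrame({"intercept": np.ones(n), "x": x})
        tcrit = stats.t.ppf(0.975, n - 2)
        for _ in range(n_sims):
            y = 1.0 + true_slope * x + rng.normal(size=n)
            fit = fit_linear_model(y, design)
            est, se = fit.term("x")["estimate"], fit.term("x")["se"]
            covered += est - tcrit * se <= true_slope <= est + tcrit * se
        assert 0.93 <= covered / n_sims <= 0.97


class TestAgeTrend:
    def test_switching_exon_has_positive_age_effect(self, default_pipeline):
        _, _, si, samples, _ = default_pipeline
        res = age_trend(si, sample_frame(samples), ("MAPT", "exon10"))
        assert res.age_p < 1e-4
        assert res.age_coefficient > 0
        assert set(res.covariates_used) == {"sex", "rin", "race"}

    def test_covariates_dropped_when_unavailable(self, default_pipeline):
        _, _, si, samples, _ = default_pipeline
        meta = sample_frame(samples).copy()
        meta["rin"] = np.nan  # e.g. RNA-seq dataset without RIN
        res = age_trend(si, meta, ("MAPT", "exon10"))
        assert "rin" not in res.covariates_used

    def test_adult_only_plateau_is_flat(self):
        # switch completed at birth, sampled only in adulthood across a
        # multi-region adult brain-bank-sized cohort (134 donors, 10 regions)
        cortical = ["DFC", "OFC", "MFC", "VFC", "M1C", "S1C",
                    "A1C", "STC", "ITC", "V1C"]
        cfg = SimulationConfig(
            n_donors=268,
            regions={c: 1.0 for c in cortical},
            age_range=(40.0, 30947.0),
            postnatal_age_min=16 * 365.25 + 266,  # adults 16+
            switches=(SwitchSpec("MAPT", "exon10", 0.2, 0.6, 266.0, 8.0),),
            seed=5,
        )
        m, a, s, _ = simulate_dataset(cfg)
        feats = aggregate_features(m, a)
        si = compute_splicing_index(feats)
        adults = [rec for rec in s if rec.postnatal]
        res = age_trend(si, sample_frame(adults), ("MAPT", "exon10"))
        assert abs(res.age_coefficient) < 0.01  # per log10-day

    def test_constant_response_degenerates_to_p_one(self, default_pipeline):
        _, _, si, samples, _ = default_pipeline
        flat = si.values.copy()
        flat.loc[("MAPT", "exon10")] = 0.5
        res = age_trend(flat, sample_frame(samples), ("MAPT", "exon10"))
        assert res.degenerate and res.age_p == 1.0

    def test_too_few_samples(self, default_pipeline):
        _, _, si, samples, _ = default_pipeline
        few = sample_frame(samples).iloc[:5]
        sub = si.values[few.index]
        with pytest.raises(InsufficientDataError):
            age_trend(sub, few, ("MAPT", "exon10"))


def _regional_config(seed, neurogenic_mult=0.3):
    regions = {
        code: (neurogenic_mult if code in DEFAULT_NEUROGENIC else 1.0)
        for code in sorted(DEFAULT_REGION_CODES)
    }
    return SimulationConfig(
        n_donors=20,
        regions=regions,
        switches=(
            SwitchSpec("MAPT", "exon10", 0.2, 0.6, 266.0, 8.0),
            flat_exon("MAPT", "exon2", 0.4),
        ),
        gene_body_probes=16,
        seed=seed,
    )


class TestRegionalModel:
    def test_neurogenic_deficit_recovered(self):
        cfg = _regional_config(seed=0)
        m, a, s, _ = simulate_dataset(cfg)
        feats = aggregate_features(m, a)
        res = regional_model(feats, sample_frame(s), ("MAPT", "gene"), "DFC")
        sig = res.contrasts[res.contrasts.p_adj < 0.05]
        assert set(sig.index) == set(DEFAULT_NEUROGENIC)
        assert (sig.estimate < 0).all()

    def test_null_regions_mostly_quiet(self):
        cfg = _regional_config(seed=1, neurogenic_mult=1.0)
        m, a, s, _ = simulate_dataset(cfg)
        feats = aggregate_features(m, a)
        res = regional_model(feats, sample_frame(s), ("MAPT", "gene"), "DFC")
        assert len(res.significant()) == 0

    def test_single_region_rejected(self, default_pipeline):
        _, feats, _, samples, _ = default_pipeline
        with pytest.raises(ValidationError):
            regional_model(feats, sample_frame(samples), ("MAPT", "gene"), "DFC")

    def test_reference_must_be_present(self):
        cfg = _regional_config(seed=2)
        m, a, s, _ = simulate_dataset(cfg)
        feats = aggregate_features(m, a)
        with pytest.raises(ValidationError, match="reference region"):
            regional_model(feats, sample_frame(s), ("MAPT", "gene"), "NOPE")

    def test_reference_change_preserves_fitted_values(self):
        cfg = _regional_config(seed=3)
        m, a, s, _ = simulate_dataset(cfg)
        feats = aggregate_features(m, a)
        meta = sample_frame(s)
        y = feats.values.loc[("MAPT", "gene")]
        keep = y.notna()
        preds = []
        for ref in ("DFC", "HIP"):
            design, _ = build_design(meta.loc[keep[keep].index],
                                     region_reference=ref)
            fit = fit_linear_model(y[keep].to_numpy(), design)
            preds.append(design.to_numpy() @ fit.coefficients["estimate"].to_numpy())
        np.testing.assert_allclose(preds[0], preds[1], atol=1e-10)

    def test_low_n_region_flagged_but_reported(self):
        cfg = _regional_config(seed=4)
        m, a, s, _ = simulate_dataset(cfg)
        feats = aggregate_features(m, a)
        meta = sample_frame(s)
        # keep only 2 samples of one non-reference region
        drop = meta.index[meta.region == "HIP"][2:]
        meta = meta.drop(index=drop)
        sub = feats.values[meta.index]
        res = regional_model(sub, meta, ("MAPT", "gene"), "DFC")
        assert bool(res.contrasts.at["HIP", "low_n"])
        assert "HIP" in res.contrasts.index
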