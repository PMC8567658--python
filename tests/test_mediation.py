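import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import musclemeth as mm
from musclemeth.core_io import ValidationError
from musclemeth.ewas import build_design
from musclemeth.mediation import (beta_regression, derive_hormone_indices,
                                  estimate_fibre_from_tpm, fibre_sex_difference,
                                  free_testosterone,
                                  free_testosterone_fixed_point, hormone_pcs,
                                  hormone_scan, stratified_fibre_meta)


class TestFibreFromTpm:
    def test_half_ratio(self):
        assert estimate_fibre_from_tpm(100, 60, 40) == pytest.approx(0.5)

    def test_zero_myh7(self):
        assert estimate_fibre_from_tpm(0, 50, 50) == pytest.approx(0.0)

    def test_scale_invariance(self):
        a = estimate_fibre_from_tpm(30, 50, 20)
        b = estimate_fibre_from_tpm(7 * 30, 7 * 50, 7 * 20)
        assert a == pytest.approx(b)

    def test_zero_total_is_nan(self):
        assert np.isnan(estimate_fibre_from_tpm(0.0, 0.0, 0.0))

    def test_negative_tpm_raises(self):
        with pytest.raises(ValidationError):
            estimate_fibre_from_tpm(-1, 1, 1)


class TestBetaRegression:
    def _simulate(self, beta_sex=0.4, phi=30.0, n=200, rng=None):
        rng = np.random.default_rng(rng)
        sex = np.array(["F"] * (n // 2) + ["M"] * (n // 2))
        mu = special.expit(0.1 + beta_sex * (sex == "M"))
        y = rng.beta(mu * phi, (1 - mu) * phi)
        return y, sex

    def test_parameter_recovery_and_ci_coverage(self):
        hits, errs = 0, []
        n_reps = 40
        for rep in range(n_reps):
            y, sex = self._simulate(rng=rep)
            res = fibre_sex_difference(y, sex)
            row = res[res["term"] == "sex"].iloc[0]
            errs.append(row["coef"] - 0.4)
            hits += (row["coef"] - 1.96 * row["se"] <= 0.4
                     <= row["coef"] + 1.96 * row["se"])
        assert abs(np.mean(errs)) < 0.1
        assert hits / n_reps > 0.85

    def test_null_gives_small_coefficient(self):
        y, sex = self._simulate(beta_sex=0.0, rng=123)
        res = fibre_sex_difference(y, sex)
        row = res[res["term"] == "sex"].iloc[0]
        assert abs(row["coef"]) < 0.2
        assert row["p"] > 0.001

    def test_large_phi_limit_recovers_group_mean_logits(self):
        rng = np.random.default_rng(9)
        sex = np.array(["F"] * 100 + ["M"] * 100)
        mu = np.where(sex == "M", 0.6, 0.45)
        y = np.clip(mu + rng.normal(0, 1e-4, 200), 1e-6, 1 - 1e-6)
        res = fibre_sex_difference(y, sex)
        icept = res.loc[res["term"] == "Intercept", "coef"].iloc[0]
        slope = res.loc[res["term"] == "sex", "coef"].iloc[0]
        assert icept == pytest.approx(special.logit(0.45), abs=0.01)
        assert icept + slope == pytest.approx(special.logit(0.6), abs=0.01)

    def test_boundary_values_handled_by_shrinkage(self):
        y = np.array([0.0, 0.2, 0.5, 0.8, 1.0] * 10)
        sex = np.array(["F", "M"] * 25)
        res = fibre_sex_difference(y, sex)
        assert np.isfinite(res["coef"]).all()


class TestStratifiedFibreMeta:
    def test_no_fibre_effects_yields_no_hits(self):
        cfg = mm.SimConfig(n_cohorts=2, n_probes=3000, n_samples=(80, 80),
                           frac_sex_cpgs=0.1, effect_size=0.15,
                           frac_fibre_cpgs=0.0, small_array_cohort=False, seed=21)
        studies, _, truth = mm.simulate_cohorts(cfg)
        res = mm.run_sex_meta(studies, call_dmrs=False)
        sex_dmps = res["meta"].index[res["meta"]["is_dmp"]]
        out = stratified_fibre_meta(studies, sex_dmps)
        assert len(out["fibre_cpgs"]) <= max(2, 0.005 * len(sex_dmps))

    def test_planted_mediated_share_recovered(self):
        cfg = mm.SimConfig(n_cohorts=2, n_probes=4000, n_samples=(150, 150),
                           frac_sex_cpgs=0.1, effect_size=0.15,
                           frac_fibre_cpgs=0.0,
                           frac_sex_cpgs_fibre_mediated=0.15,
                           small_array_cohort=False, seed=22)
        studies, _, truth = mm.simulate_cohorts(cfg)
        res = mm.run_sex_meta(studies, call_dmrs=False)
        sex_dmps = res["meta"].index[res["meta"]["is_dmp"]]
        out = stratified_fibre_meta(studies, sex_dmps)
        assert abs(out["fraction_of_sex_dmps"] - 0.15) < 0.05

    def test_sex_never_enters_group_design(self):
        cfg = mm.SimConfig(n_cohorts=2, n_probes=300, n_samples=(60, 60),
                           small_array_cohort=False, seed=23)
        studies, _, _ = mm.simulate_cohorts(cfg)
        # the per-group design built from the cohort covariates excludes sex
        study = studies[0]
        terms = ["type1_ratio"] + [t for t in study.design_formula if "sex" not in t]
        sub = study.subset_samples(study.samples.index[study.samples["sex"] == "F"])
        X = build_design(sub.samples, terms)
        assert not any("sex" in c for c in X.columns)

    def test_subset_bh_at_least_as_many_discoveries(self, rng):
        # restricting BH to a promising subset cannot lose discoveries that
        # genome-wide BH would have made inside that subset
        from musclemeth.calibrate_meta import bh_adjust
        p = np.concatenate([rng.uniform(0, 1e-4, 30), rng.uniform(size=2_000)])
        subset = np.arange(100)
        genome_wide = (bh_adjust(p) < 0.005)[subset].sum()
        restricted = (bh_adjust(p[subset]) < 0.005).sum()
        assert restricted >= genome_wide


@pytest.fixture(scope="module")
def cohort():
    cfg = mm.SimConfig(n_cohorts=2, n_probes=4000, n_samples=(120, 40),
                       frac_sex_cpgs=0.0, frac_fibre_cpgs=0.0,
                       small_array_cohort=False, seed=31)
    studies, _, _ = mm.simulate_cohorts(cfg)
    return studies[0]


class TestHormoneScan:

    def test_independent_hormone_is_null(self, cohort):
        panel = mm.synthgen.simulate_hormones(cohort.samples, rng=1)
        out = hormone_scan(cohort, panel["T"], sex="M", covariates=["age"])
        assert out["n_dmps"] < 5

    def test_constant_hormone_raises(self, cohort):
        const = pd.Series(1.0, index=cohort.samples.index)
        with pytest.raises(ValidationError, match="constant"):
            hormone_scan(cohort, const, sex="M")

    def test_hormone_equal_to_planted_driver_recovers_targets(self, cohort):
        # construct a hormone equal to a latent covariate that drives 200 CpGs
        rng = np.random.default_rng(5)
        males = cohort.samples.index[cohort.samples["sex"] == "M"]
        driver = pd.Series(rng.normal(size=len(cohort.samples)),
                           index=cohort.samples.index)
        study = mm.CohortStudy(cohort.name, cohort.beta.copy(),
                               cohort.samples.copy(), cohort.design_formula)
        targets = study.beta.index[:200]
        bump = 0.04 * driver.to_numpy()
        study.beta.loc[targets] = np.clip(
            study.beta.loc[targets].to_numpy() + bump[None, :], 0, 1)
        out = hormone_scan(study, driver, sex="M", covariates=["age"])
        hits = out["results"].loc[out["results"]["fdr"] < 0.005].index
        assert len(set(hits) & set(targets)) > 150

    def test_first_two_pcs_capture_most_variance(self, cohort):
        panel = mm.synthgen.simulate_hormones(cohort.samples, rng=2)
        pcs = hormone_pcs(panel[["E2", "FSH", "LH", "progesterone"]], n_pcs=2)
        X = np.log(panel[["E2", "FSH", "LH", "progesterone"]].to_numpy())
        X = (X - X.mean(0)) / X.std(0)
        total = X.var(0).sum()
        explained = pcs.to_numpy().var(0).sum() / total
        assert explained >= 2 / 4  # first two PCs beat any two raw hormones on average


class TestHormoneIndices:
    def test_fai_arithmetic(self):
        panel = pd.DataFrame({"T": [20.0], "SHBG": [50.0]})
        out = derive_hormone_indices(panel)
        assert out["FAI"].iloc[0] == pytest.approx(40.0)

    def test_free_fraction_monotone_as_shbg_drops(self):
        fractions = [free_testosterone(20.0, s) / 20_000.0
                     for s in (100.0, 50.0, 10.0, 1.0)]
        assert all(np.diff(fractions) > 0)

    def test_cubic_matches_fixed_point_oracle(self):
        for t, s in [(20.0, 50.0), (1.2, 70.0), (35.0, 15.0), (10.0, 120.0)]:
            cubic = free_testosterone(t, s)
            fp = free_testosterone_fixed_point(t, s)
            assert cubic == pytest.approx(fp, rel=1e-8)

    def test_physiological_free_fraction(self):
        # typical male: ~1-3% of total testosterone is free
        frac = free_testosterone(20.0, 40.0) / 20_000.0
        assert 0.005 < frac < 0.05

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValidationError):
            derive_hormone_indices(pd.DataFrame({"T": [0.0], "SHBG": [50.0]}))
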