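"""Tests of the partial Spearman primitive, BH adjustment, prevalence
filtering, the model cascade and sensitivity analyses.  The partial Spearman
oracle ranks, residualizes via explicit normal equations and correlates --
independent of the library code path."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from osagut import (
    bh_adjust,
    combined_abundance,
    partial_spearman,
    prevalence_filter,
    run_cascade,
    sensitivity_suite,
)
from osagut.association import default_models


def oracle_partial_spearman(x, y, cov_columns):
    """Rank -> residualize by explicit normal equations -> Pearson."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    d = np.column_stack([np.ones(len(x))] + cov_columns)
    beta_x = np.linalg.solve(d.T @ d, d.T @ rx)
    beta_y = np.linalg.solve(d.T @ d, d.T @ ry)
    ex, ey = rx - d @ beta_x, ry - d @ beta_y
    return float(ex @ ey / np.sqrt((ex**2).sum() * (ey**2).sum()))


class TestPartialSpearman:
    def test_no_covariates_equals_classic_spearman(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        rho, p, n = partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert n == 50

    def test_perfect_correlation(self, rng):
        x = rng.normal(size=40)
        cov = pd.DataFrame({"c": rng.normal(size=40)})
        rho, p, _ = partial_spearman(x, x.copy(), cov)
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(25):
            n = 50
            x, y = rng.normal(size=n), rng.normal(size=n)
            c = rng.normal(size=n)
            rho, _, _ = partial_spearman(x, y, pd.DataFrame({"c": c}))
            assert rho == pytest.approx(oracle_partial_spearman(x, y, [c]), abs=1e-10)

    def test_categorical_covariate_matches_oracle(self, rng):
        n = 60
        x, y = rng.normal(size=n), rng.normal(size=n)
        g = rng.choice(["a", "b", "c"], size=n)
        cov = pd.DataFrame({"g": pd.Categorical(g)})
        rho, _, _ = partial_spearman(x, y, cov)
        cols = [(g == lv).astype(float) for lv in pd.unique(g)[1:]]
        assert rho == pytest.approx(oracle_partial_spearman(x, y, cols), abs=1e-10)

    def test_complete_case_handling(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        x[:5] = np.nan
        _, _, n = partial_spearman(x, y)
        assert n == 25

    def test_covariate_equal_to_x_is_error(self, rng):
        x = rng.normal(size=40)
        with pytest.raises(ValueError):
            partial_spearman(x, rng.normal(size=40), pd.DataFrame({"c": x}))

    def test_too_few_observations_is_error(self, rng):
        with pytest.raises(ValueError):
            partial_spearman(
                rng.normal(size=5), rng.normal(size=5),
                pd.DataFrame({"a": rng.normal(size=5), "b": rng.normal(size=5)}),
            )

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_transform_invariance(self, seed):
        r = np.random.default_rng(seed)
        x, y, c = r.normal(size=30), r.normal(size=30), r.normal(size=30)
        cov = pd.DataFrame({"c": c})
        rho1, p1, _ = partial_spearman(x, y, cov)
        rho2, p2, _ = partial_spearman(np.exp(x), y**3, cov)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestBH:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(size=rng.integers(1, 40))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs, atol=1e-12)

    def test_matches_step_up_oracle(self, rng):
        p = rng.random(25)
        m = len(p)
        order = np.argsort(p)
        oracle = np.empty(m)
        for rank_i, idx in enumerate(order, start=1):
            candidates = [
                p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
            ]
            oracle[idx] = min(1.0, min(candidates))
        assert np.allclose(bh_adjust(p), oracle, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_order_preserving(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert (np.argsort(p) == np.argsort(q, kind="stable")).all() or (
            np.diff(q[np.argsort(p)]) >= -1e-15
        ).all()


class TestPrevalenceFilter:
    def test_boundary_inclusive_removal(self):
        ab = pd.DataFrame(np.zeros((100, 2)), columns=["s1", "s2"])
        ab.iloc[0, 0] = 0.5   # exactly 1% prevalence -> removed
        ab.iloc[:2, 1] = 0.5  # 2% -> kept
        ab["rest"] = 1.0
        kept = prevalence_filter(ab)
        assert "s1" not in kept and "s2" in kept and "rest" in kept

    def test_eleven_of_thousand_kept(self):
        ab = pd.DataFrame({"s": np.zeros(1000), "rest": np.ones(1000)})
        ab.iloc[:11, 0] = 0.1
        assert "s" in prevalence_filter(ab)


class TestCombinedAbundance:
    def test_closure_and_empty(self, small_cohort):
        all_sp = list(small_cohort.abundance.columns)
        assert np.allclose(combined_abundance(small_cohort.abundance, all_sp), 100.0)
        assert (combined_abundance(small_cohort.abundance, []) == 0.0).all()

    def test_arithmetic(self):
        ab = pd.DataFrame({"a": [0.03], "b": [0.05], "c": [0.92]})
        assert combined_abundance(ab, ["a", "b"]).iloc[0] == pytest.approx(8.0)

    def test_unknown_species_rejected(self, small_cohort):
        with pytest.raises(KeyError):
            combined_abundance(small_cohort.abundance, ["nope"])


class TestCascade:
    def test_hit_sets_nested_and_recovery(self, medium_cohort):
        c = medium_cohort
        cas = run_cascade(c.analysis_exposures, c.abundance, c.covariates)
        for e in ("ahi", "t90", "odi"):
            hits3 = set(cas.hits[e])
            stage2 = cas.table[(cas.table.exposure == e) & (cas.table.stage == 2)]
            assert hits3 <= set(cas.stage1_hits[e])
            assert set(stage2.feature) == set(cas.stage1_hits[e])
        odi_hits = set(cas.hits["odi"])
        recovered = len(odi_hits & c.truth.positive_species) / len(c.truth.positive_species)
        assert recovered >= 0.8

    def test_complete_case_n_differs_by_exposure(self, medium_cohort):
        c = medium_cohort
        cas = run_cascade(c.analysis_exposures, c.abundance, c.covariates)
        t1 = cas.table[cas.table.stage == 1]
        n_ahi = t1[t1.exposure == "ahi"].n.iloc[0]
        n_odi = t1[t1.exposure == "odi"].n.iloc[0]
        assert n_ahi < n_odi  # AHI loses the invalid-flow participants

    def test_null_cohort_rare_hits(self):
        import osagut

        false_rates = []
        for seed in range(3):
            c = osagut.generate_cohort(
                osagut.CohortConfig(
                    n_participants=400, n_species=80, n_ko=300, n_gmm=8,
                    effect_size=0.0, n_confounded=0, confounding_strength=0.0,
                    bp_effect=0.0, seed=100 + seed,
                )
            )
            cas = run_cascade(c.analysis_exposures, c.abundance, c.covariates)
            n_retained = len(cas.retained_species)
            total_hits = sum(len(v) for v in cas.hits.values())
            false_rates.append(total_hits / (3 * n_retained))
        assert np.mean(false_rates) <= 0.05

    def test_empty_stage1_gives_empty_downstream(self, rng):
        n = 120
        exposures = pd.DataFrame({"odi": rng.normal(size=n)})
        ab = pd.DataFrame(
            rng.dirichlet(np.ones(10), size=n), columns=[f"s{i}" for i in range(10)]
        )
        cov = pd.DataFrame({"age": rng.uniform(50, 64, n)})
        from osagut.association import ModelSpec

        models = {
            "screening": ModelSpec("screening", ("age",)),
            "main": ModelSpec("main", ("age",)),
            "extended": ModelSpec("extended", ("age",)),
        }
        cas = run_cascade(exposures, ab, cov, models=models, exposure_names=("odi",))
        assert cas.hits["odi"] == []
        assert (cas.table.stage == 1).all()


class TestSensitivity:
    def test_clean_cohort_variants_match_extended(self):
        import osagut

        cfg = osagut.CohortConfig(
            n_participants=400, n_species=60, n_ko=300, n_gmm=8,
            n_true_pos=5, n_true_neg=5, n_confounded=3,
            metformin_prevalence=0.0, ppi_prevalence=0.0,
            antihypertensive_prevalence=0.0, lipid_med_prevalence=0.0,
            antibiotic_prevalence=0.0, lung_disease_prevalence=0.0,
            antidiabetic_prevalence=0.0, seed=55,
        )
        c = osagut.generate_cohort(cfg)
        cas = run_cascade(c.analysis_exposures, c.abundance, c.covariates)
        sens = sensitivity_suite(cas.hits, c.analysis_exposures, c.abundance, c.covariates)
        ext = cas.table[cas.table.stage == 3]
        for name in ("no_antibiotics", "no_lung_disease"):
            merged = sens[name].merge(
                ext, on=["exposure", "feature"], suffixes=("_v", "_e")
            )
            assert np.allclose(merged.rho_v, merged.rho_e, atol=1e-12)
            assert (merged.n_v == merged.n_e).all()

    def test_exclusion_bookkeeping(self, medium_cohort):
        c = medium_cohort
        cas = run_cascade(c.analysis_exposures, c.abundance, c.covariates)
        sens = sensitivity_suite(cas.hits, c.analysis_exposures, c.abundance, c.covariates)
        ext = cas.table[(cas.table.stage == 3) & (cas.table.exposure == "odi")]
        v = sens["no_antibiotics"]
        v_odi = v[v.exposure == "odi"]
        flagged = c.covariates["antibiotic_6mo"].astype(bool)
        cov_cols = list(default_models()["extended"].covariates)
        eligible = (
            c.analysis_exposures["odi"].notna()
            & c.covariates[cov_cols].notna().all(axis=1)
        )
        expected_n = int((eligible & ~flagged).sum())
        assert (v_odi.n == expected_n).all()

    def test_planted_hits_survive_variants(self, medium_cohort):
        c = medium_cohort
        cas = run_cascade(c.analysis_exposures, c.abundance, c.covariates)
        sens = sensitivity_suite(cas.hits, c.analysis_exposures, c.abundance, c.covariates)
        planted = c.truth.positive_species | c.truth.negative_species
        for name, table in sens.items():
            sub = table[table.feature.isin(planted)]
            assert sub.retained.mean() >= 0.9, name
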