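"""Validation-stage statistics against enumeration oracles and simulations."""

import numpy as np
import pandas as pd
import pytest
from _oracles import hwe_oracle, mw_exact_oracle
from scipy import stats

from poolgwas.validate import (
    backward_stepwise,
    bonferroni_threshold,
    case_control_allele_test,
    compare_outcome_models,
    fit_logistic,
    hwe_exact_p,
    ifn_activity_score,
    ifn_by_genotype,
    make_combination_outcome,
    mann_whitney,
    odds_ratio_ci,
    pca_ancestry,
    qc_genotypes,
    refit_with_ancestry_covariate,
)

# ---------------------------------------------------------------------------
# Hardy-Weinberg QC


class TestHWE:
    def test_equilibrium_table_passes(self):
        # (AA=25, Aa=50, aa=25) sits at the HWE mode
        p = hwe_exact_p(50, 25, 25)
        assert p == pytest.approx(hwe_oracle(50, 25, 25))
        assert p > 0.01

    @pytest.mark.parametrize("counts", [(0, 0, 30), (0, 30, 0)])
    def test_monomorphic_is_p_one(self, counts):
        assert hwe_exact_p(*counts) == 1.0

    def test_matches_enumeration_oracle_exhaustively(self):
        """Every genotype table with up to 12 subjects, plus random larger ones."""
        for n in range(1, 13):
            for het in range(n + 1):
                for hom_minor in range(n - het + 1):
                    hom_major = n - het - hom_minor
                    assert hwe_exact_p(het, hom_minor, hom_major) == pytest.approx(
                        hwe_oracle(het, hom_minor, hom_major), rel=1e-10
                    )
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(13, 51))
            het = int(rng.integers(0, n + 1))
            hom_minor = int(rng.integers(0, n - het + 1))
            assert hwe_exact_p(het, hom_minor, n - het - hom_minor) == pytest.approx(
                hwe_oracle(het, hom_minor, n - het - hom_minor), rel=1e-10
            )

    def test_gross_disequilibrium_detected(self):
        # all homozygotes, no heterozygotes: flagrant HWE violation
        assert hwe_exact_p(0, 20, 20) < 1e-6


class TestGenotypeQC:
    def _subjects(self, genos, ancestry="African"):
        return pd.DataFrame(
            {
                "subject": [f"V{i}" for i in range(len(genos))],
                "ancestry": ancestry,
                "role": "validation_case",
                "snp00001": genos,
            }
        )

    def test_clean_snp_passes(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        report = qc_genotypes(self._subjects(g), ["snp00001"])
        assert bool(report.iloc[0]["pass"])

    def test_low_call_rate_fails(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        g[:15] = np.nan  # call rate 0.97
        report = qc_genotypes(self._subjects(g), ["snp00001"])
        assert report.iloc[0]["call_rate"] == pytest.approx(0.97)
        assert not bool(report.iloc[0]["pass"])

    def test_monomorphic_snp_passes_hwe(self):
        report = qc_genotypes(self._subjects([0.0] * 50), ["snp00001"])
        assert report.iloc[0]["hwe_p_African"] == 1.0
        assert bool(report.iloc[0]["pass"])

    def test_hwe_checked_within_each_ancestry(self, rng):
        # balanced within each ancestry, violating only when one is broken
        g_afr = np.array([1.0] * 0 + [0.0] * 25 + [2.0] * 25)  # no hets
        g_eur = rng.binomial(2, 0.5, 50).astype(float)
        subjects = pd.concat(
            [
                self._subjects(g_afr, "African"),
                self._subjects(g_eur, "European"),
            ],
            ignore_index=True,
        )
        report = qc_genotypes(subjects, ["snp00001"])
        assert report.iloc[0]["hwe_p_African"] < 0.01
        assert not bool(report.iloc[0]["pass"])


# ---------------------------------------------------------------------------
# logistic models


def _sim_logistic(rng, n, or_true, maf=0.3, base_p=0.2):
    g = rng.binomial(2, maf, n).astype(float)
    p = 1 / (1 + np.exp(-(np.log(base_p / (1 - base_p)) + np.log(or_true) * g)))
    y = (rng.random(n) < p).astype(float)
    return pd.Series(y, name="ab"), pd.DataFrame({"g": g})


class TestFitLogistic:
    def test_constant_predictor_flagged(self):
        y = pd.Series([0, 1, 0, 1, 1, 0], dtype=float)
        X = pd.DataFrame({"g": [1.0] * 6})
        fit = fit_logistic(y, X)
        assert not fit.ok and "constant_predictor" in fit.flag

    def test_single_class_outcome_flagged(self):
        y = pd.Series([1.0] * 10)
        X = pd.DataFrame({"g": np.arange(10, dtype=float)})
        assert fit_logistic(y, X).flag == "single_class_outcome"

    def test_ci_coverage_of_true_or(self, rng):
        """True OR 3.0 falls inside its own 95% CI in >= 93% of replicates."""
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            y, X = _sim_logistic(rng, 1000, 3.0)
            fit = fit_logistic(y, X)
            if not fit.ok:
                continue
            _, lo, hi = fit.odds_ratios["g"]
            hits += lo <= 3.0 <= hi
        assert hits / n_rep >= 0.93

    def test_null_wald_p_uniform(self, rng):
        """Under no association the Wald P-values are uniform (KS < 0.05)."""
        pvals = []
        for _ in range(2000):
            y, X = _sim_logistic(rng, 200, 1.0)
            fit = fit_logistic(y, X)
            if fit.ok:
                pvals.append(fit.pvalues["g"])
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.05

    def test_complete_cases_only(self, rng):
        y, X = _sim_logistic(rng, 200, 2.0)
        X.loc[:9, "g"] = np.nan
        fit = fit_logistic(y, X)
        assert fit.n == 190


class TestOddsRatioCI:
    def test_null_coefficient(self):
        or_, lo, hi = odds_ratio_ci(0.0, 0.2)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_closed_form_ln2(self):
        or_, lo, hi = odds_ratio_ci(np.log(2), 0.1)
        assert (round(or_, 2), round(lo, 2), round(hi, 2)) == (2.0, 1.64, 2.43)

    def test_reproduces_published_style_interval(self):
        # se back-computed from a printed 2.40 (1.51 to 3.81) interval
        or_, lo, hi = odds_ratio_ci(0.8755, 0.2361)
        assert (round(or_, 2), round(lo, 2), round(hi, 2)) == (2.40, 1.51, 3.81)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_ci(0.5, 0.0)


class TestBackwardStepwise:
    def test_null_predictor_removed_at_stay_rate(self, rng):
        """A single null predictor survives ~alpha_stay of the time."""
        kept = 0
        n_rep = 400
        for _ in range(n_rep):
            y, X = _sim_logistic(rng, 400, 1.0)
            res = backward_stepwise(y, X, test_interactions=False)
            kept += len(res.fit.terms) > 0
        rate = kept / n_rep
        se = np.sqrt(0.1 * 0.9 / n_rep)
        assert abs(rate - 0.1) < 2.5 * se + 0.01

    def test_strong_predictor_retained_among_nulls(self, rng):
        retained = 0
        n_rep = 60
        for _ in range(n_rep):
            y, X = _sim_logistic(rng, 1000, 3.0)
            for j in range(4):
                X[f"null{j}"] = rng.binomial(2, 0.3, 1000).astype(float)
            res = backward_stepwise(y, X, test_interactions=False)
            retained += "g" in res.fit.terms
        assert retained / n_rep >= 0.95

    def test_empty_model_is_valid_result(self, rng):
        y = pd.Series((rng.random(300) < 0.3).astype(float))
        X = pd.DataFrame({"flat": [1.0] * 300})  # degenerate, gets dropped
        res = backward_stepwise(y, X)
        assert res.fit.terms == ()
        assert res.eliminated == ("flat",)

    def test_kept_covariates_survive_elimination(self, rng):
        y, X = _sim_logistic(rng, 400, 1.0)
        X["anc"] = rng.binomial(1, 0.5, 400).astype(float)
        res = backward_stepwise(y, X, keep=("anc",), test_interactions=False)
        assert "anc" in res.fit.terms


class TestCombinationOutcomes:
    def test_both_positive_rule(self):
        x = pd.Series([1.0, 1.0, 0.0, np.nan])
        y = pd.Series([1.0, 0.0, 1.0, 1.0])
        out = make_combination_outcome(x, y, "both_positive")
        assert out.tolist()[:3] == [1.0, 0.0, 0.0]
        assert np.isnan(out.iloc[3])

    def test_positive_negative_rule(self):
        x = pd.Series([1.0, 1.0, 0.0])
        y = pd.Series([1.0, 0.0, 0.0])
        out = make_combination_outcome(x, y, "x_positive_y_negative")
        assert out.tolist() == [0.0, 1.0, 0.0]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            make_combination_outcome(pd.Series([1.0]), pd.Series([0.0]), "xor")

    def test_identical_fits_keep_first_without_switch(self, rng):
        y, X = _sim_logistic(rng, 300, 2.0)
        fit = fit_logistic(y, X, name="ro")
        chosen, table = compare_outcome_models([fit, fit])
        assert chosen is fit
        assert table["delta_aic"].abs().max() == 0.0

    def test_small_aic_gain_keeps_individual_model(self):
        from poolgwas.validate import AssociationFit

        ind = AssociationFit(outcome="ro", terms=("g",), aic=100.0)
        combo = AssociationFit(outcome="ro+dsdna", terms=("g",), aic=98.5)
        chosen, _ = compare_outcome_models([ind, combo])
        assert chosen is ind

    def test_combination_wins_when_genotype_drives_joint_phenotype(self, rng):
        """Genotype -> joint Ro+dsDNA positivity: combination model fits best."""
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 500
            g = rng.binomial(2, 0.3, n).astype(float)
            # joint phenotype from a logistic model on genotype
            pj = 1 / (1 + np.exp(-(np.log(0.08 / 0.92) + np.log(3.5) * g)))
            joint = rng.random(n) < pj
            ro = np.where(joint, 1.0, (rng.random(n) < 0.25).astype(float))
            dsdna = np.where(joint, 1.0, (rng.random(n) < 0.3).astype(float))
            # avoid accidental joint positivity among non-joint subjects
            both = (~joint) & (ro == 1) & (dsdna == 1)
            dsdna[both] = 0.0
            X = pd.DataFrame({"g": g})
            fits = [
                fit_logistic(pd.Series(ro), X, name="ro"),
                fit_logistic(pd.Series(dsdna), X, name="dsdna"),
            ]
            fits.sort(key=lambda f: f.aic)
            combo = fit_logistic(
                make_combination_outcome(pd.Series(ro), pd.Series(dsdna), "both_positive"),
                X,
                name="ro+dsdna",
            )
            chosen, _ = compare_outcome_models([fits[0], fits[1], combo])
            wins += chosen.outcome == "ro+dsdna"
        assert wins / n_rep >= 0.90


# ---------------------------------------------------------------------------
# IFN-α comparisons


class TestIFN:
    def test_activity_score_standardization(self):
        assert ifn_activity_score(1.0, 1.0, 0.5) == 0.0
        assert ifn_activity_score(2.0, 1.0, 0.5) == 2.0
        assert ifn_activity_score(3.2, 1.0, 0.5) == pytest.approx(4.4)
        with pytest.raises(ValueError):
            ifn_activity_score(1.0, 0.0, 0.0)

    def test_exact_p_hand_enumerated(self):
        # U = 0 with groups of 3: 2/20 arrangements as extreme
        cmp_ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert cmp_.u_statistic == 0.0
        assert cmp_.pvalue == pytest.approx(0.1)
        assert cmp_.method == "exact"

    def test_identical_samples_p_one(self):
        cmp_ = mann_whitney([1, 2, 3], [1, 2, 3])
        assert cmp_.pvalue == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_instances(self, rng):
        for _ in range(60):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            pooled = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
            x, y = pooled[:n1], pooled[n1:]
            assert mann_whitney(x, y).pvalue == pytest.approx(
                mw_exact_oracle(list(x), list(y))
            )

    def test_power_against_shifted_lognormal(self, rng):
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x = np.exp(rng.normal(0.5, 1.0, 200))
            y = np.exp(rng.normal(0.0, 1.0, 200))
            hits += mann_whitney(x, y).pvalue < 0.01
        assert hits / n_rep >= 0.95

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_carrier_grouping(self, rng):
        subjects = pd.DataFrame(
            {
                "snp00001": rng.binomial(2, 0.4, 300).astype(float),
                "ifn_score": rng.normal(0, 1, 300),
            }
        )
        cmp_ = ifn_by_genotype(subjects, "snp00001", grouping="carrier")
        carriers = (subjects["snp00001"] > 0).sum()
        assert cmp_.n_x == carriers
        assert cmp_.n_y == 300 - carriers


# ---------------------------------------------------------------------------
# case-control allelic test


class TestAllelicTest:
    def test_equal_frequencies_or_one(self):
        cases = [1.0] * 50 + [0.0] * 50
        res = case_control_allele_test(cases, cases)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_hand_computed_contingency(self):
        """Allele table 30/170 vs 20/180: OR and chi-square by hand."""
        # genotypes summing to those allele counts
        cases = [1.0] * 30 + [0.0] * 70  # 200 alleles, 30 minor
        controls = [1.0] * 20 + [0.0] * 80
        res = case_control_allele_test(cases, controls)
        assert res.table == ((30, 170), (20, 180))
        assert res.odds_ratio == pytest.approx(30 * 180 / (170 * 20))
        # hand chi-square without continuity correction
        obs = np.array([[30, 170], [20, 180]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert res.chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_null_p_uniform_at_study_scale(self, rng):
        pvals = []
        for _ in range(500):
            cases = rng.binomial(2, 0.3, 538).astype(float)
            controls = rng.binomial(2, 0.3, 522).astype(float)
            pvals.append(case_control_allele_test(cases, controls).pvalue)
        assert stats.kstest(pvals, "uniform").statistic < 0.07

    def test_zero_cell_flagged(self):
        res = case_control_allele_test([0.0] * 10, [1.0] * 5 + [0.0] * 5)
        assert res.flag is not None
        assert np.isnan(res.odds_ratio)


class TestBonferroni:
    def test_printed_thresholds(self):
        assert float(f"{bonferroni_threshold(0.05, 7):.1e}") == 7.1e-3
        assert float(f"{bonferroni_threshold(0.05, 35):.1e}") == 1.4e-3

    def test_single_test_unchanged(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


# ---------------------------------------------------------------------------
# ancestry principal components


def _two_pop_genotypes(rng, n_per=300, n_snps=13, sep=0.4):
    f1 = rng.uniform(0.1, 0.5, n_snps)
    f2 = np.clip(f1 + sep, 0.0, 0.99)
    g1 = rng.binomial(2, f1, size=(n_per, n_snps)).astype(float)
    g2 = rng.binomial(2, f2, size=(n_per, n_snps)).astype(float)
    geno = pd.DataFrame(
        np.vstack([g1, g2]), columns=[f"snp{i}" for i in range(n_snps)]
    )
    labels = pd.Series(["African"] * n_per + ["European"] * n_per)
    return geno, labels


class TestAncestryPCA:
    def test_separated_populations_high_concordance(self, rng):
        geno, labels = _two_pop_genotypes(rng)
        res = pca_ancestry(geno, labels)
        assert res.concordance["African"] > 0.9
        assert res.concordance["European"] > 0.9
        assert res.pvalue < 1e-10
        assert res.bin_labels["African"] != res.bin_labels["European"]

    def test_identical_populations_near_chance(self, rng):
        geno, labels = _two_pop_genotypes(rng, sep=0.0)
        res = pca_ancestry(geno, labels)
        assert 0.5 <= res.concordance["African"] < 0.62
        assert 0.5 <= res.concordance["European"] < 0.62

    def test_single_fixed_difference_snp_perfect(self):
        geno = pd.DataFrame({"snp0": [0.0] * 20 + [2.0] * 20})
        labels = pd.Series(["African"] * 20 + ["European"] * 20)
        res = pca_ancestry(geno, labels)
        assert res.concordance == {"African": 1.0, "European": 1.0}

    def test_constant_matrix_rejected(self):
        geno = pd.DataFrame({"snp0": [1.0] * 10})
        with pytest.raises(ValueError):
            pca_ancestry(geno, pd.Series(["A"] * 10))

    def test_sign_convention_first_subject_nonnegative(self, rng):
        geno, labels = _two_pop_genotypes(rng)
        res = pca_ancestry(geno, labels)
        assert res.scores.iloc[0] >= 0

    def test_bins_partition_subjects(self, rng):
        geno, labels = _two_pop_genotypes(rng)
        res = pca_ancestry(geno, labels)
        assert res.bins.isin(["upper", "lower"]).all()
        assert len(res.bins) == len(geno)


class TestAncestryRefit:
    def test_orthogonal_pc_leaves_coefficient(self, rng):
        y, X = _sim_logistic(rng, 2000, 2.0)
        pc1 = pd.Series(rng.normal(0, 1, 2000))
        res = refit_with_ancestry_covariate(y, X, pc1)
        assert abs(res.coef_change["g"]) < 0.1

    def test_confounded_coefficient_attenuates(self, rng):
        n = 3000
        anc = rng.binomial(1, 0.5, n).astype(float)
        g = rng.binomial(2, np.where(anc == 1, 0.5, 0.15)).astype(float)
        p = 1 / (1 + np.exp(-(-1.5 + 1.2 * anc)))  # ancestry drives outcome
        y = pd.Series((rng.random(n) < p).astype(float))
        X = pd.DataFrame({"g": g})
        pc1 = pd.Series(anc + rng.normal(0, 0.1, n))  # PC1 tracks ancestry
        res = refit_with_ancestry_covariate(y, X, pc1)
        assert abs(res.with_pc.coef["g"]) < abs(res.without_pc.coef["g"])

    def test_constant_pc_flagged(self, rng):
        y, X = _sim_logistic(rng, 300, 2.0)
        res = refit_with_ancestry_covariate(y, X, pd.Series([1.0] * 300))
        assert not res.with_pc.ok
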