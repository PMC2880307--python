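"""Variance decomposition, heritability, genetic correlations, Holm, ANCOVA."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import panelgen as pg
from panelgen.quantgen import UnbalancedDesignError
from conftest import make_pheno


def brute_force_ss(pheno, trait):
    """Direct textbook sums of squares for the balanced two-way layout."""
    grand = pheno[trait].mean()
    nl = pheno["line"].nunique()
    nr = len(pheno) // (nl * 2)
    ss_l = sum(
        2 * nr * (g[trait].mean() - grand) ** 2
        for _, g in pheno.groupby("line")
    )
    ss_s = sum(
        nl * nr * (g[trait].mean() - grand) ** 2
        for _, g in pheno.groupby("sex")
    )
    line_m = pheno.groupby("line")[trait].mean()
    sex_m = pheno.groupby("sex")[trait].mean()
    cell_m = pheno.groupby(["line", "sex"])[trait].mean()
    ss_ls = nr * sum(
        (cell_m[l, s] - line_m[l] - sex_m[s] + grand) ** 2
        for l, s in cell_m.index
    )
    ss_e = sum(
        (row[trait] - cell_m[row["line"], row["sex"]]) ** 2
        for _, row in pheno.iterrows()
    )
    return ss_l, ss_s, ss_ls, ss_e


class TestLineSexAnova:
    def test_all_identical_observations_degenerate(self):
        ph = make_pheno({(l, s): [7.0, 7.0] for l in ("L1", "L2")
                         for s in ("female", "male")})
        vd = pg.fit_line_sex_anova(ph, "trait")
        assert vd.sigma2_line == vd.sigma2_line_sex == vd.sigma2_error == 0.0
        assert vd.degenerate
        assert math.isnan(vd.f_line)

    def test_mean_squares_match_brute_force(self, toy_pheno_2x2x2):
        vd = pg.fit_line_sex_anova(toy_pheno_2x2x2, "trait")
        ss_l, ss_s, ss_ls, ss_e = brute_force_ss(toy_pheno_2x2x2, "trait")
        assert vd.ms_line * vd.df_line == pytest.approx(ss_l, rel=1e-12)
        assert vd.ms_sex * vd.df_sex == pytest.approx(ss_s, rel=1e-12)
        assert vd.ms_line_sex * vd.df_line_sex == pytest.approx(ss_ls, rel=1e-12)
        assert vd.ms_error * vd.df_error == pytest.approx(ss_e, rel=1e-12)
        assert (vd.df_line, vd.df_sex, vd.df_line_sex, vd.df_error) == (1, 1, 1, 4)

    def test_sum_of_squares_conservation(self, panel_pheno):
        vd = pg.fit_line_sex_anova(panel_pheno, "trait")
        total = ((panel_pheno["trait"] - panel_pheno["trait"].mean()) ** 2).sum()
        parts = (vd.ms_line * vd.df_line + vd.ms_sex * vd.df_sex
                 + vd.ms_line_sex * vd.df_line_sex + vd.ms_error * vd.df_error)
        assert parts == pytest.approx(total, rel=1e-9)

    def test_unbalanced_table_rejected(self, toy_pheno_2x2x2):
        unbal = toy_pheno_2x2x2.drop(index=0)
        with pytest.raises(UnbalancedDesignError):
            pg.fit_line_sex_anova(unbal, "trait")

    def test_negative_component_truncated_and_flagged(self):
        # strong error variance, no line signal -> raw line component often < 0
        rng = np.random.default_rng(0)
        for seed in range(20):
            design = pg.ExperimentDesign(n_lines=5, n_reps=3)
            tv = pg.TrueVariances(sigma2_line=0.0, sigma2_line_sex=0.0, sigma2_error=2.0)
            ph = pg.simulate_phenotypes(design, tv, seed=seed)
            vd = pg.fit_line_sex_anova(ph, "trait")
            assert vd.sigma2_line >= 0.0 and vd.sigma2_line_sex >= 0.0
            if vd.truncated_line or vd.truncated_line_sex:
                return
        pytest.fail("no truncation observed across 20 null simulations")


class TestHeritability:
    @pytest.mark.parametrize(
        "s2l, s2ls, s2e, expected",
        [(1.0, 0.5, 4.5, 0.25), (1.0, 0.0, 0.0, 1.0), (0.0, 0.0, 3.0, 0.0)],
    )
    def test_ratio_arithmetic(self, toy_pheno_2x2x2, s2l, s2ls, s2e, expected):
        vd = pg.fit_line_sex_anova(toy_pheno_2x2x2, "trait")
        forced = dataclasses.replace(
            vd, sigma2_line=s2l, sigma2_line_sex=s2ls, sigma2_error=s2e)
        h2 = pg.broad_sense_heritability(forced)
        assert h2.h2 == pytest.approx(expected)
        assert not h2.degenerate

    def test_zero_total_variance_flagged(self, toy_pheno_2x2x2):
        vd = pg.fit_line_sex_anova(toy_pheno_2x2x2, "trait")
        forced = dataclasses.replace(
            vd, sigma2_line=0.0, sigma2_line_sex=0.0, sigma2_error=0.0)
        h2 = pg.broad_sense_heritability(forced)
        assert h2.h2 == 0.0 and h2.degenerate


class TestCrossSexCorrelation:
    def test_identical_sexes_no_noise_gives_unity(self):
        vals = {("L%d" % i, s): [float(i), float(i)] for i in range(1, 7)
                for s in ("female", "male")}
        r = pg.cross_sex_correlation(make_pheno(vals), "trait")
        assert r.r_mf == pytest.approx(1.0, abs=1e-10)

    def test_constant_one_sex_raises(self):
        vals = {}
        for i in range(1, 6):
            vals[("L%d" % i, "female")] = [float(i), float(i)]
            vals[("L%d" % i, "male")] = [3.0, 3.0]
        with pytest.raises(ValueError, match="undefined"):
            pg.cross_sex_correlation(make_pheno(vals), "trait")

    def test_five_line_toy_matches_direct_arithmetic(self):
        rng = np.random.default_rng(3)
        vals = {}
        for i in range(1, 6):
            for s in ("female", "male"):
                vals[("L%d" % i, s)] = list(rng.normal(i, 1.0, size=4))
        ph = make_pheno(vals)
        res = pg.cross_sex_correlation(ph, "trait")
        # brute force: line means per sex, covariance / ANOVA sigma product
        means = ph.groupby(["line", "sex"])["trait"].mean().unstack()
        cov = np.cov(means["female"], means["male"], ddof=1)[0, 1]
        sigs = {}
        for s in ("female", "male"):
            sub = ph[ph["sex"] == s]
            lm = sub.groupby("line")["trait"].mean()
            ms_line = 4 * ((lm - sub["trait"].mean()) ** 2).sum() / 4
            ms_err = ((sub["trait"] - sub["line"].map(lm)) ** 2).sum() / (5 * 3)
            sigs[s] = math.sqrt(max(0.0, (ms_line - ms_err) / 4))
        assert res.r_mf == pytest.approx(cov / (sigs["female"] * sigs["male"]), abs=1e-12)

    def test_shared_line_effects_recovered_near_one(self, study_design):
        tv = pg.TrueVariances(sigma2_line=2.0, sigma2_line_sex=0.0, sigma2_error=0.5)
        rs = [pg.cross_sex_correlation(
            pg.simulate_phenotypes(study_design, tv, seed=200 + i), "trait").r_mf
            for i in range(100)]
        assert np.mean(rs) >= 0.9

    def test_independent_per_sex_effects_near_zero(self, study_design):
        tv = pg.TrueVariances(sigma2_line=0.0, sigma2_line_sex=2.0, sigma2_error=0.5)
        rs = [pg.cross_sex_correlation(
            pg.simulate_phenotypes(study_design, tv, seed=300 + i), "trait").r_mf
            for i in range(100)]
        assert abs(np.mean(rs)) <= 0.1


class TestTraitCorrelation:
    def test_exact_linear_dependence_gives_unity(self):
        rng = np.random.default_rng(1)
        vals = {}
        for i in range(1, 8):
            base = rng.normal(i, 0.0, size=3)
            for s in ("female", "male"):
                vals[("L%d" % i, s)] = list(base)
        ph = make_pheno(vals)
        ph["trait2"] = 2.0 * ph["trait"]
        res = pg.trait_correlation(ph, "trait", "trait2", scope="pooled")
        assert res.r_gt == pytest.approx(1.0, abs=1e-9)

    def test_se_convention_reproduces_printed_value(self):
        """SE = sqrt((1 - r^2)/(n - 2)): r = -0.38 at 40 lines -> 0.15 at 2 dp."""
        se = math.sqrt((1 - 0.38**2) / (40 - 2))
        assert round(se, 2) == 0.15

    def test_type_i_error_calibration(self, study_design):
        """Independent traits: fraction of p < 0.05 stays near nominal.

        Components chosen so line means estimate genetic values almost
        exactly (the correlation's p uses ANOVA sigmas in the denominator).
        """
        tv = pg.TrueVariances(sigma2_line=2.0, sigma2_line_sex=0.0, sigma2_error=0.1)
        n_sims, hits = 2000, 0
        master = np.random.default_rng(0)  # per-replicate seeds from one stream
        for _ in range(n_sims):
            s1, s2 = master.integers(2**31, size=2)
            ph = pg.simulate_phenotypes(study_design, tv, seed=s1, trait="t1")
            ph["t2"] = pg.simulate_phenotypes(study_design, tv, seed=s2,
                                              trait="t2")["t2"]
            if pg.trait_correlation(ph, "t1", "t2", "pooled").p < 0.05:
                hits += 1
        assert 0.04 <= hits / n_sims <= 0.06

    def test_insufficient_lines_rejected(self):
        vals = {("L%d" % i, s): [1.0 * i, 2.0] for i in range(1, 4)
                for s in ("female", "male")}
        ph = make_pheno(vals)
        ph["trait2"] = ph["trait"]
        with pytest.raises(ValueError):
            pg.trait_correlation(ph, "trait", "trait2")


class TestCoefficientsOfVariation:
    def test_direct_formula(self, toy_pheno_2x2x2):
        vd = pg.fit_line_sex_anova(toy_pheno_2x2x2, "trait")
        forced = dataclasses.replace(
            vd, sigma2_line=3.0, sigma2_line_sex=1.0, sigma2_error=4.0)
        cv = pg.coefficients_of_variation(forced, mean=20.0)
        assert cv.cv_g == pytest.approx(10.0)
        assert cv.cv_e == pytest.approx(10.0)

    def test_zero_mean_rejected(self, toy_pheno_2x2x2):
        vd = pg.fit_line_sex_anova(toy_pheno_2x2x2, "trait")
        with pytest.raises(ValueError):
            pg.coefficients_of_variation(vd, mean=0.0)


def brute_force_holm(pvals, alpha):
    """Largest prefix of the sorted p-values all clearing their step thresholds."""
    order = np.argsort(pvals, kind="mergesort")
    m = len(pvals)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


class TestSequentialBonferroni:
    def test_hand_worked_step_down(self):
        flags = pg.sequential_bonferroni([0.001, 0.01, 0.02, 0.04], alpha=0.05)
        assert flags.tolist() == [True, True, True, True]

    def test_single_test_reduces_to_plain_threshold(self):
        assert pg.sequential_bonferroni([0.04], alpha=0.05).tolist() == [True]
        assert pg.sequential_bonferroni([0.06], alpha=0.05).tolist() == [False]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            pg.sequential_bonferroni([0.5, 1.2])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_brute_force_and_dominates_bonferroni(self, pvals, alpha):
        p = np.array(pvals)
        flags = pg.sequential_bonferroni(p, alpha=alpha)
        assert flags.tolist() == brute_force_holm(p, alpha).tolist()
        plain = p <= alpha / len(p)
        assert (flags | ~plain).all()  # Holm rejects a superset of Bonferroni

    def test_matches_statsmodels_on_random_inputs(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 12))
            expected, *_ = multipletests(p, alpha=0.05, method="holm")
            assert pg.sequential_bonferroni(p, 0.05).tolist() == expected.tolist()


class TestMutantAncova:
    @staticmethod
    def _table(rng, n, shift=0.0, slope=1.5):
        rows = []
        for s in ("female", "male"):
            cov = rng.uniform(5, 10, size=n)
            y = 2.0 + shift + slope * cov + rng.normal(0, 1.0, size=n)
            for k in range(n):
                rows.append(("X", s, f"V{k:02d}", y[k], cov[k]))
        return pd.DataFrame(rows, columns=["line", "sex", "vial", "tag", "protein"])

    def test_identical_groups_give_zero_f(self):
        rng = np.random.default_rng(0)
        t = self._table(rng, 10)
        res = pg.mutant_ancova(t, t.copy(), covariate="protein", trait="tag")
        assert res.f_genotype == pytest.approx(0.0, abs=1e-8)
        assert res.p_genotype == pytest.approx(1.0, abs=1e-6)
        assert res.lsmeans["mutant"] == pytest.approx(res.lsmeans["control"])

    def test_power_for_three_sigma_shift(self):
        hits = 0
        for i in range(100):
            rng = np.random.default_rng(500 + i)
            mut = self._table(rng, 20, shift=3.0)
            ctl = self._table(rng, 20, shift=0.0)
            if pg.mutant_ancova(mut, ctl, "protein", "tag").p_genotype < 0.01:
                hits += 1
        assert hits >= 95

    def test_matches_normal_equations_oracle(self):
        """8-observation stratified ANCOVA vs direct linear algebra."""
        from scipy import stats as sps
        mut = pd.DataFrame({
            "line": "A", "sex": "female", "vial": [f"V{i}" for i in range(4)],
            "tag": [3.1, 4.0, 5.2, 6.1], "protein": [1.0, 2.0, 3.0, 4.0]})
        ctl = pd.DataFrame({
            "line": "B", "sex": "female", "vial": [f"V{i}" for i in range(4)],
            "tag": [2.0, 3.5, 4.1, 5.9], "protein": [1.1, 2.1, 2.9, 4.2]})
        res = pg.mutant_ancova(mut, ctl, "protein", "tag", scope="female")
        y = np.array([3.1, 4.0, 5.2, 6.1, 2.0, 3.5, 4.1, 5.9])
        g = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        c = np.array([1.0, 2.0, 3.0, 4.0, 1.1, 2.1, 2.9, 4.2])
        ones = np.ones(8)
        x_full = np.column_stack([ones, g, c])
        x_red = np.column_stack([ones, c])

        def sse(x):
            b = np.linalg.solve(x.T @ x, x.T @ y)
            r = y - x @ b
            return r @ r

        f = (sse(x_red) - sse(x_full)) / (sse(x_full) / 5)
        p = sps.f.sf(f, 1, 5)
        assert res.p_genotype == pytest.approx(p, abs=1e-10)

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(1)
        t = self._table(rng, 5)
        t["protein"] = 7.0
        with pytest.raises(ValueError, match="rank-deficient|constant"):
            pg.mutant_ancova(t, t.copy(), "protein", "tag")
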