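"""Relative fitness, genetic-architecture estimation, line selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antagene.fitness import (
    GeneticArchitecture,
    coefficient_of_variation,
    compute_relative_fitness,
    fit_bivariate_components,
    heritability,
    relative_fitness_from_values,
    reml_anova_components,
    select_lines,
)
from antagene.simulate import FitnessSimConfig, simulate_fitness_study


def _assay_table(values: dict[tuple[str, str], list[float]]) -> pd.DataFrame:
    rows = [
        (line, sex, i + 1, v)
        for (line, sex), vs in values.items()
        for i, v in enumerate(vs)
    ]
    return pd.DataFrame(rows, columns=["line", "sex", "replicate", "value"])


class TestRelativeFitness:
    def test_single_line_self_normalises_to_one(self):
        rf = compute_relative_fitness(
            _assay_table({("A", "F"): [17.0], ("A", "M"): [0.4]})
        )
        assert (rf.line_means["rel_fitness"] == 1.0).all()

    def test_hand_computed_progeny_counts(self):
        rf = compute_relative_fitness(
            _assay_table(
                {("A", "F"): [10, 20], ("B", "F"): [30, 40], ("C", "F"): [25, 15]}
            )
        )
        means = rf.line_means.set_index("line")["rel_fitness"]
        assert means["A"] == pytest.approx(0.375)
        assert means["B"] == pytest.approx(0.875)
        assert means["C"] == pytest.approx(0.5)

    def test_per_sex_maximum_replicate_value_is_one(self, default_fitness_study):
        _, assays, _ = default_fitness_study
        rf = compute_relative_fitness(assays)
        for sex, grp in rf.replicates.groupby("sex"):
            assert grp["rel_value"].max() == pytest.approx(1.0)

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        base = _assay_table(
            {("A", "F"): [10, 20], ("B", "F"): [30, 40],
             ("A", "M"): [0.2, 0.3], ("B", "M"): [0.5, 0.1]}
        )
        scaled = base.copy()
        scaled.loc[scaled["sex"] == "F", "value"] *= c
        a = compute_relative_fitness(base).line_means
        b = compute_relative_fitness(scaled).line_means
        assert np.allclose(a["rel_fitness"], b["rel_fitness"])

    def test_all_zero_sex_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_relative_fitness(
                _assay_table({("A", "F"): [0.0, 0.0], ("A", "M"): [0.1]})
            )


class TestScalarFormulas:
    def test_heritability_published_components(self):
        # hemiclonal x2 correction on the printed variance components
        assert heritability(0.0070, 0.0153) == pytest.approx(0.6278, abs=1e-4)
        assert heritability(0.0014, 0.0222) == pytest.approx(0.1186, abs=1e-4)
        assert heritability(0.0, 0.5) == 0.0

    def test_heritability_rejects_degenerate(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)
        with pytest.raises(ValueError):
            heritability(-0.1, 0.2)

    def test_cv_formula_and_published_ratio(self):
        assert coefficient_of_variation(0.0225, 0.5) == pytest.approx(30.0)
        assert coefficient_of_variation(0.0, 0.5) == 0.0
        # CV_A/CV_R depends only on the variance ratio, matching the
        # published female values 21.28/31.49
        ratio = np.sqrt(0.0070 / 0.0153)
        assert ratio == pytest.approx(21.28 / 31.49, abs=2e-3)

    def test_cv_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(0.1, 0.0)


class TestAnovaComponents:
    def test_within_line_constant_data(self):
        rf = relative_fitness_from_values(
            _assay_table(
                {("A", "F"): [0.2, 0.2], ("B", "F"): [0.6, 0.6],
                 ("C", "F"): [0.4, 0.4],
                 ("A", "M"): [0.5, 0.5], ("B", "M"): [0.3, 0.3],
                 ("C", "M"): [0.1, 0.1]}
            )
        )
        arch = reml_anova_components(rf)
        assert arch.V_resid_f == pytest.approx(0.0)
        assert arch.V_line_f == pytest.approx(np.var([0.2, 0.6, 0.4], ddof=1))

    def test_ms_line_below_ms_resid_floors_at_zero(self):
        # strong within-line spread, identical line means
        rf = relative_fitness_from_values(
            _assay_table(
                {("A", "F"): [0.1, 0.9], ("B", "F"): [0.9, 0.1],
                 ("C", "F"): [0.5, 0.5],
                 ("A", "M"): [0.2, 0.8], ("B", "M"): [0.8, 0.2],
                 ("C", "M"): [0.5, 0.5]}
            )
        )
        arch = reml_anova_components(rf)
        assert arch.V_line_f == 0.0
        assert arch.V_line_m == 0.0

    def test_unbalanced_design_rejected(self):
        tbl = _assay_table(
            {("A", "F"): [0.2, 0.3], ("B", "F"): [0.6],
             ("A", "M"): [0.5], ("B", "M"): [0.3]}
        )
        with pytest.raises(ValueError, match="unbalanced"):
            reml_anova_components(relative_fitness_from_values(tbl))


@pytest.fixture(scope="module")
def default_fit(default_fitness_study):
    _, assays, _ = default_fitness_study
    rf = relative_fitness_from_values(assays)
    arch = fit_bivariate_components(
        rf, n_iter=6000, burn_in=1000, thin=2, n_chains=2, seed=1
    )
    return rf, arch


class TestGibbsSampler:
    def test_posterior_draw_invariants(self, default_fit):
        _, arch = default_fit
        ch = arch.chains
        assert (ch["r_MF"].abs() <= 1).all()
        for c in ("V_line_f", "V_line_m", "V_resid_f", "V_resid_m"):
            assert (ch[c] >= 0).all()

    def test_agrees_with_anova_oracle(self, default_fit):
        rf, arch = default_fit
        oracle = reml_anova_components(rf)
        assert arch.V_resid_f == pytest.approx(oracle.V_resid_f, rel=0.1)
        assert arch.V_resid_m == pytest.approx(oracle.V_resid_m, rel=0.1)
        assert arch.cov_fm == pytest.approx(oracle.cov_fm, abs=8e-4)

    def test_null_genetic_variance_recovery(self):
        cfg = FitnessSimConfig(
            seed=21, n_lines=60, V_line_f=0.0, V_line_m=0.0, r_MF_true=0.0
        )
        assays, _ = simulate_fitness_study(cfg)
        rf = relative_fitness_from_values(assays)
        arch = fit_bivariate_components(
            rf, n_iter=4000, burn_in=1000, thin=2, n_chains=2, seed=2
        )
        lo, hi = arch.ci["r_MF"]
        assert lo <= 0.0 <= hi
        assert arch.V_line_f < 0.005 and arch.V_line_m < 0.005

    def test_near_noiseless_covariance_matches_moment_oracle(self):
        cfg = FitnessSimConfig(
            seed=8, n_lines=200, V_line_f=0.02, V_line_m=0.02, r_MF_true=-0.6,
            V_resid_f=1e-5, V_resid_m=1e-5,
        )
        assays, _ = simulate_fitness_study(cfg)
        rf = relative_fitness_from_values(assays)
        arch = fit_bivariate_components(
            rf, n_iter=6000, burn_in=1000, thin=2, n_chains=2, seed=3
        )
        wide = rf.wide()
        sample_cov = np.cov(wide["F"], wide["M"], ddof=1)[0, 1]
        assert arch.cov_fm == pytest.approx(sample_cov, rel=0.05)

    def test_nonconvergence_flagged_not_silent(self, default_fitness_study):
        _, assays, _ = default_fitness_study
        rf = relative_fitness_from_values(assays)
        arch = fit_bivariate_components(
            rf, n_iter=220, burn_in=200, thin=1, n_chains=1, seed=4,
            ess_floor=1e6,
        )
        assert not arch.converged

    def test_deterministic_given_seed(self, default_fitness_study):
        _, assays, _ = default_fitness_study
        rf = relative_fitness_from_values(assays)
        kw = dict(n_iter=600, burn_in=200, thin=2, n_chains=1, seed=5)
        a1 = fit_bivariate_components(rf, **kw)
        a2 = fit_bivariate_components(rf, **kw)
        pd.testing.assert_frame_equal(a1.chains, a2.chains)


class TestSelectLines:
    def _relfit(self, f_vals, m_vals, reps=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = {}
        for i, (f, m) in enumerate(zip(f_vals, m_vals)):
            line = f"L{i:02d}"
            rows[(line, "F")] = list(f + noise * rng.standard_normal(reps))
            rows[(line, "M")] = list(m + noise * rng.standard_normal(reps))
        return relative_fitness_from_values(_assay_table(rows))

    def test_anticorrelated_ranks_pick_extremes(self):
        n = 20
        f = np.linspace(0.1, 0.9, n)
        m = f[::-1].copy()
        rf = self._relfit(f, m)
        sel = select_lines(rf)
        # rank_m - rank_f extremes sit at the ends of the diagonal
        assert set(sel.high_m_low_f) == {f"L{i:02d}" for i in range(5)}
        assert set(sel.low_m_high_f) == {f"L{i:02d}" for i in range(n - 5, n)}

    def test_groups_disjoint_and_total_fifteen(self, default_fitness_study):
        _, assays, _ = default_fitness_study
        sel = select_lines(relative_fitness_from_values(assays))
        groups = [set(sel.high_m_low_f), set(sel.low_m_high_f), set(sel.average)]
        assert all(len(g) == 5 for g in groups)
        assert len(groups[0] | groups[1] | groups[2]) == 15

    def test_matches_brute_force_oracle_on_20_lines(self):
        rng = np.random.default_rng(42)
        f = rng.uniform(0.1, 1.0, 20)
        m = rng.uniform(0.1, 1.0, 20)
        rf = self._relfit(f, m, noise=0.02, seed=1)
        sel = select_lines(rf)

        # independent oracle: recompute ranks/filter from first principles
        from scipy.stats import rankdata

        lm = rf.line_means.pivot(index="line", columns="sex", values="rel_fitness")
        se = rf.line_means.pivot(index="line", columns="sex", values="se")
        pooled = np.sqrt(se["F"] ** 2 + se["M"] ** 2)
        eligible = pooled[pooled <= pooled.quantile(0.75)].index
        rank_f = pd.Series(rankdata(lm["F"]), index=lm.index)
        rank_m = pd.Series(rankdata(lm["M"]), index=lm.index)
        score = (rank_m - rank_f)[eligible].sort_values(kind="mergesort")
        assert set(sel.low_m_high_f) == set(score.index[:5])
        assert set(sel.high_m_low_f) == set(score.index[-5:])
        med = (len(lm) + 1) / 2
        rest = eligible.difference(score.index[:5].union(score.index[-5:]))
        mid = ((rank_m - med).abs() + (rank_f - med).abs())[rest]
        assert set(sel.average) == set(mid.sort_values(kind="mergesort").index[:5])

    def test_filter_relaxes_with_warning_when_too_few_lines(self):
        n = 16  # quartile filter would leave only 12 eligible
        rng = np.random.default_rng(2)
        f, m = rng.uniform(0.2, 1, n), rng.uniform(0.2, 1, n)
        rf = self._relfit(f, m, noise=0.05, seed=3)
        with pytest.warns(UserWarning, match="relaxed"):
            sel = select_lines(rf)
        assert len(sel.all_lines) == 15

    def test_too_few_lines_rejected(self):
        rf = self._relfit([0.1, 0.5], [0.6, 0.2])
        with pytest.raises(ValueError):
            select_lines(rf)
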