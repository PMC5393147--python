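"""Per-feature regression, fold changes, BH adjustment, group comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypoxamir import (
    ExpressionMatrix,
    bh_adjust,
    differential_groups,
    fit_feature_models,
    fold_changes_vs_reference,
    format_significant_fraction,
    results_frame,
    significant_fraction_pct,
    simulate_mirna_panel,
    simulate_tissue_cohort,
)
from conftest import make_metadata


def panel_meta(n_lines=2, replicates=2):
    sample_ids, lines, pcts = [], [], []
    for li in range(n_lines):
        for pct in (20.9, 1.0, 0.2):
            for r in range(replicates):
                sample_ids.append(f"L{li}_{pct}_{r}")
                lines.append(f"line{li}")
                pcts.append(pct)
    return make_metadata(sample_ids, lines, pcts)


class TestFitFeatureModels:
    def test_noiseless_planted_slope_is_exact(self):
        m, meta, truth = simulate_mirna_panel(
            n_features=30, noise_sd=0.0, effect_per_step=1.0, seed=0
        )
        results = {r.feature_id: r for r in fit_feature_models(m, meta)}
        for f in truth.responsive_features:
            assert results[f].beta_oxygen == pytest.approx(1.0, abs=1e-8)
            assert results[f].p < 1e-10
            assert results[f].degenerate

    def test_matches_statsmodels_ols_oracle(self):
        import statsmodels.api as sm

        meta = panel_meta(n_lines=2, replicates=2)
        rng = np.random.default_rng(3)
        values = rng.normal(8, 1, size=(5, len(meta)))
        m = ExpressionMatrix(
            [f"f{i}" for i in range(5)], [x.sample_id for x in meta], values, is_log=True
        )
        results = fit_feature_models(m, meta)
        t = np.array([x.oxygen_code for x in meta], dtype=float)
        line2 = np.array([1.0 if x.cell_line == "line1" else 0.0 for x in meta])
        X = sm.add_constant(np.column_stack([t, line2]))
        for i, r in enumerate(results):
            fit = sm.OLS(values[i], X).fit()
            assert r.beta_oxygen == pytest.approx(fit.params[1], abs=1e-10)
            assert r.se == pytest.approx(fit.bse[1], abs=1e-10)
            assert r.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_result_invariant_to_sample_and_feature_order(self):
        m, meta, _ = simulate_mirna_panel(n_features=12, replicates=2, seed=5)
        base = {r.feature_id: r for r in fit_feature_models(m, meta)}
        rng = np.random.default_rng(0)
        sperm = rng.permutation(m.n_samples)
        fperm = rng.permutation(m.n_features)
        shuffled = ExpressionMatrix(
            [m.feature_ids[i] for i in fperm],
            [m.sample_ids[j] for j in sperm],
            m.values[np.ix_(fperm, sperm)],
            is_log=True,
        )
        other = {
            r.feature_id: r
            for r in fit_feature_models(shuffled, [meta[j] for j in sperm])
        }
        for f, r in base.items():
            assert other[f].beta_oxygen == pytest.approx(r.beta_oxygen, abs=1e-10)
            assert other[f].p == pytest.approx(r.p, abs=1e-10)

    def test_affine_recoding_preserves_pvalues(self):
        # ordinal codes 0/1/2 and any affine recoding span the same column
        # space, so only the slope rescales; percent coding (non-affine in
        # the ordinal codes) changes p as well
        m, meta, _ = simulate_mirna_panel(n_features=8, replicates=2, seed=6)
        ordinal = fit_feature_models(m, meta, coding="ordinal")
        percent = fit_feature_models(m, meta, coding="percent")
        p_ord = [r.p for r in ordinal]
        p_pct = [r.p for r in percent]
        assert not np.allclose(p_ord, p_pct)
        # an affine recoding of the ordinal covariate leaves p untouched and
        # rescales the slope by the inverse step
        import dataclasses

        affine_meta = [
            dataclasses.replace(x, oxygen_pct=30.0 - 10.0 * x.oxygen_code) for x in meta
        ]
        affine = fit_feature_models(m, affine_meta, coding="percent")
        assert [r.p for r in affine] == pytest.approx(p_ord, abs=1e-10)
        assert [r.beta_oxygen for r in affine] == pytest.approx(
            [-r.beta_oxygen / 10.0 for r in ordinal], abs=1e-10
        )

    def test_confounded_design_is_error(self):
        meta = make_metadata(
            ["a", "b", "c", "d"],
            ["l1", "l1", "l2", "l2"],
            [20.9, 20.9, 0.2, 0.2],
        )
        m = ExpressionMatrix(
            ["f"], ["a", "b", "c", "d"], np.ones((1, 4)), is_log=True
        )
        with pytest.raises(ValueError, match="singular design"):
            fit_feature_models(m, meta)

    def test_results_frame_sorted_by_p(self):
        m, meta, _ = simulate_mirna_panel(n_features=10, replicates=2, seed=7)
        df = results_frame(fit_feature_models(m, meta))
        assert list(df.p) == sorted(df.p)
        assert "log2fc_1pct" in df.columns and "log2fc_0.2pct" in df.columns


class TestFoldChanges:
    def test_group_mean_difference(self):
        meta = panel_meta(n_lines=1, replicates=1)
        values = np.array([[5.0, 7.0, 9.0]])
        m = ExpressionMatrix(["f"], [x.sample_id for x in meta], values, is_log=True)
        fc = fold_changes_vs_reference(m, meta, 20.9)
        assert fc.loc["f", 1.0] == pytest.approx(2.0)
        assert fc.loc["f", 0.2] == pytest.approx(4.0)
        assert 2.0 ** fc.loc["f", 0.2] == pytest.approx(16.0)

    def test_reference_vs_itself_is_zero(self):
        meta = panel_meta(n_lines=1, replicates=2)
        rng = np.random.default_rng(1)
        m = ExpressionMatrix(
            ["f"], [x.sample_id for x in meta], rng.normal(size=(1, len(meta))), is_log=True
        )
        fc_all = fold_changes_vs_reference(m, meta, 20.9)
        assert 20.9 not in fc_all.columns  # reference column omitted (always 0)

    def test_missing_reference_is_error(self):
        meta = panel_meta(n_lines=1, replicates=1)
        m = ExpressionMatrix(
            ["f"], [x.sample_id for x in meta], np.ones((1, len(meta))), is_log=True
        )
        with pytest.raises(ValueError, match="no samples"):
            fold_changes_vs_reference(m, meta, 5.0)


def bh_oracle(ps):
    """Literal step-up definition: q_i = min over j >= rank(i) of p_(j)*n/j."""
    n = len(ps)
    order = sorted(range(n), key=lambda i: ps[i])
    q = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * n / rank)
        q[i] = running
    return q


class TestBHAdjust:
    def test_hand_computed_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == [0.3]

    def test_matches_definition_oracle_on_permutations(self):
        rng = np.random.default_rng(2)
        ps = rng.uniform(size=6).tolist()
        for perm in itertools.permutations(range(6)):
            shuffled = [ps[i] for i in perm]
            assert bh_adjust(shuffled) == pytest.approx(bh_oracle(shuffled))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        ps = rng.uniform(size=40)
        _, q_sm, _, _ = multipletests(ps, method="fdr_bh")
        assert bh_adjust(ps.tolist()) == pytest.approx(q_sm.tolist())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_bounds(self, ps):
        q = bh_adjust(ps)
        assert all(qi >= pi - 1e-12 for qi, pi in zip(q, ps))
        assert all(qi <= 1.0 for qi in q)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestDifferentialGroups:
    def cohort(self, **kw):
        m, meta, truth = simulate_tissue_cohort(**kw)
        return m, [x.group for x in meta], truth

    def test_identical_groups_give_p_one_and_zero_fc(self):
        values = np.tile([[5.0, 5.0, 5.0, 5.0]], (3, 1))
        m = ExpressionMatrix(
            ["f1", "f2", "f3"], ["a", "b", "c", "d"], values, is_log=True
        )
        df = differential_groups(m, ["g1", "g1", "g2", "g2"])
        assert (df.p == 1.0).all()
        assert (df.fold_change == 0.0).all()

    def test_planted_features_recovered(self):
        m, groups, truth = self.cohort(seed=0)
        df = differential_groups(m, groups)
        rec = df[df.feature_id.isin(truth.de_features)]
        assert (rec.q < 0.05).mean() >= 0.8
        # direction: planted features are up in non-responders
        assert (rec.fold_change > 0).all()

    def test_null_cohort_yields_no_discoveries_typically(self):
        counts = []
        for seed in range(10):
            m, groups, _ = self.cohort(frac_de=0.0, seed=seed)
            df = differential_groups(m, groups)
            counts.append(int((df.q < 0.05).sum()))
        assert np.median(counts) == 0

    def test_two_levels_required(self):
        m, groups, _ = self.cohort(seed=1)
        with pytest.raises(ValueError, match="two group levels"):
            differential_groups(m, ["x"] * len(groups))


class TestSignificanceSummary:
    @pytest.mark.parametrize(
        "n_sig, n_total, pct",
        [(41, 1896, 2.2), (33, 800, 4.1), (0, 10, 0.0), (10, 10, 100.0)],
    )
    def test_percentages(self, n_sig, n_total, pct):
        assert significant_fraction_pct(n_sig, n_total) == pct

    def test_format(self):
        assert format_significant_fraction(41, 1896) == "2.2% (41/1896)"

    def test_validation(self):
        with pytest.raises(ValueError):
            significant_fraction_pct(5, 4)
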