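import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from heatnuc.differential import (
    CONTRASTS,
    ContrastThresholds,
    VariancePrior,
    adjust_pvalues,
    call_significance,
    contrast_summary,
    dap_set,
    fit_variance_prior,
    moderated_t,
    pooled_stats,
    run_contrasts,
    storey_pi0,
)
from heatnuc.quant_io import AbundanceMatrix, Condition, SampleDesign


def brute_force_bh(p):
    """Independent step-up oracle: for each p, the minimum over larger
    ranks of p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * n / j for j in range(rank_i, n + 1)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestContrastDefinitions:
    def test_canonical_set(self):
        got = [(c.id, c.numerator.value, c.denominator.value) for c in CONTRASTS]
        assert got == [
            ("C1", "H4", "T22"),
            ("C2", "H24", "T22"),
            ("C3", "R22", "T22"),
            ("C4", "H24", "H4"),
            ("C5", "R22", "H4"),
            ("C6", "R22", "H24"),
        ]

    def test_default_alphas(self):
        th = ContrastThresholds()
        assert [th.alpha[c.id] for c in CONTRASTS] == [
            0.0005, 0.001, 0.001, 0.0004, 0.0007, 0.0005,
        ]


class TestPooledStats:
    def test_zero_variance(self):
        fc, s, df = pooled_stats([5, 5, 5], [3, 3, 3])
        assert (fc, s, df) == (2.0, 0.0, 4)

    def test_identity(self):
        fc, _, _ = pooled_stats([1, 2, 3], [1, 2, 3])
        assert fc == 0.0

    def test_hand_computed(self):
        # x=(1,2): ss=0.5; y=(3,5): ss=2; pooled = 2.5/2
        fc, s, df = pooled_stats([1, 2], [3, 5])
        assert fc == -2.5
        assert s == pytest.approx(1.25)
        assert df == 2

    def test_insufficient_values(self):
        with pytest.raises(ValueError):
            pooled_stats([1.0], [1.0, 2.0])

    def test_nan_dropped(self):
        fc, _, df = pooled_stats([1, 2, np.nan], [3, 4, 5])
        assert fc == pytest.approx(1.5 - 4.0)
        assert df == 3


class TestVariancePrior:
    def test_recovers_s0_from_chisq_draws(self):
        rng = np.random.default_rng(17)
        s = 0.09 * rng.chisquare(4, size=5000) / 4.0
        prior = fit_variance_prior(s, np.full(5000, 4.0))
        assert prior.s0_sq == pytest.approx(0.09, rel=0.10)

    def test_constant_variances_give_infinite_d0(self):
        prior = fit_variance_prior(np.full(100, 0.04), np.full(100, 4.0))
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.04)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        s = rng.chisquare(4, size=500) / 4.0
        df = np.full(500, 4.0)
        a = fit_variance_prior(s, df)
        perm = rng.permutation(500)
        b = fit_variance_prior(s[perm], df[perm])
        assert a.d0 == pytest.approx(b.d0)
        assert a.s0_sq == pytest.approx(b.s0_sq)

    def test_recovers_finite_d0(self):
        # s_g^2 ~ s0^2 * d0/chi2_d0 * chi2_df/df with d0=8
        rng = np.random.default_rng(23)
        d0, s0_sq, n = 8.0, 0.09, 20000
        var_g = s0_sq * d0 / rng.chisquare(d0, size=n)
        s = var_g * rng.chisquare(4, size=n) / 4.0
        prior = fit_variance_prior(s, np.full(n, 4.0))
        assert prior.d0 == pytest.approx(d0, rel=0.2)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.1)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="zero"):
            fit_variance_prior(np.zeros(100), np.full(100, 4.0))

    def test_too_few_proteins_errors(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_variance_prior(np.ones(10), np.full(10, 4.0))


class TestModeratedT:
    def test_zero_fc(self):
        t, _, p = moderated_t(0.0, 0.1, 4, VariancePrior(4.0, 0.1), 3, 3)
        assert t == 0.0
        assert p == 1.0

    def test_d0_zero_matches_ordinary_t(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            x = rng.normal(0, 1, 3)
            y = rng.normal(0.5, 1, 3)
            fc, s, df = pooled_stats(x, y)
            t, _, p = moderated_t(fc, s, df, VariancePrior(0.0, 1.0), 3, 3)
            t_ref, p_ref = stats.ttest_ind(x, y)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_large_d0_limit(self):
        prior = VariancePrior(1e12, 0.25)
        _, s_post, _ = moderated_t(1.0, 4.0, 4, prior, 3, 3)
        assert s_post == pytest.approx(0.25, rel=1e-9)

    def test_posterior_variance_is_convex_combination(self):
        rng = np.random.default_rng(9)
        for _ in range(10_000):
            s_g = float(rng.uniform(0, 2))
            s0 = float(rng.uniform(0.01, 2))
            d0 = float(rng.uniform(0.1, 50))
            df = float(rng.integers(1, 10))
            _, s_post, _ = moderated_t(1.0, s_g, df, VariancePrior(d0, s0), 3, 3)
            assert min(s_g, s0) - 1e-12 <= s_post <= max(s_g, s0) + 1e-12

    def test_degenerate_zero_posterior(self):
        t, _, p = moderated_t(1.0, 0.0, 4, VariancePrior(0.0, 1.0), 3, 3)
        assert p == 0.0 and t == math.inf
        t, _, p = moderated_t(0.0, 0.0, 4, VariancePrior(0.0, 1.0), 3, 3)
        assert p == 1.0 and t == 0.0


class TestAdjustPvalues:
    def test_plain_bh_small_example(self):
        padj, _ = adjust_pvalues(np.array([0.01, 0.02, 0.04]), method="bh_plain")
        np.testing.assert_allclose(padj, [0.03, 0.03, 0.04])

    def test_all_ones(self):
        padj, calib = adjust_pvalues(np.ones(10), method="storey_lambda")
        assert (padj == 1.0).all()
        assert calib["pi0_hat"] == 1.0

    def test_matches_bruteforce_on_all_permutations(self):
        base = np.array([0.001, 0.01, 0.2, 0.5, 0.8, 0.04])
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            padj, _ = adjust_pvalues(p, method="bh_plain")
            np.testing.assert_allclose(padj, brute_force_bh(p), atol=1e-14)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, ps):
        p = np.array(ps)
        padj, calib = adjust_pvalues(p)
        assert ((padj >= p - 1e-15) & (padj <= 1.0)).all()
        assert padj[np.argsort(p, kind="mergesort")] == pytest.approx(
            np.sort(padj), abs=1e-12
        )
        # p_adj >= p_raw * pi0
        assert (padj >= p * calib["pi0_hat"] - 1e-12).all()

    def test_empty(self):
        padj, _ = adjust_pvalues(np.array([]))
        assert len(padj) == 0

    def test_storey_pi0_null_uniform(self):
        rng = np.random.default_rng(2)
        assert storey_pi0(rng.random(100_000)) == pytest.approx(1.0, abs=0.02)


class TestCallSignificance:
    def test_positive_call(self):
        assert call_significance([1.2], [0.0001], 0.0005)[0] == 1

    def test_boundary_inclusive(self):
        assert call_significance([1.0], [0.0005], 0.0005)[0] == 1

    def test_not_significant(self):
        assert call_significance([1.0], [0.01], 0.0005)[0] == 0

    def test_untestable_zeroed(self):
        call = call_significance([2.0], [0.0001], 0.05, untestable=np.array([True]))
        assert call[0] == 0


def _simulate_matrix(rng, n, design, effects=None, sigma=0.3):
    base = rng.normal(20, 2, size=n)
    cols = {}
    for s, c in zip(design.samples, design.conditions):
        mu = base.copy()
        if effects is not None:
            mu = mu + effects.get(c, np.zeros(n))
        cols[s] = mu + rng.normal(0, sigma, size=n)
    return AbundanceMatrix(
        pd.DataFrame(cols, index=[f"P{i}" for i in range(n)]), scale="log2"
    )


class TestRunContrasts:
    def test_null_simulation_error_control(self, design):
        rng = np.random.default_rng(1)
        m = _simulate_matrix(rng, 2000, design)
        th = ContrastThresholds(
            alpha={c.id: 0.01 for c in CONTRASTS}, mode="adjusted_p"
        )
        ct = run_contrasts(m, design, th)
        frac = (ct["call"] != 0).mean()
        assert frac <= 0.02

    def test_planted_power(self, design):
        rng = np.random.default_rng(4)
        n = 600
        effects = {
            Condition.H4: np.r_[np.full(100, 2.0), np.zeros(n - 100)],
            Condition.H24: np.r_[np.full(100, 2.0), np.zeros(n - 100)],
        }
        m = _simulate_matrix(rng, n, design, effects=effects)
        ct = run_contrasts(m, design)
        planted = {f"P{i}" for i in range(100)}
        for cid in ("C1", "C2"):
            sub = ct[(ct["contrast"] == cid) & ct["accession"].isin(planted)]
            power = (sub["call"] == 1).mean()
            assert power >= 0.95

    def test_dap_set_is_union(self, design):
        rng = np.random.default_rng(8)
        m = _simulate_matrix(
            rng, 300, design,
            effects={Condition.H24: np.r_[np.full(30, 2.0), np.zeros(270)]},
        )
        ct = run_contrasts(m, design)
        expected = set(ct.loc[ct["call"] != 0, "accession"])
        assert set(dap_set(ct)) == expected

    def test_antisymmetry(self, design):
        # swapping numerator/denominator negates fc and t, preserves p;
        # verified by relabeling H4 <-> T22 samples
        rng = np.random.default_rng(12)
        m = _simulate_matrix(
            rng, 200, design,
            effects={Condition.H4: rng.normal(0, 1, 200)},
        )
        ct = run_contrasts(m, design)
        swapped = SampleDesign(
            design.samples,
            tuple(
                {Condition.H4: Condition.T22, Condition.T22: Condition.H4}.get(c, c)
                for c in design.conditions
            ),
            design.replicates,
        )
        ct_swapped = run_contrasts(m, swapped)
        a = ct[ct["contrast"] == "C1"].set_index("accession")
        b = ct_swapped[ct_swapped["contrast"] == "C1"].set_index("accession")
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-12)
        np.testing.assert_allclose(a["t_mod"], -b["t_mod"], atol=1e-10)
        np.testing.assert_allclose(a["p_raw"], b["p_raw"], atol=1e-12)

    def test_full_pipeline_matches_ordinary_t_with_d0_zero(self, design):
        rng = np.random.default_rng(3)
        m = _simulate_matrix(rng, 1000, design)
        ct = run_contrasts(m, design, prior=VariancePrior(0.0, 1.0))
        for contrast in CONTRASTS:
            xs = design.samples_for(contrast.numerator)
            ys = design.samples_for(contrast.denominator)
            t_ref, p_ref = stats.ttest_ind(
                m.data[xs].to_numpy(), m.data[ys].to_numpy(), axis=1
            )
            sub = ct[ct["contrast"] == contrast.id]
            np.testing.assert_allclose(sub["t_mod"], t_ref, atol=1e-10)
            np.testing.assert_allclose(sub["p_raw"], p_ref, atol=1e-10)

    def test_missing_condition_errors(self, design):
        partial = SampleDesign(
            design.samples[:9], design.conditions[:9], design.replicates[:9]
        )
        rng = np.random.default_rng(0)
        m = _simulate_matrix(rng, 100, partial)
        with pytest.raises(ValueError, match="R22"):
            run_contrasts(m, partial)

    def test_untestable_flagged_not_dropped(self, design):
        rng = np.random.default_rng(7)
        m = _simulate_matrix(rng, 100, design)
        t22 = design.samples_for(Condition.T22)
        m.data.loc["P0", t22[1:]] = np.nan  # 1 observed in T22
        ct = run_contrasts(m, design)
        row = ct[(ct["accession"] == "P0") & (ct["contrast"] == "C1")].iloc[0]
        assert bool(row["untestable"])
        assert row["call"] == 0
        assert len(ct) == 600

    def test_summary_counts(self, design):
        rng = np.random.default_rng(21)
        m = _simulate_matrix(
            rng, 400, design,
            effects={Condition.R22: np.r_[np.full(40, 3.0), np.zeros(360)]},
        )
        ct = run_contrasts(m, design)
        summary = contrast_summary(ct).set_index("contrast")
        assert summary.loc["C3", "up"] >= 35
        assert (summary["total"] == summary["up"] + summary["down"]).all()
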