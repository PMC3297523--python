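"""Moderated-t machinery against brute-force oracles: the shrinkage formula
evaluated directly, BH step-up against an O(n^2) tail minimum, classical-t
limits, promoter aggregation tie-breaks, and FDR calibration on nulls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from epiherit import de_dm_stats as dd


def bh_oracle(p):
    """O(n^2) direct step-up: p_adj(i) = min over j with p_j >= p_i ranked."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(n)
    for i in range(n):
        adj[order[i]] = min(min(n / (j + 1) * ranked[j] for j in range(i, n)), 1.0)
    return adj


def two_group_matrix(rng, n_feat=50, n1=4, n2=4, effect=None):
    x = rng.normal(0.0, 1.0, (n_feat, n1 + n2))
    # heterogeneous per-feature variances so the prior has something to shrink
    x *= rng.uniform(0.4, 2.5, n_feat)[:, None]
    if effect is not None:
        x[:, n1:] += effect[:, None]
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    matrix = pd.DataFrame(x, columns=cols, index=[f"g{i}" for i in range(n_feat)])
    labels = pd.Series(["A"] * n1 + ["B"] * n2, index=cols)
    return matrix, labels


class TestModeratedT:
    def test_matches_direct_shrinkage_formula(self, rng):
        matrix, labels = two_group_matrix(rng)
        fit = dd.fit_moderated_t(matrix, labels, groups=("A", "B"))
        x = matrix.to_numpy()
        n1 = n2 = 4
        m1, m2 = x[:, :n1].mean(1), x[:, n1:].mean(1)
        s2 = (x[:, :n1].var(1, ddof=1) * (n1 - 1) + x[:, n1:].var(1, ddof=1) * (n2 - 1)) / (
            n1 + n2 - 2
        )
        d0, s0 = fit.d0, fit.s0_sq
        s2_post = (d0 * s0 + (n1 + n2 - 2) * s2) / (d0 + n1 + n2 - 2)
        t_direct = (m2 - m1) / np.sqrt(s2_post * (1 / n1 + 1 / n2))
        assert np.allclose(fit.table["t"].to_numpy(), t_direct, atol=1e-10, rtol=0)
        assert np.allclose(fit.table["s2"].to_numpy(), s2, atol=1e-12)
        # prior df satisfies the trigamma moment equation it was solved from
        e = np.log(s2) - special.digamma(3.0) + np.log(3.0)
        assert special.polygamma(1, d0 / 2) == pytest.approx(
            np.var(e, ddof=1) - special.polygamma(1, 3.0), rel=1e-8
        )

    def test_posterior_variance_between_prior_and_sample(self, rng):
        matrix, labels = two_group_matrix(rng, n_feat=80)
        fit = dd.fit_moderated_t(matrix, labels)
        d0, s0, d = fit.d0, fit.s0_sq, fit.df_resid
        s2 = fit.table["s2"].to_numpy()
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        assert np.all(s2_post >= np.minimum(s2, s0) - 1e-12)
        assert np.all(s2_post <= np.maximum(s2, s0) + 1e-12)

    def test_single_feature_reduces_to_classical_pooled_t(self, rng):
        matrix, labels = two_group_matrix(rng, n_feat=1)
        fit = dd.fit_moderated_t(matrix, labels, groups=("A", "B"))
        assert fit.d0 == 0.0
        x = matrix.to_numpy()[0]
        res = stats.ttest_ind(x[4:], x[:4], equal_var=True)
        assert fit.table["t"].iloc[0] == pytest.approx(res.statistic, abs=1e-12)
        assert fit.table["p"].iloc[0] == pytest.approx(res.pvalue, abs=1e-12)

    def test_identical_variances_force_complete_shrinkage(self, rng):
        # equal per-feature variances: d0 -> inf and the prior is the common s2
        base = rng.normal(0, 1, 8)
        base = (base - base.mean()) / base.std(ddof=1)  # exact unit variance
        shifts = rng.normal(0, 2, 30)
        x = base[None, :] + shifts[:, None]
        cols = [f"s{i}" for i in range(8)]
        matrix = pd.DataFrame(x, columns=cols)
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=cols)
        fit = dd.fit_moderated_t(matrix, labels, groups=("A", "B"))
        assert np.isinf(fit.d0)
        s2 = fit.table["s2"].iloc[0]
        assert fit.s0_sq == pytest.approx(s2, rel=1e-10)
        t_expected = fit.table["log2fc"] / np.sqrt(s2 * 0.5)
        assert np.allclose(fit.table["t"], t_expected, atol=1e-10)

    def test_increasing_a_true_effect_never_decreases_abs_t(self, rng):
        noise = rng.normal(0, 1, (40, 8)) * rng.uniform(0.5, 2, 40)[:, None]
        # centre the target feature's group contrast so the noise does not
        # mask small effects with an opposite-signed baseline fold change
        noise[0, :4] -= noise[0, :4].mean()
        noise[0, 4:] -= noise[0, 4:].mean()
        cols = [f"s{i}" for i in range(8)]
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=cols)
        prev = None
        for effect in [0.0, 0.5, 1.0, 2.0, 4.0]:
            x = noise.copy()
            x[0, 4:] += effect
            fit = dd.fit_moderated_t(pd.DataFrame(x, columns=cols), labels, groups=("A", "B"))
            cur = abs(fit.table["t"].iloc[0])
            if prev is not None:
                assert cur >= prev - 1e-12
            prev = cur

    def test_small_groups_rejected(self, rng):
        matrix, labels = two_group_matrix(rng, n1=1, n2=4)
        with pytest.raises(ValueError):
            dd.fit_moderated_t(matrix, labels)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert dd.bh_adjust([0.05]).tolist() == [0.05]

    def test_hand_computed_step_up(self):
        assert np.allclose(dd.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200)
    )
    def test_matches_quadratic_oracle(self, p):
        assert np.allclose(dd.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(0, 1, 150)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(dd.bh_adjust(p), expected, atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone_in_rank(self, rng):
        p = rng.uniform(0, 1, 100)
        adj = dd.bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            dd.bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            dd.bh_adjust([-0.1])


class TestCalls:
    def test_all_p_one_gives_empty_set(self, rng):
        matrix, labels = two_group_matrix(rng, n_feat=10)
        fit = dd.fit_moderated_t(matrix, labels)
        fit.table["p_adj"] = 1.0
        assert dd.call_significant(fit) == []

    def test_strong_single_effect_is_called(self, rng):
        called = 0
        reps = 20
        for _ in range(reps):
            x = rng.normal(0, 0.1, (100, 8))
            x[0, 4:] += 2.0
            cols = [f"s{i}" for i in range(8)]
            fit = dd.fit_moderated_t(
                pd.DataFrame(x, columns=cols, index=[f"g{i}" for i in range(100)]),
                pd.Series(["A"] * 4 + ["B"] * 4, index=cols),
                groups=("A", "B"),
            )
            called += "g0" in dd.call_significant(fit, fdr=0.05)
        assert called >= 0.95 * reps

    def test_null_positive_rate_at_most_nominal(self, rng):
        # no true effects: the mean fraction called must respect the FDR target
        fracs = []
        for _ in range(200):
            x = rng.normal(0, 1, (60, 8))
            cols = [f"s{i}" for i in range(8)]
            fit = dd.fit_moderated_t(
                pd.DataFrame(x, columns=cols), pd.Series(["A"] * 4 + ["B"] * 4, index=cols)
            )
            fracs.append(len(dd.call_significant(fit, 0.05)) / 60)
        mc_sem = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert np.mean(fracs) <= 0.05 + 2 * mc_sem


class TestAggregatePromoters:
    def _fit_from(self, p, logfc, probe_ids):
        table = pd.DataFrame(
            {
                "mean1": 0.0, "mean2": logfc, "log2fc": logfc, "s2": 1.0,
                "t": logfc, "p": p, "p_adj": dd.bh_adjust(p),
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
        return dd.ModeratedTestFit(table=table, groups=("A", "B"), d0=1.0, s0_sq=1.0,
                                   df_resid=6.0)

    def _probe_table(self, probe_ids, promoters, starts):
        return pd.DataFrame(
            {
                "probe_id": probe_ids, "chrom": "chr1", "start": starts,
                "end": np.asarray(starts) + 50, "promoter_id": promoters,
            }
        )

    def test_most_significant_probe_wins(self):
        fit = self._fit_from([0.3, 0.001, 0.2], [1.0, 0.5, 2.0], ["p1", "p2", "p3"])
        calls = dd.aggregate_promoters(fit, self._probe_table(
            ["p1", "p2", "p3"], ["prom"] * 3, [0, 100, 200]))
        assert calls.loc["prom", "probe_id"] == "p2"

    def test_single_probe_promoter(self):
        fit = self._fit_from([0.4], [1.0], ["p1"])
        calls = dd.aggregate_promoters(fit, self._probe_table(["p1"], ["prom"], [0]))
        assert calls.loc["prom", "probe_id"] == "p1"

    def test_equal_p_tie_broken_by_larger_fold_change_then_coordinate(self):
        fit = self._fit_from([0.1, 0.1], [1.5, 0.5], ["p1", "p2"])
        calls = dd.aggregate_promoters(fit, self._probe_table(
            ["p1", "p2"], ["prom"] * 2, [100, 0]))
        assert calls.loc["prom", "probe_id"] == "p1"
        fit2 = self._fit_from([0.1, 0.1], [-1.0, 1.0], ["p1", "p2"])
        calls2 = dd.aggregate_promoters(fit2, self._probe_table(
            ["p1", "p2"], ["prom"] * 2, [200, 100]))
        assert calls2.loc["prom", "probe_id"] == "p2"  # same |FC|: smaller start

    def test_direction_is_sign_of_best_probe_fold_change(self):
        fit = self._fit_from([0.001, 0.5], [-2.0, 1.0], ["p1", "p2"])
        calls = dd.aggregate_promoters(fit, self._probe_table(
            ["p1", "p2"], ["prom"] * 2, [0, 100]))
        assert calls.loc["prom", "direction"] == -1
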