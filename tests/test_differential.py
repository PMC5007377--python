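import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import orgscreen as og
from orgscreen.config import with_overrides
from orgscreen.differential import _trigamma_inverse
from orgscreen.errors import OrgscreenError

AB = og.ComparisonSpec("AB", "A", "B")
BA = og.ComparisonSpec("BA", "B", "A")


def hand_pooled(a, b):
    a, b = np.asarray(a), np.asarray(b)
    df = len(a) + len(b) - 2
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    return a.mean() - b.mean(), ss / df, df


class TestGroupStats:
    def test_hand_computed_pooled_variance(self, toy_3v3_matrix):
        table, n_a, n_b = og.group_stats(toy_3v3_matrix, AB)
        assert (n_a, n_b) == (3, 3)
        lfc, s_sq, df = hand_pooled([5.0, 5.2, 5.4], [3.0, 3.1, 3.2])
        assert table.loc["g1", "log2fc"] == pytest.approx(2.1, abs=1e-12)
        assert table.loc["g1", "log2fc"] == pytest.approx(lfc, abs=1e-12)
        assert table.loc["g1", "s_sq"] == pytest.approx(s_sq, abs=1e-12)
        assert table.loc["g1", "df"] == df == 4

    def test_identical_constant_groups(self, toy_3v3_matrix):
        table, _, _ = og.group_stats(toy_3v3_matrix, AB)
        assert table.loc["g2", "log2fc"] == 0.0
        assert table.loc["g2", "s_sq"] == 0.0

    def test_antisymmetry(self, toy_3v3_matrix):
        fwd, _, _ = og.group_stats(toy_3v3_matrix, AB)
        rev, _, _ = og.group_stats(toy_3v3_matrix, BA)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["s_sq"], rev["s_sq"])


class TestVariancePrior:
    def test_identical_variances_give_degenerate_prior(self):
        prior = og.estimate_variance_prior(np.full(100, 0.25), df=4)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.25)

    def test_too_few_genes(self):
        with pytest.raises(OrgscreenError, match=">=50"):
            og.estimate_variance_prior(np.full(20, 0.25), df=4)

    def test_all_zero_variances(self):
        with pytest.raises(OrgscreenError, match="zero"):
            og.estimate_variance_prior(np.zeros(100), df=4)

    def test_parameter_recovery_from_generative_model(self):
        """Sampling sigma^2 ~ scaled-inv-chi2(4, 1), then s^2 | sigma^2 on
        df=4, the moment fit recovers d0 within 20% and s0^2 within 10%."""
        rng = np.random.default_rng(2024)
        n, d0, s0, df = 10_000, 4.0, 1.0, 4
        sigma2 = d0 * s0 / rng.chisquare(d0, n)
        s_sq = sigma2 * rng.chisquare(df, n) / df
        prior = og.estimate_variance_prior(s_sq, df=df)
        assert abs(prior.d0 - d0) / d0 < 0.20
        assert abs(prior.s0_sq - s0) / s0 < 0.10

    def test_trigamma_inverse_is_an_inverse(self):
        from scipy.special import polygamma

        for x in (0.1, 0.5, 2.0, 10.0, 500.0):
            y = float(polygamma(1, x))
            assert _trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestModeratedTest:
    def stats_frame(self, lfc, s_sq, df=4):
        return pd.DataFrame({"log2fc": lfc, "s_sq": s_sq, "df": df})

    def test_null_center(self):
        out = og.moderated_test(
            self.stats_frame([0.0], [0.3]), og.ModerationParams(4, 0.1), 3, 3
        )
        assert out["t_mod"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_no_moderation_equals_classical_t(self, toy_3v3_matrix):
        """d0 = 0 reproduces the ordinary pooled two-sample t (scipy oracle)."""
        table, n_a, n_b = og.group_stats(toy_3v3_matrix, AB)
        out = og.moderated_test(table, og.ModerationParams(0, 1.0), n_a, n_b)
        a = toy_3v3_matrix.group_values("A").to_numpy()
        b = toy_3v3_matrix.group_values("B").to_numpy()
        for i, gene in enumerate(["g1", "g3"]):  # g2 is constant (0/0 handled apart)
            row = toy_3v3_matrix.gene_ids.index(gene)
            t_ref, p_ref = sps.ttest_ind(a[row], b[row], equal_var=True)
            assert out.loc[gene, "t_mod"] == pytest.approx(t_ref, abs=1e-9)
            assert out.loc[gene, "p"] == pytest.approx(p_ref, abs=1e-9)

    def test_infinite_prior_ranks_by_fold_change(self):
        rng = np.random.default_rng(0)
        lfc = rng.normal(size=50)
        s_sq = rng.chisquare(4, 50)
        out = og.moderated_test(
            self.stats_frame(lfc, s_sq), og.ModerationParams(np.inf, 0.2), 3, 3
        )
        assert list(np.argsort(-np.abs(out["t_mod"]))) == list(np.argsort(-np.abs(lfc)))
        # normal tail: p = 2*Phi(-|t|)
        assert np.allclose(out["p"], 2 * sps.norm.sf(np.abs(out["t_mod"])))

    def test_moderation_shrinks_between_s2_and_s0(self):
        rng = np.random.default_rng(1)
        s_sq = rng.chisquare(4, 200) / 4
        prior = og.ModerationParams(4.0, 0.25)
        frame = self.stats_frame(np.ones(200), s_sq)
        out = og.moderated_test(frame, prior, 3, 3)
        s_tilde_sq = (out["log2fc"] / out["t_mod"]) ** 2 / (2 / 3)
        lo = np.minimum(s_sq, prior.s0_sq)
        hi = np.maximum(s_sq, prior.s0_sq)
        assert ((s_tilde_sq >= lo - 1e-12) & (s_tilde_sq <= hi + 1e-12)).all()

    def test_zero_variance_nonzero_fc_requires_prior(self):
        frame = self.stats_frame([1.0], [0.0])
        with pytest.raises(OrgscreenError, match="prior"):
            og.moderated_test(frame, og.ModerationParams(0, 1.0), 3, 3)
        out = og.moderated_test(frame, og.ModerationParams(4, 0.1), 3, 3)
        assert np.isfinite(out["t_mod"].iloc[0])


class TestBH:
    def test_single_p(self):
        assert og.adjust_bh([0.37]) == pytest.approx([0.37])

    def test_hand_stepup_example(self):
        q = og.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_another_hand_example(self):
        # sorted p: .01 .04 .30 1.0 -> m p/j: .04 .08 .40 1.0, step-up mins
        q = og.adjust_bh([0.30, 0.01, 1.0, 0.04])
        assert q == pytest.approx([0.4, 0.04, 1.0, 0.08])

    @given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=60))
    def test_q_dominates_p_and_is_monotone(self, p):
        p = np.array(p)
        q = og.adjust_bh(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_ties_share_a_q(self):
        q = og.adjust_bh([0.02, 0.02, 0.5])
        assert q[0] == q[1]

    @pytest.mark.parametrize("bad", [[0.0], [-0.1], [1.1]])
    def test_out_of_range_p(self, bad):
        with pytest.raises(OrgscreenError):
            og.adjust_bh(bad)


class TestCalls:
    @pytest.mark.parametrize(
        "lfc, q, expected",
        [
            (1.3, 0.01, "enriched"),
            (1.3, 0.06, "ns"),
            (-1.5, 0.04, "depleted"),
            (1.2, 0.05, "enriched"),   # thresholds inclusive
            (1.19, 0.01, "ns"),
            (-1.1, 0.001, "ns"),
        ],
    )
    def test_call_rule(self, lfc, q, expected):
        table = pd.DataFrame({"log2fc": [lfc], "q": [q]})
        out = og.call_genes(table, tau=1.2, alpha=0.05)
        assert out["call"].iloc[0] == expected

    def test_q_required(self):
        with pytest.raises(OrgscreenError):
            og.call_genes(pd.DataFrame({"log2fc": [1.0]}), 1.2, 0.05)


class TestScreenStage:
    def test_swap_groups_swaps_calls(self, small_simulation, default_config):
        """Antisymmetry of the full stage: reversing a comparison's groups
        exchanges enriched and depleted calls exactly."""
        _, matrix, _ = small_simulation
        tau, alpha = 1.2, 0.05
        fwd = og.run_comparison(matrix, og.ComparisonSpec("C1", "HH4 HN", "HH4 PS"), tau, alpha)
        rev = og.run_comparison(matrix, og.ComparisonSpec("C1r", "HH4 PS", "HH4 HN"), tau, alpha)
        swap = {"enriched": "depleted", "depleted": "enriched", "ns": "ns"}
        assert (rev["call"] == fwd["call"].map(swap)).all()

    def test_pair_variance_pooling_option(self, small_simulation):
        """The per-pair variance mode runs on 4 residual df, the default
        full-design mode on 18."""
        from orgscreen.config import with_overrides

        _, matrix, _ = small_simulation
        pair_cfg = with_overrides(og.PipelineConfig(), variance_pooling="pair")
        pair = og.run_screen(matrix, pair_cfg)
        glob = og.run_screen(matrix, og.PipelineConfig())
        assert (pair["C1"]["df"] == 4).all()
        assert (glob["C1"]["df"] == 18).all()
        # fold changes are per-pair in both modes
        assert np.allclose(pair["C1"]["log2fc"], glob["C1"]["log2fc"])

    def test_type_I_control_on_all_null(self, default_sheet, default_config):
        """With nothing planted, the per-comparison call rate at alpha=0.05
        stays within the binomial envelope of 0.05."""
        params = og.PlantedSignatureParams(
            n_genes=4_000, n_enriched=0, n_depleted=0, n_decoy=0
        )
        rates = []
        for seed in range(3):
            matrix, _ = og.simulate_expression(
                default_sheet, params, default_config.expression, seed=seed
            )
            tables = og.run_screen(matrix, default_config)
            for t in tables.values():
                rates.append((t["call"] != "ns").mean())
        n = 4_000 * len(rates)
        se = np.sqrt(0.05 * 0.95 / n)
        assert np.mean(rates) <= 0.05 + 3 * se

    def test_oracle_equivalence_unmoderated_pipeline(self, toy_3v3_matrix):
        """With d0=0 the full stage matches a brute-force classical-t
        pipeline (scipy t-test + hand BH) to 1e-9."""
        table = og.run_comparison(
            toy_3v3_matrix, AB, tau=1.2, alpha=0.05,
            prior=og.ModerationParams(0, 1.0),
        )
        a = toy_3v3_matrix.group_values("A").to_numpy()
        b = toy_3v3_matrix.group_values("B").to_numpy()
        p_ref = []
        for row in range(3):
            if np.ptp(a[row]) == 0 and np.ptp(b[row]) == 0 and a[row, 0] == b[row, 0]:
                p_ref.append(1.0)
            else:
                p_ref.append(sps.ttest_ind(a[row], b[row], equal_var=True).pvalue)
        m = len(p_ref)
        order = np.argsort(p_ref)
        q_ref = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            j = m - rank_from_top
            running = min(running, m * p_ref[idx] / j)
            q_ref[idx] = running
        assert np.allclose(table["p"], p_ref, atol=1e-9)
        assert np.allclose(table["q"], q_ref, atol=1e-9)
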