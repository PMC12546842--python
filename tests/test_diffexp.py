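"""Imputation, linear model, variance moderation, contrasts, BH,
regulation calls and the power module — against hand arithmetic and
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cyclequant import diffexp
from cyclequant.datatypes import AbundanceMatrix, ChannelDesign, ValidationError
from conftest import make_design


def log2_matrix(design, values, ids=None):
    ids = ids or [f"Bd{i}" for i in range(len(values))]
    data = pd.DataFrame(
        values, index=pd.Index(ids, name="protein_id"), columns=design.channel_ids
    )
    return AbundanceMatrix(data, "log2")


class TestImputation:
    def test_group_mean_fills_missing_replicate(self):
        design = make_design(n_plexes=3, conditions=("AP",), n_refs=1)
        m = log2_matrix(design, [[3.0, 0.0, np.nan, 0.0, 5.0, 0.0]])
        out, mask = diffexp.impute_missing(m, design)
        assert out.data.loc["Bd0", "P2.AP"] == pytest.approx(4.0)
        assert mask.loc["Bd0", "P2.AP"]
        assert int(mask.to_numpy().sum()) == 1

    def test_complete_matrix_unchanged(self):
        design = make_design(n_plexes=2)
        rng = np.random.default_rng(0)
        m = log2_matrix(design, rng.normal(size=(4, len(design.channel_ids))))
        out, mask = diffexp.impute_missing(m, design)
        pd.testing.assert_frame_equal(out.data, m.data)
        assert not mask.to_numpy().any()

    def test_fully_missing_group_gets_row_minimum(self):
        design = make_design(n_plexes=2, conditions=("AP", "T1h"), n_refs=1)
        vals = [[np.nan, 3.0, 2.0, np.nan, 1.5, 2.0]]  # T1h missing in both plexes
        # columns: P1.AP P1.T1h P1.GS1 P2.AP P2.T1h P2.GS1
        vals = [[3.0, np.nan, 2.0, 1.5, np.nan, 2.0]]
        m = log2_matrix(design, vals)
        out, _ = diffexp.impute_missing(m, design)
        assert out.data.loc["Bd0", "P1.T1h"] == pytest.approx(1.5)
        assert out.data.loc["Bd0", "P2.T1h"] == pytest.approx(1.5)

    def test_protein_without_observations_dropped(self, caplog):
        design = make_design(n_plexes=1)
        vals = [[1.0] * len(design.channel_ids),
                [np.nan] * len(design.channel_ids)]
        m = log2_matrix(design, vals)
        with caplog.at_level("WARNING"):
            out, _ = diffexp.impute_missing(m, design)
        assert out.shape[0] == 1


def _two_condition_design(n_plexes=1, n_rep=5):
    """n_rep replicates of AP_Ec and T4h per plex (replicate channels)."""
    rows = []
    for p in range(n_plexes):
        plex = f"P{p+1}"
        for r in range(n_rep):
            rows.append((plex, f"AP_Ec{r}", "AP_Ec", p * n_rep + r + 1, False))
            rows.append((plex, f"T4h{r}", "T4h", p * n_rep + r + 1, False))
    return ChannelDesign(pd.DataFrame(
        rows, columns=["plex_id", "channel_label", "condition", "replicate",
                       "is_reference"],
    ), require_reference=False)


class TestConditionModel:
    def test_balanced_contrast_equals_difference_of_means(self):
        design = _two_condition_design()
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(6, 10))
        m = log2_matrix(design, Y)
        model = diffexp.ModeratedConditionModel(design).fit(m)
        cond = design.table["condition"].to_numpy()
        want = Y[:, cond == "T4h"].mean(axis=1) - Y[:, cond == "AP_Ec"].mean(axis=1)
        np.testing.assert_allclose(model.effects_["T4h"], want, rtol=1e-10)

    def test_plex_shift_does_not_change_contrasts(self):
        design = make_design(
            n_plexes=3, conditions=("AP", "Ec", "AP_Ec", "T1h", "T4h"), n_refs=1
        )
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(8, len(design.channel_ids)))
        m = log2_matrix(design, Y)
        base = diffexp.ModeratedConditionModel(design).fit(m)
        shifted = Y.copy()
        p2 = [i for i, c in enumerate(design.channel_ids) if c.startswith("P2.")]
        shifted[:, p2] += 3.7
        m2 = log2_matrix(design, shifted)
        other = diffexp.ModeratedConditionModel(design).fit(m2)
        pd.testing.assert_frame_equal(base.effects_, other.effects_)

    def test_residual_variance_matches_brute_force_ols(self):
        design = make_design(
            n_plexes=2, conditions=("AP_Ec", "T4h"), n_refs=1
        )
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(5, len(design.channel_ids)))
        m = log2_matrix(design, Y)
        model = diffexp.ModeratedConditionModel(design).fit(m)
        # brute-force: explicit design matrix per protein
        tbl = design.table
        use = [c for c in design.channel_ids
               if not tbl.loc[c, "is_reference"]]
        X = np.column_stack([
            np.ones(len(use)),
            [tbl.loc[c, "condition"] == "T4h" for c in use],
            [tbl.loc[c, "plex_id"] == "P2" for c in use],
        ]).astype(float)
        for g in range(5):
            y = m.data[use].iloc[g].to_numpy()
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            df = len(use) - 3
            assert model.s2_.iloc[g] == pytest.approx(rss / df, rel=1e-10)

    def test_rank_deficient_design_reported(self):
        # condition perfectly aliased with plex
        rows = [("P1", "A", "AP_Ec", 1, False), ("P1", "B", "AP_Ec", 2, False),
                ("P2", "C", "T4h", 1, False), ("P2", "D", "T4h", 2, False)]
        design = ChannelDesign(pd.DataFrame(
            rows, columns=["plex_id", "channel_label", "condition", "replicate",
                           "is_reference"]), require_reference=False)
        m = log2_matrix(design, np.random.default_rng(0).normal(size=(4, 4)))
        with pytest.raises(ValidationError, match="aliased"):
            diffexp.ModeratedConditionModel(design).fit(m)


class TestModeration:
    def test_shrinkage_formula_hand_example(self):
        out = diffexp.posterior_variance(np.array([3.0]), 4.0, d0=4.0, s02=1.0)
        assert out[0] == pytest.approx(2.0)

    def test_d0_zero_returns_sample_variances(self):
        s2 = np.array([0.5, 1.0, 2.0])
        np.testing.assert_allclose(
            diffexp.posterior_variance(s2, 4.0, 0.0, 1.0), s2
        )

    def test_infinite_d0_collapses_to_prior(self):
        s2 = np.array([0.5, 1.0, 2.0])
        np.testing.assert_allclose(
            diffexp.posterior_variance(s2, 4.0, np.inf, 0.8), 0.8
        )

    def test_identical_variances_trigger_infinite_prior_df(self):
        s2 = np.full(50, 1.3)
        d0, s02, post = diffexp.moderate_variances(s2, 8.0)
        assert np.isinf(d0)
        np.testing.assert_allclose(post, s02)

    def test_moment_matching_recovers_known_prior(self):
        # variances drawn from s02 * chi2_d / d scaled prior with d0
        rng = np.random.default_rng(7)
        d0_true, s02_true, dg = 6.0, 0.5, 8.0
        true_var = s02_true * d0_true / rng.chisquare(d0_true, 20000)
        s2 = true_var * rng.chisquare(dg, 20000) / dg
        d0, s02, _ = diffexp.moderate_variances(s2, dg)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s02 == pytest.approx(s02_true, rel=0.05)


class TestContrasts:
    def _fitted(self, seed=0, n=40, delta=0.0):
        design = _two_condition_design()
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(n, 10))
        cond = design.table["condition"].to_numpy()
        Y[:, cond == "T4h"] += delta
        return diffexp.ModeratedConditionModel(design).fit(
            log2_matrix(design, Y)
        )

    def test_zero_contrast_gives_t_zero_p_one(self):
        # replicate-level noise identical in both conditions: the
        # condition means are exactly equal, so log2FC = 0
        design = _two_condition_design()
        rng = np.random.default_rng(0)
        rep_noise = rng.normal(size=(5, 5))
        cond = design.table["condition"].to_numpy()
        Y = np.zeros((5, 10))
        Y[:, cond == "AP_Ec"] = rep_noise
        Y[:, cond == "T4h"] = rep_noise
        model = diffexp.ModeratedConditionModel(design).fit(log2_matrix(design, Y))
        res = model.contrast("T4h")
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-10)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-10)

    def test_t_statistic_matches_hand_computation(self):
        model = self._fitted(seed=5, delta=2.0)
        res = model.contrast("T4h", d0=0.0)
        mult = np.sqrt(2.0 / 5.0)  # balanced 5-vs-5 contrast SE multiplier
        g = 7
        want_t = model.effects_["T4h"].iloc[g] / (
            np.sqrt(model.s2_.iloc[g]) * mult
        )
        assert res["t"].iloc[g] == pytest.approx(want_t, rel=1e-10)
        want_p = 2 * stats.t.sf(abs(want_t), model.df_resid_)
        assert res["p"].iloc[g] == pytest.approx(want_p, rel=1e-10)

    def test_se_multiplier_is_sqrt_2_over_n(self):
        model = self._fitted()
        assert model.fit_.se_mult["T4h"] == pytest.approx(
            np.sqrt(2.0 / 5.0), abs=1e-4
        )

    def test_moderation_preserves_t_sign_and_fc_monotonicity(self):
        model = self._fitted(seed=9, delta=0.5)
        raw = model.contrast("T4h", d0=0.0)
        mod = model.contrast("T4h")
        assert (np.sign(raw["t"]) == np.sign(mod["t"])).all()
        # |t| monotone in |log2FC| at fixed variance: same posterior var for
        # all proteins when d0 = inf
        res = model.contrast("T4h", d0=np.inf)
        order_fc = np.argsort(np.abs(res["log2fc"].to_numpy()))
        assert (np.diff(np.abs(res["t"].to_numpy())[order_fc]) >= -1e-12).all()


class TestBH:
    def test_step_up_hand_example(self):
        q = diffexp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert diffexp.bh_adjust([0.2])[0] == pytest.approx(0.2)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_subnormal=False), min_size=1, max_size=60))
    def test_matches_brute_force_step_up_and_is_monotone(self, pvals):
        p = np.asarray(pvals)
        got = diffexp.bh_adjust(p)
        # brute-force step-up with explicit cummin from the largest rank
        n = len(p)
        order = np.argsort(p, kind="stable")
        want = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * n / rank)
            want[idx] = running
        np.testing.assert_allclose(got, want, rtol=1e-10)
        srt = np.argsort(p, kind="stable")
        assert (np.diff(got[srt]) >= -1e-12).all()


class TestCallsAndFolds:
    @pytest.mark.parametrize(
        "log2fc,q,expected",
        [(3.20, 0.001, "up"), (0.0, 0.5, "ns"), (-1.5, 0.01, "down"),
         (1.0, 0.049, "up"), (0.99, 0.001, "ns"), (1.5, 0.05, "ns")],
    )
    def test_regulation_calls(self, log2fc, q, expected):
        assert diffexp.classify_regulation([log2fc], [q])[0] == expected

    def test_table1_threshold_variant(self):
        # stricter two-log2-unit criterion used for the exit-phase table
        assert diffexp.classify_regulation([3.2], [0.001], fc_threshold=2.0)[0] == "up"
        assert diffexp.classify_regulation([1.5], [0.001], fc_threshold=2.0)[0] == "ns"

    @pytest.mark.parametrize(
        "log2fc,fold", [(3.20, 9.2), (0.0, 1.0), (2.86, 7.3), (1.0, 2.0)]
    )
    def test_linear_fold_rounding(self, log2fc, fold):
        assert diffexp.fold_change_linear(log2fc) == pytest.approx(fold)


class TestModeratedF:
    def test_null_protein_has_f_zero_p_one(self):
        rows = []
        for cond in ("AP_Ec", "T1h", "T4h"):
            for r in range(4):
                rows.append(("P1", f"{cond}{r}", cond, r + 1, False))
        design = ChannelDesign(pd.DataFrame(
            rows, columns=["plex_id", "channel_label", "condition", "replicate",
                           "is_reference"]), require_reference=False)
        # identical replicate noise in every condition: all condition
        # effects are exactly zero while residual variance is real
        rng = np.random.default_rng(1)
        rep_noise = rng.normal(size=(12, 4))
        Y = np.concatenate([rep_noise, rep_noise, rep_noise], axis=1)
        model = diffexp.ModeratedConditionModel(design).fit(log2_matrix(design, Y))
        res = model.f_test(d0=0.0)
        np.testing.assert_allclose(res["F"], 0.0, atol=1e-18)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-10)

    def test_equals_classical_anova_f_with_d0_zero(self):
        # single plex, 3 conditions x 4 replicates: the moderated F with
        # d0 = 0 must reproduce the classical one-way ANOVA F
        rows = []
        for cond in ("AP_Ec", "T1h", "T4h"):
            for r in range(4):
                rows.append(("P1", f"{cond}{r}", cond, r + 1, False))
        design = ChannelDesign(pd.DataFrame(
            rows, columns=["plex_id", "channel_label", "condition", "replicate",
                           "is_reference"]), require_reference=False)
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(30, 12))
        model = diffexp.ModeratedConditionModel(design).fit(log2_matrix(design, Y))
        res = model.f_test(d0=0.0)
        cond = design.table["condition"].to_numpy()
        groups = [Y[:, cond == c] for c in ("AP_Ec", "T1h", "T4h")]
        for g in range(30):
            f_oracle, p_oracle = stats.f_oneway(*[grp[g] for grp in groups])
            assert res["F"].iloc[g] == pytest.approx(f_oracle, rel=1e-10)
            assert res["p"].iloc[g] == pytest.approx(p_oracle, rel=1e-10)

    def test_strong_archetype_is_detected(self, small_result, small_study):
        sp = small_result.predator
        res = sp.model.f_test()
        changed = study_ids = small_study.truth.archetype_id
        strong = res.index.intersection(
            study_ids[study_ids >= 0].index
        )
        # nearly all truly changing proteins pass p < 0.001
        frac = (res.loc[strong, "p"] < 1e-3).mean()
        assert frac > 0.9


class TestPower:
    def test_zero_sd_gives_full_power_fraction(self):
        spec = diffexp.PowerSpec(sd=np.zeros(5))
        assert diffexp.detection_power_fraction(spec) == 1.0

    def test_matches_statsmodels_power_oracle(self):
        from statsmodels.stats.power import TTestIndPower

        sds = np.array([0.2, 0.3, 0.5, 0.8])
        ours = diffexp.t_test_power(sds, n=5, fold=1.5, alpha=0.05)
        oracle = TTestIndPower().power(
            effect_size=np.log2(1.5) / sds, nobs1=5, ratio=1.0, alpha=0.05
        )
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_boundary_power_is_counted(self):
        from scipy.optimize import brentq

        sd_star = brentq(
            lambda s: diffexp.t_test_power(np.array([s]), 5, 1.5, 0.05)[0] - 0.8,
            0.05, 2.0, xtol=1e-12,
        )
        spec = diffexp.PowerSpec(sd=np.array([sd_star]))
        assert diffexp.detection_power_fraction(spec) == 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            diffexp.PowerSpec(fold=0.9)
        with pytest.raises(ValueError):
            diffexp.PowerSpec(n=1)
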