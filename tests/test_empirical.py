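"""Tests for the empirical pipeline, the RM-ANOVA and the fixture generator."""

import numpy as np
import pandas as pd
import pytest

from adaptrate import (ExperimentBlock, analyze_block, analyze_experiment,
                       clean_trials, generate_fixture_experiment,
                       load_experiment_dir, longest_contiguous, rm_anova,
                       select_steady_state, write_experiment_dir)
from adaptrate.exceptions import IncompleteMatrixError, TooShortSegmentError
from conftest import prescribed_ar_series


def make_block(endpoints, flags=None, target=10.0, added_noise=None,
               subject="S01", condition="NO", Q_added=0.0):
    n = len(endpoints)
    df = pd.DataFrame({
        "trial": np.arange(1, n + 1),
        "endpoint": endpoints,
        "target": target,
        "added_noise": np.zeros(n) if added_noise is None else added_noise,
    })
    for name in ("backwards", "short", "offscreen"):
        df[name] = False
    if flags:
        for idx, name in flags:
            df.loc[idx, name] = True
    return ExperimentBlock(subject=subject, condition=condition, trials=df,
                           Q_added=Q_added)


class TestCleaning:
    def test_accidental_clicks_removed_without_breaks(self):
        block = make_block(np.arange(6.0),
                           flags=[(1, "short"), (3, "backwards")])
        out = clean_trials(block)
        assert len(out.trials) == 4
        assert out.trials["segment"].nunique() == 1

    def test_all_valid_identity(self):
        block = make_block(np.arange(10.0))
        out = clean_trials(block)
        assert len(out.trials) == 10
        assert out.trials["segment"].nunique() == 1

    def test_offscreen_breaks_contiguity(self):
        block = make_block(np.arange(4.0), flags=[(1, "offscreen")])
        out = clean_trials(block)
        assert len(out.trials) == 3
        assert list(out.trials["segment"]) == [0, 1, 1]


class TestSegmentation:
    def test_break_splits_100_into_longest_90(self):
        block = make_block(np.random.default_rng(0).normal(10, 1, 100),
                           flags=[(9, "offscreen")])
        seg = longest_contiguous(clean_trials(block))
        assert len(seg) == 90

    def test_no_breaks_whole_block(self):
        block = make_block(np.random.default_rng(0).normal(10, 1, 50))
        assert len(longest_contiguous(clean_trials(block))) == 50

    def test_tie_broken_by_earliest(self):
        # segments of 40, 40, 19 -> first 40-run wins
        flags = [(40, "offscreen"), (81, "offscreen")]
        endpoints = np.random.default_rng(1).normal(10, 1, 101)
        seg = longest_contiguous(clean_trials(make_block(endpoints, flags)))
        assert len(seg) == 40
        assert seg["trial"].iloc[0] == 1

    def test_too_short_longest_segment(self):
        block = make_block(np.arange(10.0), flags=[(5, "offscreen")])
        with pytest.raises(TooShortSegmentError):
            longest_contiguous(clean_trials(block))


class TestSteadyState:
    def _segment(self, endpoints, target=10.0):
        b = clean_trials(make_block(endpoints, target=target))
        return longest_contiguous(b)

    def test_stationary_segment_kept_whole(self):
        rng = np.random.default_rng(3)
        seg = self._segment(10.0 + 0.5 * np.sin(rng.normal(size=80)))
        out = select_steady_state(seg)
        assert len(out) == 80

    def test_initial_transient_trimmed(self):
        """Large initial miscalibration decaying over ~30 trials is cut;
        a brute-force scan of the true generating change point agrees."""
        rng = np.random.default_rng(4)
        transient = 8.0 * np.exp(-np.arange(80) / 10.0)
        endpoints = 10.0 + transient + rng.normal(0, 0.5, 80)
        seg = self._segment(endpoints)
        out = select_steady_state(seg)
        start = len(seg) - len(out)
        assert start >= 15  # the 20-trial window must clear the transient
        # independent check: at the detected start the transient is small
        assert transient[start] < 2.0

    def test_too_short_segment(self):
        seg = pd.DataFrame({
            "trial": np.arange(1, 16),
            "endpoint": 10.0 + np.random.default_rng(0).normal(0, 1, 15),
            "target": 10.0,
        })
        with pytest.raises(TooShortSegmentError):
            select_steady_state(seg)

    def test_burn_in_override(self):
        seg = self._segment(10.0 + np.random.default_rng(5).normal(0, 1, 60))
        out = select_steady_state(seg, burn_in=10)
        assert len(out) == 50


class TestAnalyzeBlock:
    def test_no_added_noise_all_estimators_coincide(self):
        rng = np.random.default_rng(6)
        block = make_block(rng.normal(10, 1, 60), Q_added=0.0)
        seg = select_steady_state(longest_contiguous(clean_trials(block)))
        res = analyze_block(seg, Q_added=0.0)
        assert res.arset.silver == pytest.approx(res.arset.conventional, rel=1e-12)
        assert res.arset.analytic == pytest.approx(res.arset.conventional, rel=1e-12)

    def test_prescribed_process_with_added_noise(self):
        """Analytic recovers the prescribed rate; conventional is biased
        far more negative (the noise-masking artifact)."""
        s = prescribed_ar_series(A=-0.3, Q=5.0, n=1000, seed=8, x_i=22.4)
        df = pd.DataFrame({"trial": np.arange(1, 1001),
                           "endpoint": s.x_m, "target": 22.4,
                           "added_noise": s.eta_q})
        res = analyze_block(df, Q_added=5.0)
        assert res.arset.analytic == pytest.approx(-0.3, abs=0.1)
        assert res.arset.silver == pytest.approx(-0.3, rel=1e-9)
        assert res.arset.conventional < -0.8

    def test_missing_added_noise_column(self):
        df = pd.DataFrame({"trial": [1, 2, 3, 4],
                           "endpoint": [1.0, 2.0, 1.5, 2.5], "target": 2.0})
        res = analyze_block(df, Q_added=1.0)
        assert res.arset.silver is None
        assert res.arset.conventional is not None
        assert res.arset.analytic is not None


class TestRmAnova:
    def test_identical_conditions_give_zero_f(self):
        wide = pd.DataFrame({"NO": [1.0, 2.0, 3.0], "LOW": [1.0, 2.0, 3.0],
                             "HIGH": [1.0, 2.0, 3.0]})
        res = rm_anova(wide)
        assert res.F == 0.0
        assert all(res.pairwise["p_bonf"] == 1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_statsmodels_reference(self, seed):
        """F and uncorrected df/p agree with an independent implementation."""
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(seed)
        wide = pd.DataFrame(rng.normal(size=(26, 3)),
                            columns=["NO", "LOW", "HIGH"])
        res = rm_anova(wide)
        long = wide.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="value")
        ref = AnovaRM(long, depvar="value", subject="subject",
                      within=["condition"]).fit().anova_table
        assert res.F == pytest.approx(float(ref["F Value"].iloc[0]), abs=1e-6)
        if not res.sphericity_violated:
            assert res.p == pytest.approx(float(ref["Pr > F"].iloc[0]), abs=1e-6)
            assert (res.df1, res.df2) == (2, 50)
        else:
            assert res.df1 < 2 and res.df2 < 50  # GG-shrunk df

    def test_gg_correction_applied_when_sphericity_violated(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=26)
        wide = pd.DataFrame({
            "NO": base + rng.normal(0, 0.01, 26),
            "LOW": base + rng.normal(0, 0.01, 26),
            "HIGH": base + rng.normal(0, 5.0, 26),
        })
        res = rm_anova(wide)
        assert res.sphericity_violated
        assert res.df1 < 2.0 and res.df2 < 50.0
        assert res.df1 == pytest.approx(2 * res.eps)

    def test_incomplete_matrix_rejected(self):
        wide = pd.DataFrame({"NO": [1.0, 2.0, 3.0], "LOW": [1.0, np.nan, 3.0],
                             "HIGH": [1.0, 2.0, 3.0]})
        with pytest.raises(IncompleteMatrixError):
            rm_anova(wide)
        with pytest.raises(IncompleteMatrixError):
            rm_anova(np.ones((2, 3)))

    def test_pairwise_bonferroni_bounded(self):
        rng = np.random.default_rng(2)
        res = rm_anova(pd.DataFrame(rng.normal(size=(10, 3)),
                                    columns=["NO", "LOW", "HIGH"]))
        assert len(res.pairwise) == 3
        assert ((res.pairwise["p_bonf"] <= 1.0)
                & (res.pairwise["p_bonf"] >= res.pairwise["p_unc"])).all()


class TestFixtureGenerator:
    def test_block_counts(self):
        blocks, manifest = generate_fixture_experiment(n_subjects=4, seed=1)
        assert len(blocks) == 12
        for b in blocks:
            valid = ~(b.trials[["backwards", "short", "offscreen"]].any(axis=1))
            assert valid.sum() == 100

    def test_no_noise_blocks_have_zero_added_noise(self):
        blocks, _ = generate_fixture_experiment(n_subjects=2, seed=2)
        for b in blocks:
            if b.condition == "NO":
                assert (b.trials["added_noise"] == 0).all()
            else:
                valid = ~(b.trials[["backwards", "short", "offscreen"]].any(axis=1))
                assert b.trials.loc[valid, "added_noise"].std() > 0.5

    def test_orders_are_permutations_and_reproducible(self):
        _, m1 = generate_fixture_experiment(n_subjects=6, seed=3)
        _, m2 = generate_fixture_experiment(n_subjects=6, seed=3)
        orders1 = [tuple(v["order"]) for v in m1["subjects"].values()]
        assert orders1 == [tuple(v["order"]) for v in m2["subjects"].values()]
        for order in orders1:
            assert sorted(order) == ["HIGH", "LOW", "NO"]

    def test_round_trip_via_directory(self, tmp_path):
        blocks, manifest = generate_fixture_experiment(n_subjects=2, seed=4)
        root = write_experiment_dir(blocks, manifest, tmp_path / "exp")
        loaded, manifest2 = load_experiment_dir(root)
        assert manifest2["subjects"] == manifest["subjects"]
        assert len(loaded) == len(blocks)
        a = blocks[0].trials.reset_index(drop=True)
        b = [x for x in loaded
             if (x.subject, x.condition) == (blocks[0].subject,
                                             blocks[0].condition)][0].trials
        pd.testing.assert_frame_equal(a, b, check_dtype=False, atol=1e-9)

    def test_pipeline_end_to_end_excludes_nothing_by_default(self):
        blocks, _ = generate_fixture_experiment(n_subjects=3, seed=5)
        table, excluded = analyze_experiment(blocks)
        assert excluded == []
        assert set(table["condition"]) == {"NO", "LOW", "HIGH"}
        assert len(table) == 9
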