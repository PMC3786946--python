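"""Test-retest variability, variance components, ICC and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrt.reliability import (PairedOutcomeTable, ReliabilityError, effect_size,
                               icc, summarize_pairs, summarize_study, var_percent,
                               variance_components)


def pingouin_icc1(test, retest):
    """Independent one-way random-effects ICC(1,1) oracle."""
    import pingouin as pg
    n = len(test)
    df = pd.DataFrame({
        "subj": np.repeat(np.arange(n), 2),
        "rater": np.tile([0, 1], n),
        "y": np.column_stack([test, retest]).ravel(),
    })
    res = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
    return float(res.set_index("Type").loc["ICC(1,1)", "ICC"])


def table(test, retest):
    return PairedOutcomeTable("x", "r", np.asarray(test, float), np.asarray(retest, float))


class TestVarPercent:
    @pytest.mark.parametrize("t,r,expected", [
        (1.0, 1.0, 0.0),
        (1.1, 0.9, 20.0),
        (0.9, 1.1, 20.0),   # symmetric under session swap
    ])
    def test_definition_and_symmetry(self, t, r, expected):
        assert var_percent(t, r) == pytest.approx(expected)

    def test_zero_pair_mean_raises_for_scalars(self):
        with pytest.raises(ReliabilityError):
            var_percent(1.0, -1.0)

    def test_zero_pair_mean_excluded_with_warning_for_arrays(self):
        with pytest.warns(RuntimeWarning, match="zero test/retest mean"):
            v = var_percent(np.array([1.0, 1.0]), np.array([-1.0, 1.0]))
        assert np.isnan(v[0]) and v[1] == 0.0


class TestVarianceComponents:
    def test_two_by_two_anova_by_hand(self):
        # subjects {(1,1),(3,3)}: zero within, BSMSS = 2*[(1-2)^2+(3-2)^2]/(2-1) = 4
        vc = variance_components(table([1.0, 3.0], [1.0, 3.0]))
        assert vc["wsmss"] == 0.0
        assert vc["bsmss"] == pytest.approx(4.0)
        assert vc["bssd"] == pytest.approx(np.sqrt(2.0))  # SD of subject means {1,3}
        assert vc["wssd"] == 0.0

    def test_identical_values_give_zero_components(self):
        vc = variance_components(table([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]))
        assert vc["wsmss"] == 0.0 and vc["bsmss"] == 0.0

    def test_matches_general_anova_decomposition(self):
        # independent route: grand ANOVA identities on random tables
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.normal(10, 3, (10, 2))
            vc = variance_components(table(x[:, 0], x[:, 1]))
            N = 10
            grand = x.mean()
            ss_between = 2 * np.sum((x.mean(axis=1) - grand) ** 2)
            ss_within = np.sum((x - x.mean(axis=1, keepdims=True)) ** 2)
            assert vc["bsmss"] == pytest.approx(ss_between / (N - 1), rel=1e-12)
            assert vc["wsmss"] == pytest.approx(ss_within / N, rel=1e-12)
            # total SS partitions exactly
            assert ss_between + ss_within == pytest.approx(np.sum((x - grand) ** 2), rel=1e-12)


class TestICC:
    def test_identity_between_sessions_gives_one(self):
        assert icc(table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])) == pytest.approx(1.0)

    def test_equal_subject_means_give_minus_one(self):
        # subject means identical, sessions differ: BSMSS = 0
        assert icc(table([1.2, 0.7, 1.4], [0.8, 1.3, 0.6])) == pytest.approx(-1.0)

    def test_all_identical_undefined(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(icc(table([1.0, 1.0], [1.0, 1.0])))

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            x = rng.normal(8, rng.uniform(0.5, 4), (10, 2))
            mine = icc(table(x[:, 0], x[:, 1]))
            ref = pingouin_icc1(x[:, 0], x[:, 1])
            assert mine == pytest.approx(ref, rel=1e-10, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_bounded_in_minus_one_one(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (rng.integers(2, 12), 2)) * rng.uniform(0.1, 50)
        val = icc(table(x[:, 0], x[:, 1]))
        if np.isfinite(val):
            assert -1.0 <= val <= 1.0 + 1e-12

    def test_monotone_in_between_subject_spread(self):
        # fixed within-subject offsets; growing subject separation
        rng = np.random.default_rng(3)
        offsets = rng.normal(0, 0.3, 8)
        vals = []
        for spread in (0.1, 0.5, 1.0, 2.0, 4.0):
            means = np.linspace(-spread, spread, 8) + 10.0
            vals.append(icc(table(means + offsets, means - offsets)))
        assert np.all(np.diff(vals) > 0)

    def test_invariant_under_common_rescaling(self):
        x = np.random.default_rng(9).normal(5, 2, (10, 2))
        a = icc(table(x[:, 0], x[:, 1]))
        b = icc(table(17.3 * x[:, 0], 17.3 * x[:, 1]))
        assert a == pytest.approx(b, rel=1e-12)


class TestEffectSize:
    # all eight published challenge rows: (delta, base T-RT, post T-RT) -> d
    PUBLISHED = [
        (-7, 11, 7, 0.76), (-8, 15, 7, 0.68), (-13, 8, 5, 1.95), (-8, 7, 11, 0.87),
        (-11, 6, 4, 2.16), (-4, 10, 4, 0.53), (-12, 8, 4, 1.90), (-5, 10, 7, 0.58),
    ]

    @pytest.mark.parametrize("delta,base,post,expected", PUBLISHED)
    def test_reproduces_published_values(self, delta, base, post, expected):
        assert round(effect_size(delta, base, post), 2) == expected

    def test_zero_change_gives_zero(self):
        assert effect_size(0.0, 6.0, 4.0) == 0.0

    def test_zero_pooled_variability_rejected(self):
        with pytest.raises(ReliabilityError):
            effect_size(5.0, 0.0, 0.0)


class TestSummaries:
    def _outcomes(self, rng, n=6):
        rows = []
        for s in range(n):
            base = rng.uniform(4, 10)
            for sess in ("test", "retest"):
                vt_c = base * rng.uniform(0.95, 1.05)
                for region, vt in (("Cerebellum", vt_c), ("CortexA", 2 * vt_c)):
                    rows.append({"subject": s, "session": sess, "region": region,
                                 "VT": vt, "BPP": vt - vt_c, "BPND": vt / vt_c - 1})
        return pd.DataFrame(rows)

    def test_permuting_subjects_leaves_summary_unchanged(self):
        rng = np.random.default_rng(21)
        df = self._outcomes(rng)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = summarize_study(df).sort_values(["outcome", "region"]).reset_index(drop=True)
        b = summarize_study(shuffled).sort_values(["outcome", "region"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_incomplete_pairs_dropped_with_warning(self):
        df = self._outcomes(np.random.default_rng(2))
        df = df[~((df.subject == 0) & (df.session == "retest"))]
        with pytest.warns(RuntimeWarning, match="dropped"):
            out = summarize_study(df)
        assert (out.n_subjects == 5).all()

    def test_reference_region_summarised_for_vt_only(self):
        out = summarize_study(self._outcomes(np.random.default_rng(3)))
        cer = out[out.region == "Cerebellum"]
        assert set(cer.outcome) == {"VT"}

    def test_summary_row_fields_consistent(self):
        t = table([4.0, 5.0, 6.0], [4.4, 4.8, 6.3])
        row = summarize_pairs(t)
        assert row.icc == pytest.approx(icc(t))
        assert row.wssd == pytest.approx(np.sqrt(row.wsmss))
        v = var_percent(t.test, t.retest)
        assert row.var_mean_pct == pytest.approx(np.mean(v))
        assert row.var_sd_pct == pytest.approx(np.std(v, ddof=1))
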