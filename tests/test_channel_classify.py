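"""Channel classification rules, delta.meth.diff, ANOVA, enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epichannel.channel_classify import (
    EXPECTED,
    INCONCLUSIVE,
    INDUCIBLE,
    NOT_APPLICABLE,
    OPPOSITE,
    STABLE,
    CATEGORIES,
    acclimation_anova,
    build_channel_table,
    classify_channel,
    classify_direction,
    delta_meth_diff,
    enrichment_randomization,
    hepatosomatic_index,
)

ALPHA = 0.0125
MIN_DIFF = 15.0


class TestClassifyChannel:
    @pytest.mark.parametrize(
        "qw,dw,qt,dt,category,induced",
        [
            (0.5, 5, 0.9, 2, STABLE, set()),
            (0.001, 20, 0.3, 2, INDUCIBLE, {"within"}),
            (0.3, 2, 0.001, -20, INDUCIBLE, {"trans"}),
            (0.001, 20, 0.001, 30, INDUCIBLE, {"within", "trans"}),
            (0.001, 10, 0.001, -12, INCONCLUSIVE, set()),
            (0.001, 10, 0.9, 2, INCONCLUSIVE, set()),
            # precedence: one comparison fully inducible, other merely significant
            (0.001, 20, 0.001, 10, INDUCIBLE, {"within"}),
            (np.nan, 0, 0.5, 0, STABLE, set()),
        ],
    )
    def test_rules(self, qw, dw, qt, dt, category, induced):
        cat, ind = classify_channel(qw, dw, qt, dt, ALPHA, MIN_DIFF)
        assert cat == category and set(ind) == induced

    def test_boundary_q_is_not_significant(self):
        cat, _ = classify_channel(ALPHA, 20, ALPHA, 20, ALPHA, MIN_DIFF)
        assert cat == STABLE


class TestClassifyDirection:
    def test_sign_match(self):
        d, c = classify_direction(20.0, 18.0, 0.0, frozenset({"within"}))
        assert d == EXPECTED and not c

    def test_sign_mismatch(self):
        d, c = classify_direction(20.0, -16.0, 0.0, frozenset({"within"}))
        assert d == OPPOSITE and not c

    def test_conflict_trans_wins_flagged(self):
        d, c = classify_direction(20.0, 16.0, -17.0, frozenset({"within", "trans"}))
        assert d == OPPOSITE and c

    def test_agreeing_comparisons(self):
        d, c = classify_direction(-20.0, -16.0, -17.0, frozenset({"within", "trans"}))
        assert d == EXPECTED and not c

    def test_zero_wild_diff_not_applicable(self):
        d, c = classify_direction(0.0, 16.0, 0.0, frozenset({"within"}))
        assert d == NOT_APPLICABLE and c

    def test_not_inducible_not_applicable(self):
        d, c = classify_direction(20.0, 5.0, 5.0, frozenset())
        assert d == NOT_APPLICABLE and not c


class TestDeltaMethDiff:
    @pytest.mark.parametrize(
        "wild,exp,value",
        [
            (30.0, 30.0, 100.0),
            (30.0, 0.0, 70.0),
            (20.0, 35.0, 115.0),   # overshoot allowed
            (-30.0, -30.0, 100.0),  # orientation flips both signs
            (-30.0, 0.0, 70.0),
            (-20.0, 10.0, 70.0),   # opposite-direction change scores lower
        ],
    )
    def test_formula(self, wild, exp, value):
        assert delta_meth_diff(wild, exp) == pytest.approx(value)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-100, 100, allow_nan=False))
    def test_exact_match_scores_100_any_orientation(self, wild):
        assert delta_meth_diff(wild, wild) == pytest.approx(100.0)

    def test_vectorized(self):
        out = delta_meth_diff([30, -30], [30, -20])
        assert out == pytest.approx([100.0, 90.0])


def _anova_oracle_balanced(y):
    """Textbook balanced two-way SS decomposition on a 2x2xn array."""
    y = np.asarray(y, dtype=float)  # shape (2, 2, n)
    n = y.shape[2]
    grand = y.mean()
    a_means = y.mean(axis=(1, 2))   # direction
    b_means = y.mean(axis=(0, 2))   # acclimation
    cell_means = y.mean(axis=2)
    ss_a = 2 * n * ((a_means - grand) ** 2).sum()
    ss_b = 2 * n * ((b_means - grand) ** 2).sum()
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ((y - cell_means[:, :, None]) ** 2).sum()
    df_err = 4 * (n - 1)
    return (ss_b / 1) / (ss_err / df_err), (ss_ab / 1) / (ss_err / df_err)


class TestAcclimationAnova:
    def _long(self, y):
        y = np.asarray(y, dtype=float)
        rows = []
        for i, d in enumerate(("hypo", "hyper")):
            for j, a in enumerate(("within", "trans")):
                for v in y[i, j]:
                    rows.append((v, d, a))
        arr = np.array(rows, dtype=object)
        return arr[:, 0].astype(float), arr[:, 1], arr[:, 2]

    def test_balanced_fixture_matches_hand_ss(self):
        rng = np.random.default_rng(7)
        y = rng.normal(100, 5, size=(2, 2, 5))
        y[:, 1] += 6.0  # trans shift
        f_b, f_ab = _anova_oracle_balanced(y)
        res = acclimation_anova(*self._long(y))
        assert res.f_acclimation == pytest.approx(f_b, abs=1e-6)
        assert res.f_interaction == pytest.approx(f_ab, abs=1e-6)

    def test_equal_cell_means_zero_interaction(self):
        base = np.array([98.0, 100.0, 102.0])
        y = np.stack([
            np.stack([base, base]),
            np.stack([base, base]),
        ])
        res = acclimation_anova(*self._long(y))
        assert res.f_interaction == pytest.approx(0.0, abs=1e-9)
        assert res.f_acclimation == pytest.approx(0.0, abs=1e-9)

    def test_uniform_trans_shift_main_effect_only(self):
        rng = np.random.default_rng(11)
        y = rng.normal(90, 1, size=(2, 2, 30))
        y[:, 1] += 10.0
        res = acclimation_anova(*self._long(y))
        assert res.f_acclimation > 50
        assert res.p_acclimation < 1e-6
        assert res.p_interaction > 0.01

    def test_empty_cell_flagged(self):
        vals = [1.0, 2.0, 3.0, 4.0, 1.5, 2.5]
        dirs = ["hypo", "hypo", "hyper", "hyper", "hypo", "hyper"]
        accl = ["within", "within", "within", "within", "trans", "trans"]
        # remove the (hyper, trans) cell
        res = acclimation_anova(
            np.array(vals[:5]), np.array(dirs[:5]), np.array(accl[:5])
        )
        assert res.interaction_estimable is False and np.isnan(res.f_interaction)


class TestEnrichment:
    def test_observed_equals_expected_chi2_zero(self):
        cats = np.array(
            [INDUCIBLE] * 100 + [STABLE] * 100 + [INCONCLUSIVE] * 100, dtype=object
        )
        obs = {INDUCIBLE: 50, STABLE: 50, INCONCLUSIVE: 50}
        res = enrichment_randomization(cats, obs, 150, reps=400, seed=0)
        assert res.chi2 < 1.0 and res.p > 0.5

    def test_enriched_pop_dms_significant(self):
        rng = np.random.default_rng(2)
        cats = np.array(
            [INDUCIBLE] * 30 + [STABLE] * 900 + [INCONCLUSIVE] * 70, dtype=object
        )
        rng.shuffle(cats)
        obs = {INDUCIBLE: 60, STABLE: 30, INCONCLUSIVE: 10}  # 10x inducible
        res = enrichment_randomization(cats, obs, 100, reps=400, seed=0)
        assert res.p < 0.001

    def test_fixed_seed_reproducible(self):
        cats = np.array([INDUCIBLE] * 50 + [STABLE] * 150, dtype=object)
        obs = {INDUCIBLE: 20, STABLE: 30, INCONCLUSIVE: 0}
        a = enrichment_randomization(cats, obs, 50, reps=200, seed=42)
        b = enrichment_randomization(cats, obs, 50, reps=200, seed=42)
        assert a.expected == b.expected and a.p == b.p

    def test_oversized_draw_errors(self):
        cats = np.array([STABLE] * 10, dtype=object)
        with pytest.raises(ValueError):
            enrichment_randomization(cats, {STABLE: 5}, 11, reps=10, seed=0)


class TestHsi:
    def test_formula(self):
        assert hepatosomatic_index(0.05, 1.0) == pytest.approx(5.0)
        assert hepatosomatic_index(2.0, 2.0) == pytest.approx(100.0)

    @pytest.mark.parametrize("liver,total", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_rejected(self, liver, total):
        with pytest.raises(ValueError):
            hepatosomatic_index(liver, total)


class TestBuildChannelTable:
    def _tables(self):
        pop = pd.DataFrame({
            "chrom": ["chr1"] * 4, "pos": [10, 20, 30, 40],
            "meth_diff": [20.0, -25.0, 30.0, 18.0],
        })
        within = pd.DataFrame({
            "chrom": ["chr1"] * 4, "pos": [10, 20, 30, 40],
            "meth_diff": [18.0, -2.0, 10.0, 2.0],
            "q": [0.001, 0.5, 0.001, 0.8],
        })
        trans = pd.DataFrame({
            "chrom": ["chr1"] * 4, "pos": [10, 20, 30, 40],
            "meth_diff": [19.0, -20.0, 12.0, 1.0],
            "q": [0.001, 0.001, 0.002, 0.9],
        })
        return pop, within, trans

    def test_partition_and_calls(self):
        pop, within, trans = self._tables()
        tab = build_channel_table(pop, within, trans, ALPHA, MIN_DIFF)
        assert len(tab) == 4
        by_pos = tab.set_index("pos")
        assert by_pos.loc[10, "category"] == INDUCIBLE
        assert by_pos.loc[10, "direction"] == EXPECTED
        assert by_pos.loc[20, "category"] == INDUCIBLE
        assert by_pos.loc[20, "direction"] == EXPECTED  # -20 matches wild -25
        assert by_pos.loc[20, "orientation_flipped"]
        assert by_pos.loc[30, "category"] == INCONCLUSIVE
        assert by_pos.loc[40, "category"] == STABLE
        # categories always partition: exactly one category per site
        assert tab["category"].isin(CATEGORIES).all()

    def test_delta_values_oriented(self):
        pop, within, trans = self._tables()
        tab = build_channel_table(pop, within, trans, ALPHA, MIN_DIFF)
        by_pos = tab.set_index("pos")
        # site 20: wild -25 flipped to 25, exp flips -20 -> 20: 100-(25-20)=95
        assert by_pos.loc[20, "delta_meth_diff_trans"] == pytest.approx(95.0)
        assert by_pos.loc[10, "delta_meth_diff_within"] == pytest.approx(98.0)

    def test_sites_missing_from_comparison_dropped(self):
        pop, within, trans = self._tables()
        within = within[within["pos"] != 30]
        tab = build_channel_table(pop, within, trans, ALPHA, MIN_DIFF)
        assert 30 not in set(tab["pos"])


class TestClosedLoop:
    def test_partition_counts_sum(self, default_result):
        tab = default_result.channel_table
        counts = default_result.summary["category_counts"]
        assert sum(counts.values()) == len(tab) == default_result.summary["n_pop_dms"]

    def test_category_accuracy(self, channel_truth):
        ind = channel_truth[channel_truth["category"] == INDUCIBLE]
        correct = ind["planted_class"].isin(
            ["inducible-expected", "inducible-opposite"]
        )
        assert len(ind) >= 40
        assert correct.mean() >= 0.9

    def test_direction_accuracy(self, channel_truth):
        ind = channel_truth[
            (channel_truth["category"] == INDUCIBLE)
            & channel_truth["planted_class"].isin(
                ["inducible-expected", "inducible-opposite"]
            )
        ]
        ok = (
            ((ind["planted_class"] == "inducible-expected") & (ind["direction"] == EXPECTED))
            | ((ind["planted_class"] == "inducible-opposite") & (ind["direction"] == OPPOSITE))
        )
        assert ok.mean() >= 0.95

    def test_trans_closer_to_wild_than_within(self, channel_truth):
        """Accentuation across generations: delta.meth.diff trans > within."""
        exp = channel_truth[
            (channel_truth["planted_class"] == "inducible-expected")
            & (channel_truth["category"] == INDUCIBLE)
        ]
        assert len(exp) >= 20
        assert exp["delta_meth_diff_trans"].mean() > exp["delta_meth_diff_within"].mean()
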