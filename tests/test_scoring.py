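"""2^-ddCt fold changes, per-gene thresholds, and the 0/1 scoring statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcsig import (
    DOWN,
    INFLAMMATORY,
    NON_INFLAMMATORY,
    UP,
    build_scorecard,
    call_class,
    concordance,
    derive_thresholds,
    fold_change,
    score_condition,
)


def ct_rows(gene, condition, claimed, cts, ct18=10.0):
    return [
        (gene, condition, claimed, r + 1, ct, ct18) for r, ct in enumerate(np.atleast_1d(cts))
    ]


def make_ct(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "condition", "claimed_class", "replicate", "ct_target", "ct_18s"]
    )


def thresholds_frame(entries):
    """entries: gene -> (threshold, direction)"""
    return pd.DataFrame(
        {
            "threshold": {g: t for g, (t, _) in entries.items()},
            "direction": {g: d for g, (_, d) in entries.items()},
        }
    ).rename_axis("gene_id")


class TestFoldChange:
    def test_reference_identity_and_one_cycle_doubling(self):
        rows = ct_rows("g1", "untreated", "unknown", 26.0)
        rows += ct_rows("g1", "stim", INFLAMMATORY, 25.0)
        fc = fold_change(make_ct(rows))
        assert fc.values.loc["g1", "untreated"] == 1.0
        assert fc.values.loc["g1", "stim"] == pytest.approx(2.0)

    def test_replicate_folds_averaged_arithmetically(self):
        # folds 2, 4, 6 <-> ddCt -1, -2, -log2(6)
        cts = 26.0 - np.log2([2.0, 4.0, 6.0])
        rows = ct_rows("g1", "untreated", "unknown", 26.0)
        rows += ct_rows("g1", "stim", INFLAMMATORY, cts)
        fc = fold_change(make_ct(rows))
        assert fc.values.loc["g1", "stim"] == pytest.approx(4.0)
        assert fc.n_replicates.loc["g1", "stim"] == 3

    def test_housekeeping_normalization(self):
        # equal shifts in target and 18s cancel in dCt
        rows = ct_rows("g1", "untreated", "unknown", 26.0, ct18=10.0)
        rows += ct_rows("g1", "stim", INFLAMMATORY, 28.0, ct18=12.0)
        fc = fold_change(make_ct(rows))
        assert fc.values.loc["g1", "stim"] == pytest.approx(1.0)

    def test_missing_reference_names_gene(self):
        rows = ct_rows("g1", "stim", INFLAMMATORY, 25.0)
        with pytest.raises(ValueError, match="g1"):
            fold_change(make_ct(rows))

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(0)
        rows = []
        genes = [f"g{i}" for i in range(5)]
        conds = ["untreated", "a", "b"]
        cts = {}
        for g in genes:
            for c in conds:
                vals = rng.uniform(20, 30, 3)
                cts[(g, c)] = vals
                rows += ct_rows(g, c, "unknown", vals, ct18=10.0)
        fc = fold_change(make_ct(rows))
        for g in genes:
            ref = np.mean(cts[(g, "untreated")] - 10.0)
            for c in ("a", "b"):
                expected = np.mean(2.0 ** -((cts[(g, c)] - 10.0) - ref))
                assert fc.values.loc[g, c] == pytest.approx(expected)


class TestThresholds:
    def test_hand_computed_medians_and_mean(self):
        fc = pd.DataFrame(
            {
                "i1": [4.0], "i2": [8.0], "i3": [16.0],
                "n1": [0.5], "n2": [1.0], "n3": [2.0],
            },
            index=pd.Index(["g1"], name="gene_id"),
        )
        refs = {c: INFLAMMATORY for c in ("i1", "i2", "i3")}
        refs |= {c: NON_INFLAMMATORY for c in ("n1", "n2", "n3")}
        thr = derive_thresholds(fc, refs, {"g1": UP})
        assert thr.loc["g1", "median_inflammatory"] == 8.0
        assert thr.loc["g1", "median_noninflammatory"] == 1.0
        assert thr.loc["g1", "threshold"] == 4.5

    def test_even_replicate_median_midpoint(self):
        fc = pd.DataFrame(
            {"i1": [2.0], "i2": [4.0], "n1": [1.0], "n2": [1.0]},
            index=pd.Index(["g1"], name="gene_id"),
        )
        refs = {"i1": INFLAMMATORY, "i2": INFLAMMATORY,
                "n1": NON_INFLAMMATORY, "n2": NON_INFLAMMATORY}
        thr = derive_thresholds(fc, refs, {"g1": UP})
        assert thr.loc["g1", "median_inflammatory"] == 3.0

    def test_identical_class_medians_warn(self):
        fc = pd.DataFrame(
            {"i1": [2.0], "n1": [2.0]}, index=pd.Index(["g1"], name="gene_id")
        )
        with pytest.warns(UserWarning, match="equal class medians"):
            thr = derive_thresholds(
                fc, {"i1": INFLAMMATORY, "n1": NON_INFLAMMATORY}, {"g1": UP}
            )
        assert thr.loc["g1", "threshold"] == 2.0

    def test_class_without_reference_conditions_rejected(self):
        fc = pd.DataFrame({"i1": [2.0]}, index=pd.Index(["g1"], name="gene_id"))
        with pytest.raises(ValueError, match="per class"):
            derive_thresholds(fc, {"i1": INFLAMMATORY}, {"g1": UP})

    def test_threshold_lies_between_differing_medians(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(20)]
        fc = pd.DataFrame(
            rng.lognormal(0, 1, (20, 6)),
            index=pd.Index(genes, name="gene_id"),
            columns=["i1", "i2", "i3", "n1", "n2", "n3"],
        )
        refs = {"i1": INFLAMMATORY, "i2": INFLAMMATORY, "i3": INFLAMMATORY,
                "n1": NON_INFLAMMATORY, "n2": NON_INFLAMMATORY, "n3": NON_INFLAMMATORY}
        thr = derive_thresholds(fc, refs, {g: UP for g in genes})
        lo = thr[["median_inflammatory", "median_noninflammatory"]].min(axis=1)
        hi = thr[["median_inflammatory", "median_noninflammatory"]].max(axis=1)
        differ = lo < hi
        assert ((thr.loc[differ, "threshold"] > lo[differ])
                & (thr.loc[differ, "threshold"] < hi[differ])).all()


def quoted_rule_oracle(direction, claimed, value, threshold):
    """Direct enumeration of the scoring sentence, case by case."""
    if direction == UP:
        if claimed == INFLAMMATORY:
            return 1 if value > threshold else 0
        return 1 if value < threshold else 0
    if claimed == INFLAMMATORY:
        return 1 if value < threshold else 0
    return 1 if value > threshold else 0


class TestScoreCondition:
    def test_up_gene_above_threshold(self):
        thr = thresholds_frame({"g1": (4.5, UP)})
        assert score_condition({"g1": 6.0}, thr, INFLAMMATORY)["g1"] == 1
        assert score_condition({"g1": 6.0}, thr, NON_INFLAMMATORY)["g1"] == 0

    def test_value_at_threshold_scores_zero(self):
        for direction in (UP, DOWN):
            thr = thresholds_frame({"g1": (4.5, direction)})
            for claim in (INFLAMMATORY, NON_INFLAMMATORY):
                assert score_condition({"g1": 4.5}, thr, claim)["g1"] == 0

    def test_eight_case_truth_table_matches_oracle(self):
        threshold = 2.0
        for direction, claim, side in itertools.product(
            (UP, DOWN), (INFLAMMATORY, NON_INFLAMMATORY), (1.0, 3.0)
        ):
            thr = thresholds_frame({"g1": (threshold, direction)})
            got = score_condition({"g1": side}, thr, claim)["g1"]
            assert got == quoted_rule_oracle(direction, claim, side, threshold)

    def test_unknown_gene_rejected(self):
        thr = thresholds_frame({"g1": (1.0, UP)})
        with pytest.raises(ValueError, match="g2"):
            score_condition({"g2": 1.0}, thr, INFLAMMATORY)

    @given(
        value=st.floats(0.01, 100.0),
        threshold=st.floats(0.01, 100.0),
        direction=st.sampled_from([UP, DOWN]),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_duality_and_scale_equivariance(self, value, threshold, direction, scale):
        thr = thresholds_frame({"g": (threshold, direction)})
        s_inf = score_condition({"g": value}, thr, INFLAMMATORY)["g"]
        s_ninf = score_condition({"g": value}, thr, NON_INFLAMMATORY)["g"]
        # the two claims partition the off-threshold cases
        assert s_inf + s_ninf == (0 if value == threshold else 1)
        # multiplying value and threshold by c > 0 leaves scores unchanged
        thr_scaled = thresholds_frame({"g": (threshold * scale, direction)})
        assert score_condition({"g": value * scale}, thr_scaled, INFLAMMATORY)["g"] == s_inf


class TestConcordance:
    @pytest.mark.parametrize(
        "k,n,percent",
        [(51, 54, 94), (54, 54, 100), (43, 54, 80), (46, 54, 85), (48, 54, 89),
         (52, 54, 96), (53, 54, 98), (35, 44, 80), (40, 44, 91), (0, 10, 0)],
    )
    def test_percent_formatting_matches_printed_pairs(self, k, n, percent):
        c = concordance([1] * k + [0] * (n - k))
        assert c.percent == percent
        assert c.k_of_n == f"{k}/{n}"
        assert c.fraction == pytest.approx(k / n)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            concordance([])


class TestClassCall:
    def test_unanimous_and_tie(self):
        thr = thresholds_frame({f"g{i}": (1.0, UP) for i in range(4)})
        res = call_class({f"g{i}": 2.0 for i in range(4)}, thr)
        assert res.call == INFLAMMATORY and res.margin == 1.0
        res = call_class({"g0": 2.0, "g1": 2.0, "g2": 0.5, "g3": 0.5}, thr)
        assert res.call == NON_INFLAMMATORY and res.margin == 0.0

    @given(
        folds=st.lists(st.floats(0.1, 10.0), min_size=3, max_size=9),
        claim=st.sampled_from([INFLAMMATORY, NON_INFLAMMATORY]),
    )
    @settings(max_examples=60, deadline=None)
    def test_call_agrees_with_majority_concordance(self, folds, claim):
        thr = thresholds_frame({f"g{i}": (1.0, UP) for i in range(len(folds))})
        values = {f"g{i}": v for i, v in enumerate(folds)}
        scores = score_condition(values, thr, claim)
        if concordance(scores).fraction > 0.5:
            assert call_class(values, thr).call == claim


class TestScoreCardRoundTrip:
    def test_planted_directions_score_perfectly_at_zero_noise(self):
        from dcsig import SyntheticConfig, generate_ct_table, generate_expression

        cfg = SyntheticConfig(n_genes=80, n_signature_up=6, n_signature_down=4, seed=21)
        _, _, _, truth = generate_expression(cfg)
        conditions = [
            ("infA", INFLAMMATORY), ("infB", INFLAMMATORY),
            ("ninfA", NON_INFLAMMATORY), ("ninfB", NON_INFLAMMATORY),
        ]
        ct = generate_ct_table(cfg, truth, conditions, log2_fold=2.0, noise_sd=0.0)
        fc = fold_change(ct)
        thr = derive_thresholds(fc, dict(conditions), truth.directions)
        for cond, cls in conditions:
            card = build_scorecard(fc, thr, cond)
            assert card.claimed_class == cls
            assert card.concordance.fraction == 1.0
            assert card.class_call == cls
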