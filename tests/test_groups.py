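"""Post-hoc grouping, group comparison, and interrater reliability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neorsa import (
    ObservationRecord,
    RSASummary,
    assign_groups,
    compare_rsa,
    make_observation_records,
    paired_ratings,
    percent_agreement,
    weighted_kappa,
)


def _obs(subject, rater, pattern):
    return ObservationRecord(subject_id=subject, rater_id=rater, pattern=pattern,
                             eyes_closed=True, gross_movement=False)


class TestAssignGroups:
    def test_consensus_maps_to_groups(self):
        obs = [
            _obs("S1", "R1", "irregular_shallow"),
            _obs("S1", "R2", "irregular_shallow"),
            _obs("S2", "R1", "regular_deep"),
            _obs("S2", "R2", "regular_deep"),
        ]
        groups, excluded = assign_groups(obs)
        assert groups == {"S1": 2, "S2": 1}
        assert excluded == []

    def test_two_rater_tie_excluded(self):
        obs = [
            _obs("S1", "R1", "regular_deep"),
            _obs("S1", "R2", "irregular_shallow"),
        ]
        groups, excluded = assign_groups(obs)
        assert "S1" not in groups
        assert excluded == ["S1"]

    def test_full_cohort_partitions(self):
        cohort = [(f"S{i:02d}", "A" if i % 2 else "B") for i in range(18)]
        obs = make_observation_records(cohort, agreement_prob=1.0, seed=0)
        groups, excluded = assign_groups(obs)
        assert len(groups) + len(excluded) == 18
        assert len(groups) == 18  # perfect agreement: nobody excluded

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assign_groups([])


def _summaries(values_g1, values_g2):
    out = []
    for i, v in enumerate(values_g1):
        out.append(RSASummary(rsa_mean=v, auc=v / 2, subject_id=f"A{i}"))
    for i, v in enumerate(values_g2):
        out.append(RSASummary(rsa_mean=v, auc=v / 2, subject_id=f"B{i}"))
    groups = {f"A{i}": 1 for i in range(len(values_g1))}
    groups.update({f"B{i}": 2 for i in range(len(values_g2))})
    return out, groups


class TestCompareRSA:
    def test_identical_groups_null(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        summaries, groups = _summaries(vals, vals)
        res = compare_rsa(summaries, groups)
        assert res.ratio_of_means == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_label_swap_inverts_ratio(self):
        summaries, groups = _summaries([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        res = compare_rsa(summaries, groups)
        swapped = {k: 3 - v for k, v in groups.items()}
        res_swapped = compare_rsa(summaries, swapped)
        assert res_swapped.ratio_of_means == pytest.approx(1.0 / res.ratio_of_means)

    def test_small_group_rejected(self):
        summaries, groups = _summaries([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            compare_rsa(summaries, groups)

    def test_summary_text_mentions_both_groups(self):
        summaries, groups = _summaries([1.0, 2.0], [3.0, 4.0])
        text = compare_rsa(summaries, groups).summary()
        assert "group 1" in text and "group 2" in text


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self):
        r = ["regular_deep", "irregular_shallow"] * 5
        for scheme in ("unweighted", "linear", "quadratic"):
            assert weighted_kappa(r, r, scheme=scheme).kappa == pytest.approx(1.0)

    def test_worked_2x2_table(self):
        # table a=10, b=1, c=1, d=8: po = 0.90, pe = (11*11 + 9*9)/400 = 0.505
        # kappa = (0.90 - 0.505) / (1 - 0.505) = 0.797979...
        r1 = [0] * 11 + [1] * 9
        r2 = [0] * 10 + [1] + [0] + [1] * 8
        res = weighted_kappa(r1, r2, scheme="linear")
        assert res.observed_agreement == pytest.approx(0.90)
        assert res.expected_agreement == pytest.approx(0.505)
        assert res.kappa == pytest.approx(0.797979797979798, abs=1e-12)

    def test_marginal_product_table_gives_zero(self):
        # counts equal to the outer product of the marginals => chance level
        r1, r2 = [], []
        for i, ni in enumerate((8, 2)):
            for j, w in enumerate((5, 5)):
                count = ni * w // 10
                r1 += [i] * count
                r2 += [j] * count
        res = weighted_kappa(r1, r2, scheme="unweighted")
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_two_category_linear_equals_unweighted(self):
        rng = np.random.default_rng(3)
        r1 = rng.integers(0, 2, 50).tolist()
        r2 = rng.integers(0, 2, 50).tolist()
        lin = weighted_kappa(r1, r2, scheme="linear").kappa
        unw = weighted_kappa(r1, r2, scheme="unweighted").kappa
        assert lin == pytest.approx(unw, abs=1e-12)

    def test_degenerate_single_category_undefined(self):
        res = weighted_kappa(["a"] * 10, ["a"] * 10)
        assert not res.defined

    @pytest.mark.parametrize("scheme", ["unweighted", "linear", "quadratic"])
    def test_matches_sklearn(self, scheme):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        r1 = rng.integers(0, 4, 200)
        r2 = np.where(rng.random(200) < 0.7, r1, rng.integers(0, 4, 200))
        weights = None if scheme == "unweighted" else scheme
        expected = cohen_kappa_score(r1, r2, weights=weights)
        got = weighted_kappa(r1.tolist(), r2.tolist(), scheme=scheme).kappa
        assert got == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=60
        )
    )
    def test_kappa_at_most_one_and_relabel_invariant(self, pairs):
        r1 = [p[0] for p in pairs]
        r2 = [p[1] for p in pairs]
        res = weighted_kappa(r1, r2, scheme="linear", categories=[0, 1, 2, 3])
        if res.defined:
            assert res.kappa <= 1.0 + 1e-12
            # order-preserving relabeling of both raters leaves kappa unchanged
            relabeled = weighted_kappa(
                [x * 2 for x in r1], [x * 2 for x in r2],
                scheme="linear", categories=[0, 2, 4, 6],
            )
            assert relabeled.kappa == pytest.approx(res.kappa, abs=1e-9)
            off_diag = res.contingency.sum() - np.trace(res.contingency)
            assert (res.kappa == pytest.approx(1.0)) == (off_diag == 0)


class TestPercentAgreement:
    def test_arithmetic(self):
        r1 = list(range(20))
        r2 = list(range(18)) + [99, 98]
        assert percent_agreement(r1, r2) == pytest.approx(0.90)

    def test_all_match(self):
        assert percent_agreement([1, 2, 3], [1, 2, 3]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_agreement([], [])

    def test_generator_agreement_recovered(self):
        cohort = [(f"S{i:04d}", "A") for i in range(1000)]
        obs = make_observation_records(cohort, agreement_prob=0.97, seed=5)
        r1, r2 = paired_ratings(obs)
        assert 0.95 <= percent_agreement(r1, r2) <= 0.99
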