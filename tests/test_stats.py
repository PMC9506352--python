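"""Tests of pairwise t-tests, the compact letter display and dose-response
aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pawcal.stats import (
    GroupTable,
    build_dose_response,
    letter_display,
    pairwise_tests,
)


def _p_matrix(labels, significant_pairs):
    """Build a p-matrix with p=0.01 on the given pairs, 0.5 elsewhere."""
    p = pd.DataFrame(0.5, index=labels, columns=labels)
    np.fill_diagonal(p.values, 1.0)
    for a, b in significant_pairs:
        p.loc[a, b] = p.loc[b, a] = 0.01
    return p


def _relation_from_letters(display, labels):
    """Significance relation implied by the letters: True = differ."""
    return {
        (a, b): not display.share(a, b)
        for a, b in itertools.combinations(labels, 2)
    }


def _brute_force_valid_cover(labels, significant_pairs, n_letters):
    """Is there an assignment of <= n_letters letter-columns (cliques of the
    non-significance graph) covering every non-significant pair and every
    group?  Exhaustive over all clique subsets -- oracle for small n."""
    sig = set(map(frozenset, significant_pairs))
    nonsig_pairs = [
        frozenset(p)
        for p in itertools.combinations(labels, 2)
        if frozenset(p) not in sig
    ]
    # all cliques of the non-significance graph
    cliques = []
    for r in range(1, len(labels) + 1):
        for subset in itertools.combinations(labels, r):
            if all(
                frozenset((a, b)) not in sig
                for a, b in itertools.combinations(subset, 2)
            ):
                cliques.append(set(subset))
    for r in range(1, n_letters + 1):
        for cover in itertools.combinations(cliques, r):
            union = set().union(*cover)
            if union != set(labels):
                continue
            if all(any(p <= c for c in cover) for p in nonsig_pairs):
                return r
    return None


class TestPairwise:
    def test_identical_groups(self):
        table = GroupTable({"a": [2, 4, 6], "b": [2, 4, 6]})
        p = pairwise_tests(table)
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        # (1,2,3) vs (4,5,6): pooled sd 1, t = -3/sqrt(2/3), df = 4
        from scipy import stats as sps

        table = GroupTable({"a": [1, 2, 3], "b": [4, 5, 6]})
        p = pairwise_tests(table)
        t = -3.0 / np.sqrt(2.0 / 3.0)
        expected = 2 * sps.t.sf(abs(t), df=4)
        assert p.loc["a", "b"] == pytest.approx(expected, rel=1e-9)
        assert p.loc["a", "b"] == pytest.approx(0.0214, abs=5e-4)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        table = GroupTable({c: rng.normal(size=6) for c in "abcd"})
        p = pairwise_tests(table)
        assert np.allclose(p.values, p.values.T)
        assert np.allclose(np.diag(p.values), 1.0)

    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            p_same = pairwise_tests(GroupTable({"a": [5, 5], "b": [5, 5]}))
        assert p_same.loc["a", "b"] == 1.0
        with pytest.warns(UserWarning):
            p_diff = pairwise_tests(GroupTable({"a": [5, 5], "b": [7, 7]}))
        assert p_diff.loc["a", "b"] == 0.0

    def test_welch_flag_changes_result_under_heteroscedasticity(self):
        rng = np.random.default_rng(1)
        table = GroupTable(
            {"a": rng.normal(0, 0.1, 4), "b": rng.normal(1, 10.0, 12)}
        )
        student = pairwise_tests(table).loc["a", "b"]
        welch = pairwise_tests(table, welch=True).loc["a", "b"]
        assert student != pytest.approx(welch, rel=1e-6)

    def test_holm_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(2)
        table = GroupTable({c: rng.normal(i, 1, 6) for i, c in enumerate("abcd")})
        raw = pairwise_tests(table)
        adj = pairwise_tests(table, holm=True)
        off_diag = ~np.eye(4, dtype=bool)
        assert np.all(adj.values[off_diag] >= raw.values[off_diag] - 1e-12)

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            GroupTable({"a": [1.0], "b": [1, 2]})


class TestLetterDisplay:
    def test_all_pairs_significant(self):
        labels = ["g1", "g2", "g3"]
        p = _p_matrix(labels, itertools.combinations(labels, 2))
        display = letter_display(p)
        assert [display.letters[g] for g in labels] == ["a", "b", "c"]

    def test_no_pair_significant(self):
        labels = ["g1", "g2", "g3"]
        display = letter_display(_p_matrix(labels, []))
        assert all(display.letters[g] == "a" for g in labels)

    def test_extremes_only_matches_brute_force(self):
        labels = ["g1", "g2", "g3", "g4"]
        sig = [("g1", "g4")]
        display = letter_display(_p_matrix(labels, sig))
        # iff-sharing relation reproduced
        relation = _relation_from_letters(display, labels)
        assert relation == {
            pair: (set(pair) == {"g1", "g4"})
            for pair in itertools.combinations(labels, 2)
        }
        # letter count matches the brute-force minimal clique cover
        n_used = len(set("".join(display.letters.values())))
        assert n_used == _brute_force_valid_cover(labels, sig, n_used)
        assert _brute_force_valid_cover(labels, sig, n_used - 1) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_random_graphs_reconstruct_relation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        labels = [f"g{i}" for i in range(n)]
        sig = [
            pair
            for pair in itertools.combinations(labels, 2)
            if rng.random() < 0.4
        ]
        display = letter_display(_p_matrix(labels, sig))
        relation = _relation_from_letters(display, labels)
        expected = {
            pair: frozenset(pair) in set(map(frozenset, sig))
            for pair in itertools.combinations(labels, 2)
        }
        assert relation == expected
        # every group carries at least one letter
        assert all(display.letters[g] for g in labels)


class TestDoseResponse:
    def _metrics(self):
        rng = np.random.default_rng(3)
        rows = []
        for treatment, mean in [("low", 2e-4), ("high", 5e-4)]:
            for r in range(6):
                rows.append(
                    {
                        "well_id": f"{treatment}_r{r}",
                        "treatment": treatment,
                        "auc": mean + rng.normal(0, 1e-5),
                    }
                )
        return pd.DataFrame(rows)

    def _doses(self):
        return pd.DataFrame(
            [
                {"treatment": "low", "energy_per_mass": 5e4},
                {"treatment": "high", "energy_per_mass": 5e5},
            ]
        )

    def test_single_treatment(self):
        metrics = self._metrics()
        metrics = metrics[metrics["treatment"] == "low"]
        out = build_dose_response(metrics, self._doses().iloc[:1])
        assert len(out) == 1
        assert out.loc[0, "n"] == 6

    def test_sorted_by_energy_with_summary(self):
        out = build_dose_response(self._metrics(), self._doses())
        assert list(out["treatment"]) == ["low", "high"]
        assert np.all(out["se"] >= 0)
        assert out.loc[0, "mean"] == pytest.approx(2e-4, rel=0.05)

    def test_missing_dose_record_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="without dose records"):
            out = build_dose_response(self._metrics(), self._doses().iloc[:1])
        assert list(out["treatment"]) == ["low"]
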