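"""The SCC decision engine: minimal prefix decisions, transitions, sweeps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scclassify.classify import ClassSet, PosteriorRecord, map_decision
from scclassify.scc import (
    collective_certainty,
    collective_certainty_sweep,
    cross_tabulate,
    default_beta_grid,
    is_correct,
    scc_decide,
    subset_label,
    threshold_sweep,
    tradeoff_curve,
    transition_profile,
    write_decisions,
)


def brute_force_decision(probs, class_set, beta, tol=1e-12):
    """Independent oracle: enumerate every non-empty subset, keep those with
    mass >= beta, return the minimum cardinality among them and whether the
    sorted prefix of that cardinality attains beta."""
    k = len(probs)
    best = k
    for r in range(1, k + 1):
        if any(
            sum(probs[i] for i in comb) >= beta - tol
            for comb in itertools.combinations(range(k), r)
        ):
            best = r
            break
    return best


class TestDecide:
    def test_map_threshold_keeps_close_call_atomic(self, three_classes):
        rec = PosteriorRecord("r", np.array([0.34, 0.33, 0.33]))
        dec = scc_decide(rec, three_classes, 1 / 3)
        assert dec.decision == ("Adeno",)
        assert dec.precision == 1

    def test_high_certainty_read_stays_atomic_at_high_beta(self, three_classes):
        rec = PosteriorRecord("r", np.array([0.99, 0.005, 0.005]))
        dec = scc_decide(rec, three_classes, 0.99)
        assert dec.decision == ("Adeno",)
        assert dec.achieved_certainty == pytest.approx(0.99)

    def test_hand_cumulative_example(self, three_classes):
        rec = PosteriorRecord("r", np.array([0.5, 0.3, 0.2]))
        dec = scc_decide(rec, three_classes, 0.75)
        assert dec.decision == ("Adeno", "COVID")
        assert dec.achieved_certainty == pytest.approx(0.8)
        assert dec.precision == 2

    def test_beta_one_returns_all_nonzero_classes(self, three_classes):
        rec = PosteriorRecord("r", np.array([0.5, 0.3, 0.2]))
        assert scc_decide(rec, three_classes, 1.0).precision == 3
        degenerate = PosteriorRecord("d", np.array([1.0, 0.0, 0.0]))
        assert scc_decide(degenerate, three_classes, 1.0).decision == ("Adeno",)

    @pytest.mark.parametrize("beta", [0.0, -0.2, 1.0001])
    def test_beta_outside_unit_interval_rejected(self, three_classes, beta):
        rec = PosteriorRecord("r", np.full(3, 1 / 3))
        with pytest.raises(ValueError):
            scc_decide(rec, three_classes, beta)

    def test_ties_follow_class_order(self, three_classes):
        rec = PosteriorRecord("r", np.array([0.25, 0.5, 0.25]))
        dec = scc_decide(rec, three_classes, 0.75)
        assert dec.decision == ("COVID", "Adeno")

    @settings(max_examples=150, deadline=None)
    @given(
        raw=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=4).filter(
            lambda xs: sum(xs) > 1e-9
        ),
        beta=st.floats(0.01, 1.0),
    )
    def test_oracle_equivalence_and_minimality(self, raw, beta):
        probs = np.array(raw) / sum(raw)
        k = len(probs)
        cs = ClassSet(tuple(f"c{i}" for i in range(k)))
        rec = PosteriorRecord("h", probs)
        dec = scc_decide(rec, cs, beta)
        assert dec.precision == brute_force_decision(probs, cs, beta)
        assert dec.achieved_certainty >= beta - 1e-12 or dec.precision == sum(
            probs > 0
        )
        # minimality witness: dropping the last member falls below beta
        if dec.precision > 1:
            last = probs[[cs.index(c) for c in dec.decision[-1:]]][0]
            assert dec.achieved_certainty - last < beta

    @settings(max_examples=150, deadline=None)
    @given(
        raw=st.lists(st.floats(0.001, 1.0), min_size=2, max_size=4),
    )
    def test_map_equivalence_at_one_over_k(self, raw):
        probs = np.array(raw) / sum(raw)
        cs = ClassSet(tuple(f"c{i}" for i in range(len(probs))))
        rec = PosteriorRecord("h", probs)
        dec = scc_decide(rec, cs, 1.0 / len(probs))
        assert dec.precision == 1
        assert dec.decision[0] == map_decision(rec, cs)

    @settings(max_examples=100, deadline=None)
    @given(
        raw=st.lists(st.floats(0.001, 1.0), min_size=3, max_size=3),
        b1=st.floats(0.05, 1.0),
        b2=st.floats(0.05, 1.0),
    )
    def test_monotone_nesting(self, three_classes, raw, b1, b2):
        lo, hi = min(b1, b2), max(b1, b2)
        probs = np.array(raw) / sum(raw)
        rec = PosteriorRecord("h", probs)
        d_lo = scc_decide(rec, three_classes, lo)
        d_hi = scc_decide(rec, three_classes, hi)
        assert set(d_lo.decision) <= set(d_hi.decision)
        assert d_hi.decision[: d_lo.precision] == d_lo.decision


class TestTransitions:
    def test_partial_sums(self, three_classes):
        rec = PosteriorRecord("r", np.array([0.5, 0.3, 0.2]))
        np.testing.assert_allclose(
            transition_profile(rec, three_classes).cut_points, [0.5, 0.8]
        )

    def test_degenerate_posterior_saturates(self, three_classes):
        rec = PosteriorRecord("r", np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(
            transition_profile(rec, three_classes).cut_points, [1.0, 1.0]
        )

    def test_two_class_transition_is_max_responsibility(self):
        cs = ClassSet(("1", "2"))
        rec = PosteriorRecord("AL", np.array([0.9905, 0.0095]))
        prof = transition_profile(rec, cs)
        assert prof.cut_points[0] == pytest.approx(0.9905)

    def test_first_cut_point_is_map_certainty_and_decides_precision(
        self, three_classes
    ):
        rng = np.random.default_rng(6)
        for probs in rng.dirichlet(np.ones(3), size=50):
            rec = PosteriorRecord("r", probs)
            cuts = transition_profile(rec, three_classes).cut_points
            assert cuts[0] == pytest.approx(np.max(probs))
            for beta in (0.4, 0.7, 0.9, 0.99):
                prec = scc_decide(rec, three_classes, beta).precision
                expected = 1 + int(np.searchsorted(cuts + 1e-12, beta))
                assert prec == expected


class TestCorrectness:
    def test_compound_decision_containing_truth_is_correct(self, three_classes):
        rec = PosteriorRecord("r", np.array([0.45, 0.1, 0.45]))
        dec = scc_decide(rec, three_classes, 0.8)
        assert set(dec.decision) == {"Adeno", "SARS"}
        assert is_correct(dec, "Adeno", three_classes)
        assert not is_correct(dec, "COVID", three_classes)

    def test_full_set_always_correct(self, three_classes):
        rec = PosteriorRecord("r", np.array([0.4, 0.3, 0.3]))
        dec = scc_decide(rec, three_classes, 1.0)
        for truth in three_classes:
            assert is_correct(dec, truth, three_classes)

    def test_unknown_truth_rejected(self, three_classes):
        dec = scc_decide(
            PosteriorRecord("r", np.full(3, 1 / 3)), three_classes, 0.5
        )
        with pytest.raises(ValueError):
            is_correct(dec, "Ebola", three_classes)


class TestSweep:
    def test_default_grid_is_map_plus_49_steps(self):
        grid = default_beta_grid(3)
        assert len(grid) == 50
        assert grid[0] == pytest.approx(1 / 3)
        assert grid[1] == 0.51 and grid[-1] == 0.99

    def test_degenerate_record_occupies_single_subset(self, three_classes):
        recs = [PosteriorRecord("r", np.array([1.0, 0.0, 0.0]), truth="Adeno")]
        sweep = threshold_sweep(recs, three_classes)
        assert (sweep["subset"] == "Adeno").all()
        assert sweep["correct"].all()

    def test_counts_conserved_at_every_beta(self, three_classes):
        rng = np.random.default_rng(2)
        recs = [
            PosteriorRecord(f"r{i}", p, truth="SARS")
            for i, p in enumerate(rng.dirichlet(np.ones(3), size=40))
        ]
        sweep = threshold_sweep(recs, three_classes)
        assert (sweep.groupby("beta")["count"].sum() == 40).all()

    def test_no_precision1_row_below_map_certainty(self, three_classes):
        rng = np.random.default_rng(3)
        recs = [
            PosteriorRecord(f"r{i}", p)
            for i, p in enumerate(rng.dirichlet(np.ones(3), size=30))
        ]
        sweep = threshold_sweep(recs, three_classes, betas=[0.99])
        singles = sweep[sweep["precision"] == 1]["count"].sum()
        expected = sum(np.max(r.probs) >= 0.99 - 1e-12 for r in recs)
        assert singles == expected


class TestTradeoffAndCollective:
    def _labelled_records(self, n=60, seed=4):
        rng = np.random.default_rng(seed)
        labels = ("Adeno", "COVID", "SARS")
        recs = []
        for i, p in enumerate(rng.dirichlet([2, 1, 1], size=n)):
            recs.append(
                PosteriorRecord(f"r{i}", p, truth=labels[rng.integers(0, 3)])
            )
        return recs

    def test_all_degenerate_correct_records_sit_at_optimum(self, three_classes):
        recs = [
            PosteriorRecord(f"r{i}", np.array([1.0, 0.0, 0.0]), truth="Adeno")
            for i in range(5)
        ]
        curve = tradeoff_curve(recs, three_classes)
        assert (curve["n_compound"] == 0).all()
        assert (curve["n_correct"] == 5).all()

    def test_map_beta_has_no_compound_decisions(self, three_classes):
        curve = tradeoff_curve(self._labelled_records(), three_classes, [1 / 3])
        assert curve.loc[0, "n_compound"] == 0

    def test_correct_count_non_decreasing_in_beta(self, three_classes):
        curve = tradeoff_curve(self._labelled_records(), three_classes)
        assert (np.diff(curve["n_correct"]) >= 0).all()

    def test_collective_product_rule(self, three_classes):
        recs = [
            PosteriorRecord("a", np.array([0.9, 0.05, 0.05])),
            PosteriorRecord("b", np.array([0.9, 0.05, 0.05])),
        ]
        decs = [scc_decide(r, three_classes, 0.5) for r in recs]
        prod, log_prod = collective_certainty(decs)
        assert prod == pytest.approx(0.81)
        assert log_prod == pytest.approx(np.log(0.81))

    def test_collective_certainty_non_decreasing_in_beta(self, three_classes):
        recs = self._labelled_records()
        sweep = collective_certainty_sweep(recs, three_classes)
        assert (np.diff(sweep["log_collective"]) >= -1e-12).all()

    def test_collective_of_certain_decisions_is_one(self, three_classes):
        recs = [PosteriorRecord("a", np.array([1.0, 0.0, 0.0]))]
        decs = [scc_decide(r, three_classes, 0.9) for r in recs]
        assert collective_certainty(decs)[0] == pytest.approx(1.0)


class TestCrossTab:
    def test_two_class_table_structure_with_margins(self):
        cs = ClassSet(("1", "2"))
        probs = [(0.95, 0.05), (0.9, 0.1), (0.2, 0.8), (0.55, 0.45)]
        labels = ["R", "R", "D", "D"]
        decs = [
            scc_decide(PosteriorRecord(f"s{i}", np.array(p)), cs, 0.6)
            for i, p in enumerate(probs)
        ]
        table = cross_tabulate(decs, labels, cs)
        assert list(table.index) == ["1", "2", "1-or-2", "Sum"]
        assert table.loc["Sum", "Sum"] == 4
        assert table.loc["1", "R"] == 2
        assert table.loc["1-or-2", "D"] == 1  # the 0.55 state at beta 0.6

    def test_empty_compound_rows_retained_with_zero_counts(self):
        cs = ClassSet(("1", "2"))
        decs = [
            scc_decide(PosteriorRecord("s", np.array([1.0, 0.0])), cs, 0.5)
        ]
        table = cross_tabulate(decs, ["D"], cs)
        assert table.loc["1-or-2", "D"] == 0

    def test_length_mismatch_rejected(self):
        cs = ClassSet(("1", "2"))
        decs = [
            scc_decide(PosteriorRecord("s", np.array([1.0, 0.0])), cs, 0.5)
        ]
        with pytest.raises(ValueError):
            cross_tabulate(decs, ["D", "R"], cs)


class TestDecisionIO:
    def test_decision_tsv_uses_or_joined_labels(self, tmp_path, three_classes):
        recs = [
            PosteriorRecord("r0", np.array([0.5, 0.3, 0.2]), truth="COVID"),
        ]
        decs = [scc_decide(r, three_classes, 0.75) for r in recs]
        path = tmp_path / "dec.tsv"
        write_decisions(
            decs, path, truths={"r0": "COVID"}, class_set=three_classes
        )
        df = pd.read_csv(path, sep="\t")
        assert df.loc[0, "decision"] == "Adeno-or-COVID"
        assert bool(df.loc[0, "correct"]) is True
        assert subset_label(("SARS", "Adeno"), three_classes) == "Adeno-or-SARS"
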