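"""Differential expression: tests, FDR, state calls, subsets, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gliomanet as g
from gliomanet.de import OVER, UNCHANGED, UNDER
from gliomanet.io import ConsistencyError


class TestWelchT:
    def test_identical_groups(self):
        t, p = g.welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_frozen_closed_form_value(self):
        # means 2 vs 5, both variances 1: t = -3/sqrt(2/3), df = 4
        t, p = g.welch_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert p == pytest.approx(0.021312, abs=1e-4)

    def test_swap_negates_t(self):
        t1, p1 = g.welch_t([1, 2, 3], [4, 5, 7])
        t2, p2 = g.welch_t([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_conventions(self):
        assert g.welch_t([2, 2], [2, 2]) == (0.0, 1.0)
        t, p = g.welch_t([3, 3], [1, 1])
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            g.welch_t([1], [2, 3])


class TestAdjustFdr:
    def test_single_p_unchanged(self):
        assert g.adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        assert np.allclose(g.adjust_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_step_up_against_brute_force(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        # independent step-up oracle: q_i = min over j with p_j >= p_i
        # of p_j * n / rank(j)
        n = len(p)
        order = np.argsort(p)
        ranked = p[order]
        oracle = np.empty(n)
        running = np.inf
        for i in range(n - 1, -1, -1):
            running = min(running, ranked[i] * n / (i + 1))
            oracle[order[i]] = running
        q = g.adjust_fdr(p)
        assert np.allclose(q, oracle)
        assert np.allclose(q, [0.004, 0.02, 0.0266667, 0.8])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            g.adjust_fdr([0.5, 1.5])

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        assert np.all(g.adjust_fdr(p, method="storey") <= g.adjust_fdr(p) + 1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.lists(
            st.floats(0, 1, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_rank_monotone_and_bounded(self, p):
        q = g.adjust_fdr(p)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallStates:
    def _planted_expr(self, effect, noise, seed=0, n=20):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(50)]
        refs = rng.normal(7, noise, size=(50, n))
        tumors = rng.normal(7, noise, size=(50, n))
        tumors[0] += effect  # plant one gene
        values = np.hstack([refs, tumors])
        cols = [f"N{i}" for i in range(n)] + [f"T{i}" for i in range(n)]
        meta = pd.DataFrame(
            {"grade": ["NORMAL"] * n + ["PA1"] * n}, index=cols
        )
        return g.ExpressionMatrix(
            values=pd.DataFrame(values, index=genes, columns=cols), metadata=meta
        )

    def test_planted_over_gene_called(self):
        expr = self._planted_expr(effect=2.0, noise=0.3)
        table = g.call_states(expr, "PA1").table
        assert table.loc["g0", "state"] == OVER

    def test_state_invariants_hold_exactly(self, small_cohort):
        expr, _ = small_cohort
        table = g.call_states(expr, "GBM4", q_threshold=1e-4).table
        over = table[table["state"] == OVER]
        under = table[table["state"] == UNDER]
        assert ((over["q"] < 1e-4) & (over["mean_log_ratio"] > 0)).all()
        assert ((under["q"] < 1e-4) & (under["mean_log_ratio"] < 0)).all()
        unchanged = table[table["state"] == UNCHANGED]
        ok = unchanged["flagged"] | (unchanged["q"] >= 1e-4) | (
            unchanged["mean_log_ratio"] == 0
        )
        assert ok.all()

    def test_constant_gene_flagged_unchanged(self):
        expr = self._planted_expr(effect=0.0, noise=0.3)
        expr.values.iloc[5, :] = 7.0  # constant across every sample
        table = g.call_states(expr, "PA1").table
        row = table.iloc[5]
        assert row["flagged"] and row["state"] == UNCHANGED and np.isnan(row["p"])

    def test_order_invariance(self, tiny_expression):
        rng = np.random.default_rng(1)
        expr = self._planted_expr(effect=2.0, noise=0.3)
        t1 = g.call_states(expr, "PA1").table
        gene_perm = list(rng.permutation(expr.genes))
        sample_perm = list(rng.permutation(expr.samples))
        shuffled = g.ExpressionMatrix(
            values=expr.values.loc[gene_perm, sample_perm],
            metadata=expr.metadata.loc[sample_perm],
        )
        t2 = g.call_states(shuffled, "PA1").table
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())

    def test_too_few_samples_rejected(self, tiny_expression):
        with pytest.raises(ConsistencyError):
            g.call_states(tiny_expression, "PA1")  # one PA1 sample only


class TestExclusiveSubsets:
    @staticmethod
    def _tables(states: dict[str, list[str]], genes: list[str]):
        out = {}
        for grade, st_list in states.items():
            table = pd.DataFrame(
                {
                    "t": 0.0,
                    "p": 1.0,
                    "q": 1.0,
                    "mean_log_ratio": 0.0,
                    "state": st_list,
                    "flagged": False,
                },
                index=genes,
            )
            out[grade] = g.StateTable(grade=grade, table=table)
        return out

    def test_gene_in_all_four(self):
        tables = self._tables(
            {gr: [UNDER] for gr in g.TUMOR_GRADES}, genes=["x"]
        )
        part = g.exclusive_subsets(tables, UNDER)
        assert part.cell(*g.TUMOR_GRADES) == {"x"}

    def test_gene_in_two_grades_only(self):
        tables = self._tables(
            {
                "PA1": [OVER],
                "AS2": [UNCHANGED],
                "AS3": [UNDER],
                "GBM4": [OVER],
            },
            genes=["x"],
        )
        part = g.exclusive_subsets(tables, OVER)
        assert part.cell("PA1", "GBM4") == {"x"}
        assert part.cell("PA1") == set()

    def test_random_toy_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(50)]
        states = {
            gr: list(rng.choice([UNDER, UNCHANGED, OVER], size=50))
            for gr in g.TUMOR_GRADES
        }
        tables = self._tables(states, genes)
        for direction in (UNDER, OVER):
            part = g.exclusive_subsets(tables, direction)
            # brute force over all 15 non-empty grade subsets
            from itertools import combinations

            seen = set()
            for r in range(1, 5):
                for combo in combinations(g.TUMOR_GRADES, r):
                    expected = {
                        gene
                        for i, gene in enumerate(genes)
                        if all(states[gr][i] == direction for gr in combo)
                        and all(
                            states[gr][i] != direction
                            for gr in g.TUMOR_GRADES
                            if gr not in combo
                        )
                    }
                    assert part.cell(*combo) == expected
                    seen |= expected
            # partition covers exactly the direction-positive genes
            assert part.all_genes() == seen
            sizes = sum(len(v) for v in part.cells.values())
            assert sizes == len(part.all_genes())  # cells disjoint

    def test_mismatched_universe_rejected(self):
        t1 = self._tables({"PA1": [UNDER]}, ["a"])["PA1"]
        t2 = self._tables({"AS2": [UNDER]}, ["b"])["AS2"]
        with pytest.raises(ConsistencyError):
            g.exclusive_subsets({"PA1": t1, "AS2": t2}, UNDER)


class TestEnrichment:
    def test_zero_hits_gives_one(self):
        assert g.enrichment_fisher(0, 5, 5, 20) == pytest.approx(1.0)

    def test_forced_outcome_gives_one(self):
        assert g.enrichment_fisher(5, 5, 5, 5) == pytest.approx(1.0)

    def test_extreme_overlap_value(self):
        assert g.enrichment_fisher(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            g.enrichment_fisher(6, 5, 5, 10)


class TestGradeTrend:
    def test_perfect_linearity(self):
        r, _ = g.grade_trend([10, 20, 30, 40])
        assert r == pytest.approx(1.0)

    def test_antisymmetry(self):
        r, _ = g.grade_trend([40, 30, 20, 10])
        assert r == pytest.approx(-1.0)

    def test_frozen_hand_computed_value(self):
        # cov-sum = 455, dev-sums 5 and 49275: r = 455/sqrt(5*49275)
        r, p = g.grade_trend([100, 180, 190, 400])
        assert r == pytest.approx(455 / math.sqrt(5 * 49275), abs=1e-12)
        assert r == pytest.approx(0.91667, abs=1e-5)
        assert 0 < p < 1

    def test_constant_counts_rejected(self):
        with pytest.raises(ValueError):
            g.grade_trend([5, 5, 5, 5])
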