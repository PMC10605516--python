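"""Tests for contingency analysis, Fisher ORs, BH post-hoc and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nchypergeom_fisher

from historiskscore.association import (
    build_contingency,
    chi_square,
    fisher_or,
    kendall_tau,
    pearson_r,
    posthoc_bh,
    reproduce_signature_screen,
    wilcoxon_rank_sum,
)
from historiskscore.datasets import load_mutation_tables


def grid_search_conditional_mle(table, lo=-6.0, hi=6.0, step=1e-4):
    """Argmax of the noncentral hypergeometric likelihood on a log-OR grid."""
    a = table[0][0]
    r1 = table[0][0] + table[0][1]
    n = sum(map(sum, table))
    c1 = table[0][0] + table[1][0]
    grid = np.arange(lo, hi, step)
    ll = nchypergeom_fisher.logpmf(a, n, r1, c1, np.exp(grid))
    return float(np.exp(grid[np.argmax(ll)]))


def expand_table_to_cases(table):
    """Per-case (risk, value) rows from a 2x2 table of counts."""
    rows = []
    for g, (wild, mut) in zip(("low", "high"), np.asarray(table)):
        rows += [(g, 0)] * wild + [(g, 1)] * mut
    df = pd.DataFrame(rows, columns=["risk_group", "value"])
    df["case_id"] = [f"c{i}" for i in range(len(df))]
    return df


class TestBuildContingency:
    def test_diagonal_two_cases(self):
        risk = pd.Series(["low", "high"], index=["a", "b"])
        val = pd.Series(["wt", "mut"], index=["a", "b"])
        t = build_contingency(risk, val)
        assert t.loc["low", "wt"] == 1 and t.loc["high", "mut"] == 1
        assert t.to_numpy().sum() == 2

    def test_reconstructs_published_tsc1_table(self):
        df = expand_table_to_cases([[177, 28], [196, 11]])
        risk = df.set_index("case_id")["risk_group"]
        val = df.set_index("case_id")["value"]
        t = build_contingency(risk, val)
        assert t.to_numpy().tolist() == [[177, 28], [196, 11]]
        assert t.sum(axis=1).tolist() == [205, 207]
        assert t.sum(axis=0).tolist() == [373, 39]

    def test_row_order_permutation_invariant(self, rng):
        df = expand_table_to_cases([[10, 5], [7, 3]])
        perm = df.sample(frac=1, random_state=1)
        t1 = build_contingency(
            df.set_index("case_id")["risk_group"], df.set_index("case_id")["value"]
        )
        t2 = build_contingency(
            perm.set_index("case_id")["risk_group"], perm.set_index("case_id")["value"]
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_disjoint_cases_rejected(self):
        risk = pd.Series(["low"], index=["a"])
        val = pd.Series(["wt"], index=["b"])
        with pytest.raises(ValueError, match="overlap"):
            build_contingency(risk, val)


class TestFisherOR:
    @pytest.mark.parametrize(
        "gene, expected_or", [("TSC1", 0.36), ("ERBB3", 0.46), ("FGFR3", 0.49)]
    )
    def test_published_mutation_tables(self, gene, expected_or):
        res = fisher_or(load_mutation_tables()[gene])
        assert round(res.odds_ratio, 2) == expected_or

    def test_identical_rows_give_unit_or(self):
        res = fisher_or([[20, 10], [20, 10]])
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0)

    def test_conditional_mle_matches_grid_search(self):
        for table in ([[177, 28], [196, 11]], [[12, 7], [5, 19]], [[30, 2], [25, 9]]):
            res = fisher_or(table)
            assert abs(res.odds_ratio - grid_search_conditional_mle(table)) < 1e-3

    def test_transpose_invariance_and_row_swap_reciprocal(self):
        t = np.array([[175, 30], [192, 15]])
        assert fisher_or(t).odds_ratio == pytest.approx(fisher_or(t.T).odds_ratio)
        assert fisher_or(t[::-1]).odds_ratio == pytest.approx(
            1.0 / fisher_or(t).odds_ratio, rel=1e-9
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_or([[0, 0], [5, 3]])

    def test_zero_cell_pushes_ci_bound_to_limit(self):
        res = fisher_or([[10, 0], [5, 5]])  # no mutations in the low-risk row
        assert np.isinf(res.odds_ratio) and np.isinf(res.ci_high)
        res = fisher_or([[0, 10], [5, 5]])
        assert res.odds_ratio == 0.0 and res.ci_low == 0.0


class TestChiSquare:
    def test_independent_margins_give_zero_statistic(self):
        stat, df, p = chi_square([[10, 20], [10, 20]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_two_by_two(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 60*(100-400)^2/(30*30*30*30) = 20/3
        stat, df, p = chi_square([[10, 20], [20, 10]])
        assert df == 1
        assert stat == pytest.approx(20 / 3)

    def test_permutation_invariance(self, rng):
        t = rng.integers(1, 30, (3, 4))
        s1, _, _ = chi_square(t)
        s2, _, _ = chi_square(t[::-1, ::-1])
        assert s1 == pytest.approx(s2)

    def test_monte_carlo_p_close_to_asymptotic(self):
        t = [[30, 20], [20, 30]]
        stat, _, p_asym = chi_square(t)
        _, _, p_mc = chi_square(t, n_monte_carlo=2000, seed=0)
        assert abs(p_mc - p_asym) < 0.05


class TestPosthocBH:
    def test_all_ones_none_significant(self):
        flags = posthoc_bh([1.0, 1.0, 1.0])
        assert not any(sig for _, _, sig in flags)

    def test_worked_step_up_example(self):
        flags = posthoc_bh([0.01, 0.04, 0.30], fdr=0.20)
        ranks = [f[0] for f in flags]
        crits = [f[1] for f in flags]
        sigs = [f[2] for f in flags]
        assert ranks == [1, 2, 3]
        assert crits == pytest.approx([0.2 / 3, 0.4 / 3, 0.2])
        assert sigs == [True, True, False]

    def test_single_test_threshold(self):
        assert posthoc_bh([0.19])[0][2] is True
        assert posthoc_bh([0.21])[0][2] is False

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20),
        st.floats(min_value=0.01, max_value=0.5),
        st.floats(min_value=0.0, max_value=0.5),
    )
    @settings(derandomize=True, max_examples=100)
    def test_flags_monotone_in_fdr(self, ps, fdr, bump):
        low = posthoc_bh(ps, fdr=fdr)
        high = posthoc_bh(ps, fdr=fdr + bump)
        for (_, _, s_low), (_, _, s_high) in zip(low, high):
            assert s_high or not s_low


class TestRankAndCorrelation:
    def test_identical_samples_not_significant(self, rng):
        x = rng.normal(size=20)
        _, p = wilcoxon_rank_sum(np.concatenate([x, x]), ["a"] * 20 + ["b"] * 20)
        assert p > 0.9

    def test_separated_groups_exact_p(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        # U = 0; exact two-sided p = 2 * 1/C(6,3) = 0.1
        assert p == pytest.approx(0.1)

    def test_label_swap_leaves_p_unchanged(self, rng):
        v = rng.normal(size=30)
        g = np.array(["a"] * 15 + ["b"] * 15)
        _, p1 = wilcoxon_rank_sum(v, g)
        _, p2 = wilcoxon_rank_sum(v, np.where(g == "a", "b", "a"))
        assert p1 == pytest.approx(p2)

    def test_perfect_and_inverse_association(self):
        x = np.arange(10.0)
        assert kendall_tau(x, x)[0] == pytest.approx(1.0)
        assert kendall_tau(x, -x)[0] == pytest.approx(-1.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_tau_matches_pair_counting_oracle(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        tau, _ = kendall_tau(x, y)
        conc = disc = 0
        for i in range(20):
            for j in range(i + 1, 20):
                s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
                conc += s > 0
                disc += s < 0
        # no ties in continuous draws: tau-b reduces to (C-D)/C(n,2)
        assert tau == pytest.approx((conc - disc) / (20 * 19 / 2))

    def test_zero_variance_rejected_for_pearson(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSignatureScreen:
    def test_empty_signature_list(self):
        risk = pd.Series(["low", "high"], index=["a", "b"])
        sigs = pd.DataFrame(columns=["case_id", "signature", "value"])
        assert reproduce_signature_screen(risk, sigs) == []

    def test_published_tables_reproduce_printed_odds_ratios(self):
        frames = []
        risk = None
        for gene, table in load_mutation_tables().items():
            df = expand_table_to_cases(table.to_numpy())
            df["case_id"] = gene + "_" + df["case_id"]
            frames.append(
                df.assign(signature=gene)[["case_id", "signature", "value"]]
            )
            r = df.set_index("case_id")["risk_group"]
            risk = r if risk is None else pd.concat([risk, r])
        results = reproduce_signature_screen(risk, pd.concat(frames))
        ors = {
            r.signature: round(r.odds_ratio, 2)
            for r in results
            if r.test == "fisher"
        }
        assert ors == {"TSC1": 0.36, "ERBB3": 0.46, "FGFR3": 0.49}

    def test_multicategory_signature_gets_posthoc_flags(self, rng):
        n = 300
        group = rng.integers(0, 2, n)
        cat = np.where(
            group == 1,
            rng.choice(["A", "B", "C"], n, p=[0.6, 0.2, 0.2]),
            rng.choice(["A", "B", "C"], n, p=[0.2, 0.4, 0.4]),
        )
        risk = pd.Series(
            np.where(group == 1, "high", "low"),
            index=[f"c{i}" for i in range(n)],
        )
        sigs = pd.DataFrame(
            {"case_id": risk.index, "signature": "cluster", "value": cat}
        )
        results = reproduce_signature_screen(risk, sigs)
        posthoc = [r for r in results if r.test == "fisher_one_vs_rest"]
        assert len(posthoc) == 3
        assert all(r.rank is not None and r.critical_value is not None for r in posthoc)
        # critical values increase with rank
        by_rank = sorted(posthoc, key=lambda r: r.rank)
        assert all(
            a.critical_value < b.critical_value
            for a, b in zip(by_rank, by_rank[1:])
        )

    def test_independent_signature_usually_screened_out(self, rng):
        screened_out = 0
        n = 2000
        for _ in range(50):
            group = rng.integers(0, 2, n)
            value = rng.integers(0, 2, n)  # independent of group
            risk = pd.Series(
                np.where(group == 1, "high", "low"),
                index=[f"c{i}" for i in range(n)],
            )
            sigs = pd.DataFrame(
                {"case_id": risk.index, "signature": "noise", "value": value}
            )
            results = reproduce_signature_screen(risk, sigs)
            assert results[0].test == "chi_square"
            screened_out += len(results) == 1  # no follow-up Fisher test
        assert screened_out >= 40  # expect ~90% at alpha = 0.10
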