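"""Associations between risk groups and molecular / histopathologic signatures.

The evaluation layer cross-tabulates the binary risk groups against
case-level signature categories (mutation status, molecular subtype
clusters, squamous phenotype) and tests the association:

* chi-square screening for n x m tables (no continuity correction; an
  optional Monte-Carlo p-value is available for sparse tables),
* Fisher's exact test for 2 x 2 tables, reporting the conditional
  maximum-likelihood odds ratio under the noncentral hypergeometric
  model with its exact 95 % CI,
* Wilcoxon rank-sum for numeric variables, Kendall's tau-b and Pearson
  correlation,
* the Benjamini-Hochberg step-up procedure at FDR 0.20 for post-hoc
  one-vs-rest comparisons of multi-category signatures, with critical
  value ``rank / n_comparisons * FDR`` and significance assigned to all
  tests ranked at or below the last p-value strictly below its critical
  value.

Orientation convention for 2 x 2 tables: rows are risk groups (low,
high), columns are signature categories (reference first, e.g.
wild-type, mutated), so the odds ratio is the odds of the second
category in the high-risk group relative to the low-risk group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio

__all__ = [
    "FisherResult",
    "AssociationResult",
    "build_contingency",
    "fisher_or",
    "chi_square",
    "posthoc_bh",
    "wilcoxon_rank_sum",
    "kendall_tau",
    "pearson_r",
    "reproduce_signature_screen",
]

RISK_ORDER = ("low", "high")


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class AssociationResult:
    signature: str
    test: str
    statistic: float
    p_value: float
    category: str | None = None
    odds_ratio: float | None = None
    ci: tuple[float, float] | None = None
    rank: int | None = None
    critical_value: float | None = None
    significant: bool | None = None


def build_contingency(
    risk_groups: pd.Series,
    signature_values: pd.Series,
    include_missing: bool = False,
) -> pd.DataFrame:
    """Cross-tabulate risk group against a categorical signature.

    Both inputs are indexed by case_id; only overlapping cases enter the
    table (complete-case analysis).  Missing values are dropped unless
    ``include_missing`` keeps them as an explicit column.  Rows follow
    the (low, high) risk order when applicable.
    """
    common = risk_groups.index.intersection(signature_values.index)
    if common.empty:
        raise ValueError("no overlapping case_ids between risk groups and signature")
    r = risk_groups.loc[common]
    v = signature_values.loc[common]
    if include_missing:
        v = v.astype(object).where(v.notna(), "missing")
    else:
        keep = v.notna()
        r, v = r[keep], v[keep]
    table = pd.crosstab(r, v)
    if set(table.index) == set(RISK_ORDER):
        table = table.loc[list(RISK_ORDER)]
    return table


def fisher_or(table: np.ndarray | pd.DataFrame) -> FisherResult:
    """Fisher's exact test on a 2 x 2 table with the conditional-MLE OR.

    The odds ratio maximizes the noncentral hypergeometric likelihood
    conditional on the table margins; the 95 % CI inverts the exact
    test.  A zero cell pushes the CI bound to 0 or inf; a zero margin is
    an error (the odds ratio is undefined).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: odds ratio undefined")
    res = _conditional_odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(
        odds_ratio=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(p),
    )


def chi_square(
    table: np.ndarray | pd.DataFrame,
    n_monte_carlo: int = 0,
    seed: int = 0,
) -> tuple[float, int, float]:
    """Pearson chi-square on an n x m table -> (statistic, df, p).

    No continuity correction.  With ``n_monte_carlo > 0`` the p-value is
    instead estimated by sampling tables with the observed margins
    (useful when asymptotic theory is doubtful for sparse tables); the
    statistic and df are unchanged.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError(f"need an n x m table with n, m >= 2, got shape {t.shape}")
    res = stats.chi2_contingency(t, correction=False)
    if (res.expected_freq == 0).any():
        raise ValueError("zero expected count in a cell")
    statistic, p, df = float(res.statistic), float(res.pvalue), int(res.dof)
    if n_monte_carlo > 0:
        rng = np.random.default_rng(seed)
        rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
        cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))
        hits = 0
        for _ in range(n_monte_carlo):
            perm = pd.crosstab(rows, rng.permutation(cols)).to_numpy()
            s = stats.chi2_contingency(perm, correction=False).statistic
            hits += s >= statistic - 1e-12
        p = (hits + 1) / (n_monte_carlo + 1)
    return statistic, df, p


def posthoc_bh(
    p_values: np.ndarray, n_comparisons: int | None = None, fdr: float = 0.20
) -> list[tuple[int, float, bool]]:
    """Benjamini-Hochberg step-up significance flags at a given FDR.

    P-values are ranked ascending; the critical value of the test at
    rank k is ``k / n_comparisons * fdr``; every test ranked at or below
    the largest k with ``p_(k) < critical_k`` is significant.  Returns
    ``(rank, critical_value, significant)`` in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p) if n_comparisons is None else n_comparisons
    order = np.argsort(p, kind="stable")
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    crit = ranks / n * fdr
    passing = ranks[p < crit - 0]  # strict inequality
    k_star = passing.max() if passing.size else 0
    return [
        (int(ranks[i]), float(crit[i]), bool(ranks[i] <= k_star))
        for i in range(len(p))
    ]


def wilcoxon_rank_sum(
    values: np.ndarray, group_labels: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test across two groups."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    levels = pd.unique(group_labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    a = values[group_labels == levels[0]]
    b = values[group_labels == levels[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kendall_tau(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall's tau-b (tie-corrected) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of length >= 3")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def reproduce_signature_screen(
    risk_groups: pd.Series,
    signatures: pd.DataFrame,
    screen_alpha: float = 0.10,
    fdr: float = 0.20,
) -> list[AssociationResult]:
    """Screen signatures against risk groups, with BH post-hoc tests.

    ``signatures`` is a long table (``case_id``, ``signature``,
    ``value``).  Every signature is screened with a chi-square test; a
    two-category signature passing the screen (p <= screen_alpha) gets a
    Fisher odds ratio; a multi-category one gets one-vs-rest Fisher
    tests per category followed by the BH step-up at the given FDR.
    """
    results: list[AssociationResult] = []
    for name, sub in signatures.groupby("signature", sort=True):
        values = sub.set_index("case_id")["value"]
        table = build_contingency(risk_groups, values)
        if min(table.shape) < 2:
            continue  # degenerate: signature constant over shared cases
        statistic, _, p = chi_square(table)
        results.append(
            AssociationResult(
                signature=str(name), test="chi_square", statistic=statistic, p_value=p
            )
        )
        if p > screen_alpha:
            continue
        if table.shape == (2, 2):
            fr = fisher_or(table)
            results.append(
                AssociationResult(
                    signature=str(name),
                    test="fisher",
                    statistic=fr.odds_ratio,
                    p_value=fr.p_value,
                    odds_ratio=fr.odds_ratio,
                    ci=(fr.ci_low, fr.ci_high),
                )
            )
        else:
            per_category: list[tuple[str, FisherResult]] = []
            for cat in table.columns:
                collapsed = np.column_stack(
                    [
                        table.drop(columns=cat).sum(axis=1).to_numpy(),
                        table[cat].to_numpy(),
                    ]
                )
                per_category.append((str(cat), fisher_or(collapsed)))
            flags = posthoc_bh(
                [fr.p_value for _, fr in per_category], fdr=fdr
            )
            for (cat, fr), (rank, crit, sig) in zip(per_category, flags):
                results.append(
                    AssociationResult(
                        signature=str(name),
                        test="fisher_one_vs_rest",
                        statistic=fr.odds_ratio,
                        p_value=fr.p_value,
                        category=cat,
                        odds_ratio=fr.odds_ratio,
                        ci=(fr.ci_low, fr.ci_high),
                        rank=rank,
                        critical_value=crit,
                        significant=sig,
                    )
                )
    return results
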