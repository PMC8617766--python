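"""Replicate-level significance testing and correlation reporting.

One-way ANOVA with Tukey's HSD post hoc test produces the pairwise
significance decisions behind the superscript-letter annotation used in
bioactivity tables (groups sharing a letter are not significantly
different), plus Pearson correlations between endpoint panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ContractError,
    InsufficientReplicatesError,
    UndefinedCorrelationError,
)


@dataclass
class ReplicateGroup:
    """A labelled set of replicate measurements in common units."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 2:
            raise InsufficientReplicatesError(
                f"group {self.label!r}: need >= 2 replicates, got {len(self.values)}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError(f"group {self.label!r}: non-finite replicate value")


@dataclass
class TukeyResult:
    """ANOVA F statistic plus the symmetric Tukey HSD decision matrix."""

    labels: list
    f_statistic: float
    p_value: float
    significant: np.ndarray  # bool matrix, True = significantly different
    p_values: np.ndarray
    alpha: float
    means: np.ndarray


def anova_tukey(groups, alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA with Tukey HSD pairwise decisions at ``alpha``.

    Tukey's studentized-range test uses the pooled within-group variance;
    unbalanced designs are handled by the Tukey-Kramer correction built
    into the underlying test.
    """
    groups = [g if isinstance(g, ReplicateGroup) else ReplicateGroup(*g) for g in groups]
    if len(groups) < 2:
        raise InsufficientReplicatesError("need >= 2 groups")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    arrays = [g.values for g in groups]
    f_stat, p_val = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pvals = np.asarray(hsd.pvalue, dtype=float)
    np.fill_diagonal(pvals, 1.0)
    significant = pvals < alpha
    np.fill_diagonal(significant, False)
    return TukeyResult(
        labels=[g.label for g in groups],
        f_statistic=float(f_stat),
        p_value=float(p_val),
        significant=significant,
        p_values=pvals,
        alpha=alpha,
        means=np.array([g.values.mean() for g in groups]),
    )


def _letters(k: int) -> str:
    """0 -> 'a', 1 -> 'b', ..., 26 -> 'aa' (spreadsheet style)."""
    out = ""
    k += 1
    while k:
        k, rem = divmod(k - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def compact_letter_display(
    significant: np.ndarray,
    labels,
    order=None,
) -> dict:
    """Assign superscript letters so that two groups share a letter iff
    their pairwise difference is *not* significant.

    Uses the insert-and-absorb algorithm: walk the groups in display order,
    split any letter column containing a newly contradicted pair, then
    absorb redundant columns.  ``order`` gives the display order of group
    indices (e.g. ascending mean for lower-is-better endpoints, so that
    'a' marks the best performer); default is input order.
    """
    sig = np.asarray(significant, dtype=bool)
    if sig.shape[0] != sig.shape[1] or not np.array_equal(sig, sig.T):
        raise ContractError("decision matrix must be square and symmetric")
    n = sig.shape[0]
    if len(labels) != n:
        raise ContractError("labels length must match matrix size")
    order = list(range(n)) if order is None else list(order)

    # columns are sets of group indices that may legally share a letter
    columns: list[set] = [set(order[:1])]
    for g in order[1:]:
        inserted = False
        new_columns: list[set] = []
        for col in columns:
            conflicts = {h for h in col if sig[g, h]}
            if not conflicts:
                col.add(g)
                inserted = True
                new_columns.append(col)
            else:
                new_columns.append(col)
                keep = col - conflicts
                # split: duplicate the non-conflicting part and add g there
                cand = keep | {g}
                if not any(cand <= c for c in new_columns):
                    new_columns.append(cand)
                    inserted = True
        if not inserted:
            new_columns.append({g})
        # absorb columns contained in another
        columns = []
        for col in sorted(new_columns, key=len, reverse=True):
            if not any(col <= c for c in columns):
                columns.append(col)

    # greedy sweep: drop columns whose pairs and members are already covered
    def covered_without(idx):
        pairs = set()
        members = set()
        for j, col in enumerate(columns):
            if j == idx:
                continue
            members |= col
            for a in col:
                for b in col:
                    if a < b:
                        pairs.add((a, b))
        needed_pairs = {
            (a, b) for a in range(n) for b in range(a + 1, n) if not sig[a, b]
        }
        return needed_pairs <= pairs and members == set(range(n))

    j = 0
    while j < len(columns):
        if len(columns) > 1 and covered_without(j):
            columns.pop(j)
        else:
            j += 1

    # letter columns in order of their best-ranked member
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    assignment: dict = {labels[g]: "" for g in range(n)}
    for k, col in enumerate(columns):
        for g in sorted(col, key=lambda x: rank[x]):
            assignment[labels[g]] += _letters(k)
    # order letters within each group alphabetically (e.g. "ab" not "ba")
    return {lab: "".join(sorted(s)) for lab, s in assignment.items()}


def letters_for_endpoint(
    groups,
    alpha: float = 0.05,
    direction: str = "lower_better",
) -> dict:
    """ANOVA + Tukey + compact letters for one endpoint.

    Letters are assigned in ascending-mean order for lower-is-better
    endpoints (IC50: 'a' = most potent) and descending-mean order for
    higher-is-better ones.
    """
    res = anova_tukey(groups, alpha=alpha)
    ascending = direction == "lower_better"
    order = list(np.argsort(res.means if ascending else -res.means, kind="stable"))
    return compact_letter_display(res.significant, res.labels, order=order)


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Requires equal lengths >= 3 and nonzero variance in both arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise UndefinedCorrelationError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in one argument")
    r, _ = sps.pearsonr(x, y)
    return float(r)


def correlation_table(panel_means: pd.DataFrame, reference: str, others) -> pd.DataFrame:
    """Pearson r of a reference endpoint against several others.

    ``panel_means`` is samples x endpoints; rows missing either variable are
    excluded pairwise (positive controls typically lack phenolic totals).
    """
    rows = []
    for other in others:
        sub = panel_means[[reference, other]].dropna()
        rows.append(
            {
                "endpoint": other,
                "against": reference,
                "n": len(sub),
                "r": round(pearson(sub[reference], sub[other]), 3),
            }
        )
    return pd.DataFrame(rows)
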