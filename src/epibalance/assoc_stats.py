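"""Expression-activity classification and mark/expression association stats.

Genes are active when their log2 expression is strictly above 7.5 (ties at
the threshold count as silent).  Group summaries report the median expression
and fraction active of a gene group; the net-intensity quadrant fractions
condition both ways (on expression status and on the sign of the net, with a
net of exactly 0 on the non-positive side).  Association between a mark and
activity is tested with Pearson's chi-square on the 2x2 table, without
continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .arraydata import ExpressionTable, MARKS
from .genescore import CLASS_NAMES, MarkClass, NetIntensity

ACTIVITY_THRESHOLD = 7.5


@dataclass(frozen=True)
class ActivityCall:
    symbol: str
    condition: str
    active: bool


@dataclass(frozen=True)
class GroupSummary:
    group_name: str
    n: int
    median_expression: float
    fraction_expressed: float


@dataclass(frozen=True)
class NetQuadrantFractions:
    """Conditional fractions linking net-intensity sign and activity.

    Denominators differ between the two directions of conditioning, so the
    complementary fractions need not sum to 1.  A fraction with an empty
    denominator is ``None`` (undefined), never 0.
    """

    pair: str
    n_net_positive: int
    n_net_nonpositive: int
    n_expressed: int
    n_silent: int
    f_expressed_given_net_positive: float | None
    f_silent_given_net_nonpositive: float | None
    f_net_positive_given_expressed: float | None
    f_net_nonpositive_given_silent: float | None


@dataclass(frozen=True)
class Contingency2x2:
    counts: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    p: float


def classify_expression(
    expr: ExpressionTable, threshold: float = ACTIVITY_THRESHOLD
) -> list[ActivityCall]:
    """Active/silent call per gene; strictly above threshold is active."""
    return [
        ActivityCall(symbol=s, condition=expr.condition, active=v > threshold)
        for s, v in sorted(expr.values.items())
    ]


def group_summary(
    group: Iterable[str],
    expr: ExpressionTable,
    calls: Sequence[ActivityCall],
    name: str,
) -> GroupSummary:
    """Median expression and fraction active over a gene group."""
    symbols = sorted(set(group))
    if not symbols:
        raise ValueError(f"group {name!r} is empty")
    missing = [s for s in symbols if s not in expr.values]
    if missing:
        raise ValueError(f"group {name!r}: {missing[0]!r} has no expression value")
    active = {c.symbol for c in calls if c.active}
    values = np.array([expr.values[s] for s in symbols])
    return GroupSummary(
        group_name=name,
        n=len(symbols),
        median_expression=float(np.median(values)),
        fraction_expressed=sum(s in active for s in symbols) / len(symbols),
    )


def net_quadrant_fractions(
    nets: Sequence[NetIntensity], calls: Sequence[ActivityCall]
) -> NetQuadrantFractions:
    """Conditional activity/net-sign fractions over a bivalent gene group."""
    pairs = {n.pair for n in nets}
    if len(pairs) > 1:
        raise ValueError(f"mixed pairs: {sorted(pairs)}")
    pair = next(iter(pairs), "")
    active_by = {c.symbol: c.active for c in calls}
    pos_active = pos_silent = neg_active = neg_silent = 0
    for n in nets:
        if n.symbol not in active_by:
            raise ValueError(f"gene {n.symbol!r} has no activity call")
        active = active_by[n.symbol]
        if n.net > 0:
            pos_active += active
            pos_silent += not active
        else:  # net exactly 0 counts as non-positive
            neg_active += active
            neg_silent += not active

    def frac(num: int, den: int) -> float | None:
        return num / den if den else None

    n_pos = pos_active + pos_silent
    n_neg = neg_active + neg_silent
    n_act = pos_active + neg_active
    n_sil = pos_silent + neg_silent
    return NetQuadrantFractions(
        pair=pair,
        n_net_positive=n_pos,
        n_net_nonpositive=n_neg,
        n_expressed=n_act,
        n_silent=n_sil,
        f_expressed_given_net_positive=frac(pos_active, n_pos),
        f_silent_given_net_nonpositive=frac(neg_silent, n_neg),
        f_net_positive_given_expressed=frac(pos_active, n_act),
        f_net_nonpositive_given_silent=frac(neg_silent, n_sil),
    )


def chi_square_2x2(counts: Sequence[Sequence[float]]) -> Contingency2x2:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    The statistic is sum((O-E)^2 / E) with expected counts from the margins;
    the p-value comes from the chi-square distribution with 1 df.  Any zero
    margin makes the expected counts degenerate and raises.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(row, col) / total
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(chi2_dist.sf(stat, df=1))
    a, b = table[0]
    c, d = table[1]
    return Contingency2x2(
        counts=((int(a), int(b)), (int(c), int(d))),
        chi2=stat,
        p=p,
    )


def mark_activity_report(
    classes: Sequence[MarkClass],
    calls: Sequence[ActivityCall],
    expr: ExpressionTable,
    nets: Mapping[str, Sequence[NetIntensity]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-condition association tables between marks/classes and activity.

    Returns three tables: ``marks`` (one row per mark: marked-gene count,
    fraction of expressed genes carrying the mark, fraction of marked genes
    expressed, median expression of the marked group, and the chi-square test
    of mark status vs activity), ``classes`` (one row per combination class
    with size, median expression and fraction expressed), and — when ``nets``
    is given — ``net`` with the conditional quadrant fractions per pair.
    """
    class_by = {c.symbol: c.cls for c in classes}
    active_by = {c.symbol: c.active for c in calls if c.symbol in class_by}
    symbols = sorted(class_by)
    n_expressed = sum(active_by.get(s, False) for s in symbols)

    mark_members = {
        "H3K4me3": {"K4_only", "K4_K27", "K4_DNAMe", "trivalent"},
        "H3K27me3": {"K27_only", "K4_K27", "K27_DNAMe", "trivalent"},
        "DNAMe": {"DNAMe_only", "K4_DNAMe", "K27_DNAMe", "trivalent"},
    }
    mark_rows = []
    for mark in MARKS:
        members = [s for s in symbols if class_by[s] in mark_members[mark]]
        n_marked = len(members)
        marked_expressed = sum(active_by.get(s, False) for s in members)
        unmarked = len(symbols) - n_marked
        unmarked_expressed = n_expressed - marked_expressed
        if n_marked and unmarked:
            test = chi_square_2x2(
                [
                    [marked_expressed, n_marked - marked_expressed],
                    [unmarked_expressed, unmarked - unmarked_expressed],
                ]
            )
            chi2_val, p_val = test.chi2, test.p
        else:
            chi2_val, p_val = math.nan, math.nan
        median = (
            float(np.median([expr.values[s] for s in members])) if members else math.nan
        )
        mark_rows.append(
            {
                "mark": mark,
                "n_marked": n_marked,
                "f_expressed_with_mark": (marked_expressed / n_expressed)
                if n_expressed
                else math.nan,
                "f_marked_expressed": (marked_expressed / n_marked)
                if n_marked
                else math.nan,
                "median_expression_marked": median,
                "chi2": chi2_val,
                "p": p_val,
            }
        )

    class_rows = []
    for cls in CLASS_NAMES:
        members = [s for s in symbols if class_by[s] == cls]
        class_rows.append(
            {
                "cls": cls,
                "n": len(members),
                "median_expression": float(np.median([expr.values[s] for s in members]))
                if members
                else math.nan,
                "fraction_expressed": (
                    sum(active_by.get(s, False) for s in members) / len(members)
                )
                if members
                else math.nan,
            }
        )

    report = {
        "marks": pd.DataFrame(mark_rows),
        "classes": pd.DataFrame(class_rows),
    }
    if nets is not None:
        net_rows = []
        for pair, pair_nets in nets.items():
            f = net_quadrant_fractions(pair_nets, calls)
            net_rows.append(
                {
                    "pair": pair,
                    "n_net_positive": f.n_net_positive,
                    "n_net_nonpositive": f.n_net_nonpositive,
                    "f_expressed_given_net_positive": f.f_expressed_given_net_positive,
                    "f_silent_given_net_nonpositive": f.f_silent_given_net_nonpositive,
                    "f_net_positive_given_expressed": f.f_net_positive_given_expressed,
                    "f_net_nonpositive_given_silent": f.f_net_nonpositive_given_silent,
                }
            )
        report["net"] = pd.DataFrame(net_rows)
    return report
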