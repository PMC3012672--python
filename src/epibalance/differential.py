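"""Between-condition deltas of mark totals and expression, and concordance.

The change of a gene's epigenetic mark between two conditions is the delta of
its gene-level total intensity (condition2 - condition1); a gene is
differentially modified when |delta| > 5.  Expression change is the delta of
log2 expression, differential when |delta| > 2.  Joining a mark's calls with
the expression calls yields the four concordance quadrants (H3K4me3 moves
with expression, H3K27me3 against it); differential genes whose directions do
not match either pattern are discordant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .arraydata import ExpressionTable, MARK_H3K27ME3, MARK_H3K4ME3
from .genescore import GeneMarkScore, scores_by_symbol

MARK_DELTA_THRESHOLD = 5.0
EXPRESSION_DELTA_THRESHOLD = 2.0

CALL_INCREASED = "increased"
CALL_DECREASED = "decreased"
CALL_UNCHANGED = "unchanged"

QUAD_K4UP_EXPRUP = "K4up_exprUp"
QUAD_K4DOWN_EXPRDOWN = "K4down_exprDown"
QUAD_K27UP_EXPRDOWN = "K27up_exprDown"
QUAD_K27DOWN_EXPRUP = "K27down_exprUp"
QUAD_DISCORDANT = "discordant"
QUAD_OTHER = "other"


@dataclass(frozen=True)
class DeltaRecord:
    symbol: str
    quantity: str  # a mark name or "expression"
    delta: float
    call: str


@dataclass(frozen=True)
class ConcordanceQuadrant:
    symbol: str
    quadrant: str


def _direction_call(delta: float, threshold: float) -> str:
    if delta > threshold:
        return CALL_INCREASED
    if delta < -threshold:
        return CALL_DECREASED
    return CALL_UNCHANGED


def delta_mark(
    scores1: Sequence[GeneMarkScore],
    scores2: Sequence[GeneMarkScore],
    threshold: float = MARK_DELTA_THRESHOLD,
) -> list[DeltaRecord]:
    """Per-gene change of one mark's total intensity between two conditions."""
    by1 = scores_by_symbol(scores1)
    by2 = scores_by_symbol(scores2)
    if set(by1) != set(by2):
        raise ValueError("gene universes of the two conditions differ")
    marks = {s.mark for s in scores1} | {s.mark for s in scores2}
    if len(marks) > 1:
        raise ValueError(f"mixed marks in delta computation: {sorted(marks)}")
    (mark,) = marks or {"<empty>"}
    records = []
    for symbol in sorted(by1):
        delta = by2[symbol].total_intensity - by1[symbol].total_intensity
        records.append(
            DeltaRecord(
                symbol=symbol,
                quantity=mark,
                delta=delta,
                call=_direction_call(delta, threshold),
            )
        )
    return records


def delta_expression(
    expr1: ExpressionTable,
    expr2: ExpressionTable,
    threshold: float = EXPRESSION_DELTA_THRESHOLD,
) -> list[DeltaRecord]:
    """Per-gene change of log2 expression between two conditions."""
    if set(expr1.values) != set(expr2.values):
        raise ValueError("gene universes of the two expression tables differ")
    records = []
    for symbol in sorted(expr1.values):
        delta = expr2.values[symbol] - expr1.values[symbol]
        records.append(
            DeltaRecord(
                symbol=symbol,
                quantity="expression",
                delta=delta,
                call=_direction_call(delta, threshold),
            )
        )
    return records


def concordance_quadrants(
    mark_deltas: Sequence[DeltaRecord],
    expr_deltas: Sequence[DeltaRecord],
) -> list[ConcordanceQuadrant]:
    """Join one mark's differential calls with the expression calls.

    Only genes with both a differential mark call and a differential
    expression call receive a quadrant.  H3K4me3 concordance means same
    direction as expression, H3K27me3 concordance the opposite direction;
    any other mark with both calls present is labeled ``other``.
    """
    marks = {d.quantity for d in mark_deltas}
    if len(marks) > 1:
        raise ValueError(f"mixed quantities in mark deltas: {sorted(marks)}")
    mark = next(iter(marks), None)
    expr_call = {
        d.symbol: d.call for d in expr_deltas if d.call != CALL_UNCHANGED
    }
    quads: list[ConcordanceQuadrant] = []
    for d in mark_deltas:
        if d.call == CALL_UNCHANGED:
            continue
        e = expr_call.get(d.symbol)
        if e is None:
            continue
        if mark == MARK_H3K4ME3:
            if d.call == CALL_INCREASED and e == CALL_INCREASED:
                q = QUAD_K4UP_EXPRUP
            elif d.call == CALL_DECREASED and e == CALL_DECREASED:
                q = QUAD_K4DOWN_EXPRDOWN
            else:
                q = QUAD_DISCORDANT
        elif mark == MARK_H3K27ME3:
            if d.call == CALL_INCREASED and e == CALL_DECREASED:
                q = QUAD_K27UP_EXPRDOWN
            elif d.call == CALL_DECREASED and e == CALL_INCREASED:
                q = QUAD_K27DOWN_EXPRUP
            else:
                q = QUAD_DISCORDANT
        else:
            q = QUAD_OTHER
        quads.append(ConcordanceQuadrant(symbol=d.symbol, quadrant=q))
    return quads


def top_changed_genes(deltas: Sequence[DeltaRecord], n: int = 100) -> list[DeltaRecord]:
    """The ``n`` records with the largest |delta|.

    Sorted by |delta| descending; ties broken by symbol lexicographic order.
    Requesting more records than available returns the full list with a
    warning.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n > len(deltas):
        warnings.warn(
            f"requested top {n} of only {len(deltas)} records; returning all",
            stacklevel=2,
        )
    ranked = sorted(deltas, key=lambda d: (-abs(d.delta), d.symbol))
    return ranked[:n]
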