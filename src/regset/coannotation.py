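"""Modular enrichment analysis: frequent co-annotation mining and testing.

Input elements become transactions (the set of annotation terms attached to
each element, at most two sources per analysis); an FP-tree miner extracts
closed itemsets (FP-growth; no proper superset with identical support) or
maximal itemsets (FP-max; no frequent proper superset), and each mined
co-annotation is then tested as a single composite term.

The FP-tree header table is ordered by descending item support with
lexicographic tie-breaks, so mining order — and therefore output order —
is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .bias import PwfFit, term_odds
from .data_model import AnnotationDatabase, Universe
from .stats import (
    ContingencyCounts,
    EnrichmentRow,
    PVALUE_FLOOR,
    bh_adjust,
    hypergeom_pvalue,
    relative_enrichment,
    wallenius_pvalue,
)

__all__ = [
    "TransactionSet",
    "CoAnnotation",
    "CoAnnotationRow",
    "MAX_INPUT_ELEMENTS",
    "MAX_SOURCES",
    "build_transactions",
    "mine_closed",
    "mine_maximal",
    "test_coannotations",
]

MAX_INPUT_ELEMENTS = 1000
MAX_SOURCES = 2
DEFAULT_MIN_SUPPORT_FRAC = 0.10


@dataclass(frozen=True)
class TransactionSet:
    """element → set of (source-prefixed) annotation term IDs."""

    transactions: Mapping[str, frozenset[str]]
    n_elements: int  # size of the input list the support fraction refers to
    n_unannotated: int = 0

    def __post_init__(self) -> None:
        for e, items in self.transactions.items():
            if not items:
                raise ValueError(f"empty transaction for {e!r}")


@dataclass(frozen=True)
class CoAnnotation:
    itemset: frozenset[str]
    support_elements: frozenset[str]

    @property
    def support(self) -> int:
        return len(self.support_elements)


@dataclass(frozen=True)
class CoAnnotationRow(EnrichmentRow):
    coannotation: str = ""


def build_transactions(
    input_elements: Sequence[str] | frozenset[str],
    dbs: Sequence[AnnotationDatabase],
) -> TransactionSet:
    """One transaction per annotated input element; term IDs are namespaced
    ``source:term`` so two databases cannot collide."""
    elements = sorted(set(input_elements))
    if len(elements) > MAX_INPUT_ELEMENTS:
        raise ValueError(
            f"co-annotation discovery is limited to input lists of up to "
            f"{MAX_INPUT_ELEMENTS} elements (got {len(elements)})"
        )
    if len(dbs) > MAX_SOURCES:
        raise ValueError(
            f"co-annotation discovery is limited to up to {MAX_SOURCES} "
            f"annotation sources per analysis (got {len(dbs)})"
        )
    if not dbs:
        raise ValueError("at least one annotation database is required")
    element_to_terms: dict[str, set[str]] = {}
    for db in dbs:
        for tid, (_, elems) in db.terms.items():
            namespaced = f"{db.source_name}:{tid}"
            for e in elems:
                element_to_terms.setdefault(e, set()).add(namespaced)
    transactions = {
        e: frozenset(element_to_terms[e]) for e in elements if e in element_to_terms
    }
    return TransactionSet(
        transactions=transactions,
        n_elements=len(elements),
        n_unannotated=len(elements) - len(transactions),
    )


# ---------------------------------------------------------------------------
# FP-tree


class _FPNode:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item: Optional[str], parent: Optional["_FPNode"]):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, _FPNode] = {}


def _build_tree(
    weighted_transactions: Sequence[tuple[Sequence[str], int]],
    min_count: int,
) -> tuple[_FPNode, dict[str, list[_FPNode]], list[str]]:
    counts: dict[str, int] = {}
    for items, cnt in weighted_transactions:
        for it in items:
            counts[it] = counts.get(it, 0) + cnt
    frequent = [it for it, c in counts.items() if c >= min_count]
    # header order: support descending, ties lexicographic
    order = sorted(frequent, key=lambda it: (-counts[it], it))
    rank = {it: i for i, it in enumerate(order)}
    root = _FPNode(None, None)
    header: dict[str, list[_FPNode]] = {it: [] for it in order}
    for items, cnt in weighted_transactions:
        path = sorted((it for it in items if it in rank), key=rank.__getitem__)
        node = root
        for it in path:
            child = node.children.get(it)
            if child is None:
                child = _FPNode(it, node)
                node.children[it] = child
                header[it].append(child)
            child.count += cnt
            node = child
    return root, header, order


def _mine(
    weighted_transactions: Sequence[tuple[Sequence[str], int]],
    min_count: int,
    suffix: frozenset[str],
    out: dict[frozenset[str], int],
) -> None:
    _, header, order = _build_tree(weighted_transactions, min_count)
    # mine least-frequent first (reverse header order)
    for item in reversed(order):
        nodes = header[item]
        support = sum(n.count for n in nodes)
        itemset = suffix | {item}
        out[itemset] = support
        # conditional pattern base: prefix paths of this item's nodes
        cond: list[tuple[list[str], int]] = []
        for node in nodes:
            path: list[str] = []
            p = node.parent
            while p is not None and p.item is not None:
                path.append(p.item)
                p = p.parent
            if path:
                cond.append((path, node.count))
        if cond:
            _mine(cond, min_count, itemset, out)


def _frequent_itemsets(ts: TransactionSet, min_count: int) -> dict[frozenset[str], int]:
    tx = [(sorted(items), 1) for _, items in sorted(ts.transactions.items())]
    out: dict[frozenset[str], int] = {}
    _mine(tx, min_count, frozenset(), out)
    return out


def _support_elements(ts: TransactionSet, itemset: frozenset[str]) -> frozenset[str]:
    return frozenset(e for e, items in ts.transactions.items() if itemset <= items)


def _min_count(ts: TransactionSet, min_support_frac: float) -> int:
    if not (0.0 < min_support_frac <= 1.0):
        raise ValueError("min_support_frac must be in (0, 1]")
    # "minimum number of elements" semantics: round the fraction up
    return max(1, math.ceil(min_support_frac * ts.n_elements))


def _ordered(coanns: list[CoAnnotation]) -> list[CoAnnotation]:
    return sorted(coanns, key=lambda c: (-c.support, tuple(sorted(c.itemset))))


def mine_closed(
    ts: TransactionSet,
    min_support_frac: float = DEFAULT_MIN_SUPPORT_FRAC,
) -> list[CoAnnotation]:
    """All frequent itemsets with no proper superset of identical support
    (FP-growth + closure filter), ordered by support desc then itemset."""
    min_count = _min_count(ts, min_support_frac)
    freq = _frequent_itemsets(ts, min_count)
    by_support: dict[int, list[frozenset[str]]] = {}
    for iset, sup in freq.items():
        by_support.setdefault(sup, []).append(iset)
    closed: list[CoAnnotation] = []
    for iset, sup in freq.items():
        if any(iset < other for other in by_support[sup] if len(other) > len(iset)):
            continue
        closed.append(CoAnnotation(itemset=iset, support_elements=_support_elements(ts, iset)))
    return _ordered(closed)


def mine_maximal(
    ts: TransactionSet,
    min_support_frac: float = DEFAULT_MIN_SUPPORT_FRAC,
) -> list[CoAnnotation]:
    """Frequent itemsets with no frequent proper superset (FP-max)."""
    min_count = _min_count(ts, min_support_frac)
    freq = _frequent_itemsets(ts, min_count)
    maximal: list[frozenset[str]] = []
    for iset in sorted(freq, key=len, reverse=True):
        if any(iset < m for m in maximal):
            continue
        maximal.append(iset)
    return _ordered(
        [CoAnnotation(itemset=i, support_elements=_support_elements(ts, i)) for i in maximal]
    )


# ---------------------------------------------------------------------------
# testing mined co-annotations


def _member_elements(member: str, dbs: Sequence[AnnotationDatabase]) -> frozenset[str]:
    source, _, tid = member.partition(":")
    for db in dbs:
        if db.source_name == source and tid in db.terms:
            return db.term_elements(tid)
    raise KeyError(f"co-annotation member {member!r} not found in the given databases")


def test_coannotations(
    coanns: Sequence[CoAnnotation],
    input_elements: frozenset[str] | set[str],
    dbs: Sequence[AnnotationDatabase],
    universe: Universe,
    method: str = "hypergeom",
    pwf: Optional[PwfFit] = None,
    odds_mode: str = "ratio-of-means",
    composite_background: str = "intersection",
) -> list[CoAnnotationRow]:
    """Test each co-annotation as one composite term.

    The composite background set is the set of universe elements annotated
    with ALL members (intersection, matching the support definition on the
    input side); ``composite_background='union'`` uses elements annotated
    with at least one member instead. Co-annotations whose composite set is
    empty are skipped. FDR is corrected over the co-annotation result set.
    """
    if composite_background not in ("intersection", "union"):
        raise ValueError(f"unknown composite background mode {composite_background!r}")
    if method == "wallenius" and pwf is None:
        raise ValueError("method='wallenius' requires a fitted PWF")
    tested_input = frozenset(input_elements) & universe.elements
    if not tested_input:
        raise ValueError("input has no elements in the background")
    N, M = len(tested_input), universe.M
    db_universe: set[str] = set()
    for db in dbs:
        db_universe |= db.annotated_universe()

    rows: list[CoAnnotationRow] = []
    for coann in coanns:
        member_sets = [_member_elements(m, dbs) for m in sorted(coann.itemset)]
        composite_full = member_sets[0]
        for s in member_sets[1:]:
            composite_full = composite_full & s if composite_background == "intersection" else composite_full | s
        composite = composite_full & universe.elements
        if not composite:
            continue  # untestable in this background
        support = tested_input & composite
        x = len(support)
        if x == 0:
            continue
        counts = ContingencyCounts(x=x, n=len(composite), N=N, M=M)
        if method == "wallenius":
            w: Optional[float] = term_odds(pwf, composite, universe.elements, mode=odds_mode)
            pval = wallenius_pvalue(counts, w)
        else:
            w = None
            pval = hypergeom_pvalue(counts)
        label = "&".join(sorted(coann.itemset))
        rows.append(CoAnnotationRow(
            term_id=label,
            term_name=label,
            source="+".join(db.source_name for db in dbs),
            counts=counts,
            w=w,
            pvalue=max(pval, PVALUE_FLOOR),
            padj=1.0,
            rel_enrichment=relative_enrichment(counts, len(composite_full), len(db_universe)),
            support=frozenset(support),
            input_elements=frozenset(support),
            coannotation=label,
        ))
    if rows:
        padj = bh_adjust([r.pvalue for r in rows])
        rows = [replace(r, padj=max(q, r.pvalue)) for r, q in zip(rows, padj)]
        rows.sort(key=lambda r: (r.padj, r.pvalue, r.term_id))
    return rows
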