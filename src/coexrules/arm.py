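"""Apriori frequent-itemset mining and association rules.

A from-scratch, exact implementation of level-wise Apriori with
anti-monotone candidate pruning, plus rule generation and filtering by
the three classical measures:

* support(X)    = |{T in D : X subseteq T}| / |D|
* confidence(X => Y) = supp(X u Y) / supp(X)
* lift(X => Y)  = supp(X u Y) / (supp(X) * supp(Y))

All measures are computed and compared as exact rational numbers
(:class:`fractions.Fraction`), so threshold comparisons such as
"support >= 0.5 over 9 transactions means at least ceil(4.5) = 5
transactions" and the inclusive "lift >= 2" bound are free of
floating-point wobble. Output orderings are deterministic: itemsets by
(size, lexicographic), rules by (lift desc, support desc,
lexicographic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

__all__ = [
    "Itemset",
    "AssociationRule",
    "support",
    "apriori",
    "generate_rules",
    "filter_rules",
    "mine_rules",
]


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    return Fraction(x).limit_denominator(10**6)


@dataclass(frozen=True)
class Itemset:
    """A set of items with its exact support in the mined database."""

    items: frozenset
    support: Fraction

    def __post_init__(self) -> None:
        if not 0 <= self.support <= 1:
            raise ValueError("support must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class AssociationRule:
    """Rule antecedent => consequent with support, confidence and lift."""

    antecedent: frozenset
    consequent: frozenset
    support: Fraction
    confidence: Fraction
    lift: Fraction

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")

    @property
    def rule_text(self) -> str:
        lhs = ",".join(sorted(self.antecedent))
        rhs = ",".join(sorted(self.consequent))
        return f"{{{lhs}}} => {{{rhs}}}"

    def members(self) -> frozenset:
        return self.antecedent | self.consequent


def _normalize_db(db) -> list[frozenset]:
    """Accept a TransactionDB or an iterable of item collections."""
    from .discretize import TransactionDB, to_transactions

    if isinstance(db, TransactionDB):
        return to_transactions(db)
    return [frozenset(t) for t in db]


def support(itemset: Iterable, db) -> Fraction:
    """Exact fraction of transactions containing every item.

    The empty itemset has support 1 (vacuous containment); an empty
    database is an error.
    """
    transactions = _normalize_db(db)
    if not transactions:
        raise ValueError("empty transaction database")
    target = frozenset(itemset)
    hits = sum(1 for t in transactions if target <= t)
    return Fraction(hits, len(transactions))


def _min_count(min_support, n: int) -> int:
    frac = _as_fraction(min_support)
    if not 0 < frac <= 1:
        raise ValueError("min_support must lie in (0, 1]")
    return max(1, math.ceil(frac * n))


def apriori(db, min_support, max_len: int | None = None) -> list[Itemset]:
    """Level-wise frequent-itemset mining with subset pruning.

    Returns every itemset whose support reaches ``min_support``
    (compared exactly: at least ``ceil(min_support * |D|)`` of the
    ``|D|`` transactions), each with its exact support, canonically
    ordered by (size, lexicographic item tuple).
    """
    transactions = _normalize_db(db)
    if not transactions:
        raise ValueError("empty transaction database")
    n = len(transactions)
    need = _min_count(min_support, n)

    counts: dict = {}
    for t in transactions:
        for item in t:
            counts[item] = counts.get(item, 0) + 1
    frequent: dict[tuple, int] = {
        (item,): c for item, c in counts.items() if c >= need
    }
    all_frequent = dict(frequent)
    level = sorted(frequent)
    k = 1
    while level and (max_len is None or k < max_len):
        level_set = set(level)
        candidates = []
        for a, b in combinations(level, 2):
            if a[:-1] == b[:-1]:  # join on shared (k-1)-prefix
                cand = a[:-1] + tuple(sorted((a[-1], b[-1])))
                if all(
                    cand[:i] + cand[i + 1 :] in level_set for i in range(len(cand))
                ):
                    candidates.append(cand)
        next_level = {}
        for cand in candidates:
            cset = frozenset(cand)
            c = sum(1 for t in transactions if cset <= t)
            if c >= need:
                next_level[cand] = c
        all_frequent.update(next_level)
        level = sorted(next_level)
        k += 1
    return [
        Itemset(frozenset(t), Fraction(c, n))
        for t, c in sorted(all_frequent.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]


def generate_rules(
    itemsets: Sequence[Itemset], db=None, min_confidence=0.99
) -> list[AssociationRule]:
    """All rules X => Z\\X from frequent itemsets Z meeting ``min_confidence``.

    Confidence and lift are computed from the stored supports (every
    subset of a frequent itemset is frequent, so its support is
    available; ``db`` is accepted for interface symmetry and only used
    as a fallback lookup). Output is deterministic: lift descending,
    then support descending, then lexicographic.
    """
    min_conf = _as_fraction(min_confidence)
    lookup = {iset.items: iset.support for iset in itemsets}

    def supp(items: frozenset) -> Fraction:
        if items in lookup:
            return lookup[items]
        if db is not None:
            return support(items, db)
        raise KeyError(f"support unavailable for {sorted(items)}")

    rules = []
    for iset in itemsets:
        z = iset.items
        if len(z) < 2:
            continue
        members = sorted(z)
        for r in range(1, len(z)):
            for x in combinations(members, r):
                xs = frozenset(x)
                conf = iset.support / supp(xs)
                if conf >= min_conf:
                    ys = z - xs
                    lift = iset.support / (supp(xs) * supp(ys))
                    rules.append(
                        AssociationRule(xs, ys, iset.support, conf, lift)
                    )
    rules.sort(
        key=lambda r: (
            -r.lift,
            -r.support,
            tuple(sorted(r.antecedent)),
            tuple(sorted(r.consequent)),
        )
    )
    return rules


def filter_rules(rules: Sequence[AssociationRule], min_lift=2.0) -> list[AssociationRule]:
    """Keep rules with ``lift >= min_lift`` (inclusive bound)."""
    threshold = _as_fraction(min_lift)
    return [r for r in rules if r.lift >= threshold]


def mine_rules(
    db,
    min_support=0.5,
    min_confidence=0.99,
    min_lift=2.0,
    max_len: int | None = 5,
) -> list[AssociationRule]:
    """Apriori + rule generation + lift filter in one call."""
    itemsets = apriori(db, min_support, max_len=max_len)
    rules = generate_rules(itemsets, min_confidence=min_confidence)
    return filter_rules(rules, min_lift=min_lift)
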