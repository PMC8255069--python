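"""Guilt-by-association function prediction from association rules.

Uncharacterized genes that repeatedly appear in high-confidence,
high-lift rules together with annotated genes are assigned a putative
category by majority vote over their annotated rule partners.
Antecedent and consequent membership are treated symmetrically as
"association"; a partner gene is counted once per rule. A tie between
categories is reported as ambiguous with both categories listed.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .arm import AssociationRule

CATEGORIES = ("chemosensory", "non_chemosensory", "unannotated")

__all__ = ["PutativeFunction", "predict_functions", "predictions_frame"]


@dataclass(frozen=True)
class PutativeFunction:
    """A putative category for an unannotated gene, with its evidence."""

    gene_id: str
    predicted_categories: tuple[str, ...]
    ambiguous: bool
    n_rules: int
    n_annotated_partners: int
    category_counts: tuple[tuple[str, int], ...]
    supporting_rules: tuple[str, ...]

    @property
    def predicted_category(self) -> str:
        return "|".join(self.predicted_categories)


def _category_lookup(annotations) -> dict[str, str]:
    if isinstance(annotations, pd.DataFrame):
        if "gene_id" in annotations.columns:
            return dict(zip(annotations["gene_id"], annotations["category"]))
        return annotations["category"].to_dict()
    return dict(annotations)


def predict_functions(
    rules: Sequence[AssociationRule],
    annotations: Mapping[str, str] | pd.DataFrame,
) -> list[PutativeFunction]:
    """Predict categories for unannotated genes appearing in rules.

    For each unannotated gene found in any rule (antecedent or
    consequent), its rules are collected and the annotated partner
    genes across those rules tallied per category; the majority
    category is predicted (ties are flagged ambiguous and all tied
    categories reported). Genes whose rules contain no annotated
    partner are excluded. Genes present in rules but missing from the
    annotation table are treated as unannotated with a warning.
    Predictions are invariant to the order of the input rules.
    """
    lookup = _category_lookup(annotations)
    seen_missing = set()

    def category(gene: str) -> str:
        if gene not in lookup:
            if gene not in seen_missing:
                seen_missing.add(gene)
            return "unannotated"
        return lookup[gene]

    by_gene: dict[str, list[AssociationRule]] = {}
    for rule in rules:
        for gene in rule.members():
            if category(gene) == "unannotated":
                by_gene.setdefault(gene, []).append(rule)
    if seen_missing:
        warnings.warn(
            f"{len(seen_missing)} gene(s) in rules missing from annotations; "
            "treated as unannotated",
            stacklevel=2,
        )

    predictions = []
    for gene in sorted(by_gene):
        votes: Counter = Counter()
        rule_texts = set()
        for rule in by_gene[gene]:
            rule_texts.add(rule.rule_text)
            for partner in rule.members() - {gene}:
                cat = category(partner)
                if cat != "unannotated":
                    votes[cat] += 1
        total = sum(votes.values())
        if total == 0:
            continue  # no annotated evidence
        best = max(votes.values())
        winners = tuple(sorted(c for c, v in votes.items() if v == best))
        predictions.append(
            PutativeFunction(
                gene_id=gene,
                predicted_categories=winners,
                ambiguous=len(winners) > 1,
                n_rules=len(by_gene[gene]),
                n_annotated_partners=total,
                category_counts=tuple(sorted(votes.items())),
                supporting_rules=tuple(sorted(rule_texts)),
            )
        )
    return predictions


def predictions_frame(predictions: Sequence[PutativeFunction]) -> pd.DataFrame:
    """Tabular view of predictions (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in predictions],
            "predicted_category": [p.predicted_category for p in predictions],
            "ambiguous": [p.ambiguous for p in predictions],
            "n_rules": [p.n_rules for p in predictions],
            "n_partners": [p.n_annotated_partners for p in predictions],
            "supporting_rules": ["; ".join(p.supporting_rules) for p in predictions],
        }
    )
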