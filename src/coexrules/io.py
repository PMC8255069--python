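"""Readers and writers for the pipeline's plain-text formats.

Everything is diffable text: counts / metadata / annotations / module
assignments as TSV, rules and predictions and centralities as CSV,
transactions in basket format (one line per transaction:
``sample_id<TAB>comma-separated items``), networks as GraphML or edge
lists, and a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
from fractions import Fraction
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .arm import AssociationRule
from .coexpression import EigengeneMatrix, ModuleAssignment
from .discretize import TransactionDB
from .preprocess import TREATMENTS, CountMatrix
from .prediction import PutativeFunction, predictions_frame


# ---------------------------------------------------------------- counts

def read_count_matrix(counts_path, metadata_path) -> CountMatrix:
    """Read a counts TSV (genes x samples) and a sample-metadata TSV.

    Validates: unique gene and sample ids, integer non-negative counts
    (errors name the offending cell), metadata covering every sample
    with a recognized treatment.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicated gene id: {dup!r}")
    values = counts.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    if not np.all(values == np.floor(values)):
        g, s = np.argwhere(values != np.floor(values))[0]
        raise ValueError(
            f"non-integer count at gene {counts.index[g]!r}, "
            f"sample {counts.columns[s]!r}"
        )
    counts = counts.astype(int)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    bad = set(meta["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValueError(f"unknown treatment(s) in metadata: {sorted(bad)}")
    return CountMatrix(counts, meta)


def write_count_matrix(cm: CountMatrix, counts_path, metadata_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.metadata.to_csv(metadata_path, sep="\t")


# ----------------------------------------------------------- annotations

def read_annotations(path) -> pd.DataFrame:
    """Annotation TSV with columns ``gene_id`` and ``category``."""
    table = pd.read_csv(path, sep="\t")
    if not {"gene_id", "category"} <= set(table.columns):
        raise ValueError("annotation table needs 'gene_id' and 'category' columns")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicated gene id in annotations: {dup!r}")
    return table


def write_annotations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- modules

def write_module_assignment(modules: ModuleAssignment, path) -> None:
    out = pd.DataFrame(
        {"module_label": modules.labels, "module_color": modules.colors()}
    )
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_eigengenes(eg: EigengeneMatrix, path) -> None:
    out = eg.values.copy()
    out["explained_variance"] = eg.explained_variance
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------- transactions

def write_transactions_basket(db: TransactionDB, path) -> None:
    """Basket format: ``transaction_id<TAB>item1,item2,...`` per line."""
    from .discretize import to_transactions

    transactions = to_transactions(db)
    with open(path, "w") as fh:
        for tid, items in zip(db.transaction_ids, transactions):
            fh.write(f"{tid}\t{','.join(sorted(items))}\n")


def read_transactions_basket(path) -> tuple[list[str], list[frozenset]]:
    """Read basket-format transactions; returns (ids, item sets)."""
    ids, transactions = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            tid, _, items = line.partition("\t")
            ids.append(tid)
            transactions.append(
                frozenset(i for i in items.split(",") if i)
            )
    return ids, transactions


# ----------------------------------------------------------------- rules

def write_rules_csv(rules: Sequence[AssociationRule], path) -> None:
    table = pd.DataFrame(
        {
            "antecedent": [";".join(sorted(r.antecedent)) for r in rules],
            "consequent": [";".join(sorted(r.consequent)) for r in rules],
            "support": [float(r.support) for r in rules],
            "confidence": [float(r.confidence) for r in rules],
            "lift": [float(r.lift) for r in rules],
            "rule_text": [r.rule_text for r in rules],
        }
    )
    table.to_csv(path, index=False)


def read_rules_csv(path) -> list[AssociationRule]:
    table = pd.read_csv(path)
    rules = []
    for row in table.itertuples(index=False):
        rules.append(
            AssociationRule(
                antecedent=frozenset(str(row.antecedent).split(";")),
                consequent=frozenset(str(row.consequent).split(";")),
                support=Fraction(row.support).limit_denominator(10**6),
                confidence=Fraction(row.confidence).limit_denominator(10**6),
                lift=Fraction(row.lift).limit_denominator(10**6),
            )
        )
    return rules


def write_predictions_csv(predictions: Sequence[PutativeFunction], path) -> None:
    predictions_frame(predictions).to_csv(path, index=False)


# -------------------------------------------------------------- networks

def export_graphml(net: nx.Graph, path) -> None:
    """GraphML with node ``category`` and edge ``weight`` attributes.

    Round-trips through standard GraphML readers; an empty network is
    an error.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    nx.write_graphml(net, path)


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, "weight": data.get("weight", 1.0)}
        for u, v, data in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


# -------------------------------------------------------------- manifest

def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
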