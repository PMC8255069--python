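"""Equal-frequency discretization of expression into transactions.

A five-step, rank-based procedure converts each gene's expression
profile into interval labels:

1. sort the values in ascending order;
2. split the sorted values into ``k`` contiguous groups whose sizes
   differ by at most one (earlier groups take the extra element when
   ``n mod k != 0``);
3. the groups are the bins;
4. each boundary is the midpoint between the maximum of one bin and
   the minimum of the next;
5. every original value is mapped to the index of its interval.

With ``k = 2`` the output is a binary over/under-expression matrix:
1 = over-expressed, 0 = under-expressed. Viewing samples as transaction
ids and over-expressed genes as items turns the matrix into a
transaction database for association-rule mining.

Tie handling (the procedure above assumes distinct values): a boundary
may never fall inside a run of equal values, so the whole tie block is
assigned to the lower bin and group sizes rebalance; if that leaves no
valid strictly-increasing boundary (e.g. a constant gene) the gene is
rejected. Labels therefore depend only on value ranks, making the
procedure invariant under strictly increasing transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizationModel",
    "TransactionDB",
    "equal_frequency_bins",
    "apply_bins",
    "discretize_matrix",
    "to_transactions",
]


@dataclass(frozen=True)
class DiscretizationModel:
    """Per-gene interval boundaries (k - 1 strictly increasing cut points)."""

    boundaries: tuple[float, ...]
    k: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if len(self.boundaries) != self.k - 1:
            raise ValueError("expected k - 1 boundaries")
        if any(b >= c for b, c in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")


@dataclass
class TransactionDB:
    """Sample x gene incidence matrix of interval labels.

    For the default two-bin discretization the entries are binary
    (1 = over-expressed = item present). Samples are transaction ids,
    genes are items.
    """

    incidence: pd.DataFrame  # samples x genes, integer labels

    def __post_init__(self) -> None:
        values = self.incidence.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            raise ValueError("incidence must be integer-valued")

    @property
    def is_binary(self) -> bool:
        values = self.incidence.to_numpy()
        return bool(((values == 0) | (values == 1)).all())

    @property
    def transaction_ids(self) -> pd.Index:
        return self.incidence.index

    @property
    def items(self) -> pd.Index:
        return self.incidence.columns


def equal_frequency_bins(values, k: int) -> DiscretizationModel:
    """Fit equal-frequency bin boundaries for one gene.

    Requires ``n >= k >= 2`` and at least ``k`` distinct values
    arrangeable into non-empty, strictly separated groups; an all-equal
    vector raises.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")
    ordered = np.sort(arr, kind="stable")
    base, extra = divmod(n, k)
    sizes = [base + 1 if i < extra else base for i in range(k)]
    cuts = list(np.cumsum(sizes)[:-1])  # tentative split positions
    boundaries: list[float] = []
    prev_cut = 0
    for cut in cuts:
        cut = max(cut, prev_cut + 1)
        # push the split past any tie block so the boundary is strict
        while cut < n and ordered[cut - 1] == ordered[cut]:
            cut += 1
        if cut >= n:
            raise ValueError("ties leave no valid strictly increasing boundary")
        lo, hi = ordered[cut - 1], ordered[cut]
        midpoint = lo / 2.0 + hi / 2.0  # halves first: no overflow at the extremes
        # rounding may push the midpoint onto a group extreme; keep the
        # boundary in [lo, hi) so labels split exactly at the groups
        if midpoint >= hi:
            midpoint = np.nextafter(hi, -np.inf)
        if midpoint < lo:
            midpoint = lo
        boundaries.append(midpoint)
        prev_cut = cut
    return DiscretizationModel(tuple(boundaries), k)


def apply_bins(values, model: DiscretizationModel) -> np.ndarray:
    """Map values to interval indices 0 .. k-1 given fitted boundaries."""
    arr = np.asarray(values, dtype=float)
    return np.searchsorted(np.asarray(model.boundaries), arr, side="left").astype(int)


def discretize_matrix(expr: pd.DataFrame, k: int = 2) -> TransactionDB:
    """Discretize a genes x samples expression matrix gene by gene.

    Genes for which no valid boundaries exist (constant genes, heavy
    ties) are dropped with a warning. Returns a :class:`TransactionDB`
    of samples x genes interval labels (binary for ``k = 2``).
    """
    labels, kept, dropped = [], [], []
    for gene, row in expr.iterrows():
        try:
            model = equal_frequency_bins(row.to_numpy(), k)
        except ValueError:
            dropped.append(gene)
            continue
        labels.append(apply_bins(row.to_numpy(), model))
        kept.append(gene)
    if dropped:
        warnings.warn(
            f"discretize_matrix: dropped {len(dropped)} gene(s) without valid bins",
            stacklevel=2,
        )
    matrix = (
        np.vstack(labels) if labels else np.empty((0, expr.shape[1]), dtype=int)
    )
    df = pd.DataFrame(matrix.T, index=expr.columns, columns=pd.Index(kept, name="gene_id"))
    df.index.name = "sample_id"
    return TransactionDB(df.astype(int))


def to_transactions(db: TransactionDB) -> list[frozenset]:
    """One transaction per sample: the set of genes labelled 1.

    Requires a binary database (k = 2). The round trip back to an
    incidence matrix is lossless given the item universe.
    """
    if not db.is_binary:
        raise ValueError("transactions require a binary (k = 2) database")
    values = db.incidence.to_numpy()
    items = np.asarray(db.items)
    return [frozenset(items[row == 1]) for row in values]
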