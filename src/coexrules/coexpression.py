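"""Weighted co-expression network analysis.

Implements the classic weighted-correlation workflow on an expression
matrix of log2(normalized count + 1) values: absolute-Pearson
similarity, soft-threshold adjacency ``a_ij = s_ij ** beta``, signed-R2
scale-free topology fit for choosing beta, the unsigned topological
overlap matrix (TOM), average-linkage hierarchical clustering of
1 - TOM, a static tree cut with a minimum module size, module
eigengenes (first principal component of the standardized module
submatrix) and iterative merging of modules whose eigengenes are more
than 75% correlated (dissimilarity below the merge cut of 0.25).

Modules are labelled by decreasing size with integer labels (1 =
largest); label 0 means "unassigned" (grey). :data:`MODULE_COLORS`
provides the conventional color names for cosmetic parity with standard
co-expression tooling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

logger = logging.getLogger(__name__)

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)
UNASSIGNED_COLOR = "grey"
UNASSIGNED = 0


@dataclass
class ModuleAssignment:
    """Gene -> module labels; 0 is the unassigned (grey) label."""

    labels: pd.Series  # int per gene, index = gene ids

    @property
    def gene_ids(self) -> pd.Index:
        return self.labels.index

    def module_ids(self) -> list[int]:
        """Named module labels, sorted (excludes unassigned)."""
        return sorted(int(m) for m in self.labels.unique() if m != UNASSIGNED)

    def sizes(self) -> pd.Series:
        """Genes per named module."""
        counts = self.labels[self.labels != UNASSIGNED].value_counts().sort_index()
        counts.index = counts.index.astype(int)
        return counts

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def colors(self) -> pd.Series:
        """Conventional color name per gene (grey = unassigned)."""

        def color(m: int) -> str:
            if m == UNASSIGNED:
                return UNASSIGNED_COLOR
            if m - 1 < len(MODULE_COLORS):
                return MODULE_COLORS[m - 1]
            return f"module{m}"

        return self.labels.map(color).rename("module_color")


@dataclass
class EigengeneMatrix:
    """Per-module eigengene profiles (modules x samples, unit norm)."""

    values: pd.DataFrame
    explained_variance: pd.Series


def similarity(expr: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Unsigned co-expression similarity ``s_ij = |cor(x_i, x_j)|``.

    ``expr`` is genes x samples. Genes with zero variance are dropped
    with a warning (their correlation is undefined). Requires at least
    three samples.
    """
    if method != "pearson":
        raise ValueError("only pearson correlation is supported")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(expr.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} constant gene(s) from similarity", stacklevel=2
        )
        values = values[keep]
    index = expr.index[keep]
    s = np.atleast_2d(np.abs(np.corrcoef(values)))
    s = np.clip(s, 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=index, columns=index)


def adjacency(s: pd.DataFrame, beta: float = 12) -> pd.DataFrame:
    """Soft-threshold adjacency ``a_ij = s_ij ** beta`` (beta >= 1)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    return s**beta


def connectivity(a: pd.DataFrame) -> pd.Series:
    """Weighted connectivity ``k_i = sum_{j != i} a_ij``."""
    values = np.asarray(a, dtype=float)
    k = values.sum(axis=1) - np.diag(values)
    index = a.index if isinstance(a, pd.DataFrame) else pd.RangeIndex(len(k))
    return pd.Series(k, index=index, name="connectivity")


def scale_free_fit(obj, n_bins: int = 10) -> float:
    """Signed R2 of the log-log degree-distribution regression.

    Accepts an adjacency matrix (weighted connectivity is used), a
    networkx graph (node degrees) or a 1-D connectivity vector. The
    connectivities are split into ``n_bins`` equal-width bins, the
    per-bin frequency p(k) is regressed on log10(mean k per bin) and
    ``-sign(slope) * R2`` is returned: large positive values mean the
    distribution decays like a power law. Empty bins are dropped.
    Degenerate inputs (all connectivities equal, fewer than two
    occupied bins) return NaN.
    """
    import networkx as nx

    if isinstance(obj, nx.Graph):
        k = np.array([d for _, d in obj.degree()], dtype=float)
    else:
        arr = np.asarray(obj, dtype=float)
        if arr.ndim == 2:
            k = connectivity(pd.DataFrame(arr)).to_numpy()
        else:
            k = arr
    k = k[k > 0]
    if k.size < 2 or np.isclose(k.min(), k.max()):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(mask.mean())
    if len(xs) < 2:
        return float("nan")
    ys = np.log10(np.asarray(ys))
    fit = linregress(np.asarray(xs), ys)
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def select_beta(
    expr: pd.DataFrame,
    candidates=range(1, 21),
    target_fit: float = 0.8,
    n_bins: int = 10,
    min_mean_connectivity: float = 1.0,
) -> tuple[int, pd.DataFrame]:
    """Pick the soft-threshold power from scale-free topology fit.

    Returns the smallest candidate whose fit index reaches
    ``target_fit``, or the candidate with the maximal fit if none does,
    together with the full fit table (one row per candidate: fit index
    and mean/median/max connectivity) for auditing.

    Powers that degenerate the network -- mean weighted connectivity
    below ``min_mean_connectivity`` -- are excluded from selection (the
    fit index keeps climbing as the network dissolves into isolated
    nodes, which is the standard failure mode of an unguarded
    first-crossing rule); if every candidate is degenerate the guard is
    ignored. Set ``min_mean_connectivity=0`` to disable.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    s = similarity(expr)
    rows = []
    for beta in candidates:
        a = adjacency(s, beta)
        k = connectivity(a).to_numpy()
        rows.append(
            {
                "beta": beta,
                "fit_index": scale_free_fit(k, n_bins=n_bins),
                "mean_connectivity": float(k.mean()),
                "median_connectivity": float(np.median(k)),
                "max_connectivity": float(k.max()),
            }
        )
    table = pd.DataFrame(rows)
    # the binned fit index is noisy in beta; a short rolling median makes
    # the first-crossing rule robust to single-bin artifacts
    smoothed = (
        table["fit_index"].rolling(3, center=True, min_periods=1).median().to_numpy()
    )
    usable = table["mean_connectivity"].to_numpy() >= min_mean_connectivity
    if not usable.any():
        usable = np.ones(len(table), dtype=bool)
    fits = np.where(usable, smoothed, -np.inf)
    reaching = np.flatnonzero(fits >= target_fit)
    if reaching.size:
        chosen = int(table["beta"].iloc[reaching[0]])
    elif np.isfinite(fits).any():
        chosen = int(table["beta"].iloc[int(np.nanargmax(fits))])
    else:
        chosen = candidates[0]
    logger.info("select_beta: chose beta=%d", chosen)
    return chosen, table


def topological_overlap(a: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    self-adjacency is zeroed internally and the diagonal of the result
    is set to 1 by convention.
    """
    values = np.array(a, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(values, values.T):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(values, 0.0)
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError("adjacency entries must lie in [0, 1]")
    L = values @ values
    k = values.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - values
    tom = (L + values) / denom
    tom = np.clip(0.5 * (tom + tom.T), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    if isinstance(a, pd.DataFrame):
        return pd.DataFrame(tom, index=a.index, columns=a.columns)
    return pd.DataFrame(tom)


def tom_dissimilarity(tom: pd.DataFrame) -> pd.DataFrame:
    """Clustering dissimilarity ``1 - TOM``."""
    return 1.0 - tom


def hierarchical_cluster(diss: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of a dissimilarity matrix.

    Returns the scipy linkage matrix (merge tree with non-decreasing
    heights under average linkage). A single observation yields an
    empty merge list.
    """
    values = np.array(diss, dtype=float)
    if np.isnan(values).any():
        raise ValueError("dissimilarity matrix contains NaN")
    if values.shape[0] != values.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if values.shape[0] < 2:
        return np.empty((0, 4))
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    condensed = squareform(values, checks=False)
    return scipy_linkage(condensed, method=method)


def cut_modules(
    dendrogram: np.ndarray,
    gene_ids,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
) -> ModuleAssignment:
    """Static tree cut: fixed-height cut plus a minimum module size.

    The tree is cut at ``cut_height_quantile`` times the maximal merge
    height; connected subtrees below the cut are candidate modules and
    candidates smaller than ``min_module_size`` are labelled unassigned
    (0). Surviving modules are labelled by decreasing size (1 =
    largest).
    """
    gene_ids = pd.Index(gene_ids)
    n = len(gene_ids)
    if dendrogram.shape[0] == 0:
        return ModuleAssignment(pd.Series(UNASSIGNED, index=gene_ids, name="module"))
    if dendrogram.shape[0] != n - 1:
        raise ValueError("dendrogram does not match the number of genes")
    cut_height = cut_height_quantile * float(dendrogram[:, 2].max())
    raw = fcluster(dendrogram, t=cut_height, criterion="distance")
    counts = pd.Series(raw).value_counts()
    big = counts[counts >= min_module_size]
    # rank by decreasing size; break size ties by smallest original cluster id
    ranked = sorted(big.index, key=lambda c: (-big[c], c))
    relabel = {c: i + 1 for i, c in enumerate(ranked)}
    labels = pd.Series(
        [relabel.get(c, UNASSIGNED) for c in raw], index=gene_ids, name="module"
    )
    return ModuleAssignment(labels)


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    out = np.zeros_like(values, dtype=float)
    np.divide(values - mean, sd, out=out, where=sd > 0)
    return out


def _first_pc(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First right-singular vector (per-sample scores) and explained variance."""
    _, svals, vt = np.linalg.svd(x, full_matrices=False)
    total = float((svals**2).sum())
    if total == 0.0:
        return np.zeros(x.shape[1]), 0.0
    return vt[0], float(svals[0] ** 2 / total)


def module_eigengene(expr: pd.DataFrame, modules: ModuleAssignment) -> EigengeneMatrix:
    """Module eigengenes: first PC of the standardized module submatrix.

    The eigengene is a unit-norm per-sample profile; its sign is chosen
    so it correlates positively with the module's mean expression
    profile (tie broken by making the first nonzero entry positive),
    which makes the output deterministic and invariant to gene order.
    A one-gene module's eigengene is that gene's standardized profile.
    """
    rows, explained = {}, {}
    for m in modules.module_ids():
        genes = modules.genes_in(m)
        x = _standardize_rows(expr.loc[genes].to_numpy(dtype=float))
        if x.shape[0] == 1:
            e, ev = x[0].copy(), 1.0
        else:
            e, ev = _first_pc(x)
        norm = np.linalg.norm(e)
        if norm > 0:
            e = e / norm
        mean_profile = x.mean(axis=0)
        orient = float(np.dot(e, mean_profile - mean_profile.mean()))
        if orient < 0:
            e = -e
        elif orient == 0:
            nz = np.flatnonzero(e)
            if nz.size and e[nz[0]] < 0:
                e = -e
        rows[m] = e
        explained[m] = ev
    values = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    if not values.empty:
        values.columns = expr.columns
    values.index.name = "module"
    return EigengeneMatrix(values, pd.Series(explained, name="explained_variance", dtype=float))


def merge_close_modules(
    expr: pd.DataFrame, modules: ModuleAssignment, cut: float = 0.25
) -> ModuleAssignment:
    """Iteratively merge modules with eigengene dissimilarity below ``cut``.

    Dissimilarity is ``1 - cor(eigengene_a, eigengene_b)``. The closest
    pair is merged first and eigengenes are recomputed after every
    merge; with all dissimilarities >= ``cut`` the assignment is
    returned unchanged (after size-rank relabelling). Idempotent at a
    fixed cut.
    """
    labels = modules.labels.copy()
    while True:
        current = ModuleAssignment(labels)
        ids = current.module_ids()
        if len(ids) < 2:
            break
        eg = module_eigengene(expr, current).values.loc[ids]
        cor = np.corrcoef(eg.to_numpy())
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= cut:
            break
        keep, absorb = sorted((ids[i], ids[j]))
        labels = labels.replace(absorb, keep)
        logger.info("merge_close_modules: merged module %d into %d", absorb, keep)
    # relabel by decreasing size for a canonical output
    sizes = ModuleAssignment(labels).sizes()
    ranked = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    relabel = {m: i + 1 for i, m in enumerate(ranked)}
    relabel[UNASSIGNED] = UNASSIGNED
    return ModuleAssignment(labels.map(relabel).rename("module"))
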