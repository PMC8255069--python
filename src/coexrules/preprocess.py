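"""Count-matrix preprocessing and differential expression.

The entry point of the pipeline is a gene x sample matrix of non-negative
integer read counts plus per-sample metadata (treatment and replicate).
This module provides low-count filtering, median-of-ratios normalization,
a two-sample differential-expression test, Benjamini-Hochberg FDR
adjustment, and selection of differentially expressed (DE) genes by FDR
and fold change.

The DE test is a deliberately simple, documented stand-in for a negative
binomial GLM engine: counts are normalized by median-of-ratios size
factors, log2(x + 1)-transformed, and compared between groups with a
Welch two-sample t-test. Fold changes are ratios of mean normalized
counts with a pseudocount of 0.5. See ``docs/methods.md`` for why this is
adequate for the downstream network/rule-mining analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("attractant", "repellent", "control")

#: pseudocount added before log2 transformation of normalized counts
LOG_PSEUDOCOUNT = 1.0
#: pseudocount added to group means when computing fold changes
FC_PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Integer gene x sample read counts with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows (index = gene
        ids), samples as columns.
    metadata
        DataFrame indexed by sample id with columns ``treatment`` (one of
        attractant / repellent / control) and ``replicate``. Must cover
        every sample in ``counts``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups)[:5]}")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        if "treatment" not in self.metadata.columns:
            raise ValueError("metadata must have a 'treatment' column")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_of(self, treatment: str) -> list[str]:
        """Sample ids belonging to one treatment group."""
        meta = self.metadata.loc[self.sample_ids]
        return list(meta.index[meta["treatment"] == treatment])


def filter_low_counts(
    cm: CountMatrix, min_count: int = 10, sample_frac: float = 0.9
) -> CountMatrix:
    """Remove genes with low counts in more than ``sample_frac`` of samples.

    A gene is removed when the proportion of samples with count strictly
    below ``min_count`` is strictly greater than ``sample_frac`` (a gene
    low in exactly 90% of samples is retained). Gene order is preserved.
    """
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must be in (0, 1]")
    low_frac = (cm.counts < min_count).mean(axis=1)
    keep = low_frac <= sample_frac
    if not keep.any():
        warnings.warn("low-count filter removed every gene", stacklevel=2)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_low_counts: dropped %d of %d genes", n_dropped, cm.n_genes)
    return CountMatrix(cm.counts.loc[keep], cm.metadata)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each sample j the factor is the median over genes g (restricted
    to genes with a positive geometric mean across samples) of
    ``count[g, j] / geomean_g``. Raises if no gene is expressed in all
    samples.
    """
    values = cm.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(values)
    log_geomeans = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomeans)
    if not usable.any():
        raise ValueError("no gene with nonzero counts in every sample")
    ratios = log_counts[usable] - log_geomeans[usable, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def normalized_counts(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if factors is None:
        factors = size_factors(cm)
    return cm.counts / factors.loc[cm.sample_ids]


def log_normalized(cm: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(normalized count + 1) expression matrix (genes x samples)."""
    return np.log2(normalized_counts(cm, factors) + LOG_PSEUDOCOUNT)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``padj_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the sorted
    p-values, mapped back to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def differential_expression(
    cm: CountMatrix, contrast: tuple[str, str] = ("attractant", "control")
) -> pd.DataFrame:
    """Per-gene differential expression between two treatment groups.

    Returns a DataFrame with one row per gene and columns ``gene_id``,
    ``log2_fold_change`` (treatment over control, pseudocount 0.5 on the
    group means of normalized counts), ``p_value`` (Welch t-test on
    log2(normalized + 1)), ``p_adjusted`` (BH) and ``contrast``.
    Degenerate genes (identical values in both groups, all-zero genes)
    receive p = 1.
    """
    from scipy import stats

    treatment, control = contrast
    trt = cm.samples_of(treatment)
    ctl = cm.samples_of(control)
    if len(trt) < 2 or len(ctl) < 2:
        raise ValueError(
            f"need >= 2 replicates per group, got {len(trt)} {treatment} "
            f"and {len(ctl)} {control}"
        )
    norm = normalized_counts(cm)
    log_expr = np.log2(norm + LOG_PSEUDOCOUNT)
    a = log_expr[trt].to_numpy()
    b = log_expr[ctl].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero variance in both groups (incl. all-zero genes): no evidence
    p = np.where(np.isfinite(p), p, 1.0)
    mean_trt = norm[trt].mean(axis=1).to_numpy()
    mean_ctl = norm[ctl].mean(axis=1).to_numpy()
    l2fc = np.log2((mean_trt + FC_PSEUDOCOUNT) / (mean_ctl + FC_PSEUDOCOUNT))
    result = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "log2_fold_change": l2fc,
            "p_value": p,
            "p_adjusted": adjust_bh(p),
            "contrast": f"{treatment}_vs_{control}",
        }
    ).reset_index(drop=True)
    return result


def select_de_genes(
    results: pd.DataFrame, max_fdr: float = 0.05, min_fold: float = 2.0
) -> set[str]:
    """Genes with ``p_adjusted < max_fdr`` and at least ``min_fold`` change.

    The FDR comparison is strict (p_adjusted exactly at the threshold is
    excluded); the fold-change bound ``|log2FC| >= log2(min_fold)`` is
    inclusive.
    """
    if results.empty:
        return set()
    mask = (results["p_adjusted"] < max_fdr) & (
        results["log2_fold_change"].abs() >= np.log2(min_fold)
    )
    return set(results.loc[mask, "gene_id"])
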