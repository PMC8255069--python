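"""Synthetic RNA-seq counts, transaction databases and test graphs.

Every downstream stage of the pipeline is testable without any external
download thanks to generators with planted, known ground truth:

* :func:`generate_counts` emits a negative-binomial count matrix for a
  3-treatment x replicate design with planted co-expression modules
  (shared latent factor per module), planted differentially expressed
  genes (a log2 fold-change shift in one treatment) and, optionally,
  planted "rule groups" -- tightly co-regulated gene sets designed to
  binarize identically and hence surface as association rules.
* :func:`generate_transactions` emits a binary transaction database with
  planted jointly-occurring itemsets over independent Bernoulli noise.
* :func:`generate_test_graph` emits named graph families used as
  fixtures for centrality and scale-free-fit checks.

All generators take an explicit seed and use one private
``numpy.random.Generator`` stream; identical seed and configuration give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import TREATMENTS, CountMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_counts",
    "generate_transactions",
    "generate_test_graph",
    "generate_annotations",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration for :func:`generate_counts`.

    The defaults encode the study design the simulator emulates: nine
    samples (three treatments x three replicates), four planted modules
    of 50 genes with a latent within-module correlation of 0.7, 10% of
    genes shifted by log2FC = 2 in the attractant treatment, and
    negative-binomial counts (dispersion 0.1) around log-normal latent
    means.

    ``gene_noise_sd`` is the per-sample biological variability on the
    log2 scale; it sets how large the planted correlated signal is
    relative to the counting noise. ``n_rule_groups`` /
    ``rule_group_size`` / ``rule_group_cor`` plant near-identical
    ("co-binarizing") gene groups used to seed association rules; rule
    group genes are drawn from outside the modules.
    """

    n_genes: int = 300
    n_modules: int = 4
    module_size: int = 50
    n_samples: int = 9
    within_module_cor: float = 0.7
    de_gene_frac: float = 0.1
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    gene_noise_sd: float = 2.0
    n_rule_groups: int = 0
    rule_group_size: int = 5
    rule_group_cor: float = 0.99
    de_treatment: str = "attractant"
    seed: int = 0

    def __post_init__(self) -> None:
        budget = self.n_modules * self.module_size + self.n_rule_groups * self.rule_group_size
        if budget > self.n_genes:
            raise ValueError(
                f"module/rule-group budget ({budget} genes) exceeds n_genes={self.n_genes}"
            )
        for name in ("within_module_cor", "de_gene_frac", "rule_group_cor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.de_treatment not in TREATMENTS:
            raise ValueError(f"de_treatment must be one of {TREATMENTS}")


@dataclass
class GroundTruth:
    """Planted structure underlying a simulated count matrix.

    ``module_of_gene`` maps every gene to its planted module (0 =
    background, modules numbered from 1; rule groups are recorded as
    background here and listed in ``planted_rules``). ``de_genes`` maps
    planted DE genes to ``(log2_fold_change, treatment)``.
    ``planted_rules`` lists the co-binarizing gene groups.
    """

    module_of_gene: dict[str, int]
    de_genes: dict[str, tuple[float, str]]
    planted_rules: list[list[str]] = field(default_factory=list)


def _sample_metadata(n_samples: int) -> pd.DataFrame:
    treatments = [TREATMENTS[i % len(TREATMENTS)] for i in range(n_samples)]
    replicates, seen = [], {}
    for t in treatments:
        seen[t] = seen.get(t, 0) + 1
        replicates.append(seen[t])
    sample_ids = [f"{t}_{r}" for t, r in zip(treatments, replicates)]
    return pd.DataFrame(
        {"treatment": treatments, "replicate": replicates},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def generate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a count matrix with planted modules, DE genes and rule groups.

    Latent model: gene g has a baseline log2 mean ``mu_g ~ N(baseline_log_mean,
    baseline_log_sd)``. Its per-sample log2 mean is ``mu_g + gene_noise_sd *
    z_gs`` where ``z_gs = sqrt(rho) * f_ms + sqrt(1-rho) * eps_gs`` shares a
    standard-normal factor ``f_ms`` within module m (rho =
    ``within_module_cor``; background genes have rho = 0; rule groups use
    ``rule_group_cor``). Planted DE genes gain ``de_log2fc`` in the samples of
    ``de_treatment``. Counts are negative binomial with the given dispersion
    around ``2**log2mean`` (Poisson when dispersion is 0).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_digits = max(4, len(str(cfg.n_genes)))
    genes = [f"g{i:0{n_digits}d}" for i in range(cfg.n_genes)]
    meta = _sample_metadata(cfg.n_samples)
    n = cfg.n_samples

    module_of = np.zeros(cfg.n_genes, dtype=int)
    for m in range(cfg.n_modules):
        module_of[m * cfg.module_size : (m + 1) * cfg.module_size] = m + 1

    rule_start = cfg.n_modules * cfg.module_size
    rule_groups: list[list[int]] = []
    for r in range(cfg.n_rule_groups):
        lo = rule_start + r * cfg.rule_group_size
        rule_groups.append(list(range(lo, lo + cfg.rule_group_size)))
    in_rule_group = np.zeros(cfg.n_genes, dtype=bool)
    for grp in rule_groups:
        in_rule_group[grp] = True

    mu = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    module_factors = rng.normal(size=(cfg.n_modules, n))
    group_factors = rng.normal(size=(max(cfg.n_rule_groups, 1), n))
    eps = rng.normal(size=(cfg.n_genes, n))
    if n >= 2:
        # standardize each shared factor to zero mean / unit *sample* variance
        # so the planted within-module correlation holds per realization, not
        # just in expectation (the realized factor variance of a single draw
        # fluctuates strongly at small n)
        for f in (module_factors, group_factors):
            f -= f.mean(axis=1, keepdims=True)
            sd = f.std(axis=1, keepdims=True)
            np.divide(f, sd, out=f, where=sd > 0)

    # Per-gene factor loadings are inflated to compensate the attenuation of
    # observed correlations by counting noise, so the realized within-module
    # correlation of log2 counts approximately equals the configured target.
    # Delta method at the baseline mean: var of log2-scale NB noise is about
    # (1/mu + dispersion) / ln(2)^2.
    tau2 = cfg.gene_noise_sd**2
    if tau2 > 0:
        # E[1/mean] over the lognormal per-sample means exceeds 1/baseline
        # by exp((tau ln2)^2 / 2)
        inv_mean = np.exp2(-mu) * math.exp(0.5 * (cfg.gene_noise_sd * math.log(2.0)) ** 2)
        nb_var = (inv_mean + cfg.nb_dispersion) / math.log(2.0) ** 2
        inflation = 1.0 + nb_var / tau2
    else:
        inflation = np.ones(cfg.n_genes)

    def loading(target: float) -> np.ndarray:
        return np.sqrt(np.minimum(1.0, target * inflation))

    z = eps.copy()
    lam = loading(cfg.within_module_cor)
    for m in range(cfg.n_modules):
        sel = module_of == m + 1
        z[sel] = lam[sel, None] * module_factors[m] + np.sqrt(
            1.0 - lam[sel, None] ** 2
        ) * eps[sel]
    lam_rule = loading(cfg.rule_group_cor)
    for r, grp in enumerate(rule_groups):
        z[grp] = lam_rule[grp, None] * group_factors[r] + np.sqrt(
            1.0 - lam_rule[grp, None] ** 2
        ) * eps[grp]

    log2_mean = mu[:, None] + cfg.gene_noise_sd * z

    n_de = int(round(cfg.de_gene_frac * cfg.n_genes))
    eligible = np.flatnonzero(~in_rule_group)
    de_idx = rng.choice(eligible, size=min(n_de, eligible.size), replace=False)
    de_samples = (meta["treatment"] == cfg.de_treatment).to_numpy()
    if de_idx.size and de_samples.any():
        log2_mean[np.ix_(de_idx, np.flatnonzero(de_samples))] += cfg.de_log2fc

    mean = np.exp2(log2_mean)
    if cfg.nb_dispersion > 0:
        shape = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(shape, shape / (shape + mean))
    else:
        counts = rng.poisson(mean)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=meta.index),
        meta,
    )
    truth = GroundTruth(
        module_of_gene={g: int(m) for g, m in zip(genes, module_of)},
        de_genes={genes[i]: (cfg.de_log2fc, cfg.de_treatment) for i in sorted(de_idx)},
        planted_rules=[[genes[i] for i in grp] for grp in rule_groups],
    )
    return cm, truth


def generate_annotations(
    truth: GroundTruth, unannotated_frac: float = 0.4
) -> pd.DataFrame:
    """Deterministic gene annotation table consistent with a ground truth.

    Within every planted rule group the trailing ``unannotated_frac``
    (at least one gene) is labelled ``unannotated`` and the rest
    ``chemosensory``, emulating uncharacterized genes co-regulated with
    annotated chemosensory genes. All other genes are
    ``non_chemosensory``. Returns a DataFrame with columns ``gene_id``
    and ``category``.
    """
    category = {g: "non_chemosensory" for g in truth.module_of_gene}
    for grp in truth.planted_rules:
        n_un = max(1, int(round(unannotated_frac * len(grp)))) if grp else 0
        for g in grp[: len(grp) - n_un]:
            category[g] = "chemosensory"
        for g in grp[len(grp) - n_un :]:
            category[g] = "unannotated"
    return pd.DataFrame(
        {"gene_id": list(category), "category": list(category.values())}
    )


def generate_transactions(
    n_transactions: int,
    n_items: int,
    planted_itemsets: list[set[str]] | None = None,
    itemset_prob: float = 0.5,
    noise_prob: float = 0.05,
    seed: int = 0,
):
    """Binary transaction database with planted co-occurring itemsets.

    Items are named ``it00 .. itNN``. Each item occurs independently in
    each transaction with probability ``noise_prob``; on top of that,
    each planted itemset is inserted jointly into a transaction with
    probability ``itemset_prob``. Returns a
    :class:`~coexrules.discretize.TransactionDB`.
    """
    from .discretize import TransactionDB

    if not 0 <= itemset_prob <= 1 or not 0 <= noise_prob <= 1:
        raise ValueError("itemset_prob and noise_prob must be in [0, 1]")
    width = max(2, len(str(max(n_items - 1, 0))))
    items = [f"it{i:0{width}d}" for i in range(n_items)]
    item_pos = {it: i for i, it in enumerate(items)}
    planted_itemsets = planted_itemsets or []
    for s in planted_itemsets:
        unknown = set(s) - set(items)
        if unknown:
            raise ValueError(f"planted items not in item universe: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    incidence = (rng.random((n_transactions, n_items)) < noise_prob).astype(int)
    for s in planted_itemsets:
        cols = [item_pos[it] for it in s]
        hit = rng.random(n_transactions) < itemset_prob
        incidence[np.ix_(hit, cols)] = 1
    tids = [f"t{i:03d}" for i in range(n_transactions)]
    df = pd.DataFrame(incidence, index=pd.Index(tids, name="transaction_id"), columns=items)
    return TransactionDB(df)


def generate_test_graph(kind: str, n: int, seed: int | None = None, **params) -> nx.Graph:
    """Named test graphs: path, star, complete, erdos_renyi, preferential_attachment.

    ``erdos_renyi`` takes ``p`` (edge probability, default 0.1);
    ``preferential_attachment`` takes ``m`` (edges per new node, default
    2) and yields an approximately power-law degree distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "path":
        return nx.path_graph(n)
    if kind == "star":
        return nx.star_graph(n - 1)
    if kind == "complete":
        return nx.complete_graph(n)
    if kind == "erdos_renyi":
        return nx.erdos_renyi_graph(n, params.get("p", 0.1), seed=seed)
    if kind == "preferential_attachment":
        m = params.get("m", 2)
        return nx.barabasi_albert_graph(n, m, seed=seed)
    raise ValueError(f"unknown graph kind: {kind!r}")
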