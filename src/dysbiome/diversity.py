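"""Alpha/beta diversity, group significance tests, and ordination.

Alpha metrics: Shannon entropy (log base 2), Pielou evenness, observed
features and Faith's phylogenetic diversity (path to root included).
Beta metrics: Jaccard (presence/absence), Bray-Curtis, unweighted and
(raw, unnormalised) weighted UniFrac.  Group differences are tested by
Kruskal-Wallis (alpha) and PERMANOVA (beta), each corrected by
Benjamini-Hochberg within its own four-metric family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

from .core import FeatureTable, GroupTestResult, SampleMetadata

logger = logging.getLogger("dysbiome")

ALPHA_METRICS = ("shannon", "pielou", "observed_features", "faith_pd")
BETA_METRICS = ("jaccard", "bray_curtis", "unweighted_unifrac", "weighted_unifrac")


def _check_tree_covers(table: FeatureTable, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tips]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:10]}")


def alpha_diversity(
    table: FeatureTable,
    metric: str,
    tree: TreeNode | None = None,
    base: float = 2.0,
) -> pd.Series:
    """Per-sample alpha diversity for one metric.

    Shannon is computed in ``log`` base ``base`` (default 2, so "bits");
    Pielou divides by ``log(observed)`` in the same base and is therefore
    base-free.  Faith's PD needs ``tree``.
    """
    totals = table.sample_totals()
    if totals.nunique() > 1:
        logger.warning(
            "alpha diversity on unequal sample depths (%d..%d); rarefy first",
            totals.min(),
            totals.max(),
        )
    counts = table.counts.to_numpy().T  # samples x taxa
    if metric == "observed_features":
        vals = (counts > 0).sum(axis=1).astype(float)
    elif metric in ("shannon", "pielou"):
        vals = np.empty(len(counts))
        for i, row in enumerate(counts):
            nz = row[row > 0]
            p = nz / nz.sum()
            h = -(p * (np.log(p) / np.log(base))).sum()
            if metric == "pielou":
                s = len(nz)
                h = h / (np.log(s) / np.log(base)) if s > 1 else 0.0
            vals[i] = h
    elif metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a tree")
        _check_tree_covers(table, tree)
        vals = np.array(
            [faith_pd(row, table.taxon_ids, tree) for row in counts]
        )
    else:
        raise ValueError(f"unknown alpha metric {metric!r}")
    return pd.Series(vals, index=table.sample_ids, name=metric)


def beta_matrix(
    table: FeatureTable,
    metric: str,
    tree: TreeNode | None = None,
    normalized: bool = False,
) -> DistanceMatrix:
    """Pairwise sample dissimilarities for one beta metric.

    Weighted UniFrac is the raw (unnormalised) variant by default;
    ``normalized=True`` divides by the abundance-weighted tree depth.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total reads: {bad}")
    counts = table.counts.to_numpy().T
    ids = table.sample_ids
    if metric == "jaccard":
        return beta_diversity("jaccard", counts > 0, ids=ids)
    if metric == "bray_curtis":
        return beta_diversity("braycurtis", counts, ids=ids)
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        _check_tree_covers(table, tree)
        kwargs = {"taxa": table.taxon_ids, "tree": tree}
        if metric == "weighted_unifrac":
            kwargs["normalized"] = normalized
        return beta_diversity(metric, counts, ids=ids, **kwargs)
    raise ValueError(f"unknown beta metric {metric!r}")


def kruskal_wallis_alpha(
    alphas: dict[str, pd.Series],
    metadata: SampleMetadata,
) -> list[GroupTestResult]:
    """Kruskal-Wallis per alpha metric; BH correction across the family."""
    results = []
    for metric, series in alphas.items():
        labels = metadata.labels_for(series.index)
        groups = [series[labels == g].to_numpy() for g in metadata.levels()]
        stat, p = stats.kruskal(*groups)
        results.append(GroupTestResult(metric=metric, statistic=stat, p_value=p))
    _attach_bh(results)
    return results


def permanova(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    permutations: int = 999,
    seed: int = 0,
) -> GroupTestResult:
    """Two-group PERMANOVA (pseudo-F, permutation p with +1 correction)."""
    labels = metadata.labels_for(dm.ids)
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"every group needs >= 2 samples, got {sizes.to_dict()}")
    res = _skbio_permanova(
        dm, labels.to_numpy(), permutations=permutations, seed=seed
    )
    return GroupTestResult(
        metric="permanova",
        statistic=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        permutations=permutations,
    )


def permanova_family(
    dms: dict[str, DistanceMatrix],
    metadata: SampleMetadata,
    permutations: int = 999,
    seed: int = 0,
) -> list[GroupTestResult]:
    """PERMANOVA per beta metric; BH correction across the family."""
    results = []
    for i, (metric, dm) in enumerate(dms.items()):
        r = permanova(dm, metadata, permutations=permutations, seed=seed + i)
        r.metric = metric
        results.append(r)
    _attach_bh(results)
    return results


def _attach_bh(results: list[GroupTestResult]) -> None:
    if not results:
        return
    ps = [r.p_value for r in results]
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    for r, q in zip(results, qs):
        r.q_value = float(q)


def pcoa(dm: DistanceMatrix, seed: int = 0):
    """Principal coordinates (Gower double-centering eigendecomposition).

    Negative eigenvalues are reported as-is but excluded from the
    proportion-explained denominator.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", seed=seed, warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    pos = eig[eig > 0].sum()
    if pos > 0:
        res.proportion_explained = pd.Series(
            np.where(eig > 0, eig / pos, 0.0), index=res.eigvals.index
        )
    return res
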