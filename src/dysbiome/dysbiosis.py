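"""Three dysbiosis statistics against a healthy reference set.

* :func:`median_distance_test` — a test sample is "dysbiotic" when its
  median Bray-Curtis distance to the reference samples exceeds the 90%
  quantile of the reference set's own leave-one-out median distances.
* :func:`doc_analysis` — the dissimilarity-overlap curve: per sample pair,
  overlap of the shared-taxon mass vs root Jensen-Shannon divergence of
  the renormalised shared compositions; under shared ("universal")
  dynamics the curve slopes downward at high overlap.
* :func:`cloud_test` — a non-parametric outlier test: the ratio r of the
  test sample's k-nearest-neighbour neighbourhood diameter to the average
  leave-one-out diameter within a random reference subset, with an
  empirical p-value from scoring every reference sample the same way.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import FeatureTable, SampleMetadata

DEFAULT_QUANTILE = 0.90
DEFAULT_REF_FRACTIONS = (0.05, 0.15, 0.30)


# ---------------------------------------------------------------------------
# Median Bray-Curtis distance test
# ---------------------------------------------------------------------------

@dataclass
class MedianDistanceResult:
    statistics: pd.Series  # per test sample: median distance to references
    cutoff: float
    flags: pd.Series
    reference_medians: pd.Series  # leave-one-out medians within the reference


def median_distance_test(
    dm: DistanceMatrix,
    reference_ids,
    test_ids,
    quantile: float = DEFAULT_QUANTILE,
    cutoff_mode: str = "loo_median",
) -> MedianDistanceResult:
    """Flag test samples whose median distance to the reference exceeds the
    reference's own ``quantile`` cutoff.

    ``cutoff_mode='loo_median'`` (default) takes the quantile of each
    reference sample's median leave-one-out distance — the same functional
    as the test statistic, so ~10% of reference samples self-flag by
    construction.  ``'pooled'`` uses the pooled pairwise reference
    distances instead.
    """
    reference_ids = list(reference_ids)
    test_ids = list(test_ids)
    if len(reference_ids) < 3:
        raise ValueError("need at least 3 reference samples")
    overlap = set(reference_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"test/reference overlap: {sorted(overlap)[:5]}")
    df = dm.to_data_frame()
    ref_block = df.loc[reference_ids, reference_ids].to_numpy()
    n_ref = len(reference_ids)
    loo = np.array(
        [np.median(np.delete(ref_block[i], i)) for i in range(n_ref)]
    )
    ref_medians = pd.Series(loo, index=reference_ids)
    if cutoff_mode == "loo_median":
        cutoff = float(np.quantile(loo, quantile))
    elif cutoff_mode == "pooled":
        iu = np.triu_indices(n_ref, 1)
        cutoff = float(np.quantile(ref_block[iu], quantile))
    else:
        raise ValueError(f"unknown cutoff_mode {cutoff_mode!r}")
    stats_ = pd.Series(
        {t: float(np.median(df.loc[t, reference_ids])) for t in test_ids}
    )
    flags = stats_ > cutoff
    return MedianDistanceResult(
        statistics=stats_, cutoff=cutoff, flags=flags, reference_medians=ref_medians
    )


# ---------------------------------------------------------------------------
# Dissimilarity-overlap curve
# ---------------------------------------------------------------------------

@dataclass
class DOCResult:
    pairs: pd.DataFrame  # columns: sample_a, sample_b, overlap, dissimilarity
    curve: pd.DataFrame  # lowess fit: overlap grid, fitted dissimilarity
    region_bound: float
    slope: float
    spearman: float
    spearman_p: float
    bootstrap: pd.DataFrame | None = None  # per-replicate slope / spearman


def _doc_pair_stats(rel: np.ndarray):
    """Overlap and rJSD matrices for all sample pairs (columns = samples)."""
    n = rel.shape[1]
    O = np.zeros((n, n))
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        x, y = rel[:, i], rel[:, j]
        shared = (x > 0) & (y > 0)
        if not shared.any():
            O[i, j] = O[j, i] = np.nan
            D[i, j] = D[j, i] = np.nan
            continue
        xs, ys = x[shared], y[shared]
        O[i, j] = O[j, i] = 0.5 * (xs.sum() + ys.sum())
        xs = xs / xs.sum()
        ys = ys / ys.sum()
        m = 0.5 * (xs + ys)
        jsd = 0.5 * np.sum(xs * np.log(xs / m)) + 0.5 * np.sum(ys * np.log(ys / m))
        D[i, j] = D[j, i] = math.sqrt(max(jsd, 0.0))
    return O, D


def _region_stats(o: np.ndarray, d: np.ndarray, bound: float):
    mask = o > bound
    if mask.sum() < 3:
        return np.nan, np.nan, np.nan
    slope = float(np.polyfit(o[mask], d[mask], 1)[0])
    rho, p = stats.spearmanr(o[mask], d[mask])
    return slope, float(rho), float(p)


def doc_analysis(
    table: FeatureTable,
    sample_ids=None,
    lowess_frac: float = 0.3,
    region: float | str = "median",
    n_boot: int = 100,
    seed: int = 0,
) -> DOCResult:
    """Dissimilarity-overlap curve over the given samples.

    Overlap of a pair is the average total relative abundance of the taxa
    present in both; dissimilarity is the root Jensen-Shannon divergence
    (natural log) of the two compositions renormalised over the shared
    taxa.  The slope and Spearman correlation are computed within the
    high-overlap region (pairs above the median overlap by default) and a
    bootstrap over samples gives their confidence band.
    """
    sub = table if sample_ids is None else table.select_samples(sample_ids)
    if sub.n_samples < 10:
        raise ValueError("DOC needs at least 10 samples")
    rel = sub.relative_abundance().to_numpy()
    O, D = _doc_pair_stats(rel)
    n = sub.n_samples
    iu = np.triu_indices(n, 1)
    o, d = O[iu], D[iu]
    valid = ~np.isnan(o)
    if not valid.any():
        raise ValueError("no sample pair shares any taxon")
    ids = np.array(sub.sample_ids)
    pairs = pd.DataFrame(
        {
            "sample_a": ids[iu[0]][valid],
            "sample_b": ids[iu[1]][valid],
            "overlap": o[valid],
            "dissimilarity": d[valid],
        }
    )
    o, d = o[valid], d[valid]
    bound = float(np.median(o)) if region == "median" else float(region)
    slope, rho, rho_p = _region_stats(o, d, bound)
    if np.ptp(o) > 0:
        fit = lowess(d, o, frac=lowess_frac, return_sorted=True)
    else:  # all pairs at the same overlap: nothing to smooth over
        fit = np.column_stack([o, d])
    curve = pd.DataFrame(fit, columns=["overlap", "fitted_dissimilarity"])
    boot = None
    if n_boot:
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n_boot):
            take = rng.integers(0, n, size=n)
            bo, bd = [], []
            for ii in range(n):
                for jj in range(ii + 1, n):
                    a, b = take[ii], take[jj]
                    if a == b or np.isnan(O[a, b]):
                        continue
                    bo.append(O[a, b])
                    bd.append(D[a, b])
            bo, bd = np.asarray(bo), np.asarray(bd)
            if len(bo) < 3:
                continue
            bs, br, _ = _region_stats(bo, bd, float(np.median(bo)))
            rows.append({"slope": bs, "spearman": br})
        boot = pd.DataFrame(rows)
    return DOCResult(
        pairs=pairs,
        curve=curve,
        region_bound=bound,
        slope=slope,
        spearman=rho,
        spearman_p=rho_p,
        bootstrap=boot,
    )


# ---------------------------------------------------------------------------
# CLOUD test
# ---------------------------------------------------------------------------

@dataclass
class CloudResult:
    r: float
    p_value: float
    ref_fraction: float
    k: int
    n_draws: int
    reference_r: pd.Series  # each reference sample scored the same way


def default_k(n_reference: int) -> int:
    """Default neighbourhood size: ceil(5% of the reference), at least 3."""
    return max(3, math.ceil(0.05 * n_reference))


def _cloud_r(arr: np.ndarray, subset: np.ndarray, test_pos: int, k: int) -> float:
    """r for one reference subset draw: test kNN diameter over the mean
    leave-one-out kNN diameter of the subset members."""
    k_test = min(k, len(subset))
    k_mem = min(k, len(subset) - 1)  # a member's own row excludes itself
    test_diam = np.partition(arr[test_pos, subset], k_test - 1)[:k_test].mean()
    block = arr[np.ix_(subset, subset)]
    np.fill_diagonal(block, np.inf)  # exclude self from a member's neighbours
    part = np.partition(block, k_mem - 1, axis=1)[:, :k_mem]
    return float(test_diam / part.mean())


def _cloud_score(
    arr: np.ndarray,
    pool: np.ndarray,
    sample_pos: int,
    ref_fraction: float,
    k: int,
    n_draws: int,
    rng: np.random.Generator,
) -> float:
    """Mean r over random ``ref_fraction`` subsets of ``pool``."""
    size = math.ceil(ref_fraction * len(pool))
    if size >= len(pool):
        return _cloud_r(arr, pool, sample_pos, k)
    rs = [
        _cloud_r(arr, rng.choice(pool, size=size, replace=False), sample_pos, k)
        for _ in range(n_draws)
    ]
    return float(np.mean(rs))


def cloud_reference_scores(
    dm: DistanceMatrix,
    reference_ids,
    ref_fraction: float = 0.15,
    k: int | None = None,
    n_draws: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Score every reference sample leave-one-out with the CLOUD r.

    The result can be passed to :func:`cloud_test` as ``reference_r`` to
    avoid recomputing it for every test sample.
    """
    reference_ids = list(reference_ids)
    if k is None:
        k = default_k(len(reference_ids))
    rng = np.random.default_rng(seed)
    pos = {s: i for i, s in enumerate(dm.ids)}
    arr = np.asarray(dm.data)
    ref_pos = np.array([pos[s] for s in reference_ids])
    out = {}
    for i, s in enumerate(reference_ids):
        pool = np.delete(ref_pos, i)
        out[s] = _cloud_score(arr, pool, ref_pos[i], ref_fraction, k, n_draws, rng)
    return pd.Series(out)


def cloud_test(
    dm: DistanceMatrix,
    reference_ids,
    test_id: str,
    ref_fraction: float = 0.15,
    k: int | None = None,
    n_draws: int = 100,
    seed: int = 0,
    reference_r: pd.Series | None = None,
) -> CloudResult:
    """CLOUD outlier statistic for one test sample.

    Per draw a random ``ref_fraction`` subset of the reference is taken;
    r = (test sample's mean distance to its k nearest subset members) /
    (subset members' average leave-one-out analogue); the reported r is the
    mean over draws.  The empirical p is the +1-corrected fraction of
    reference samples whose own r (scored against the remaining reference)
    is at least the test sample's.
    """
    reference_ids = [s for s in reference_ids if s != test_id]
    n_ref = len(reference_ids)
    if k is None:
        k = default_k(n_ref)
    subset_size = math.ceil(ref_fraction * n_ref)
    if subset_size < k:
        raise ValueError(
            f"ref_fraction {ref_fraction} gives subset size {subset_size} < k={k}"
        )
    rng = np.random.default_rng(seed)
    pos = {s: i for i, s in enumerate(dm.ids)}
    arr = np.asarray(dm.data)
    ref_pos = np.array([pos[s] for s in reference_ids])
    r_test = _cloud_score(
        arr, ref_pos, pos[test_id], ref_fraction, k, n_draws, rng
    )
    if reference_r is None:
        reference_r = cloud_reference_scores(
            dm, reference_ids, ref_fraction, k, n_draws, seed + 1
        )
    p = (1 + int((reference_r >= r_test).sum())) / (1 + n_ref)
    return CloudResult(
        r=r_test,
        p_value=float(p),
        ref_fraction=ref_fraction,
        k=k,
        n_draws=n_draws,
        reference_r=reference_r,
    )


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

@dataclass
class DysbiosisReport:
    median_distance: MedianDistanceResult
    cloud: dict  # (sample, ref_fraction) -> CloudResult
    doc: dict  # group label -> DOCResult
    reference_group: str

    def to_dict(self) -> dict:
        md = self.median_distance
        return {
            "reference_group": self.reference_group,
            "median_distance": {
                "cutoff": md.cutoff,
                "samples": {
                    s: {"median_bc": float(md.statistics[s]), "flag": bool(md.flags[s])}
                    for s in md.statistics.index
                },
            },
            "cloud": {
                f"{s}@{frac}": {
                    "r": c.r,
                    "p_value": c.p_value,
                    "k": c.k,
                    "flag": bool(c.r > 1 and c.p_value < 0.05),
                }
                for (s, frac), c in self.cloud.items()
            },
            "doc": {
                g: {
                    "region_bound": None if r is None else r.region_bound,
                    "slope": None if r is None else r.slope,
                    "spearman": None if r is None else r.spearman,
                }
                for g, r in self.doc.items()
            },
        }


def dysbiosis_report(
    table: FeatureTable,
    metadata: SampleMetadata,
    reference_group: str,
    quantile: float = DEFAULT_QUANTILE,
    ref_fractions=DEFAULT_REF_FRACTIONS,
    k: int | None = None,
    n_draws: int = 100,
    n_boot: int = 0,
    seed: int = 0,
) -> DysbiosisReport:
    """Run all three dysbiosis tests with a shared reference group.

    Bray-Curtis distances are computed once; every non-reference sample is
    scored by the median-distance test and by CLOUD at each reference
    fraction; the DOC is fitted per group (reference-only DOC when there
    are no test samples or too few for a curve).
    """
    from .diversity import beta_matrix

    labels = metadata.labels_for(table.sample_ids)
    reference_ids = [s for s in table.sample_ids if labels[s] == reference_group]
    test_ids = [s for s in table.sample_ids if labels[s] != reference_group]
    if not reference_ids:
        raise ValueError(f"no samples in reference group {reference_group!r}")
    dm = beta_matrix(table, "bray_curtis")
    md = median_distance_test(dm, reference_ids, test_ids, quantile=quantile)
    cloud: dict = {}
    for frac in ref_fractions:
        kk = default_k(len(reference_ids)) if k is None else k
        if math.ceil(frac * len(reference_ids)) < kk:
            continue  # subset smaller than k at this fraction
        ref_r = cloud_reference_scores(
            dm, reference_ids, frac, kk, n_draws, seed + 1
        )
        for s in test_ids:
            cloud[(s, frac)] = cloud_test(
                dm, reference_ids, s, ref_fraction=frac, k=kk,
                n_draws=n_draws, seed=seed, reference_r=ref_r,
            )
    doc: dict = {}
    for group, ids in ((reference_group, reference_ids), ("test", test_ids)):
        if len(ids) >= 10:
            doc[group] = doc_analysis(
                table, ids, n_boot=n_boot, seed=seed
            )
        else:
            doc[group] = None
    return DysbiosisReport(
        median_distance=md, cloud=cloud, doc=doc, reference_group=reference_group
    )
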