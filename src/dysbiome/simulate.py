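"""Synthetic two-group cohorts with the structure the pipeline assumes.

The generators emulate a 16S case/control study: 46 cases + 30 controls,
sparse overdispersed compositions (Dirichlet-multinomial), per-sample read
totals drawn log-normally around a median of ~16,800 reads with some samples
below the 10,000-read rarefaction threshold, planted group-differential
taxa, planted dysbiotic outlier samples, and an optional "universal
dynamics" regime in which samples share one steady-state abundance profile
(the signal the dissimilarity-overlap curve detects).

Every generator is deterministic for a fixed seed and returns a truth
record sufficient to score downstream detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import FeatureTable, SampleMetadata

# Depth law defaults reproduce a median sequencing output of 16,841 reads
# with interquartile range 13,210-23,273: sigma chosen so that
# exp(1.349 * sigma) equals the IQR ratio.
DEPTH_MEDIAN = 16841.0
DEPTH_SIGMA = float(np.log(23273.0 / 13210.0) / (2 * 0.6745))


def _taxon_ids(n: int) -> list[str]:
    return [f"T{i:04d}" for i in range(n)]


def _base_proportions(n_taxa: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal ranked-abundance base composition (heavy-tailed, sparse)."""
    logp = rng.normal(0.0, 1.5, size=n_taxa)
    p = np.exp(logp)
    return p / p.sum()


@dataclass
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    ``planted_taxa`` is a list of ``(taxon_index, log2_fold_change, group)``
    tuples: the taxon's Dirichlet weight is multiplied by ``2**lfc`` in the
    named group.  ``concentration_scale`` is the total Dirichlet
    concentration; small values give the overdispersion and sparsity typical
    of stool profiles.
    """

    n_group1: int = 46
    n_group2: int = 30
    n_taxa: int = 200
    group_labels: tuple[str, str] = ("CD", "HC")
    concentration_scale: float = 50.0
    base_concentration: np.ndarray | None = None
    depth_median: float = DEPTH_MEDIAN
    depth_sigma: float = DEPTH_SIGMA
    planted_taxa: list = field(default_factory=list)
    n_outliers: int = 0
    outlier_strength: float = 10.0
    seed: int = 0


def simulate_cohort(spec: CohortSpec):
    """Draw a cohort: (FeatureTable, SampleMetadata, truth record).

    Per sample the read total is log-normal, the composition is
    Dirichlet(group-modified base concentration) and counts are multinomial,
    so column sums equal the drawn depths exactly.
    """
    if spec.n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(spec.seed)
    taxa = _taxon_ids(spec.n_taxa)
    if spec.base_concentration is not None:
        alpha = np.asarray(spec.base_concentration, dtype=float)
        if alpha.shape != (spec.n_taxa,) or np.any(alpha <= 0):
            raise ValueError("base_concentration must be positive, length n_taxa")
    else:
        alpha = spec.concentration_scale * _base_proportions(spec.n_taxa, rng)

    g1, g2 = spec.group_labels
    group_alpha = {g1: alpha.copy(), g2: alpha.copy()}
    for idx, lfc, group in spec.planted_taxa:
        if not np.isfinite(lfc):
            raise ValueError("fold-changes must be finite")
        group_alpha[group][idx] *= 2.0 ** lfc

    n_total = spec.n_group1 + spec.n_group2
    labels = [g1] * spec.n_group1 + [g2] * spec.n_group2
    sample_ids = [f"S{i:03d}" for i in range(n_total)]
    depths = np.maximum(
        1,
        rng.lognormal(np.log(spec.depth_median), spec.depth_sigma, n_total).astype(
            np.int64
        ),
    )
    counts = np.empty((spec.n_taxa, n_total), dtype=np.int64)
    for j, lab in enumerate(labels):
        comp = rng.dirichlet(group_alpha[lab])
        counts[:, j] = rng.multinomial(depths[j], comp)

    table = FeatureTable(pd.DataFrame(counts, index=taxa, columns=sample_ids))
    metadata = SampleMetadata(pd.Series(labels, index=sample_ids))
    truth = {
        "planted_taxa": [
            {"taxon": taxa[idx], "log2_fold_change": float(lfc), "group": group}
            for idx, lfc, group in spec.planted_taxa
        ],
        "outliers": [],
        "depths": {s: int(d) for s, d in zip(sample_ids, depths)},
        "group_labels": list(spec.group_labels),
        "seed": spec.seed,
    }
    if spec.n_outliers:
        outlier_ids = [sample_ids[i] for i in range(spec.n_outliers)]
        table = plant_dysbiotic_samples(
            table,
            outlier_ids,
            strength=spec.outlier_strength,
            seed=spec.seed + 1,
            concentration=alpha,
        )
        truth["outliers"] = outlier_ids
    return table, metadata, truth


def plant_dysbiotic_samples(
    table: FeatureTable,
    ids,
    strength: float = 10.0,
    seed: int = 0,
    concentration: np.ndarray | None = None,
    permute: bool = True,
) -> FeatureTable:
    """Redraw the listed samples from a perturbed composition, keeping depth.

    The Dirichlet weights are (optionally) permuted across taxa and the
    total concentration divided by ``strength``, so large ``strength`` moves
    the sample far from the cohort's typical profile.  ``strength == 1``
    with permutation disabled is the identity.
    """
    ids = list(ids)
    if not ids or (strength == 1.0 and not permute):
        return table
    missing = [s for s in ids if s not in set(table.sample_ids)]
    if missing:
        raise ValueError(f"unknown sample ids: {missing}")
    rng = np.random.default_rng(seed)
    if concentration is None:
        mean_rel = table.relative_abundance().mean(axis=1).to_numpy()
        mean_rel = np.maximum(mean_rel, 1e-12)
        concentration = 50.0 * mean_rel / mean_rel.sum()
    concentration = np.asarray(concentration, dtype=float)
    counts = table.counts.copy()
    totals = table.sample_totals()
    for s in ids:
        weights = rng.permutation(concentration) if permute else concentration.copy()
        comp = rng.dirichlet(weights / strength)
        counts[s] = rng.multinomial(int(totals[s]), comp)
    return table.with_counts(counts)


def simulate_tree(n_taxa: int, seed: int = 0) -> TreeNode:
    """Random bifurcating rooted tree with Exp(1) branch lengths.

    Leaves are named to match :func:`simulate_cohort` taxon ids.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in _taxon_ids(n_taxa):
        tip = TreeNode(name=name)
        tip.length = float(rng.exponential(1.0))
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(1.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def simulate_universal_dynamics(
    n_samples: int = 50,
    n_taxa: int = 100,
    presence_gradient: tuple[float, float] = (0.5, 0.95),
    noise_sd: float = 0.3,
    seed: int = 0,
    universal: bool = True,
    depth: int = 10_000,
) -> FeatureTable:
    """Cohort obeying (or violating) universal microbial dynamics.

    With ``universal=True`` all samples share one steady-state abundance
    vector.  Each sample has a disturbance level u ~ Uniform(0,1): it
    carries a taxon subset whose size runs along ``presence_gradient``
    (less disturbed samples carry more taxa; abundant taxa are more likely
    to be retained) and multiplicative log-normal noise around the steady
    state whose scale grows with u (base scale ``noise_sd``).  Disturbance
    thus lowers carriage and perturbs abundances together — the mechanism
    behind the negative dissimilarity-overlap slope at high overlap.  With
    ``universal=False`` every sample draws an independent abundance vector
    and the curve is flat.
    """
    rng = np.random.default_rng(seed)
    taxa = _taxon_ids(n_taxa)
    shared = np.exp(rng.normal(0.0, 1.5, size=n_taxa))
    lo, hi = presence_gradient
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        steady = (
            shared if universal else np.exp(rng.normal(0.0, 1.5, size=n_taxa))
        )
        u = rng.uniform()  # disturbance: 0 = at steady state, 1 = far from it
        frac = hi - (hi - lo) * u
        k = max(2, int(round(frac * n_taxa)))
        keep_p = steady / steady.sum()
        keep = rng.choice(n_taxa, size=k, replace=False, p=keep_p)
        x = np.zeros(n_taxa)
        scale = noise_sd * (1.0 + 3.0 * u)
        noise = rng.normal(0.0, scale, size=k) if noise_sd > 0 else 0.0
        x[keep] = steady[keep] * np.exp(noise)
        x /= x.sum()
        counts[:, j] = np.round(x * depth).astype(np.int64)
    sample_ids = [f"U{i:03d}" for i in range(n_samples)]
    return FeatureTable(pd.DataFrame(counts, index=taxa, columns=sample_ids))


def simulate_pathway_table(
    n_pathways: int = 200,
    n_per_group: tuple[int, int] = (20, 20),
    planted_effects: list | None = None,
    seed: int = 0,
    within_sd: float = 0.5,
    depth: int = 200_000,
    group_labels: tuple[str, str] = ("CD", "HC"),
):
    """Log-normal pathway abundances with multinomial sampling.

    ``planted_effects`` lists ``(pathway_index, shift_in_sd_units, group)``:
    the pathway's log abundance is raised by ``shift * within_sd`` in the
    named group, i.e. a CLR-scale shift expressed in within-group standard
    deviations.  Returns (counts DataFrame, SampleMetadata, truth record).
    """
    planted_effects = planted_effects or []
    rng = np.random.default_rng(seed)
    g1, g2 = group_labels
    n1, n2 = n_per_group
    pathways = [f"PWY-{i:04d}" for i in range(n_pathways)]
    sample_ids = [f"P{i:03d}" for i in range(n1 + n2)]
    labels = [g1] * n1 + [g2] * n2
    base_log = rng.normal(8.0, 1.0, size=n_pathways)
    shift = {g1: np.zeros(n_pathways), g2: np.zeros(n_pathways)}
    for idx, sd_units, group in planted_effects:
        shift[group][idx] += sd_units * within_sd
    counts = np.empty((n_pathways, n1 + n2), dtype=np.int64)
    for j, lab in enumerate(labels):
        log_ab = base_log + shift[lab] + rng.normal(0.0, within_sd, n_pathways)
        p = np.exp(log_ab - log_ab.max())
        counts[:, j] = rng.multinomial(depth, p / p.sum())
    df = pd.DataFrame(counts, index=pathways, columns=sample_ids)
    metadata = SampleMetadata(pd.Series(labels, index=sample_ids))
    truth = {
        "planted_effects": [
            {"pathway": pathways[idx], "shift_sd": float(s), "group": grp}
            for idx, s, grp in planted_effects
        ],
        "within_sd": within_sd,
        "group_labels": list(group_labels),
        "seed": seed,
    }
    return df, metadata, truth
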