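"""Feature-table cleaning and rarefaction.

Order of operations in the pipeline is fixed: contaminant removal
(mitochondrial/chloroplast lineages), then ultra-rare taxon removal
(prevalence < 5 samples or total < 20 counts), then rarefaction to a
common depth of 10,000 reads with exclusion of shallower samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatureTable

logger = logging.getLogger("dysbiome")

DEFAULT_CONTAMINANT_PATTERNS = ("mitochondri", "chloroplast")
DEFAULT_MIN_SAMPLES = 5
DEFAULT_MIN_TOTAL = 20
DEFAULT_RAREFACTION_DEPTH = 10_000


@dataclass
class FilterReport:
    """What a cleaning step removed and why."""

    contaminants: list = field(default_factory=list)
    ultra_rare: list = field(default_factory=list)
    excluded_samples: dict = field(default_factory=dict)
    depth: int | None = None

    def to_dict(self) -> dict:
        return {
            "contaminants": list(self.contaminants),
            "ultra_rare": list(self.ultra_rare),
            "excluded_samples": {k: int(v) for k, v in self.excluded_samples.items()},
            "depth": self.depth,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def remove_contaminants(
    table: FeatureTable, patterns=DEFAULT_CONTAMINANT_PATTERNS
) -> tuple[FeatureTable, FilterReport]:
    """Drop taxa whose lineage contains any pattern (case-insensitive)."""
    pats = [p.lower() for p in patterns]
    lower = table.lineages.str.lower()
    hit = lower.apply(lambda s: any(p in s for p in pats))
    removed = list(table.lineages.index[hit])
    if len(removed) == table.n_taxa:
        raise ValueError("contaminant patterns matched every taxon")
    kept = [t for t in table.taxon_ids if t not in set(removed)]
    return table.select_taxa(kept), FilterReport(contaminants=removed)


def remove_ultra_rare(
    table: FeatureTable,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_total: int = DEFAULT_MIN_TOTAL,
    rule: str = "or",
) -> tuple[FeatureTable, FilterReport]:
    """Drop ultra-rare taxa.

    A taxon is removed when its prevalence (samples with count > 0) is
    below ``min_samples`` or its total count across samples is below
    ``min_total`` — both thresholds strict ("less than").  ``rule='and'``
    requires both conditions instead of either.
    """
    prevalence = (table.counts > 0).sum(axis=1)
    totals = table.counts.sum(axis=1)
    low_prev = prevalence < min_samples
    low_total = totals < min_total
    if rule == "or":
        drop = low_prev | low_total
    elif rule == "and":
        drop = low_prev & low_total
    else:
        raise ValueError(f"rule must be 'or' or 'and', got {rule!r}")
    removed = list(table.counts.index[drop])
    kept = [t for t in table.taxon_ids if t not in set(removed)]
    if not kept:
        logger.warning("ultra-rare filter removed every taxon")
    out = table.select_taxa(kept) if kept else FeatureTable(
        table.counts.iloc[:0], table.lineages.iloc[:0]
    )
    return out, FilterReport(ultra_rare=removed)


def rarefy(
    table: FeatureTable,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int = 0,
) -> tuple[FeatureTable, FilterReport]:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer total reads than ``depth`` are excluded and listed
    in the report.  Subsampling is multivariate hypergeometric, so per-taxon
    expectations are ``depth * count / total``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.sample_totals()
    excluded = {s: int(t) for s, t in totals.items() if t < depth}
    kept = [s for s in table.sample_ids if s not in excluded]
    if not kept:
        raise ValueError(f"all samples below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    sub = table.select_samples(kept)
    counts = sub.counts.to_numpy()
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    rare = sub.with_counts(
        pd.DataFrame(out, index=sub.counts.index, columns=sub.counts.columns)
    )
    return rare, FilterReport(excluded_samples=excluded, depth=depth)


def rarefaction_curve(
    table: FeatureTable,
    depths,
    replicates: int = 10,
    metric: str = "observed_features",
    seed: int = 0,
    tree=None,
) -> pd.DataFrame:
    """Mean alpha-diversity vs depth per sample (depths above a sample's
    total yield NaN for that sample)."""
    from .diversity import alpha_diversity

    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    rows = {}
    for depth in depths:
        vals = pd.Series(0.0, index=table.counts.columns)
        valid = totals >= depth
        acc = np.zeros(table.n_samples)
        for _ in range(replicates):
            counts = table.counts.to_numpy()
            sub = counts.copy()
            for j, s in enumerate(table.sample_ids):
                if valid[s]:
                    sub[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
            sub_table = table.with_counts(
                pd.DataFrame(sub, index=table.counts.index, columns=table.counts.columns)
            )
            acc += alpha_diversity(sub_table, metric, tree=tree).to_numpy()
        vals[:] = acc / replicates
        vals[~valid] = np.nan
        rows[depth] = vals
    curve = pd.DataFrame(rows)
    curve.columns.name = "depth"
    return curve
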