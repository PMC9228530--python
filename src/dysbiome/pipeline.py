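"""End-to-end orchestration: filter -> rarefy -> diversity -> selection ->
effects -> dysbiosis, with every intermediate written in the documented
TSV/Newick/JSON formats so any stage can be re-run on its own.

A single global seed derives per-stage seeds by fixed offsets, so one knob
reproduces the whole run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import diffabund, diversity, dysbiosis, effects, filtering
from .core import (
    FeatureTable,
    SampleMetadata,
    read_feature_table,
    read_metadata,
    read_tree,
    write_distance_matrix,
    write_feature_table,
)

logger = logging.getLogger("dysbiome")

REPORT_SCHEMA_VERSION = 1

# fixed per-stage seed offsets off the global seed
SEED_OFFSETS = {
    "rarefy": 1,
    "permanova": 2,
    "ancom": 3,
    "clr_lasso": 4,
    "coda_lasso": 5,
    "selbal": 6,
    "effects": 7,
    "dysbiosis": 8,
    "simulate": 9,
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (file inputs or a synthetic cohort)."""

    output_dir: str = "dysbiome_out"
    table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    pathway_table: str | None = None
    synthetic: dict | None = None  # kwargs for simulate.CohortSpec
    rarefaction_depth: int = filtering.DEFAULT_RAREFACTION_DEPTH
    permutations: int = 999
    max_taxa: int = diffabund.DEFAULT_MAX_TAXA
    reference_group: str | None = None
    quantile: float = dysbiosis.DEFAULT_QUANTILE
    ref_fractions: tuple = dysbiosis.DEFAULT_REF_FRACTIONS
    n_mc: int = effects.DEFAULT_N_MC
    seed: int = 0
    beta_metrics: tuple = diversity.BETA_METRICS
    alpha_metrics: tuple = diversity.ALPHA_METRICS

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        has_files = self.table is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError("config needs exactly one of {table, synthetic}")
        if has_files and self.metadata is None:
            raise ValueError("file input requires metadata")
        needs_tree = any("unifrac" in m for m in self.beta_metrics) or (
            "faith_pd" in self.alpha_metrics
        )
        if has_files and needs_tree and self.tree is None:
            raise ValueError(
                "tree required for UniFrac/Faith PD; drop those metrics or "
                "provide a tree"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed,
        "stage_seeds": {k: seed + v for k, v in SEED_OFFSETS.items()},
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
                report["stages"][name] = {"status": "ok"}
                logger.info("stage %s ok (%.2fs)", name, time.perf_counter() - t0)
                return result
            except Exception as exc:  # noqa: BLE001 - report and skip dependents
                logger.error("stage %s failed: %s", name, exc)
                report["stages"][name] = {"status": "failed", "error": str(exc)}
                return None
        return deco

    # ---- inputs -----------------------------------------------------------
    if config.synthetic is not None:
        from .simulate import CohortSpec, simulate_cohort, simulate_tree

        spec_kwargs = dict(config.synthetic)
        spec_kwargs.setdefault("seed", seed + SEED_OFFSETS["simulate"])
        spec = CohortSpec(**spec_kwargs)
        table, metadata, truth = simulate_cohort(spec)
        tree = simulate_tree(spec.n_taxa, seed=spec.seed)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
        from .core import write_metadata, write_tree

        write_feature_table(table, out / "table.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        write_tree(tree, out / "tree.nwk")
        pathway_df = None
    else:
        table = read_feature_table(config.table)
        metadata = read_metadata(config.metadata)
        tree = read_tree(config.tree) if config.tree else None
        pathway_df = None
        if config.pathway_table:
            import pandas as pd

            pathway_df = pd.read_csv(config.pathway_table, sep="\t", index_col=0)

    # ---- filtering + rarefaction -----------------------------------------
    def _filter():
        t, rep1 = filtering.remove_contaminants(table)
        t, rep2 = filtering.remove_ultra_rare(t)
        report["filter"] = {**rep1.to_dict(), **{"ultra_rare": rep2.ultra_rare}}
        write_feature_table(t, out / "filtered.tsv")
        return t

    filtered = stage("filter")(_filter)
    if filtered is None:
        return _finish(report, out)

    def _rarefy():
        t, rep = filtering.rarefy(
            filtered, config.rarefaction_depth, seed=seed + SEED_OFFSETS["rarefy"]
        )
        report["rarefaction"] = rep.to_dict()
        write_feature_table(t, out / "rarefied.tsv")
        return t

    rarefied = stage("rarefy")(_rarefy)

    # ---- diversity --------------------------------------------------------
    if rarefied is not None:
        def _alpha():
            alphas = {
                m: diversity.alpha_diversity(rarefied, m, tree=tree)
                for m in config.alpha_metrics
            }
            tests = diversity.kruskal_wallis_alpha(alphas, metadata)
            import pandas as pd

            pd.DataFrame(alphas).to_csv(out / "alpha.tsv", sep="\t")
            report["alpha_tests"] = [t.to_dict() for t in tests]
            return alphas

        stage("alpha")(_alpha)

        def _beta():
            dms = {
                m: diversity.beta_matrix(rarefied, m, tree=tree)
                for m in config.beta_metrics
            }
            for m, dm in dms.items():
                write_distance_matrix(dm, out / f"beta_{m}.tsv")
            tests = diversity.permanova_family(
                dms,
                metadata,
                permutations=config.permutations,
                seed=seed + SEED_OFFSETS["permanova"],
            )
            report["beta_tests"] = [t.to_dict() for t in tests]
            ord_res = diversity.pcoa(dms[config.beta_metrics[0]])
            ord_res.samples.iloc[:, :3].to_csv(out / "pcoa.tsv", sep="\t")
            return dms

        stage("beta")(_beta)

    # ---- differential abundance (on the filtered, unrarefied table) -------
    def _diffabund():
        a = diffabund.ancom(filtered, metadata)
        sels = [
            diffabund.clr_lasso(
                filtered, metadata, max_taxa=config.max_taxa,
                seed=seed + SEED_OFFSETS["clr_lasso"],
            ),
            diffabund.coda_lasso(
                filtered, metadata, max_taxa=config.max_taxa,
                seed=seed + SEED_OFFSETS["coda_lasso"],
            ),
            diffabund.selbal(
                filtered, metadata, max_taxa=config.max_taxa,
                seed=seed + SEED_OFFSETS["selbal"],
            ),
        ]
        cons = diffabund.consensus(a, sels, lineages=filtered.lineages)
        a.w.to_csv(out / "ancom_w.tsv", sep="\t")
        report["ancom"] = {
            "threshold": a.threshold,
            "detected": a.detected_taxa(),
            "max_w": int(a.w.max()),
        }
        report["selection"] = {
            s.method: {"selected": list(s.selected), "score": s.score} for s in sels
        }
        report["consensus"] = {
            d: info for d, info in cons.by_group.items()
        }
        return cons

    stage("diffabund")(_diffabund)

    # ---- pathway effects ---------------------------------------------------
    if pathway_df is not None:
        def _effects():
            eff = effects.aldex_effect(
                pathway_df, metadata, n_mc=config.n_mc,
                seed=seed + SEED_OFFSETS["effects"],
            )
            eff.table.to_csv(out / "effects.tsv", sep="\t")
            ladder = effects.threshold_report(eff)
            report["effects"] = {
                str(cut): sub.index.tolist() for cut, sub in ladder.items()
            }
            return eff

        stage("effects")(_effects)

    # ---- dysbiosis ---------------------------------------------------------
    if rarefied is not None:
        def _dysbiosis():
            ref_group = config.reference_group or metadata.levels()[-1]
            rep = dysbiosis.dysbiosis_report(
                rarefied,
                metadata,
                ref_group,
                quantile=config.quantile,
                ref_fractions=tuple(config.ref_fractions),
                seed=seed + SEED_OFFSETS["dysbiosis"],
            )
            report["dysbiosis"] = rep.to_dict()
            return rep

        stage("dysbiosis")(_dysbiosis)

    return _finish(report, out)


def _finish(report: dict, out: Path) -> dict:
    report["failed"] = any(
        s.get("status") == "failed" for s in report["stages"].values()
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
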