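"""Orchestrate the full analysis as a reproducible run with provenance.

A run is described by a :class:`RunConfig` (YAML/JSON, schema-validated,
unknown keys rejected). ``run_all`` freezes the config into a manifest
before any stage executes, then runs align → preprocess → diversity →
compare → mediate, writing every intermediate to the output directory.
Result files contain no timestamps, so a rerun with the same config and
seed is byte-identical; timestamps live only in the log.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__
from .cohort_stats import comparison_table, taxon_volcano
from .containers import FormatError, SampleMetadata
from .diversity import alpha_diversity, canberra, permanova, unifrac
from .io import (align_samples, read_feature_table, read_metadata, read_tree,
                 write_feature_table, write_json, write_metadata)
from .mediation import MediationConfig, run_mediation
from .preprocess import build_mediators

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "load_config"]


class RunConfig(BaseModel):
    """Validated configuration for an end-to-end run."""

    model_config = ConfigDict(extra="forbid")

    feature_table: str
    metadata: str
    tree: str | None = None
    unit: str = "counts"
    rank: str | None = "genus"
    prevalence: float = 0.10
    pseudocount: float | str = "auto"
    confounders: list[str] = ["age", "sex"]
    penalty: float | str = "cv"
    folds: int = 10
    n_perm: int = 999
    seed: int
    outdir: str = "results"

    @field_validator("pseudocount", "penalty", mode="before")
    @classmethod
    def _numeric_or_keyword(cls, v):
        if isinstance(v, str) and v not in ("auto", "cv"):
            try:
                return float(v)
            except ValueError:
                raise ValueError(f"expected a number or keyword, got {v!r}")
        return v


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig(**data)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns a dict of written artifact paths.

    The manifest (input checksums, package version, full config) is the
    first file written. Diversity and differential abundance compare
    underweight vs non-underweight within the exposed group, mirroring
    the case-cohort design; the demographic comparison and the
    mediation analysis use the whole cohort.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("gutmediate").addHandler(fh)
    artifacts: dict[str, str] = {}

    manifest = {
        "gutmediate_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "inputs": {k: {"path": p, "sha256": _sha256(p)}
                   for k, p in (("feature_table", config.feature_table),
                                ("metadata", config.metadata),
                                ("tree", config.tree)) if p},
    }
    write_json(manifest, out / "manifest.json")
    artifacts["manifest"] = str(out / "manifest.json")

    try:
        # --- align ---------------------------------------------------
        table = read_feature_table(config.feature_table, unit_hint=config.unit)
        meta = read_metadata(config.metadata)
        table, meta = align_samples(table, meta)
        log.info("stage=align samples=%d taxa=%d", table.n_samples, table.n_taxa)

        # --- preprocess ----------------------------------------------
        rank = config.rank if (table.lineages is not None and config.rank) else None
        mediators = build_mediators(table, rank=rank, prevalence=config.prevalence,
                                    pseudocount=config.pseudocount)
        write_json(mediators.provenance, out / "preprocess_provenance.json")
        artifacts["preprocess_provenance"] = str(out / "preprocess_provenance.json")
        log.info("stage=preprocess mediators=%d", len(mediators.mediator_ids))

        # working-rank relative-abundance table for beta diversity / volcano
        from .preprocess import aggregate_taxa, prevalence_filter, to_relative_abundance
        work = aggregate_taxa(table, rank) if rank else table
        work_ra = to_relative_abundance(work) if work.unit == "counts" else work
        work_ra = prevalence_filter(work_ra, config.prevalence)

        # --- diversity (underweight vs not, within exposed) ----------
        exposed = meta.data.index[meta.data["exposure"] == 1]
        uw = meta.data.loc[exposed, "underweight"].dropna()
        div_samples = list(uw.index)
        results_div: dict = {"group": "underweight within exposed",
                             "n": len(div_samples), "seed": config.seed}
        if uw.nunique() == 2 and uw.value_counts().min() >= 2:
            alpha = alpha_diversity(table.select_samples(div_samples), groups=uw)
            alpha.values.to_csv(out / "alpha_diversity.tsv", sep="\t")
            artifacts["alpha_diversity"] = str(out / "alpha_diversity.tsv")
            results_div["alpha_anova_p"] = alpha.anova_p
            dm = canberra(work_ra.select_samples(div_samples))
            dm.to_data_frame().to_csv(out / "distance_canberra.tsv", sep="\t")
            artifacts["distance_canberra"] = str(out / "distance_canberra.tsv")
            pr = permanova(dm, uw, n_perm=config.n_perm, seed=config.seed)
            results_div["permanova"] = {"canberra": {
                "pseudo_F": pr.statistic, "p": pr.p_value, "n_perm": pr.n_permutations}}
            if config.tree:
                tree = read_tree(config.tree)
                for weighted, name in ((False, "unweighted_unifrac"), (True, "weighted_unifrac")):
                    dmu = unifrac(work_ra.select_samples(div_samples), tree, weighted=weighted)
                    pru = permanova(dmu, uw, n_perm=config.n_perm, seed=config.seed)
                    results_div["permanova"][name] = {
                        "pseudo_F": pru.statistic, "p": pru.p_value,
                        "n_perm": pru.n_permutations}
        else:
            results_div["skipped"] = "need both outcome classes (>=2 samples each) among exposed"
        write_json(results_div, out / "diversity.json")
        artifacts["diversity"] = str(out / "diversity.json")
        log.info("stage=diversity done")

        # --- compare -------------------------------------------------
        demo_vars = [c for c in meta.data.columns if c not in ("exposure",)]
        comp = comparison_table(meta.data, "exposure", demo_vars)
        comp.to_csv(out / "comparison.tsv", sep="\t", index=False)
        artifacts["comparison"] = str(out / "comparison.tsv")
        if uw.nunique() == 2:
            volcano = taxon_volcano(work_ra.select_samples(div_samples), uw)
            volcano.to_csv(out / "volcano.tsv", sep="\t")
            artifacts["volcano"] = str(out / "volcano.tsv")
        log.info("stage=compare done")

        # --- mediate -------------------------------------------------
        mcfg = MediationConfig(rank=rank, prevalence=config.prevalence,
                               pseudocount=config.pseudocount,
                               confounders=tuple(config.confounders),
                               penalty=config.penalty, folds=config.folds,
                               seed=config.seed)
        med = run_mediation(table, meta, mcfg)
        frame = med.to_frame()
        tag = rank or "input_rank"
        frame.to_csv(out / f"mediation_{tag}.tsv", sep="\t", index=False)
        artifacts[f"mediation_{tag}"] = str(out / f"mediation_{tag}.tsv")
        write_json({
            "te_unadjusted": med.te_unadjusted,
            "te_unadjusted_ci": list(med.te_unadjusted_ci),
            "te_adjusted": med.te, "te_adjusted_ci": list(med.te_ci),
            "all_row": {"DE": med.all_row.de, "IE": med.all_row.ie,
                        "PM_percent": 100 * med.all_row.pm},
            "skipped": med.skipped, "provenance": med.provenance,
        }, out / f"mediation_{tag}.json")
        artifacts[f"mediation_{tag}_json"] = str(out / f"mediation_{tag}.json")
        log.info("stage=mediate done (n=%d, mediators=%d)",
                 med.provenance["n_samples"], med.provenance["n_mediators"])
    except Exception:
        log.exception("pipeline stage failed; see %s", out / "run.log")
        raise
    finally:
        logging.getLogger("gutmediate").removeHandler(fh)
        fh.close()

    write_json(artifacts, out / "artifacts.json")
    return artifacts
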