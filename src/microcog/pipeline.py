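"""End-to-end pipeline runner.

Drives the full analysis from a YAML/dict configuration: read tables,
select discriminant features at baseline, build the three balance indices,
evaluate them longitudinally and against outcomes, optionally screen
pathways and run set enrichment. Every threshold used is echoed to the run
log; results land as TSV/JSON in the output directory and the run is
deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as io_core
from .containers import TIMEPOINTS, OUTCOME_COLS
from .selection import (
    lefse,
    pathway_screen,
    fit_splsda,
    splsda_wilcoxon_filter,
    pca_pc1_select,
    hca,
    log_autoscale,
)
from .balance import (
    build_microbial_index,
    build_metabolome_index,
    build_combined_index,
    index_values,
    UndefinedIndexError,
)
from .associate import (
    longitudinal_index_comparison,
    spearman_bh,
    correlation_network,
    delta_correlation,
    bray_curtis_permanova,
    ora_enrich,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run."""

    species: dict[str, str] = field(default_factory=dict)      # timepoint -> path
    metabolites: dict[str, str] = field(default_factory=dict)  # timepoint -> path
    pathways: dict[str, str] = field(default_factory=dict)     # timepoint -> path
    metadata: str | None = None
    gmt: str | None = None
    outdir: str = "results"

    alpha: float = 0.05
    lda_threshold: float = 2.0
    n_boot: int = 30
    n_components: int = 2
    keep_x: int = 100
    pc1_upper: float = 0.15
    pc1_lower: float = -0.10
    pathway_mean_threshold: float = 0.01
    network_cutoff: float = 0.6
    n_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _log_thresholds(config: PipelineConfig) -> None:
    for key, val in asdict(config).items():
        if key not in ("species", "metabolites", "pathways", "metadata",
                       "gmt", "outdir"):
            logger.info("threshold %s = %r", key, val)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the configured inputs allow; return the result paths.

    With no metabolite tables configured, only the microbiome stages run and
    the metabolome/combined indices are marked absent in the summary.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("microcog")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {"outdir": str(out)}
    try:
        _log_thresholds(config)
        _run_stages(config, out, results)
    except Exception as exc:
        stage = results.get("_stage", "setup")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return results


def _run_stages(config: PipelineConfig, out: Path, results: dict) -> None:
    results["_stage"] = "read"
    species = {
        tp: io_core.read_feature_table(path, kind="taxon")
        for tp, path in config.species.items()
    }
    metabolites = {
        tp: io_core.read_feature_table(path, kind="metabolite")
        for tp, path in config.metabolites.items()
    }
    if config.metadata is None:
        raise ValueError("metadata path is required")
    metadata = io_core.read_metadata(config.metadata)
    if "bsl" not in species:
        raise ValueError("baseline species table is required")

    bsl_samples = species["bsl"].sample_ids
    groups = metadata.groups_for(bsl_samples).to_numpy()

    # --- discriminant stage
    results["_stage"] = "discriminant"
    taxa_set = lefse(species["bsl"], groups, alpha=config.alpha,
                     lda_threshold=config.lda_threshold,
                     n_boot=config.n_boot, seed=config.seed)
    taxa_set.frame.to_csv(out / "discriminant_taxa.tsv", sep="\t")
    logger.info("lefse retained %d taxa", len(taxa_set))

    if "bsl" in config.pathways:
        pw_table = io_core.read_feature_table(config.pathways["bsl"],
                                              kind="pathway")
        pw_set = pathway_screen(pw_table, groups,
                                mean_threshold=config.pathway_mean_threshold,
                                alpha=config.alpha)
        pw_set.frame.to_csv(out / "discriminant_pathways.tsv", sep="\t")
        logger.info("pathway screen retained %d pathways", len(pw_set))

    have_metabolome = "bsl" in metabolites
    if have_metabolome:
        model = fit_splsda(metabolites["bsl"], groups,
                           n_components=config.n_components,
                           keep_x=config.keep_x, seed=config.seed)
        met_set = splsda_wilcoxon_filter(model, metabolites["bsl"], groups,
                                         alpha=config.alpha)
        met_set.frame.to_csv(out / "discriminant_metabolites.tsv", sep="\t")
        io_core.write_json(out / "splsda_model.json", {
            "kept_features": model.kept_features_,
            "classes": [str(c) for c in model.classes_],
        })
        logger.info("splsda+wilcoxon retained %d metabolites", len(met_set))
        if len(met_set) >= 2:
            disc_vals = metabolites["bsl"].values[met_set.features()]
            scaled = log_autoscale(disc_vals)
            _, order = hca(scaled)
            heat = scaled.loc[order]
            heat.index.name = "sample_id"
            heat.to_csv(out / "heatmap_matrix.tsv", sep="\t")

    # --- index stage
    results["_stage"] = "indices"
    definitions = {}
    try:
        definitions["microbial"] = build_microbial_index(
            species["bsl"], groups, alpha=config.alpha)
    except UndefinedIndexError as exc:
        logger.warning("microbial index undefined: %s", exc)
    if have_metabolome and len(met_set) >= 2:
        try:
            pc1 = pca_pc1_select(
                metabolites["bsl"].values[met_set.features()], groups,
                upper=config.pc1_upper, lower=config.pc1_lower)
            definitions["metabolome"] = build_metabolome_index(pc1)
        except (UndefinedIndexError, ValueError) as exc:
            logger.warning("metabolome index undefined: %s", exc)
    if "microbial" in definitions and "metabolome" in definitions:
        definitions["combined"] = build_combined_index(
            definitions["microbial"], definitions["metabolome"])
    results["indices_defined"] = sorted(definitions)
    results["indices_absent"] = sorted(
        {"microbial", "metabolome", "combined"} - set(definitions))
    io_core.write_json(out / "index_definitions.json",
                       {k: d.to_dict() for k, d in definitions.items()})

    all_values = []
    for tp in TIMEPOINTS:
        if tp not in species:
            continue
        tables = {"taxon": species[tp]}
        if tp in metabolites:
            tables["metabolite"] = metabolites[tp]
        cols = {}
        for name, definition in definitions.items():
            needed = set(definition.kinds.values())
            if needed <= set(tables):
                cols[name] = index_values(tables, definition)
        if cols:
            all_values.append(pd.DataFrame(cols))
    values_frame = pd.concat(all_values) if all_values else pd.DataFrame()
    values_frame.index.name = "sample_id"
    values_frame.to_csv(out / "index_values.tsv", sep="\t")

    # --- longitudinal + association stage
    results["_stage"] = "associate"
    if not values_frame.empty:
        comparison = longitudinal_index_comparison(values_frame, metadata)
        comparison.to_csv(out / "longitudinal_comparison.tsv", sep="\t",
                          index=False)
        assoc_frames = []
        meta = metadata.frame
        for tp in TIMEPOINTS:
            tp_samples = [s for s in values_frame.index
                          if meta.loc[s, "timepoint"] == tp]
            if not tp_samples:
                continue
            outcomes = meta.loc[tp_samples, ["npz6", *OUTCOME_COLS]]
            assoc_frames.append(
                spearman_bh(values_frame.loc[tp_samples], outcomes,
                            family=f"indices-x-outcomes@{tp}")
                .assign(timepoint=tp)
            )
        assoc = pd.concat(assoc_frames, ignore_index=True)
        assoc.to_csv(out / "index_outcome_associations.tsv", sep="\t",
                     index=False)
        edges = correlation_network(assoc, cutoff=config.network_cutoff)
        edges.to_csv(out / "correlation_edges.tsv", sep="\t", index=False)

        bsl_meta = meta[meta["timepoint"] == "bsl"].set_index("participant")
        fin_meta = meta[meta["timepoint"] == "final"].set_index("participant")
        if not fin_meta.empty:
            delta = (fin_meta["npz6"] - bsl_meta["npz6"]).dropna()
            fin_ids = meta.index[meta["timepoint"] == "final"]
            fin_vals = values_frame.loc[values_frame.index.intersection(fin_ids)]
            fin_vals = fin_vals.set_axis(
                meta.loc[fin_vals.index, "participant"], axis=0)
            delta_correlation(fin_vals, delta).to_csv(
                out / "delta_npz6_correlation.tsv", sep="\t", index=False)

    results["_stage"] = "permanova"
    perm = bray_curtis_permanova(species["bsl"], groups,
                                 n_perm=config.n_permutations,
                                 seed=config.seed)
    io_core.write_json(out / "permanova.json", {
        "pseudo_f": perm.pseudo_f, "r2": perm.r2,
        "p_value": perm.p_value, "n_permutations": perm.n_permutations,
    })

    if config.gmt and have_metabolome:
        results["_stage"] = "enrich"
        library = io_core.read_gmt(config.gmt)
        universe = metabolites["bsl"].feature_ids
        query = met_set.features("Lower")
        if query:
            enrichment = ora_enrich(query, library, universe)
            enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    results.pop("_stage", None)
    results["files"] = sorted(p.name for p in out.iterdir())
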