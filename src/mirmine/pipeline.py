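"""End-to-end workflow orchestration.

Each stage is a function that reads and writes TSV/JSON files, so composing
the stages by hand (or through the CLI subcommands) reproduces ``run_pipeline``
byte for byte.  Every data-dependent threshold the run realises (filter
cutoffs, selection quantiles, prediction score cutoffs) is persisted in the
manifest: on real panels these numbers are the reproducibility record.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import panel, putative, separation, simulate, targets
from .association import MiEstimatorParams, pairwise_associations

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, cause: BaseException, manifest: dict):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    """Declarative run description (YAML or JSON file, or a plain dict).

    Either a ``simulate`` block (SimulationConfig fields) or an ``inputs``
    block of file paths (mir, mrna, targetscan, diana, validated, go, labels,
    probe_gene_map, family_mir_map) must be present.
    """

    seed: int = 0
    outdir: str = "mirmine_out"
    simulate: dict | None = None
    inputs: dict | None = None
    preprocess: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    predictions: dict = field(default_factory=dict)
    go: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs a 'simulate' or an 'inputs' block")
        for key, block in (("selection", self.selection),
                           ("predictions", self.predictions)):
            for name, v in block.items():
                if name.endswith(("pct", "percentile")) and not 0 < v <= 100:
                    raise ValueError(f"{key}.{name} must be in (0, 100]")
        # Missing input files surface inside the stage that consumes them,
        # so the pipeline error names the failing stage.

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


# ---------------------------------------------------------------- stages


def stage_simulate(sim_config: simulate.SimulationConfig, outdir: Path) -> dict:
    return simulate.write_simulation(sim_config, outdir)


def stage_preprocess(mir_path: str, mrna_path: str, params: dict,
                     outdir: Path) -> dict:
    """Optional quantile-normalisation / log2, then abundance+range filtering."""
    outdir.mkdir(parents=True, exist_ok=True)
    mir_m = panel.read_expression(mir_path, "miR")
    mrna_m = panel.read_expression(mrna_path, "mRNA-probe")
    if params.get("quantile_normalize_mrna", False):
        mrna_m = panel.quantile_normalize(mrna_m)
    log2_offset = params.get("log2_offset")
    if log2_offset is not None:
        mir_m = panel.log2_transform(mir_m, offset=log2_offset)
        mrna_m = panel.log2_transform(mrna_m, offset=log2_offset)

    common = dict(
        abundance_percentile=params.get("abundance_percentile", 10.0),
        min_count_above=params.get("min_count_above"),
    )
    mir_f, mir_rep = panel.filter_features(
        mir_m, range_rule=params.get("mir_range_rule", "value_percentile"),
        range_percentile=params.get("mir_range_percentile", 90.0), **common)
    mrna_f, mrna_rep = panel.filter_features(
        mrna_m, range_rule="fraction_of_total",
        range_fraction=params.get("mrna_range_fraction", 0.10), **common)

    paths = {"mir_filtered": outdir / "mir_filtered.tsv",
             "mrna_filtered": outdir / "mrna_filtered.tsv"}
    mir_f.write_tsv(paths["mir_filtered"])
    mrna_f.write_tsv(paths["mrna_filtered"])
    mir_rep.to_json(outdir / "mir_filter_report.json")
    mrna_rep.to_json(outdir / "mrna_filter_report.json")
    return {"paths": {k: str(v) for k, v in paths.items()},
            "mir_filter": mir_rep.__dict__, "mrna_filter": mrna_rep.__dict__}


def stage_associate(mir_path: str, mrna_path: str, params: dict, seed: int,
                    out_path: Path) -> dict:
    mir_m = panel.read_expression(mir_path, "miR")
    mrna_m = panel.read_expression(mrna_path, "mRNA-probe")
    est = MiEstimatorParams(k=params.get("k", 4),
                            noise_amplitude=params.get("noise_amplitude", 1e-8),
                            rng_seed=seed)
    assoc = pairwise_associations(mir_m, mrna_m, est)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    assoc.to_csv(out_path, sep="\t", index=False)
    return {"paths": {"associations": str(out_path)}, "n_pairs": len(assoc),
            "estimator": asdict(est)}


def stage_select(assoc_path: str, params: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    assoc = pd.read_csv(assoc_path, sep="\t")
    thresholds, selected = putative.select_strong_negative(
        assoc,
        mi_top_pct=params.get("mi_top_pct", 10.0),
        r_bottom_pct=params.get("r_bottom_pct", 2.5),
        mode=params.get("mode", "and"))
    sel_path = outdir / "selected_associations.tsv"
    selected.to_csv(sel_path, sep="\t", index=False)
    with open(outdir / "selection_thresholds.json", "w") as fh:
        json.dump(asdict(thresholds), fh, indent=2)
    return {"paths": {"selected": str(sel_path)},
            "thresholds": asdict(thresholds), "n_selected": len(selected)}


def stage_integrate(selected_path: str, targetscan_path: str, diana_path: str,
                    validated_path: str, probe_gene_map: str,
                    family_mir_map: str, params: dict, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    selected = pd.read_csv(selected_path, sep="\t")
    idmap = targets.IdMap.from_tsv(probe_gene_map, family_mir_map)
    ts = targets.load_predictions(targetscan_path, "targetscan")
    di = targets.load_predictions(diana_path, "diana")
    ts_f, ts_cut = targets.percentile_filter_predictions(
        ts, "targetscan", params.get("targetscan_percentile"))
    di_f, di_cut = targets.percentile_filter_predictions(
        di, "diana", params.get("diana_percentile"))
    val = targets.filter_validated_strong(targets.load_validated(validated_path))
    put = putative.build_putative_list(selected, ts_f, di_f, val, idmap)

    paths = {"putative": outdir / "putative_relationships.tsv",
             "targetscan_filtered": outdir / "targetscan_filtered.tsv",
             "diana_filtered": outdir / "diana_filtered.tsv",
             "validated_strong": outdir / "validated_strong.tsv"}
    put.to_csv(paths["putative"], sep="\t", index=False)
    ts_f.to_csv(paths["targetscan_filtered"], sep="\t", index=False)
    di_f.to_csv(paths["diana_filtered"], sep="\t", index=False)
    val.to_csv(paths["validated_strong"], sep="\t", index=False)
    return {"paths": {k: str(v) for k, v in paths.items()},
            "targetscan_cutoff": ts_cut, "diana_cutoff": di_cut,
            "n_putative": len(put),
            "n_validated_flagged": int(put["mirtarbase_validated"].sum())
            if len(put) else 0}


def stage_enrich(putative_path: str, targetscan_filtered: str,
                 diana_filtered: str, assoc_path: str, go_path: str,
                 probe_gene_map: str, family_mir_map: str, params: dict,
                 outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    put = pd.read_csv(putative_path, sep="\t")
    idmap = targets.IdMap.from_tsv(probe_gene_map, family_mir_map)
    assoc = pd.read_csv(assoc_path, sep="\t")
    universe = targets.map_identifiers(assoc, idmap)

    paths: dict[str, Path] = {}
    counts: dict[str, int] = {}
    for source, path in (("targetscan", targetscan_filtered),
                         ("diana", diana_filtered)):
        preds = pd.read_csv(path, sep="\t")
        table = enr.mir_active_enrichment(put, preds, universe, idmap)
        table = table.sort_values("fold_enrichment", ascending=False)
        out = outdir / f"mir_enrichment_{source}.tsv"
        table.to_csv(out, sep="\t", index=False)
        paths[f"mir_enrichment_{source}"] = out
        counts[f"n_enriched_mirs_{source}"] = len(table)

    go = enr.load_go_table(go_path)
    cats = enr.select_go_categories(
        go, tuple(params.get("substrings", enr.DEFAULT_SUBSTRINGS)),
        params.get("min_size", 5), params.get("max_size", 500))
    background = set(universe["gene_symbol"].dropna())
    go_rows = []
    if len(put):
        target_genes = set(put["gene_symbol"]) & background
        if target_genes:
            frac, fold = enr.go_target_enrichment(target_genes, cats, background)
            go_rows.append({"gene_set": "putative_targets",
                            "n_genes": len(target_genes),
                            "fraction_annotated": frac, "fold": fold})
    go_table = pd.DataFrame(go_rows,
                            columns=["gene_set", "n_genes",
                                     "fraction_annotated", "fold"])
    go_out = outdir / "go_enrichment.tsv"
    go_table.to_csv(go_out, sep="\t", index=False)
    paths["go_enrichment"] = go_out
    return {"paths": {k: str(v) for k, v in paths.items()},
            "n_go_categories_selected": len(cats), **counts}


def stage_dsep(mir_path: str, mrna_path: str, labels_path: str,
               putative_path: str, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    mir_m = panel.read_expression(mir_path, "miR")
    mrna_m = panel.read_expression(mrna_path, "mRNA-probe")
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)["phenotype"]
    dsep = separation.dsep_table(mir_m, mrna_m, labels)
    put = pd.read_csv(putative_path, sep="\t")
    annotated = separation.annotate_putative_with_dsep(put, dsep)

    paths = {"dsep": outdir / "dsep_all_pairs.tsv",
             "putative_annotated": outdir / "putative_annotated.tsv"}
    dsep.to_csv(paths["dsep"], sep="\t", index=False)
    annotated.to_csv(paths["putative_annotated"], sep="\t", index=False)
    return {"paths": {k: str(v) for k, v in paths.items()},
            "n_dsep_pairs": len(dsep)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate?/load -> preprocess -> associate -> select ->
    integrate -> enrich -> d_sep and return the manifest.

    The manifest records every stage's output paths, realised thresholds and
    row counts; identical config and seed give identical outputs.  A stage
    failure raises :class:`PipelineStageError` carrying the partial manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "outdir": str(outdir), "stages": {}}
    stage = "setup"
    try:
        t0 = time.time()
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = simulate.SimulationConfig(
                **{**config.simulate, "rng_seed": config.simulate.get(
                    "rng_seed", config.seed)})
            inputs = stage_simulate(sim_cfg, outdir / "inputs")
            manifest["stages"]["simulate"] = {"paths": inputs}
        else:
            inputs = dict(config.inputs)
        logger.info("inputs ready (%.1fs)", time.time() - t0)

        for key in ("mir_expression", "mrna_expression", "targetscan", "diana",
                    "validated", "go", "labels", "probe_gene_map",
                    "family_mir_map"):
            if key not in inputs:
                # tolerate the short aliases used in input blocks
                alias = {"mir_expression": "mir", "mrna_expression": "mrna"}
                if key in alias and alias[key] in inputs:
                    inputs[key] = inputs[alias[key]]
                else:
                    raise FileNotFoundError(f"missing input: {key}")

        stage = "preprocess"
        t0 = time.time()
        pre = stage_preprocess(inputs["mir_expression"],
                               inputs["mrna_expression"],
                               config.preprocess, outdir / "preprocess")
        manifest["stages"]["preprocess"] = pre
        logger.info("preprocess done (%.1fs)", time.time() - t0)

        stage = "associate"
        t0 = time.time()
        asc = stage_associate(pre["paths"]["mir_filtered"],
                              pre["paths"]["mrna_filtered"],
                              config.association, config.seed,
                              outdir / "associations.tsv")
        manifest["stages"]["associate"] = asc
        logger.info("associate done (%.1fs)", time.time() - t0)

        stage = "select"
        sel = stage_select(asc["paths"]["associations"], config.selection,
                           outdir / "select")
        manifest["stages"]["select"] = sel

        stage = "integrate"
        integ = stage_integrate(sel["paths"]["selected"], inputs["targetscan"],
                                inputs["diana"], inputs["validated"],
                                inputs["probe_gene_map"],
                                inputs["family_mir_map"],
                                config.predictions, outdir / "integrate")
        manifest["stages"]["integrate"] = integ

        stage = "enrich"
        enrich = stage_enrich(integ["paths"]["putative"],
                              integ["paths"]["targetscan_filtered"],
                              integ["paths"]["diana_filtered"],
                              asc["paths"]["associations"], inputs["go"],
                              inputs["probe_gene_map"],
                              inputs["family_mir_map"], config.go,
                              outdir / "enrich")
        manifest["stages"]["enrich"] = enrich

        stage = "dsep"
        dsep = stage_dsep(pre["paths"]["mir_filtered"],
                          pre["paths"]["mrna_filtered"], inputs["labels"],
                          integ["paths"]["putative"], outdir / "dsep")
        manifest["stages"]["dsep"] = dsep
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise PipelineStageError(stage, exc, manifest) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
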