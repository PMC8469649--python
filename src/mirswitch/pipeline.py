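"""End-to-end orchestration: expression -> DE -> peaks -> interactions ->
conservation -> enrichment, with a serialisable run manifest.

A run is driven by a single config mapping (YAML or JSON on disk) with
blocks ``simulate`` (optional fixture generation), ``thresholds``,
``inputs`` and ``out_dir``.  Every stage writes its table under the output
directory; the manifest records the config snapshot, input digests and the
record count after every filter, so two runs on identical inputs can be
compared file-by-file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import conservation as cons
from . import diffexpr, enrichment, interactions, io, peaks, simulate
from .errors import ConfigurationError
from .expression import filter_expressed

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage threshold in one place (defaults = the screen's canon)."""

    expression_floor: float = 5.0
    de_alpha: float = 1e-5
    de_lfc: float = 2.0
    peak_r_min: float = 0.6
    anticorr_tau: float = -0.2
    conservation_delta: float = 0.2
    top_k_per_day: int = 10
    enrichment_child_alpha: float = 0.01
    peak_level: str = "replicate"
    strict: bool = True

    def validate(self) -> None:
        if not 0 < self.de_alpha < 1:
            raise ConfigurationError("de_alpha must lie in (0, 1)")
        if not -1 <= self.peak_r_min <= 1:
            raise ConfigurationError("peak_r_min must lie in [-1, 1]")
        if not -1 <= self.anticorr_tau <= 1:
            raise ConfigurationError("anticorr_tau must lie in [-1, 1]")
        if self.conservation_delta < 0:
            raise ConfigurationError("conservation_delta must be >= 0")
        if not 0 < self.enrichment_child_alpha < 1:
            raise ConfigurationError("enrichment_child_alpha must lie in (0, 1)")


@dataclass
class RunManifest:
    """What a run saw, chose and produced."""

    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, object] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            dataclasses.asdict(self), indent=1, sort_keys=True,
            default=lambda o: o.item() if hasattr(o, "item") else str(o)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None
                 ) -> RunManifest:
    """Execute the full screen from a config mapping or config file path."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("out_dir", "results/run"))
    out.mkdir(parents=True, exist_ok=True)
    thresholds = PipelineConfig(**config.get("thresholds", {}))
    thresholds.validate()
    inputs = dict(config.get("inputs", {}))

    t0 = time.time()
    if "simulate" in config:
        sim_cfg = simulate.SimulationConfig(**config["simulate"])
        fixture = out / "fixture"
        logger.info("simulating fixture into %s", fixture)
        simulate.write_fixture_set(fixture, sim_cfg)
        inputs = {
            "vitro_mrna": fixture / "vitro_mrna.tsv",
            "vitro_mrna_samples": fixture / "vitro_mrna.samples.tsv",
            "vitro_mirna": fixture / "vitro_mirna.tsv",
            "vitro_mirna_samples": fixture / "vitro_mirna.samples.tsv",
            "vivo_mrna": fixture / "vivo_mrna.tsv",
            "vivo_mrna_samples": fixture / "vivo_mrna.samples.tsv",
            "vivo_mirna": fixture / "vivo_mirna.tsv",
            "vivo_mirna_samples": fixture / "vivo_mirna.samples.tsv",
            "interactions": sorted(str(p) for p in fixture.glob("resource*.tsv")),
            "ontology_edges": fixture / "ontology_edges.tsv",
            "ontology_annotations": fixture / "ontology_annotations.tsv",
            "gene_set": fixture / "heart_genes.txt",
            "regulators": fixture / "regulators.txt",
        }

    manifest = RunManifest(config={
        "thresholds": dataclasses.asdict(thresholds),
        "simulate": config.get("simulate"),
        "inputs": {k: [str(x) for x in v] if isinstance(v, list) else str(v)
                   for k, v in inputs.items()},
    })
    for key, val in inputs.items():
        paths = val if isinstance(val, list) else [val]
        for p in paths:
            p = Path(p)
            if not p.exists():
                raise ConfigurationError(f"input '{key}' missing: {p}")
            manifest.input_digests[p.name] = _sha256(p)

    # --- expression ------------------------------------------------------
    def load(tag: str, kind: str):
        study = io.read_expression_tsv(inputs[tag], inputs[f"{tag}_samples"],
                                       feature_kind=kind,
                                       probe_map_path=inputs.get(f"{tag}_probe_map"))
        if study.probe_to_feature is not None:
            from .expression import collapse_probes
            study = collapse_probes(study)
        return filter_expressed(study, thresholds.expression_floor)

    studies = {
        ("vitro", "mRNA"): load("vitro_mrna", "mRNA"),
        ("vitro", "miRNA"): load("vitro_mirna", "miRNA"),
        ("vivo", "mRNA"): load("vivo_mrna", "mRNA"),
        ("vivo", "miRNA"): load("vivo_mirna", "miRNA"),
    }
    manifest.counts["expressed"] = {
        f"{exp}_{kind}": len(st.feature_ids) for (exp, kind), st in studies.items()}
    logger.info("expression filtered in %.1fs: %s", time.time() - t0,
                manifest.counts["expressed"])

    # --- differential expression (in vitro course, day-0 reference) ------
    for kind, tag in [("mRNA", "de_genes"), ("miRNA", "de_mirnas")]:
        study = studies[("vitro", kind)]
        table = diffexpr.de_table(study, alpha=thresholds.de_alpha,
                                  lfc_min=thresholds.de_lfc,
                                  strict=thresholds.strict)
        table.to_csv(out / f"{tag}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        manifest.outputs[tag] = str(out / f"{tag}.tsv")
        per_day = table.loc[table["is_de"]].groupby("day")["feature_id"].nunique()
        manifest.counts[tag] = {
            "total": int(table.loc[table["is_de"], "feature_id"].nunique()),
            "per_day": {str(d): int(c) for d, c in per_day.items()},
        }

    # --- peaks (in vitro miRNAs) -----------------------------------------
    mirna_vitro = studies[("vitro", "miRNA")]
    calls = peaks.call_peaks(mirna_vitro, r_min=thresholds.peak_r_min,
                             level=thresholds.peak_level)
    peak_df = pd.DataFrame(
        [{"mirna_id": c.mirna_id, "peak_day": c.peak_day, "r_peak": c.r_peak,
          **{f"r_day{d:g}": r for d, r in zip(c.days, c.all_r)}}
         for c in calls])
    peak_df.to_csv(out / "peaks.tsv", sep="\t", index=False, float_format="%.6g")
    manifest.outputs["peaks"] = str(out / "peaks.tsv")
    manifest.counts["peaks_per_day"] = {
        f"{d:g}": int(sum(c.peak_day == d for c in calls))
        for d in mirna_vitro.days}
    top = peaks.top_k_by_day(calls, thresholds.top_k_per_day)

    if "interactions" not in inputs or not inputs["interactions"]:
        logger.warning("no interaction resources configured; "
                       "stopping after the peak stage")
        manifest.to_json(out / "manifest.json")
        return manifest

    # --- interactions ----------------------------------------------------
    tables = [interactions.read_interaction_tsv(p) for p in inputs["interactions"]]
    merged = interactions.merge_resources(tables)
    manifest.counts["interactions_merged"] = len(merged)
    annotated = {}
    for exp in ("vitro", "vivo"):
        mir, mrna = studies[(exp, "miRNA")], studies[(exp, "mRNA")]
        restricted = interactions.restrict_to_expressed(
            merged, set(mir.feature_ids), set(mrna.feature_ids))
        annotated[exp] = interactions.annotate_correlations(restricted, mir, mrna)
        annotated[exp].to_csv(out / f"correlations_{exp}.tsv", sep="\t",
                              index=False, float_format="%.6g")
        manifest.counts[f"interactions_annotated_{exp}"] = len(annotated[exp])

    # --- conservation ----------------------------------------------------
    candidates = cons.intersect_studies(annotated["vitro"], annotated["vivo"])
    manifest.counts["interactions_overlap"] = len(candidates)
    if "gene_set" in inputs:
        gene_set = io.read_gene_list(inputs["gene_set"])
        candidates = cons.restrict_gene_set(candidates, gene_set)
    manifest.counts["interactions_gene_set"] = len(candidates)
    conserved = cons.select_conserved(candidates, thresholds.conservation_delta,
                                      thresholds.anticorr_tau,
                                      strict=thresholds.strict)
    conserved.to_csv(out / "conserved.tsv", sep="\t", index=False,
                     float_format="%.6g")
    manifest.outputs["conserved"] = str(out / "conserved.tsv")
    n_int, n_mir, n_gene = cons.summarize_run(conserved)
    manifest.counts["conserved"] = {"interactions": n_int, "mirnas": n_mir,
                                    "genes": n_gene}
    regulators = io.read_gene_list(inputs["regulators"]) \
        if "regulators" in inputs else set()
    priority = cons.rank_mirnas(conserved, regulators)
    priority.to_csv(out / "mirna_priority.tsv", sep="\t", index=False)
    manifest.outputs["mirna_priority"] = str(out / "mirna_priority.tsv")

    # --- enrichment of per-day peak-miRNA targets ------------------------
    if "ontology_edges" in inputs:
        dag = io.read_ontology_tsv(inputs["ontology_edges"],
                                   inputs["ontology_annotations"])
        dag = enrichment.propagate_annotations(dag)
        annotated_genes = set().union(*dag.propagated_annotations.values())
        expressed = set(studies[("vitro", "mRNA")].feature_ids)
        universe = expressed & annotated_genes
        anti = interactions.filter_anticorrelated(annotated["vitro"],
                                                  thresholds.anticorr_tau)
        frames = []
        for day, mirnas_of_day in top.items():
            selected = set(anti.loc[anti["mirna_id"].isin(mirnas_of_day),
                                    "gene_id"]) & universe
            if not selected:
                continue
            res = enrichment.conditional_enrichment(
                dag, selected, universe, thresholds.enrichment_child_alpha)
            frame = enrichment.enrichment_frame(res)
            frame.insert(0, "peak_day", day)
            frames.append(frame)
        enr = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        manifest.outputs["enrichment"] = str(out / "enrichment.tsv")
        manifest.counts["enrichment_tests"] = len(enr)

    manifest.to_json(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return manifest
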