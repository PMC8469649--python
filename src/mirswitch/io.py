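"""Plain-TSV readers and writers for every stage artefact.

All expression values are on the log2 scale.  Formats:

* expression TSV — first column ``feature_id``, remaining columns sample ids;
* sample sheet TSV — ``sample_id``, ``day``, ``replicate``;
* probe map TSV — ``probe_id``, ``feature_id``;
* interaction TSV — ``mirna_id``, ``gene_id``[, ``score``][, ``evidence``];
* ontology edges TSV — ``child_id``, ``parent_id``; annotations TSV —
  ``gene_id``, ``term_id``;
* gene list — one id per line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import OntologyDAG
from .expression import ExpressionStudy
from .interactions import InteractionTable

FLOAT_FMT = "%.6f"


def read_expression_tsv(matrix_path: str | Path, samples_path: str | Path,
                        feature_kind: str = "mRNA",
                        probe_map_path: str | Path | None = None) -> ExpressionStudy:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    samples = pd.read_csv(samples_path, sep="\t",
                          dtype={"sample_id": str, "replicate": int})
    samples["day"] = samples["day"].astype(float)
    probe_map = None
    if probe_map_path is not None:
        pm = pd.read_csv(probe_map_path, sep="\t", dtype=str)
        probe_map = dict(zip(pm["probe_id"], pm["feature_id"]))
    return ExpressionStudy(values=values, samples=samples,
                           feature_kind=feature_kind, probe_to_feature=probe_map)


def write_expression_tsv(study: ExpressionStudy, matrix_path: str | Path,
                         samples_path: str | Path) -> None:
    study.values.to_csv(matrix_path, sep="\t", index_label="feature_id",
                        float_format=FLOAT_FMT)
    study.samples.to_csv(samples_path, sep="\t", index=False)


def write_interaction_tsv(table: InteractionTable, path: str | Path) -> None:
    rec = table.records.copy()
    rec["sources"] = rec["sources"].map(lambda s: ",".join(sorted(s)))
    rec.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_ontology_tsv(dag: OntologyDAG, edges_path: str | Path,
                       annotations_path: str | Path) -> None:
    pd.DataFrame(dag.edges, columns=["child_id", "parent_id"]).to_csv(
        edges_path, sep="\t", index=False)
    rows = [{"gene_id": g, "term_id": t}
            for t in dag.terms for g in sorted(dag.direct_annotations.get(t, set()))]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        annotations_path, sep="\t", index=False)


def read_ontology_tsv(edges_path: str | Path,
                      annotations_path: str | Path) -> OntologyDAG:
    edges_df = pd.read_csv(edges_path, sep="\t", dtype=str)
    ann_df = pd.read_csv(annotations_path, sep="\t", dtype=str)
    edges = list(zip(edges_df["child_id"], edges_df["parent_id"]))
    terms = sorted(set(edges_df["child_id"]) | set(edges_df["parent_id"])
                   | set(ann_df["term_id"]))
    direct: dict[str, set[str]] = {t: set() for t in terms}
    for g, t in zip(ann_df["gene_id"], ann_df["term_id"]):
        direct[t].add(g)
    return OntologyDAG(terms=terms, edges=edges, direct_annotations=direct)
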