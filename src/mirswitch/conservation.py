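"""Cross-study conservation of anti-correlated miRNA-mRNA interactions.

An interaction observed in both the in vitro and the in vivo course is kept
when its miRNA-target rank correlation is (a) similar between the studies
(|tau_vitro - tau_vivo| below a threshold) and (b) clearly negative in
both, i.e. consistent with active repression rather than coincidence in a
single dataset.  Surviving interactions are aggregated per miRNA to rank
candidate regulators by target count and by how many targets are
transcriptional regulators themselves.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = ["mirna_id", "gene_id", "tau_vitro", "tau_vivo", "delta"]

# Tau values are ratios of small integers, so strict threshold comparisons
# are enforced up to this tolerance; otherwise a gap of exactly 0.2 can
# round to 0.1999... and sneak past a strict cut.
EPS = 1e-9


def intersect_studies(vitro: pd.DataFrame, vivo: pd.DataFrame) -> pd.DataFrame:
    """Pairs annotated in both studies, with both tau values and their gap.

    Inputs are the per-study annotated tables [mirna_id, gene_id, tau, ...];
    output columns: mirna_id, gene_id, tau_vitro, tau_vivo, delta.
    """
    merged = vitro[["mirna_id", "gene_id", "tau"]].merge(
        vivo[["mirna_id", "gene_id", "tau"]],
        on=["mirna_id", "gene_id"], suffixes=("_vitro", "_vivo"))
    merged["delta"] = (merged["tau_vitro"] - merged["tau_vivo"]).abs()
    return merged[CANDIDATE_COLUMNS].reset_index(drop=True)


def restrict_gene_set(candidates: pd.DataFrame, gene_set: set[str]) -> pd.DataFrame:
    """Keep candidates whose target belongs to the supplied gene set."""
    if not gene_set:
        logger.warning("restrict_gene_set: empty gene set, everything is dropped")
    return candidates.loc[candidates["gene_id"].isin(gene_set)].reset_index(drop=True)


def select_conserved(candidates: pd.DataFrame, delta_max: float = 0.2,
                     tau_max: float = -0.2, strict: bool = True) -> pd.DataFrame:
    """Conservation filter: similar and negative correlation in both studies.

    Keeps candidates with delta < ``delta_max`` and both tau values below
    ``tau_max``; ``strict=False`` relaxes every comparison to <=.
    """
    if strict:
        keep = ((candidates["delta"] < delta_max - EPS)
                & (candidates["tau_vitro"] < tau_max - EPS)
                & (candidates["tau_vivo"] < tau_max - EPS))
    else:
        keep = ((candidates["delta"] <= delta_max + EPS)
                & (candidates["tau_vitro"] <= tau_max + EPS)
                & (candidates["tau_vivo"] <= tau_max + EPS))
    return candidates.loc[keep].reset_index(drop=True)


def rank_mirnas(conserved: pd.DataFrame, regulator_genes: set[str]) -> pd.DataFrame:
    """Per-miRNA target counts, sorted by reach.

    Columns: mirna_id, n_targets, target_genes (comma-joined, sorted),
    n_regulators (targets that are transcriptional regulators).  Sorted by
    n_targets descending, ties by miRNA id.
    """
    rows = []
    for mirna, grp in conserved.groupby("mirna_id"):
        targets = sorted(set(grp["gene_id"]))
        rows.append({
            "mirna_id": mirna,
            "n_targets": len(targets),
            "target_genes": ",".join(targets),
            "n_regulators": sum(g in regulator_genes for g in targets),
        })
    out = pd.DataFrame(rows, columns=["mirna_id", "n_targets", "target_genes",
                                      "n_regulators"])
    return out.sort_values(["n_targets", "mirna_id"],
                           ascending=[False, True]).reset_index(drop=True)


def summarize_run(conserved: pd.DataFrame) -> tuple[int, int, int]:
    """(interactions, unique miRNAs, unique target genes) of the final set."""
    return (len(conserved),
            conserved["mirna_id"].nunique(),
            conserved["gene_id"].nunique())
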