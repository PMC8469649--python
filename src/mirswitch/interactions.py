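"""Candidate miRNA->target interactions: resource merging, expression
restriction and Kendall rank anti-correlation screening.

Profiles from the two feature kinds of one study are compared with the
tie-corrected Kendall tau-b, computed by exact pair enumeration — with a
handful of time points the O(n^2) count is both exact and instant, and rank
correlation is robust to the monotone distortions that survive log2
preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedStatisticError
from .expression import ExpressionStudy

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["mirna_id", "gene_id", "sources", "evidence"]


@dataclass
class InteractionTable:
    """Deduplicated miRNA->gene candidate interactions with provenance.

    ``records`` columns: mirna_id, gene_id, sources (frozenset of resource
    names), evidence ("predicted" or "experimental").
    """

    records: pd.DataFrame
    name: str = "merged"

    def __post_init__(self) -> None:
        if self.records.empty:
            self.records = pd.DataFrame(columns=RECORD_COLUMNS)
        missing = set(RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"interaction table lacks columns {sorted(missing)}")
        self.records = self.records[RECORD_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.records["mirna_id"], self.records["gene_id"]))


def merge_resources(tables: list[InteractionTable]) -> InteractionTable:
    """Union interaction tables over (miRNA, gene) identity.

    Sources accumulate; a pair is experimental if any contributing resource
    is experimental.  Associative, commutative and idempotent.
    """
    if not tables:
        raise ConfigurationError("merge_resources needs at least one table")
    allrec = pd.concat([t.records for t in tables], ignore_index=True)
    if allrec.empty:
        return InteractionTable(records=allrec, name="merged")
    merged = (
        allrec.groupby(["mirna_id", "gene_id"], sort=True)
        .agg(
            sources=("sources", lambda s: frozenset().union(*s)),
            evidence=("evidence", lambda e: "experimental" if (e == "experimental").any() else "predicted"),
        )
        .reset_index()
    )
    return InteractionTable(records=merged, name="merged")


def restrict_to_expressed(table: InteractionTable, expressed_mirnas: set[str],
                          expressed_genes: set[str]) -> InteractionTable:
    """Drop interactions whose miRNA or target failed the expression floor."""
    rec = table.records
    keep = rec["mirna_id"].isin(expressed_mirnas) & rec["gene_id"].isin(expressed_genes)
    return InteractionTable(records=rec.loc[keep].reset_index(drop=True),
                            name=table.name)


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall tau-b by exact pair enumeration.

    tau_b = (C - D) / sqrt((C + D + Tx)(C + D + Ty)) where C and D count
    concordant and discordant pairs, and Tx (Ty) counts pairs tied in x (y)
    only.  Pairs tied in both contribute to neither term.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("kendall_tau needs equal-length vectors, n >= 3")
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    sx, sy = dx[iu], dy[iu]
    conc = int(np.sum((sx * sy) > 0))
    disc = int(np.sum((sx * sy) < 0))
    tx = int(np.sum((sx == 0) & (sy != 0)))
    ty = int(np.sum((sy == 0) & (sx != 0)))
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    if denom == 0:
        raise UndefinedStatisticError("kendall_tau undefined: a vector is all ties")
    return float((conc - disc) / denom)


@dataclass
class CorrelatedInteraction:
    mirna_id: str
    gene_id: str
    tau: float
    n_days: int


def annotate_correlations(table: InteractionTable, mirna_study: ExpressionStudy,
                          mrna_study: ExpressionStudy) -> pd.DataFrame:
    """Kendall tau of day-mean profiles for every interaction of one study.

    Returns a DataFrame [mirna_id, gene_id, tau, n_days].  Records whose
    miRNA or gene is absent, or whose tau is undefined (all-tied profile),
    are skipped with a log message.
    """
    if not np.array_equal(mirna_study.days, mrna_study.days):
        raise ConfigurationError(
            "miRNA and mRNA studies of one experiment must share the day grid")
    mir_means = mirna_study.day_means()
    gene_means = mrna_study.day_means()
    n_days = mir_means.shape[1]
    rows = []
    skipped = 0
    for m, g in zip(table.records["mirna_id"], table.records["gene_id"]):
        if m not in mir_means.index or g not in gene_means.index:
            skipped += 1
            continue
        try:
            tau = kendall_tau(mir_means.loc[m].to_numpy(),
                              gene_means.loc[g].to_numpy())
        except UndefinedStatisticError:
            skipped += 1
            continue
        rows.append({"mirna_id": m, "gene_id": g, "tau": tau, "n_days": n_days})
    if skipped:
        logger.info("annotate_correlations: skipped %d records", skipped)
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "tau", "n_days"])


def filter_anticorrelated(annotated: pd.DataFrame, tau_max: float = -0.2) -> pd.DataFrame:
    """Keep interactions with tau strictly below ``tau_max`` (default -0.2).

    Strictness is enforced up to a 1e-9 tolerance: tau is a ratio of small
    integers, so a value equal to the threshold must not pass on rounding.
    """
    return annotated.loc[annotated["tau"] < tau_max - 1e-9].reset_index(drop=True)


def read_interaction_tsv(path: str | Path, name: str | None = None,
                         evidence: str = "predicted",
                         score_min: float | None = None) -> InteractionTable:
    """Read one resource's interaction TSV (mirna_id, gene_id[, score[, evidence]]).

    ``score_min`` is a pass-through confidence hook: records with a score
    column below it are dropped before merging, so resource-recommended
    cut-offs can be applied without touching the merge logic.
    """
    path = Path(path)
    name = name or path.stem
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    if score_min is not None and "score" in df.columns:
        df = df.loc[df["score"] >= score_min]
    if "evidence" not in df.columns:
        df["evidence"] = evidence
    records = pd.DataFrame({
        "mirna_id": df["mirna_id"],
        "gene_id": df["gene_id"],
        "sources": [frozenset([name])] * len(df),
        "evidence": df["evidence"],
    })
    return InteractionTable(records=records, name=name)
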