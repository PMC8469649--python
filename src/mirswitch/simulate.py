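"""Synthetic paired-study generator with planted, machine-readable truth.

Emulates the statistical structure the downstream screens assume: two
replicated multi-day log2 expression time courses (an in vitro
differentiation course and an in vivo developmental course), each measured
for mRNAs and miRNAs; a minority of miRNAs with a switch-like single-day
expression peak; miRNA->target repression producing anti-correlated
profiles that are planted in one study or conserved in both; several
partially overlapping interaction resources salted with decoys; and a small
ontology DAG carrying a heart-development-like term.

Every planted property is recorded in a :class:`TruthSet` so recovery can be
scored exactly.  Generation is fully deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import ExpressionStudy
from .interactions import InteractionTable
from .enrichment import OntologyDAG

HEART_TERM = "T:heart_dev"
ROOT_TERM = "T:root"


@dataclass
class SimulationConfig:
    """Parameters of the paired-study generator.

    Defaults describe a small but realistic post-QC dataset: log2 baselines
    above the detection floor, replicated five-day in vitro and six-day
    in vivo grids, switch-like peaks of 4 log2 units, and unit-slope
    repression of planted targets.
    """

    n_genes: int = 600
    n_mirnas: int = 120
    days_vitro: tuple[float, ...] = (0, 4, 8, 12, 16)
    days_vivo: tuple[float, ...] = (9.5, 10.5, 11.5, 12.5, 13.5)
    n_replicates: int = 3
    baseline_range: tuple[float, float] = (6.0, 12.0)
    noise_sd: float = 0.3
    peak_amplitude: float = 4.0
    frac_peaked_mirnas: float = 0.04  # fraction of miRNAs peaked per day
    n_true_interactions: int = 50
    frac_conserved: float = 1.0
    repression_beta: float = 1.0
    n_decoy_interactions: int = 500
    n_resources: int = 5
    resource_coverage: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_replicates", "n_true_interactions",
                     "n_decoy_interactions", "n_resources"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("frac_peaked_mirnas", "frac_conserved", "resource_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.baseline_range[0] < self.baseline_range[1]:
            raise ConfigurationError("baseline_range lower bound must be < upper")
        for name in ("days_vitro", "days_vivo"):
            days = getattr(self, name)
            if len(days) < 3:
                raise ConfigurationError(f"{name} needs at least 3 time points")
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ConfigurationError(f"{name} must be strictly increasing")
        if (self.n_true_interactions + self.n_decoy_interactions
                > self.n_genes * self.n_mirnas):
            raise ConfigurationError(
                "n_decoy_interactions: true + decoy interactions exceed the "
                "number of distinct (miRNA, gene) pairs")


@dataclass
class TruthSet:
    """Machine-readable record of everything the generator planted."""

    peaked_mirnas: dict[str, float]          # miRNA -> vitro peak day label
    peak_day_index: dict[str, int]           # miRNA -> day index (both grids)
    true_interactions: set[tuple[str, str, str]]   # (miRNA, gene, membership)
    decoy_interactions: set[tuple[str, str]]
    cardiac_genes: set[str]
    regulator_genes: set[str]

    def conserved_pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, mem in self.true_interactions if mem == "both"}

    def true_pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.true_interactions}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "peaked_mirnas": self.peaked_mirnas,
            "peak_day_index": self.peak_day_index,
            "true_interactions": sorted(list(t) for t in self.true_interactions),
            "decoy_interactions": sorted(list(t) for t in self.decoy_interactions),
            "cardiac_genes": sorted(self.cardiac_genes),
            "regulator_genes": sorted(self.regulator_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            peaked_mirnas={k: float(v) for k, v in d["peaked_mirnas"].items()},
            peak_day_index={k: int(v) for k, v in d["peak_day_index"].items()},
            true_interactions={tuple(t) for t in d["true_interactions"]},
            decoy_interactions={tuple(t) for t in d["decoy_interactions"]},
            cardiac_genes=set(d["cardiac_genes"]),
            regulator_genes=set(d["regulator_genes"]),
        )


def _sample_sheet(prefix: str, days: Sequence[float], n_rep: int) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{prefix}_d{day:g}_r{r + 1}", "day": float(day), "replicate": r + 1}
        for day in days
        for r in range(n_rep)
    ]
    return pd.DataFrame(rows)


def _expand(day_profiles: np.ndarray, n_rep: int) -> np.ndarray:
    """Repeat each day column n_rep times (replicates of the same underlying value)."""
    return np.repeat(day_profiles, n_rep, axis=1)


def simulate_study_pair(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, ExpressionStudy, ExpressionStudy, ExpressionStudy, TruthSet]:
    """Generate (vitro mRNA, vitro miRNA, vivo mRNA, vivo miRNA, truth).

    Generator model
    ---------------
    * every feature draws a constant log2 baseline from ``baseline_range``;
    * peaked miRNAs gain ``peak_amplitude`` at exactly one day (same day
      index on both grids);
    * miRNAs carrying true interactions follow a dynamic profile spanning
      ``peak_amplitude`` log2 units (evenly spaced day levels in a random
      order, drawn per miRNA and per study), giving their targets a strong
      rank anti-correlation whatever the shape;
    * each true interaction's target day profile is its baseline minus
      ``repression_beta`` times the miRNA profile's deviation from its mean,
      applied in the member study (or both, for conserved interactions);
    * i.i.d. Gaussian noise of sd ``noise_sd`` is then added per sample.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    mirnas = [f"mir{i:03d}" for i in range(config.n_mirnas)]
    lo, hi = config.baseline_range
    gene_base = rng.uniform(lo, hi, size=config.n_genes)
    mir_base = rng.uniform(lo, hi, size=config.n_mirnas)

    n_days_vitro = len(config.days_vitro)
    n_days_vivo = len(config.days_vivo)

    # --- plant switch-like peaks: disjoint miRNA sets per day -------------
    per_day = int(round(config.frac_peaked_mirnas * config.n_mirnas))
    n_peaked = min(per_day * n_days_vitro, config.n_mirnas)
    peaked_order = rng.permutation(config.n_mirnas)[:n_peaked]
    peaked_mirnas: dict[str, float] = {}
    peak_day_index: dict[str, int] = {}
    for j, mi in enumerate(peaked_order):
        day_idx = j // per_day if per_day else 0
        peaked_mirnas[mirnas[mi]] = float(config.days_vitro[day_idx])
        peak_day_index[mirnas[mi]] = day_idx

    # --- choose interacting miRNAs (never the peaked ones) and targets ----
    free = [i for i in range(config.n_mirnas) if mirnas[i] not in peaked_mirnas]
    if config.n_true_interactions and not free:
        raise ConfigurationError("no non-peaked miRNAs left to carry interactions")
    n_int_mirnas = min(len(free), max(1, config.n_true_interactions // 3)) \
        if config.n_true_interactions else 0
    trend_pool = list(rng.choice(free, size=n_int_mirnas, replace=False)) if n_int_mirnas else []

    target_genes = rng.choice(config.n_genes,
                              size=min(config.n_true_interactions, config.n_genes),
                              replace=False)
    true_interactions: set[tuple[str, str, str]] = set()
    pair_info: list[tuple[int, int, str]] = []  # (mirna idx, gene idx, membership)
    for k in range(len(target_genes)):
        mi = int(trend_pool[int(rng.integers(len(trend_pool)))])
        gi = int(target_genes[k])
        membership = "both" if rng.random() < config.frac_conserved else \
            ("vitro" if rng.random() < 0.5 else "vivo")
        true_interactions.add((mirnas[mi], genes[gi], membership))
        pair_info.append((mi, gi, membership))

    # --- underlying day-level profiles ------------------------------------
    def mirna_day_profiles(n_days: int) -> np.ndarray:
        # Interacting miRNAs follow a study-specific dynamic profile: the
        # amplitude levels 0..peak_amplitude in a random day order, distinct
        # per miRNA and per study.  Distinct day values guarantee tau = -1
        # with their noiseless targets; independent shapes avoid making all
        # dynamic miRNAs mutually rank-correlated.
        prof = np.tile(mir_base[:, None], (1, n_days))
        levels = np.linspace(0.0, config.peak_amplitude, n_days)
        for mi in trend_pool:
            prof[mi] += rng.permutation(levels)
        for name, idx in peak_day_index.items():
            mi = mirnas.index(name)
            if idx < n_days:
                prof[mi, idx] += config.peak_amplitude
        return prof

    def gene_day_profiles(mir_prof: np.ndarray, study: str) -> np.ndarray:
        prof = np.tile(gene_base[:, None], (1, mir_prof.shape[1]))
        for mi, gi, membership in pair_info:
            if membership == "both" or membership == study:
                dev = mir_prof[mi] - mir_prof[mi].mean()
                prof[gi] = gene_base[gi] - config.repression_beta * dev
        return prof

    def build_study(day_profiles: np.ndarray, ids: list[str], days: Sequence[float],
                    kind: str, prefix: str) -> ExpressionStudy:
        underlying = _expand(day_profiles, config.n_replicates)
        noise = rng.normal(0.0, config.noise_sd, size=underlying.shape) \
            if config.noise_sd > 0 else 0.0
        sheet = _sample_sheet(prefix, days, config.n_replicates)
        values = pd.DataFrame(underlying + noise, index=ids,
                              columns=list(sheet["sample_id"]))
        return ExpressionStudy(values=values, samples=sheet, feature_kind=kind)

    mir_vitro_prof = mirna_day_profiles(n_days_vitro)
    mir_vivo_prof = mirna_day_profiles(n_days_vivo)
    gene_vitro_prof = gene_day_profiles(mir_vitro_prof, "vitro")
    gene_vivo_prof = gene_day_profiles(mir_vivo_prof, "vivo")

    vitro_mrna = build_study(gene_vitro_prof, genes, config.days_vitro, "mRNA", "vt")
    vitro_mirna = build_study(mir_vitro_prof, mirnas, config.days_vitro, "miRNA", "vt")
    vivo_mrna = build_study(gene_vivo_prof, genes, config.days_vivo, "mRNA", "vv")
    vivo_mirna = build_study(mir_vivo_prof, mirnas, config.days_vivo, "miRNA", "vv")

    # --- decoys: random pairs that were never planted ----------------------
    true_pairs = {(m, g) for m, g, _ in true_interactions}
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < config.n_decoy_interactions:
        m = mirnas[int(rng.integers(config.n_mirnas))]
        g = genes[int(rng.integers(config.n_genes))]
        if (m, g) not in true_pairs:
            decoys.add((m, g))

    # heart-like gene set: all planted targets plus a random tenth of the rest
    target_set = {genes[gi] for _, gi, _ in pair_info}
    others = [g for g in genes if g not in target_set]
    extra = set(rng.choice(others, size=len(others) // 10, replace=False)) if others else set()
    cardiac_genes = target_set | extra
    regulator_genes = set(rng.choice(genes, size=max(1, config.n_genes // 7),
                                     replace=False))

    truth = TruthSet(
        peaked_mirnas=peaked_mirnas,
        peak_day_index=peak_day_index,
        true_interactions=true_interactions,
        decoy_interactions=decoys,
        cardiac_genes=cardiac_genes,
        regulator_genes=regulator_genes,
    )
    return vitro_mrna, vitro_mirna, vivo_mrna, vivo_mirna, truth


def simulate_resources(truth: TruthSet, config: SimulationConfig) -> list[InteractionTable]:
    """Draw ``n_resources`` partially overlapping interaction tables.

    Each resource lists each planted (true or decoy) pair independently with
    probability ``resource_coverage``.  The final resource is marked as
    experimentally supported, mirroring a merge of several prediction
    databases with one validation database.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    pairs = sorted(truth.true_pairs() | truth.decoy_interactions)
    tables: list[InteractionTable] = []
    for r in range(config.n_resources):
        name = f"resource{r + 1}"
        evidence = "experimental" if r == config.n_resources - 1 else "predicted"
        mask = rng.random(len(pairs)) < config.resource_coverage
        records = pd.DataFrame(
            [{"mirna_id": m, "gene_id": g, "sources": frozenset([name]),
              "evidence": evidence}
             for (m, g), keep in zip(pairs, mask) if keep],
            columns=["mirna_id", "gene_id", "sources", "evidence"],
        )
        tables.append(InteractionTable(records=records, name=name))
    return tables


def simulate_ontology(truth: TruthSet, n_filler_terms: int = 30,
                      seed: int = 0) -> OntologyDAG:
    """Build a small acyclic single-root ontology.

    One designated term (:data:`HEART_TERM`) directly annotates exactly the
    planted heart-like gene set; filler terms hang off random existing terms
    and annotate random gene subsets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    genes = sorted(truth.cardiac_genes | truth.regulator_genes |
                   {g for _, g in truth.true_pairs()} |
                   {g for _, g in truth.decoy_interactions})
    terms = [ROOT_TERM, HEART_TERM]
    edges = [(HEART_TERM, ROOT_TERM)]
    direct: dict[str, set[str]] = {ROOT_TERM: set(),
                                   HEART_TERM: set(truth.cardiac_genes)}
    for i in range(n_filler_terms):
        term = f"T:filler{i:03d}"
        parent = terms[int(rng.integers(len(terms)))]
        terms.append(term)
        edges.append((term, parent))
        if genes:
            size = int(rng.integers(5, max(6, min(50, len(genes)))))
            direct[term] = set(rng.choice(genes, size=min(size, len(genes)),
                                          replace=False))
        else:
            direct[term] = set()
    return OntologyDAG(terms=terms, edges=edges, direct_annotations=direct)


def write_fixture_set(outdir: str | Path, config: SimulationConfig,
                      n_filler_terms: int = 30) -> TruthSet:
    """Generate the full fixture file set into ``outdir``.

    Writes per-study expression and sample-sheet TSVs, one interaction TSV
    per resource, ontology edge and annotation TSVs, a regulator-gene list
    and the truth JSON.  Byte-identical for identical configs.
    """
    from . import io as mio  # local import to avoid a cycle

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vt_m, vt_mi, vv_m, vv_mi, truth = simulate_study_pair(config)
    for tag, study in [("vitro_mrna", vt_m), ("vitro_mirna", vt_mi),
                       ("vivo_mrna", vv_m), ("vivo_mirna", vv_mi)]:
        mio.write_expression_tsv(study, out / f"{tag}.tsv", out / f"{tag}.samples.tsv")
    for table in simulate_resources(truth, config):
        mio.write_interaction_tsv(table, out / f"{table.name}.tsv")
    dag = simulate_ontology(truth, n_filler_terms=n_filler_terms, seed=config.seed)
    mio.write_ontology_tsv(dag, out / "ontology_edges.tsv", out / "ontology_annotations.tsv")
    (out / "regulators.txt").write_text(
        "\n".join(sorted(truth.regulator_genes)) + "\n")
    (out / "heart_genes.txt").write_text(
        "\n".join(sorted(truth.cardiac_genes)) + "\n")
    truth.to_json(out / "truth.json")
    (out / "config.json").write_text(json.dumps(asdict(config), sort_keys=True, indent=1))
    return truth
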