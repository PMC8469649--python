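"""Planted-truth benchmarks: recovery, precision and calibration measures.

Each function regenerates synthetic data under the benchmark's study
conditions, runs the relevant stage(s) of the screen, and scores the result
against the generator's truth records.  They are used both by the test
suite and by the reproduction script, so the numbers those report are
always recomputed from scratch.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from . import conservation as cons
from . import interactions as mi
from .diffexpr import _moderated_t_matrix, bh_adjust, estimate_prior
from .enrichment import OntologyDAG, conditional_enrichment, propagate_annotations
from .peaks import call_peaks
from .simulate import SimulationConfig, simulate_resources, simulate_study_pair


def peak_recovery(seeds: Sequence[int]) -> dict[str, float]:
    """Planted-peak benchmark: 200 miRNAs, 20 peaked per day on a 5-day
    grid, peak amplitude 4 log2 units, replicate noise sd 0.3, 3 replicates,
    call threshold r >= 0.6.

    Returns correct-day recovery among peaked miRNAs and the false-call
    rate among flat miRNAs, pooled over the seeds.
    """
    n_correct = n_peaked = n_false = n_flat = 0
    for seed in seeds:
        cfg = SimulationConfig(n_mirnas=200, n_genes=50, frac_peaked_mirnas=0.1,
                               peak_amplitude=4.0, noise_sd=0.3, n_replicates=3,
                               n_true_interactions=0, n_decoy_interactions=0,
                               seed=int(seed))
        _, vt_mirna, _, _, truth = simulate_study_pair(cfg)
        called = {c.mirna_id: c.peak_day for c in call_peaks(vt_mirna, r_min=0.6)}
        n_correct += sum(called.get(m) == d for m, d in truth.peaked_mirnas.items())
        n_peaked += len(truth.peaked_mirnas)
        flat = [m for m in vt_mirna.feature_ids if m not in truth.peaked_mirnas]
        n_false += sum(m in called for m in flat)
        n_flat += len(flat)
    return {"recovery": n_correct / n_peaked, "false_call_rate": n_false / n_flat,
            "n_peaked": n_peaked, "n_flat": n_flat}


def interaction_chain_recovery(seeds: Sequence[int]) -> dict[str, float]:
    """Planted-interaction benchmark: 50 conserved repressive pairs plus
    500 decoys per seed; full chain merge -> restrict -> correlate ->
    intersect -> select_conserved.  Returns seed-averaged recall/precision.
    """
    recalls, precisions = [], []
    for seed in seeds:
        cfg = SimulationConfig(seed=int(seed))  # defaults are the conditions
        vt_m, vt_mi_, vv_m, vv_mi_, truth = simulate_study_pair(cfg)
        merged = mi.merge_resources(simulate_resources(truth, cfg))
        annotated = {}
        for tag, (mir, mrna) in {"vitro": (vt_mi_, vt_m),
                                 "vivo": (vv_mi_, vv_m)}.items():
            restricted = mi.restrict_to_expressed(
                merged, set(mir.feature_ids), set(mrna.feature_ids))
            annotated[tag] = mi.annotate_correlations(restricted, mir, mrna)
        candidates = cons.intersect_studies(annotated["vitro"], annotated["vivo"])
        conserved = cons.select_conserved(candidates)
        found = set(zip(conserved["mirna_id"], conserved["gene_id"]))
        planted = truth.conserved_pairs()
        tp = len(found & planted)
        recalls.append(tp / len(planted))
        precisions.append(tp / len(found) if found else 0.0)
    return {"recall": float(np.mean(recalls)),
            "precision": float(np.mean(precisions)), "n_seeds": len(list(seeds))}


def de_null_fdp(seeds: Sequence[int], n_features: int = 5000,
                n_rep: int = 3) -> dict[str, float]:
    """Pure-null DE calibration: per seed, the false discovery proportion at
    BH-adjusted p < 0.05 (all discoveries are false by construction).
    """
    fdps = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        A = rng.normal(0.0, 1.0, size=(n_features, n_rep))
        B = rng.normal(0.0, 1.0, size=(n_features, n_rep))
        d = 2 * n_rep - 2
        s2 = (((A - A.mean(1, keepdims=True)) ** 2).sum(1)
              + ((B - B.mean(1, keepdims=True)) ** 2).sum(1)) / d
        d0, s0 = estimate_prior(s2, d)
        _, _, p = _moderated_t_matrix(A, B, d0, s0)
        n_disc = int((bh_adjust(p) < 0.05).sum())
        fdps.append(1.0 if n_disc > 0 else 0.0)
    return {"mean_fdp": float(np.mean(fdps)), "n_seeds": len(list(seeds))}


def de_planted_sensitivity(seed: int, n_features: int = 5000,
                           n_planted: int = 250, lfc: float = 4.0,
                           sd: float = 0.1, n_rep: int = 3) -> dict[str, float]:
    """Planted-effect DE benchmark: |log2fc| = 4 at noise sd 0.1, 3 vs 3.

    Sensitivity is scored at (adjusted p < 1e-3, |log2fc| > 2); the
    companion count is null features flagged at the stringent 1e-5 level.
    """
    rng = np.random.default_rng(int(seed))
    planted = np.zeros(n_features, dtype=bool)
    planted[:n_planted] = True
    A = rng.normal(0.0, sd, size=(n_features, n_rep))
    B = rng.normal(0.0, sd, size=(n_features, n_rep))
    A[planted] += lfc
    d = 2 * n_rep - 2
    s2 = (((A - A.mean(1, keepdims=True)) ** 2).sum(1)
          + ((B - B.mean(1, keepdims=True)) ** 2).sum(1)) / d
    d0, s0 = estimate_prior(s2, d)
    _, _, p = _moderated_t_matrix(A, B, d0, s0)
    p_adj = bh_adjust(p)
    delta = A.mean(1) - B.mean(1)
    flagged = (p_adj < 1e-3) & (np.abs(delta) > 2.0)
    strict = (p_adj < 1e-5) & (np.abs(delta) > 2.0)
    return {"sensitivity": float(flagged[planted].mean()),
            "null_flags_strict": int(strict[~planted].sum()),
            "n_planted": n_planted}


def enrichment_null_rate(seeds: Sequence[int], n_terms: int = 100,
                         n_genes: int = 1500, n_selected: int = 150
                         ) -> dict[str, float]:
    """Null ontology calibration: random annotations, random selection;
    fraction of term tests with p <= 0.01 (nominal 1%).
    """
    n_sig = n_tests = 0
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        genes = [f"g{i}" for i in range(n_genes)]
        terms = [f"t{i}" for i in range(n_terms)]
        direct = {"root": set()}
        edges = []
        for t in terms:
            size = int(rng.integers(20, 200))
            direct[t] = set(rng.choice(genes, size=size, replace=False))
            edges.append((t, "root"))
        dag = propagate_annotations(OntologyDAG(
            terms=["root"] + terms, edges=edges, direct_annotations=direct))
        universe = set().union(*dag.propagated_annotations.values())
        selected = set(rng.choice(sorted(universe), size=n_selected,
                                  replace=False))
        results = conditional_enrichment(dag, selected, universe)
        leaf = [r for r in results if r.term != "root"]
        n_tests += len(leaf)
        n_sig += sum(r.p_value <= 0.01 for r in leaf)
    return {"fraction_significant": n_sig / n_tests, "n_tests": n_tests}
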