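"""Cross-study conservation filter and miRNA prioritisation.

Interactions annotated in both studies are kept when |tau_vitro -
tau_vivo| < 0.2 and tau < -0.2 in both; survivors are restricted to the
heart-development-like gene set and aggregated per miRNA.  The final table
is scored against the planted conserved pairs.
"""

import pandas as pd

from common import FIXTURE, RESULTS, SCRATCH, ensure_fixture
from mirswitch.conservation import (intersect_studies, rank_mirnas,
                                    restrict_gene_set, select_conserved,
                                    summarize_run)
from mirswitch.io import read_gene_list

truth = ensure_fixture()
vitro = pd.read_csv(SCRATCH / "04_correlations_vitro.tsv", sep="\t")
vivo = pd.read_csv(SCRATCH / "04_correlations_vivo.tsv", sep="\t")

candidates = intersect_studies(vitro, vivo)
heart = read_gene_list(FIXTURE / "heart_genes.txt")
in_set = restrict_gene_set(candidates, heart)
conserved = select_conserved(in_set, delta_max=0.2, tau_max=-0.2)
n, n_mir, n_gene = summarize_run(conserved)
print(f"{len(candidates)} overlapping -> {len(in_set)} in the heart-like set "
      f"-> {n} conserved pairs linking {n_mir} miRNAs to {n_gene} genes")

found = set(zip(conserved["mirna_id"], conserved["gene_id"]))
planted = truth.conserved_pairs()
tp = len(found & planted)
print(f"planted-truth score: recall {tp / len(planted):.2f}, "
      f"precision {tp / len(found):.2f}")

conserved.to_csv(RESULTS / "05_conserved.tsv", sep="\t", index=False,
                 float_format="%.6g")
priority = rank_mirnas(conserved, read_gene_list(FIXTURE / "regulators.txt"))
priority.to_csv(RESULTS / "05_mirna_priority.tsv", sep="\t", index=False)
print("top regulator-reaching miRNAs:")
print(priority.head(5).to_string(index=False))
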