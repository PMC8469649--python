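"""Merge the candidate interaction resources and screen by anti-correlation.

Five partially overlapping resources are merged over (miRNA, gene)
identity, restricted to features expressed in each study, and every
surviving interaction is annotated with the Kendall tau of its miRNA and
target day-mean profiles.  The count trail merged -> expressed ->
anti-correlated (tau < -0.2) is the screen's funnel.
"""

import pandas as pd

from common import RESULTS, SCRATCH, ensure_fixture, load_study, resource_paths
from mirswitch.interactions import (annotate_correlations, filter_anticorrelated,
                                    merge_resources, read_interaction_tsv,
                                    restrict_to_expressed)

ensure_fixture()
tables = [read_interaction_tsv(p) for p in resource_paths()]
merged = merge_resources(tables)
print(f"merged {len(tables)} resources -> {len(merged)} unique interactions")

rows = []
for exp in ("vitro", "vivo"):
    mir = load_study(f"{exp}_mirna")
    mrna = load_study(f"{exp}_mrna")
    restricted = restrict_to_expressed(merged, set(mir.feature_ids),
                                       set(mrna.feature_ids))
    annotated = annotate_correlations(restricted, mir, mrna)
    anti = filter_anticorrelated(annotated, tau_max=-0.2)
    annotated.to_csv(SCRATCH / f"04_correlations_{exp}.tsv", sep="\t",
                     index=False, float_format="%.6g")
    rows.append({"study": exp, "merged": len(merged),
                 "expressed": len(restricted), "annotated": len(annotated),
                 "anticorrelated": len(anti)})
    print(f"{exp}: {len(restricted)} expressed -> {len(annotated)} annotated "
          f"-> {len(anti)} with tau < -0.2")
pd.DataFrame(rows).to_csv(RESULTS / "04_interaction_funnel.tsv", sep="\t",
                          index=False)
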