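import numpy as np
import pandas as pd
import pytest

from mirswitch.expression import ExpressionStudy


def build_study(day_values: dict, feature_kind: str = "mRNA",
                probe_to_feature=None, prefix: str = "s") -> ExpressionStudy:
    """Build a study from {feature_id: {day: [replicate values]}}.

    Every feature must list the same days with the same replicate counts.
    """
    features = list(day_values)
    days = sorted(next(iter(day_values.values())))
    rows = []
    columns = []
    samples = []
    for day in days:
        n_rep = len(day_values[features[0]][day])
        for r in range(n_rep):
            columns.append(f"{prefix}_d{day:g}_r{r + 1}")
            samples.append({"sample_id": columns[-1], "day": float(day),
                            "replicate": r + 1})
    for f in features:
        row = []
        for day in days:
            row.extend(day_values[f][day])
        rows.append(row)
    values = pd.DataFrame(np.asarray(rows, dtype=float), index=features,
                          columns=columns)
    return ExpressionStudy(values=values, samples=pd.DataFrame(samples),
                           feature_kind=feature_kind,
                           probe_to_feature=probe_to_feature)


@pytest.fixture
def simple_study():
    """Three features, three days, two replicates each."""
    return build_study({
        "f1": {0: [4.0, 4.0], 4: [6.0, 6.4], 8: [4.1, 4.1]},
        "f2": {0: [4.9, 4.9], 4: [4.9, 4.9], 8: [4.9, 4.9]},
        "f3": {0: [5.0, 5.0], 4: [5.0, 5.0], 8: [5.0, 5.0]},
    })


@pytest.fixture(scope="session")
def noiseless_sim():
    """A noise-free paired simulation whose planted structure is exact."""
    from mirswitch.simulate import SimulationConfig, simulate_study_pair

    cfg = SimulationConfig(n_genes=80, n_mirnas=30, noise_sd=0.0,
                           n_true_interactions=12, n_decoy_interactions=40,
                           frac_peaked_mirnas=0.1, seed=7)
    return cfg, simulate_study_pair(cfg)
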