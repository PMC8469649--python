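"""Shared plumbing for the numbered analysis drivers.

The drivers all work on one deterministic synthetic fixture (seed 0,
generator defaults) kept under ``scratch/fixture``; bulky per-stage TSVs
also live under ``scratch/`` while the small summary tables the analysis
reports land in ``results/``.
"""

from pathlib import Path

from mirswitch import io as mio
from mirswitch.expression import filter_expressed
from mirswitch.simulate import SimulationConfig, TruthSet, write_fixture_set

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
FIXTURE = SCRATCH / "fixture"
RESULTS = ROOT / "results"
SEED = 0


def ensure_fixture() -> TruthSet:
    if not (FIXTURE / "truth.json").exists():
        write_fixture_set(FIXTURE, SimulationConfig(seed=SEED))
    return TruthSet.from_json(FIXTURE / "truth.json")


def load_study(tag: str, floor: float | None = 5.0):
    kind = "miRNA" if "mirna" in tag else "mRNA"
    study = mio.read_expression_tsv(FIXTURE / f"{tag}.tsv",
                                    FIXTURE / f"{tag}.samples.tsv",
                                    feature_kind=kind)
    return filter_expressed(study, floor) if floor is not None else study


def resource_paths() -> list[Path]:
    return sorted(FIXTURE.glob("resource*.tsv"))
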