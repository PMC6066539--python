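import numpy as np
import pandas as pd
import pytest

from stressmem.config import StageDesign
from stressmem.io import ExpressionStudy
from stressmem.simulate import ModulePlan, SimulationSpec, simulate_expression


def make_study(fpkm, stages, genes=None) -> ExpressionStudy:
    """Build a small ExpressionStudy from an array and per-column stage labels."""
    fpkm = np.asarray(fpkm, dtype=float)
    genes = genes or [f"g{i}" for i in range(fpkm.shape[0])]
    reps: dict[str, int] = {}
    names = []
    for s in stages:
        reps[s] = reps.get(s, 0) + 1
        names.append(f"{s}_r{reps[s]}")
    mat = pd.DataFrame(fpkm, index=genes, columns=names)
    sheet = pd.DataFrame(
        {"stage": stages, "replicate": [int(n.split("_r")[1]) for n in names]},
        index=pd.Index(names, name="sample"),
    )
    return ExpressionStudy(mat, sheet, StageDesign())


@pytest.fixture
def six_sample_stages():
    return ["W", "W", "S1", "S1", "S3", "S3"]


@pytest.fixture(scope="session")
def small_sim():
    """A down-scaled planted simulation shared by several suites."""
    spec = SimulationSpec(
        n_genes=400,
        modules=(
            ModulePlan(40, (6.0, 8.0, 10.0), "[+/+]"),
            ModulePlan(40, (6.0, 6.0, 8.0), "[=/+]"),
            ModulePlan(40, (6.0, 4.0, 4.0), "[-/=]"),
        ),
        enrichment_plan=((1, "GO:0001", 8.0), (2, "GO:0002", 8.0)),
        seed=7,
    )
    study, truth = simulate_expression(spec)
    return spec, study, truth
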