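import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import orgscreen as og

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_sheet() -> og.SampleSheet:
    return og.SampleSheet.default_design()


@pytest.fixture(scope="session")
def default_config() -> og.PipelineConfig:
    return og.PipelineConfig()


@pytest.fixture(scope="session")
def small_simulation(default_sheet, default_config):
    """A modest planted simulation shared by read-only tests."""
    params = og.PlantedSignatureParams(n_genes=1_000, n_decoy=50)
    matrix, truth = og.simulate_expression(
        default_sheet, params, default_config.expression, seed=11
    )
    return params, matrix, truth


@pytest.fixture
def toy_signature() -> og.SignatureSet:
    enriched = tuple(f"E{i:02d}" for i in range(1, 32))
    depleted = tuple(f"D{i:02d}" for i in range(1, 18))
    return og.SignatureSet(enriched, depleted)


def make_matrix(values: dict[str, dict[str, list[float]]]) -> og.ExpressionMatrix:
    """Build a tiny ExpressionMatrix from {group: {gene: replicate values}}."""
    groups = list(values)
    genes = list(next(iter(values.values())))
    rows = []
    for g in groups:
        n_rep = len(values[g][genes[0]])
        for r in range(1, n_rep + 1):
            rows.append({"sample_id": f"{g}_r{r}", "group": g, "replicate": r})
    sheet = og.SampleSheet(pd.DataFrame(rows))
    data = {
        f"{g}_r{r}": [values[g][gene][r - 1] for gene in genes]
        for g in groups
        for r in range(1, len(values[g][genes[0]]) + 1)
    }
    frame = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    return og.ExpressionMatrix(frame[sheet.sample_ids], sheet)


@pytest.fixture
def toy_3v3_matrix() -> og.ExpressionMatrix:
    """Two groups x 3 replicates, 3 genes, hand-checkable numbers."""
    return make_matrix(
        {
            "A": {
                "g1": [5.0, 5.2, 5.4],
                "g2": [8.0, 8.0, 8.0],
                "g3": [2.0, 2.5, 3.0],
            },
            "B": {
                "g1": [3.0, 3.1, 3.2],
                "g2": [8.0, 8.0, 8.0],
                "g3": [2.2, 2.4, 2.9],
            },
        }
    )
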