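import numpy as np
import pandas as pd
import pytest

from toxpipe.model_io import (
    ExpressionMatrix,
    MetabolicModel,
    Metabolite,
    Reaction,
)


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    """3 genes x 4 samples: one treated condition (2 reps) vs control (2 reps)."""
    values = pd.DataFrame(
        {
            "t1": [5.0, 2.0, 7.0],
            "t2": [5.2, 2.2, 7.2],
            "c1": [3.0, 2.0, 7.1],
            "c2": [3.2, 2.4, 7.3],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["t1", "t2", "c1", "c2"],
            "chemical": ["chemX"] * 4,
            "dose_level": ["high", "high", "control", "control"],
            "duration": ["24h"] * 4,
            "test_system": ["rat_in_vivo"] * 4,
            "replicate": [1, 2, 1, 2],
            "control_group": ["chemX|24h|ctrl"] * 4,
        }
    ).set_index("sample_id")
    return ExpressionMatrix(values=values, metadata=meta)


@pytest.fixture
def chain_model() -> MetabolicModel:
    """Uptake A (lb=-10) -> A->B -> secrete B; hand-solvable demands."""
    return MetabolicModel(
        metabolites=[
            Metabolite("A", "A", exchangeable=False),
            Metabolite("B", "B", exchangeable=True),
        ],
        reactions=[
            Reaction("EX_A", "uptake A", -10.0, 0.0, "", {"A": -1.0}),
            Reaction("R_AB", "A to B", 0.0, 1000.0, "g1", {"A": -1.0, "B": 1.0}),
            Reaction("EX_B", "secrete B", 0.0, 1000.0, "", {"B": -1.0}),
        ],
    )


@pytest.fixture
def parallel_model() -> MetabolicModel:
    """Two parallel A->B routes; the weighted demand should pick the cheap one."""
    return MetabolicModel(
        metabolites=[
            Metabolite("A", "A", exchangeable=False),
            Metabolite("B", "B", exchangeable=True),
        ],
        reactions=[
            Reaction("EX_A", "uptake A", -10.0, 0.0, "", {"A": -1.0}),
            Reaction("R1", "cheap", 0.0, 1000.0, "g1", {"A": -1.0, "B": 1.0}),
            Reaction("R2", "costly", 0.0, 1000.0, "g2", {"A": -1.0, "B": 1.0}),
            Reaction("EX_B", "secrete B", 0.0, 1000.0, "", {"B": -1.0}),
        ],
    )
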