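import numpy as np
import pandas as pd
import pytest

from ontosex.core_io import STAGES, ExpressionMatrix


def make_matrix(rows: dict[str, list[float]], n_reps: int = 3) -> ExpressionMatrix:
    """Build an ExpressionMatrix from gene -> flat replicate list.

    The list is ordered stage-major (all replicates of L1, then L2-3, ...);
    use float('nan') for missing cells.
    """
    columns = pd.MultiIndex.from_tuples(
        [(s, r + 1) for s in STAGES for r in range(n_reps)],
        names=["stage", "replicate"],
    )
    data = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    data.columns = columns
    data.index.name = "gene"
    return ExpressionMatrix(data)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 5 stages x 3 replicates, fully observed."""
    rng = np.random.default_rng(42)
    return make_matrix(
        {
            "g1": list(rng.normal(0, 0.1, 15)),
            "g2": list(np.repeat([2.0, 2.0, 0.0, 0.0, 0.0], 3) + rng.normal(0, 0.1, 15)),
            "g3": list(np.repeat([0.0, 0.0, 0.0, -1.5, -2.5], 3) + rng.normal(0, 0.1, 15)),
        }
    )
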