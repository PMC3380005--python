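import numpy as np
import pandas as pd
import pytest

from mirnorm import ExpressionMatrix, SimulationConfig


@pytest.fixture
def worked_rq() -> pd.DataFrame:
    """Three-gene RQ toy: A doubles, B doubles at twice the level, C is flat."""
    return pd.DataFrame(
        {"s1": [1.0, 2.0, 1.0], "s2": [2.0, 4.0, 1.0], "s3": [4.0, 8.0, 1.0]},
        index=["A", "B", "C"],
    )


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Near-noiseless study design: no loading, no deregulation, one run."""
    return SimulationConfig(
        loading_sd=0.0,
        replicate_cv_pct_range=(1e-9, 1e-9),
        run_offset_sd=0.0,
        n_runs=1,
        deregulated_spec={},
        n_stable=14,
        seed=7,
    )


def toy_expression_matrix(
    n_genes: int = 10,
    per_group: int = 8,
    seed: int = 0,
    all_present: bool = True,
) -> ExpressionMatrix:
    """Random linear-scale matrix over the 3-group design for filter tests."""
    rng = np.random.default_rng(seed)
    samples = [f"a{i}" for i in range(3 * per_group)]
    groups = pd.Series(
        ["nonmalignant"] * per_group + ["low_grade"] * per_group + ["high_grade"] * per_group,
        index=samples,
    )
    genes = [f"g{i}" for i in range(n_genes)]
    intensities = pd.DataFrame(
        2.0 ** rng.normal(8.0, 1.0, (n_genes, len(samples))), index=genes, columns=samples
    )
    if all_present:
        flags = pd.DataFrame(True, index=genes, columns=samples)
    else:
        flags = pd.DataFrame(
            rng.random((n_genes, len(samples))) > 0.1, index=genes, columns=samples
        )
    return ExpressionMatrix(intensities=intensities, flags=flags, groups=groups)
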