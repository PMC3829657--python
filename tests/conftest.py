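import numpy as np
import pandas as pd
import pytest

import coldnet as cn


@pytest.fixture
def small_expression():
    """3 genes x 4 samples with complete metadata (1 ecotype, 2+2 reps)."""
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    metadata = pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3", "s4"],
            "ecotype": ["Col-0"] * 4,
            "treatment": ["control", "control", "cold", "cold"],
            "replicate": [1, 2, 1, 2],
        }
    ).set_index("sample")
    return cn.ExpressionMatrix(values=values, metadata=metadata)


@pytest.fixture
def compliant_truth():
    """Noiseless forward model on a compliant 50x5 pattern, 12 conditions."""
    pattern, strengths = cn.generate_connectivity(50, 5, out_degree=12, seed=11)
    activities = cn.generate_activities(
        5, 12, seed=11, tf_ids=pattern.tf_ids,
        condition_ids=[f"c{i}" for i in range(12)],
    )
    truth = cn.GroundTruth(
        connectivity=pattern, control_strengths=strengths,
        activities=activities, noise_sd=0.0, seed=11,
    )
    return truth, cn.simulate_expression(truth)
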