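import numpy as np
import pandas as pd
import pytest

from pairprompt import GeneratorConfig, GraphPromptModel, generate_benchmark
from pairprompt.encoder import BaseReadouts


def make_base(rep: np.ndarray, rep_mean: np.ndarray | None = None) -> BaseReadouts:
    """BaseReadouts wrapper around hand-set node representations."""
    rep = np.asarray(rep, dtype=float)
    return BaseReadouts(
        rep=rep,
        rep_mean=rep if rep_mean is None else np.asarray(rep_mean, float),
        rep_dim=rep.shape[1],
        delta=1,
        encoder_digest="manual",
    )


def interactions_frame(rows):
    """Rows of (a_id, a_type, b_id, b_type, itype[, label]) -> schema frame."""
    out = []
    for row in rows:
        rec = dict(
            entity_a_id=row[0], entity_a_type=row[1],
            entity_b_id=row[2], entity_b_type=row[3],
            interaction_type=row[4],
        )
        if len(row) > 5:
            rec["label"] = row[5]
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        entity_counts={"drug": 20, "protein": 26, "disease": 16, "side_effect": 14},
        pairs_per_task=100,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_benchmark(small_config):
    return generate_benchmark(small_config)


@pytest.fixture(scope="session")
def small_model(small_benchmark):
    return GraphPromptModel.from_benchmark(small_benchmark)


@pytest.fixture(scope="session")
def small_results(small_model):
    """A briefly pre-trained encoder over the small benchmark."""
    return small_model.fit(epochs=30, seed=11)
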