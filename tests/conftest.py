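import numpy as np
import pandas as pd
import pytest

from radiomix.features import extract_cohort_from_volumes
from radiomix.synthetic import (
    BODY_WEIGHT_G,
    INJECTED_KBQ,
    CohortSpec,
    generate_cohort,
)


def random_discretized(rng, max_side=8, max_levels=6):
    """A random small masked level grid for oracle comparisons."""
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[0, 0, 0] = True
    ng = int(rng.integers(2, max_levels + 1))
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    # guarantee the top level occurs so Ng is well defined
    idx = np.argwhere(mask)[0]
    levels[tuple(idx)] = ng
    return levels, mask


@pytest.fixture(scope="session")
def default_cohort():
    """Default 3-group synthetic cohort (n=90) with its extracted features."""
    spec = CohortSpec(seed=20260922)
    manifest, clinical, truth, volumes = generate_cohort(spec)
    features = extract_cohort_from_volumes(
        volumes, body_weight_g=BODY_WEIGHT_G, injected_activity_kBq=INJECTED_KBQ
    )
    groups = pd.Series(
        {tid: truth["group_labels"][tid] for tid in features.index}, name="group"
    )
    return {
        "spec": spec,
        "manifest": manifest,
        "clinical": clinical,
        "truth": truth,
        "features": features,
        "groups": groups,
    }
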