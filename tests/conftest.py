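import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_beta_table():
    """Hand-written beta table: 1 ROI, 3 voxels, 2 subjects, 2 presentations,
    2 images — small enough to verify aggregation by hand."""
    rows = []
    betas = {
        # (subject, image, presentation) -> voxel betas
        ("sub1", 0, 1): [0.1, -0.2, 0.3],   # sum 0.2
        ("sub1", 0, 2): [0.2, 0.1, 0.1],    # sum 0.4 -> repeat avg 0.3
        ("sub1", 1, 1): [0.5, 0.0, 0.0],
        ("sub1", 1, 2): [0.1, 0.2, 0.0],
        ("sub2", 0, 1): [0.3, 0.1, 0.1],    # sum 0.5
        ("sub2", 0, 2): [0.2, 0.2, 0.1],    # sum 0.5 -> repeat avg 0.5
        ("sub2", 1, 1): [0.0, 0.0, 0.1],
        ("sub2", 1, 2): [0.2, 0.1, 0.0],
    }
    for (subj, img, pres), vals in betas.items():
        for v, b in enumerate(vals):
            rows.append({"subject": subj, "image": img, "presentation": pres,
                         "roi": "PPA", "voxel": f"PPA_v{v}", "beta": b})
    return pd.DataFrame(rows)
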