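import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import latproteo as lp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

GWS = (9, 11, 13)
SAMPLES = [f"{h}{gw:02d}" for gw in GWS for h in ("L", "R")]


def make_dm(values, protein_ids=None, gws=GWS) -> lp.DesignedMatrix:
    """DesignedMatrix from an (n x 2T) array ordered L,R per ascending gw."""
    values = np.asarray(values, float)
    n = values.shape[0]
    ids = protein_ids or [f"P{i:03d}" for i in range(n)]
    samples = [f"{h}{gw:02d}" for gw in gws for h in ("L", "R")]
    intens = pd.DataFrame(values, index=pd.Index(ids, name="protein_group_id"), columns=samples)
    meta = pd.DataFrame({"gene_name": ids, "majority_ids": ids}, index=intens.index)
    design = lp.SampleDesign.from_mapping(
        {f"{h}{gw:02d}": (h, gw) for gw in gws for h in ("L", "R")}
    )
    return lp.join_design(lp.QuantMatrix(intens, meta), design)


@pytest.fixture(scope="session")
def small():
    """Deterministic <=200-protein synthetic study with every truth label planted."""
    return lp.fixture_small(7)


@pytest.fixture(scope="session")
def small_dm(small):
    matrix, design, _ = small
    return lp.join_design(matrix, design)


@pytest.fixture(scope="session")
def small_core(small_dm):
    det = lp.detection_sets(small_dm)
    return lp.log2_normalize(small_dm, det.core)
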