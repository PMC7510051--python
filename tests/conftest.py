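import numpy as np
import pandas as pd
import pytest

from fungalscape.io import OtuTable
from fungalscape.synthetic import SurveyConfig, generate_survey


@pytest.fixture(scope="session")
def small_survey():
    """Medium synthetic survey with injected artifacts, shared across tests."""
    return generate_survey(SurveyConfig(n_plots=120, n_otus=150, seed=7))


@pytest.fixture(scope="session")
def spoilage_survey():
    """200-plot survey with 10% spoilage for QC recall/specificity checks."""
    return generate_survey(
        SurveyConfig(n_plots=200, n_otus=200, frac_spoiled=0.10, seed=11)
    )


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        [[10, 0, 3], [2, 5, 1], [0, 0, 7]],
        index=["s1", "s2", "s3"],
        columns=["OTU1", "OTU2", "OTU3"],
    )
    return OtuTable(counts)


def make_qc_fixture():
    """Ten-sample fixture: 1 control, 1 shallow sample, 1 mold-spoiled sample.

    Built so that the filter chain's stage-wise sample counts are forced:
    10 initial, 9 after control removal, 8 after the depth filter, 8 through
    the OTU blocklist stages, 7 after mold flagging.
    """
    rng = np.random.default_rng(1)
    samples = [f"p{i}" for i in range(1, 10)] + ["ctrl"]
    otus = ["OTU_norm1", "OTU_norm2", "OTU_pez", "OTU_umb", "OTU_block"]
    counts = pd.DataFrame(0, index=samples, columns=otus)
    for s in samples[:9]:
        counts.loc[s, "OTU_norm1"] = 600
        counts.loc[s, "OTU_norm2"] = 350
        counts.loc[s, "OTU_pez"] = 30
        counts.loc[s, "OTU_block"] = 20
    counts.loc["p2"] = [250, 120, 20, 0, 10]  # 400 reads: below depth cutoff
    # p3: Pezizomycotina mold OTU at 35% of the post-blocklist total
    counts.loc["p3"] = [500, 150, 350, 0, 40]
    # p4: Umbelopsidales at exactly 15% post-blocklist: boundary, retained
    counts.loc["p4"] = [700, 150, 0, 150, 25]
    counts.loc["ctrl"] = [5, 3, 0, 0, 0]
    metadata = pd.DataFrame(
        {"control_flag": [s == "ctrl" for s in samples]}, index=samples
    )
    assignments = pd.DataFrame(
        {
            "mold_group": ["", "", "Pezizomycotina_mold", "Umbelopsidales", ""],
        },
        index=otus,
    )
    return OtuTable(counts), metadata, assignments
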