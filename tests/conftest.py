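import numpy as np
import pandas as pd
import pytest

from mirct.io_formats import (
    CtMatrix,
    Sample,
    SampleSheet,
    ENDOGENOUS_CONTROL,
    NEGATIVE_CONTROL,
)


@pytest.fixture
def small_ct() -> CtMatrix:
    """3 assays x 2 samples plus one endogenous and one negative control."""
    values = pd.DataFrame(
        {
            "s1": [20.0, 22.0, 24.0, 18.0, np.nan],
            "s2": [21.0, 23.0, 25.0, 18.2, np.nan],
        },
        index=pd.Index(["miR-a", "miR-b", "miR-c", "U6 rRNA", "ath-miR159a"], name="feature_id"),
    )
    return CtMatrix(
        values=values,
        control_flags={
            "U6 rRNA": ENDOGENOUS_CONTROL,
            "ath-miR159a": NEGATIVE_CONTROL,
        },
    )


@pytest.fixture
def four_group_sheet() -> SampleSheet:
    """Four genotype x treatment groups of three pooled samples each."""
    samples = []
    i = 0
    for genotype in ("wt", "P2rx7-KO"):
        for treatment in ("vehicle", "KA"):
            for _ in range(3):
                i += 1
                samples.append(
                    Sample(
                        sample_id=f"s{i:02d}",
                        genotype=genotype,
                        treatment=treatment,
                        pool_members=(f"a{2 * i - 1}", f"a{2 * i}"),
                    )
                )
    return SampleSheet(samples)
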