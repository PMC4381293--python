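import numpy as np
import pandas as pd
import pytest

from urinorm.io import CreatinineAssay, PeakTable, SampleSheet


@pytest.fixture
def tiny_peaks() -> PeakTable:
    """3 metabolites x 4 samples (2 subjects x 2 timepoints)."""
    values = pd.DataFrame(
        [[10.0, 2.0, 8.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [1.0, 3.0, 2.0, 6.0]],
        index=["creat", "m_flat", "m_var"],
        columns=["A_P1", "A_PT1", "B_P1", "B_PT1"],
    )
    ann = pd.DataFrame(
        {"name": ["creatinine", "flat", "variable"],
         "mass": [113.050, 200.0, 300.0],
         "rt": [10.1, 5.0, 6.0]},
        index=values.index,
    )
    return PeakTable(values, ann)


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet(pd.DataFrame(
        {"subject_id": ["A", "A", "B", "B"],
         "timepoint_label": ["P1", "PT1", "P1", "PT1"]},
        index=pd.Index(["A_P1", "A_PT1", "B_P1", "B_PT1"], name="sample_id"),
    ))


@pytest.fixture
def tiny_assay() -> CreatinineAssay:
    return CreatinineAssay(pd.Series(
        {"A_P1": 2.0, "A_PT1": 1.0, "B_P1": 4.0, "B_PT1": 2.0}))


@pytest.fixture
def three_subject_sheet() -> SampleSheet:
    """3 subjects x the full 10-collection design."""
    labels = ["P1", "P2", "PT1", "PT2", "PT3", "PT4", "PT5", "PT6", "PT7", "PT8"]
    rows = [(f"S{k}_{lab}", f"S{k}", lab) for k in (1, 2, 3) for lab in labels]
    frame = pd.DataFrame(
        {"subject_id": [r[1] for r in rows], "timepoint_label": [r[2] for r in rows]},
        index=pd.Index([r[0] for r in rows], name="sample_id"))
    return SampleSheet(frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
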