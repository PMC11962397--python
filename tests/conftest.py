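import numpy as np
import pytest

from tcatrace.isocorrect import MID
from tcatrace.metrics import TissueClass, TissueSample


def make_mid(metabolite_id: str, fractions) -> MID:
    fr = np.asarray(fractions, dtype=float)
    return MID(metabolite_id, fr.size - 1, fr / fr.sum())


def make_sample(
    patient_id="P001",
    fragment_id=None,
    tissue_class=TissueClass.TUMOR,
    glucose_m6=0.5,
    **mid_fractions,
) -> TissueSample:
    """Build a TissueSample from keyword MID fraction vectors."""
    mids = {met: make_mid(met, fr) for met, fr in mid_fractions.items()}
    return TissueSample(
        patient_id=patient_id,
        fragment_id=fragment_id or f"{patient_id}-T1",
        tissue_class=tissue_class,
        mids=mids,
        glucose_m6=glucose_m6,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
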