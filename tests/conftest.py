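import numpy as np
import pytest

import somastab as st


@pytest.fixture(scope="session")
def small_cohort() -> st.Cohort:
    """Reduced cohort with residuals: 3 controls + 1 case, 4 voxels/segment."""
    spec = st.CohortSpec(n_controls=3, n_cases=1, seed=11, n_voxels=4 * 49)
    effects = st.CaseEffects(onset_session="Post3m", lip_shift_segments=3.0)
    return st.simulate_cohort(spec, case_effects=effects)


@pytest.fixture(scope="session")
def control_runs(small_cohort: st.Cohort):
    """One control's runs for the two pre sessions."""
    return {
        ses: small_cohort.runs_for("sub-01", ses) for ses in ("Pre1", "Pre2")
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_segmap() -> st.SegmentMap:
    """Two voxels per segment over a 6-segment strip."""
    return st.SegmentMap(
        voxel_ids=np.arange(12), segments=np.repeat(np.arange(1, 7), 2),
        n_segments=6,
    )
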