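import numpy as np
import pytest

from denscan.data import Group, ReferenceGroup, SpecimenRecord, count_testable
from denscan.simulate import SyntheticConfig, generate_study, plant_denisovan_like

STUDY_SEED = 11


def reference_ids(records):
    return {
        ReferenceGroup.AMH: [r.specimen_id for r in records if r.group is Group.AMH],
        ReferenceGroup.NEANDERTHAL: [
            r.specimen_id for r in records if r.group is Group.NEANDERTHAL
        ],
    }


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 20/18/15 references, 10 null test subjects."""
    return generate_study(SyntheticConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def complete_study():
    """Fully observed study (no missingness) for the morphospace tests."""
    return generate_study(SyntheticConfig(seed=STUDY_SEED, missingness_rate=0.0))


@pytest.fixture(scope="session")
def planted_study(study):
    """Default study plus one Denisovan-like specimen at the default 1.5-SD effect."""
    matrix, records, profile = study
    refs = reference_ids(records)
    planted = plant_denisovan_like(
        matrix,
        profile,
        1.5,
        refs[ReferenceGroup.AMH],
        rng=np.random.default_rng(STUDY_SEED + 1),
        specimen_id="PLANTED",
        reference_group_ids=refs,
    )
    rec = SpecimenRecord("PLANTED", Group.TEST)
    rec.n_testable = count_testable("PLANTED", profile, planted)
    return planted, list(records) + [rec], profile
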