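import pytest

from metriscore import (
    ApplicabilityProfile,
    load_instrument,
    resolve_applicability,
)
from metriscore.scoring import Assessment


@pytest.fixture(scope="session")
def instrument():
    return load_instrument()


@pytest.fixture
def all_on_profile():
    return ApplicabilityProfile(
        uses_segmentation=True,
        fully_automated_segmentation=True,
        uses_handcrafted_features=True,
        uses_tabular_features=True,
        uses_end_to_end_dl=True,
    )


def make_assessment(instrument, profile, fulfilled, study_id="study"):
    """Assessment with the given items fulfilled, consistent with profile."""
    applicable = resolve_applicability(instrument, profile)
    statuses = {}
    for item_id in instrument.item_ids:
        if item_id not in applicable:
            statuses[item_id] = "not_applicable"
        elif item_id in fulfilled:
            statuses[item_id] = "fulfilled"
        else:
            statuses[item_id] = "not_fulfilled"
    return Assessment(study_id=study_id, profile=profile, statuses=statuses)
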