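import numpy as np
import pytest

from reefeye import core_data
from reefeye.synthetic import generate, paper_like_preset


@pytest.fixture(scope="session")
def preset_tables():
    """One study-calibrated synthetic dataset shared across the suite.

    Returns (records, species-mean table, log-trait table).
    """
    records = generate(paper_like_preset(seed=20260924))
    species = core_data.species_means(records)
    logs = core_data.log_transform(species)
    return records, species, logs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_specimen(specimen_id="s1", species_id="sp1", family="Labridae",
                  diel_class="diurnal", standard_length=100.0,
                  body_mass=25.0, left=None, right=None):
    """Hand-rolled specimen with sane defaults for unit tests."""
    if left is None and right is None:
        left = core_data.EyeMeasurements(ed=10.0, al=9.5, ld=4.5,
                                         pdmax=5.0, pdmin=4.4)
        right = core_data.EyeMeasurements(ed=10.2, al=9.7, ld=4.6,
                                          pdmax=5.1, pdmin=4.5)
    return core_data.SpecimenRecord(
        specimen_id=specimen_id, species_id=species_id, family=family,
        diel_class=diel_class, standard_length=standard_length,
        body_mass=body_mass,
        left=left or core_data.EyeMeasurements(),
        right=right or core_data.EyeMeasurements(),
    )
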