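import numpy as np
import pytest

from ocellus.datamodel import Dataset, MorphometricRecord, SpecimenRecord
from ocellus.treekit import Phylogeny


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_tree():
    return Phylogeny.from_string("((A:1,B:1):1,C:2);")


def make_specimen(
    species="sp01",
    specimen="sp01_01",
    sl=50.0,
    present=True,
    n_eyespots=None,
):
    return SpecimenRecord(
        species_id=species,
        specimen_id=specimen,
        standard_length_mm=sl,
        eyespot_present=present,
        n_eyespots=n_eyespots,
    )


def make_morphometrics(specimen=None, **overrides):
    """A geometrically valid morphometric record (circular features)."""
    spec = specimen if specimen is not None else make_specimen()
    values = dict(
        eye_diameter_mm=8.0,
        pupil_diameter_mm=3.6,
        eyespot_diameter_mm=8.2,
        eyespot_pupil_diameter_mm=7.0,
        eye_area_mm2=50.0,
        pupil_area_mm2=10.0,
        eyespot_area_mm2=52.0,
        eyespot_pupil_area_mm2=38.0,
    )
    values.update(overrides)
    return MorphometricRecord(specimen=spec, **values)


def presence_dataset(n_species=5, per_species=4, rng=None):
    """Small presence/absence dataset with within-species transitions."""
    rng = rng if rng is not None else np.random.default_rng(0)
    ds = Dataset()
    for i in range(n_species):
        sp = f"sp{i:02d}"
        for j in range(per_species):
            sl = float(rng.uniform(15, 150))
            ds.records.append(
                make_specimen(sp, f"{sp}_{j:02d}", sl=sl, present=bool(sl < 80))
            )
    return ds
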