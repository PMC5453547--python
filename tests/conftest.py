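import numpy as np
import pytest

from barcodeaudit.records import AlignedSequence, SpecimenCollection, SpecimenRecord
from barcodeaudit.simulate import SimConfig, generate_library, random_template


def make_record(sid, species, seq, **kw):
    return SpecimenRecord(
        specimen_id=sid,
        species=species,
        sequence=AlignedSequence(seq) if seq is not None else None,
        **kw,
    )


@pytest.fixture(scope="session")
def template():
    return random_template(np.random.default_rng(123))


@pytest.fixture(scope="session")
def default_library():
    """One shared synthetic library with planted truth (seed 7)."""
    return generate_library(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_library():
    cfg = SimConfig(
        seed=11, n_species=20, n_genera=8, n_families=2, mean_specimens=3.0,
        n_sharing_pairs=1, n_deep_splits=1, n_low_div_pairs=1, n_introduced=2,
    )
    return generate_library(cfg)


@pytest.fixture()
def four_species_collection(template):
    """Tiny hand-planted 4-species library for brute-force oracles."""
    rng = np.random.default_rng(5)
    from barcodeaudit.simulate import mutate_sequence

    a = mutate_sequence(template, 10, 3.0, rng)
    b = mutate_sequence(template, 25, 3.0, rng)
    c = mutate_sequence(a, 3, 3.0, rng)
    d = mutate_sequence(b, 40, 3.0, rng)
    records = []
    for i, (sp, founder) in enumerate(
        [("Aa x", a), ("Aa y", c), ("Bb z", b), ("Cc w", d)]
    ):
        for k in range(3):
            seq = mutate_sequence(founder, k, 3.0, rng)
            records.append(make_record(f"s{i}{k}", sp, seq, genus=sp.split()[0]))
    return SpecimenCollection(records)
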