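import numpy as np
import pytest

from ginsenolib import seed
from ginsenolib.chem import build_library


@pytest.fixture(scope="session")
def seed_library():
    """Negative-mode ion library built from the curated seed compounds."""
    return seed.seed_library()


@pytest.fixture(scope="session")
def marker_spectra():
    """Reference nominal-mass MS2 spectra of the eleven marker ginsenosides."""
    return {e.name: seed.marker_spectrum(e.name) for e in seed.GINSENOSIDE_MARKERS}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def distinct_mass_records():
    """Ten seed marker compounds whose formulas give unambiguous best matches."""
    names = [
        "notoginsenoside H",
        "glucoginsenoside Rf",
        "notoginsenoside R1",
        "pseudoginsenoside RT2",
        "chicusetsusaponin IVa",
        "malonylginsenoside Rd",
        "pseudoginsenoside Rc1",
        "malonylfloralginsenoside Rd6",
        "ginsenoside Rd",
        "malonylginsenoside Rb1",
    ]
    by_name = {r.name: r for r in seed.seed_records()}
    return [by_name[n] for n in names]


@pytest.fixture(scope="session")
def distinct_library(distinct_mass_records):
    return build_library(distinct_mass_records, polarities=("negative",))
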