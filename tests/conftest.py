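import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nmrbind import itc
from nmrbind.structure import ATOM_COLUMNS, AtomSet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

SON_25MER = "CGUAUCUUUAACUACUCAAGAUACG"


@pytest.fixture
def son_seq() -> str:
    return SON_25MER


@pytest.fixture
def itc_scheme() -> itc.TitrationScheme:
    """The study's titration layout: 100 uM cell, 1 mM syringe, 20 x 2 uL."""
    return itc.TitrationScheme(
        cell_volume=200.0, cell_conc=100.0, syringe_conc=1000.0,
        injection_volumes=(2.0,) * 20, temperature=298.0,
    )


def make_atomset(rows, coords) -> AtomSet:
    """rows: (chain, resnum, resname, atom_name, element) tuples."""
    return AtomSet(
        atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS),
        coords=np.asarray(coords, dtype=float),
    )
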