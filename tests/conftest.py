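import numpy as np
import pytest

from yfrag.speclib import LibrarySpectrum, PeakAnnotation


def make_peak(series="y", ordinal=3, z=1, mz=350.0, intensity=1.0):
    return PeakAnnotation(series, ordinal, z, mz, intensity)


def make_spectrum(sequence="PEPTIDEK", charge=2, ce=30.0, peaks=None, source=""):
    if peaks is None:
        peaks = (make_peak(),)
    return LibrarySpectrum(
        sequence=sequence,
        precursor_charge=charge,
        collision_energy=ce,
        peaks=tuple(peaks),
        source=source,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def paperlike_library():
    """A mid-sized simulated corpus shared across read-only tests."""
    from yfrag.simulate import make_fixture

    library, params = make_fixture("paperlike", n_peptides=1000, seed=42)
    return library, params
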