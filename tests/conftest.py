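import pytest

from novopair.chemistry import AminoAcidTable, MassConstants
from novopair.library_training import ScoreModel
from novopair.spectra_io import Spectrum, SpectrumPair


@pytest.fixture(scope="session")
def toy_table():
    return AminoAcidTable.integer_toy()


@pytest.fixture(scope="session")
def toy_constants():
    return MassConstants.integer_toy()


@pytest.fixture(scope="session")
def mono_table():
    return AminoAcidTable.monoisotopic()


@pytest.fixture(scope="session")
def mono_constants():
    return MassConstants.monoisotopic()


@pytest.fixture()
def toy_pair():
    """The integer-mass HCD/ETD example pair (parent mass 492)."""
    hcd = Spectrum("toy", (492 + 2) / 2, 2, 492.0, "HCD",
                   [130, 199, 277, 346], [1, 1, 1, 1])
    etd = Spectrum("toy", (492 + 3) / 3, 3, 492.0, "ETD",
                   [132, 182, 234], [1, 1, 1])
    return SpectrumPair(hcd, etd, tolerance=0.02)


@pytest.fixture(scope="session")
def sentinel_models():
    """Score models with distinct values so score composition is checkable."""
    hcd = ScoreModel(mode="HCD", s_aa=0.61, s_comp_middle=0.79, s_comp_end=0.92)
    etd = ScoreModel(mode="ETD", s_aa=0.66, s_comp=0.42)
    return hcd, etd


@pytest.fixture(scope="session")
def uniform_models():
    return (ScoreModel.uniform("HCD"), ScoreModel.uniform("ETD"))
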