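import numpy as np
import pytest

from bbmn import MsmsSpectrum
from bbmn.formula import DEFAULT_NEUTRAL_LOSSES, HYDROGEN_MASS

LOSS = {e.label: e.mass for e in DEFAULT_NEUTRAL_LOSSES}

#: Protonated parent of the pyranopyrrole monomer (C15H23NO5 + H).
MONOMER_MZ = 298.16545
#: The measured diagnostic (building-block) ion.
DIAGNOSTIC_MZ = 180.0671


@pytest.fixture
def compound1_spectrum() -> MsmsSpectrum:
    """Noise-free fixture of the monomer fragmentation route:
    parent 298.1654 losing water (-18), formaldehyde (-30) and pentene
    (-70) down to the characteristic ion near m/z 180."""
    mz = MONOMER_MZ
    ladder = []
    for label in ("H2O", "CH2O", "C5H10"):
        mz -= LOSS[label]
        ladder.append(mz)
    return MsmsSpectrum(
        id="compound1",
        precursor_mz=MONOMER_MZ,
        peaks=[(m, 5.0e4) for m in ladder],
    )


@pytest.fixture
def dimer_spectrum() -> MsmsSpectrum:
    """Noise-free symmetric-dimer fixture: 2M+H precursor, retro-[2+2]
    fragment at the monomer mass, H2O/CO/CH2O losses, monomer cascade."""
    precursor = 2 * (MONOMER_MZ - HYDROGEN_MASS) + HYDROGEN_MASS
    peaks = [(precursor - LOSS[l], 3.0e4) for l in ("H2O", "CO", "CH2O")]
    peaks.append((MONOMER_MZ, 8.0e4))
    mz = MONOMER_MZ
    for label in ("H2O", "CH2O", "C5H10"):
        mz -= LOSS[label]
        peaks.append((mz, 5.0e4))
    return MsmsSpectrum(id="dimer", precursor_mz=precursor, peaks=peaks)


def random_spectrum(rng: np.random.Generator, spec_id: str, n_peaks=None) -> MsmsSpectrum:
    """A random centroided spectrum for property tests: 4-decimal m/z,
    1-decimal intensities (the MGF serialization grid)."""
    n = int(rng.integers(2, 12)) if n_peaks is None else n_peaks
    precursor = round(float(rng.uniform(200, 800)), 4)
    mzs = np.round(rng.uniform(50, precursor - 20, size=n), 4)
    intens = np.round(rng.uniform(1e3, 1e6, size=n), 1)
    return MsmsSpectrum(
        id=spec_id,
        precursor_mz=precursor,
        peaks=list(zip(mzs.tolist(), intens.tolist())),
    )
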