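"""Synthetic LC-MS/MS data generator for building-block families.

Emits labeled MGF libraries that emulate the situation the toolkit is
built for: a family of structural analogs sharing a conserved
substructure (the "building block"), whose MS2 spectra all contain the
same diagnostic product ion while their precursors differ by small
modifications; one symmetric [2+2]-cycloaddition dimer that fragments by
retro-[2+2] cleavage plus water/CO/formaldehyde losses; decoy spectra
guaranteed to lack the diagnostic ion; and sub-threshold noise peaks.

The default scaffold encodes the phaeosphaeride A fragmentation cascade:
protonated parent m/z 298.1654 losing H2O (-18), CH2O (-30) and C5H10
(-70) down to the characteristic pyranopyrrole ion at m/z 180.0671.  The
diagnostic ion (and two conserved secondary fragments of the same unit)
are emitted UNSHIFTED across analogs — the building block is the part of
the molecule that does not change — while the cascade ladder shifts with
the precursor.

All randomness flows through a single numpy Generator; a fixed seed
yields byte-identical MGF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .formula import HYDROGEN_MASS, DEFAULT_NEUTRAL_LOSSES, NeutralLossEntry, monoisotopic_mass, parse_formula
from .spectra import MsmsSpectrum, write_mgf

__all__ = [
    "Scaffold",
    "SimConfig",
    "PHAEOSPHAERIDE_A",
    "gen_monomer_spectrum",
    "gen_dimer_spectrum",
    "gen_decoy_spectrum",
    "gen_dataset",
    "write_dataset",
]

_LOSS_BY_LABEL = {e.label: e for e in DEFAULT_NEUTRAL_LOSSES}

# noise / guard constants
_NOISE_MAX_INTENSITY = 9.5e3          # strictly below the 1.0E4 area threshold
_MIN_REAL_INTENSITY = 1.2e4           # family fragments always clear the threshold
_GUARD = 0.05                         # exclusion half-width around reserved m/z values


@dataclass(frozen=True)
class Scaffold:
    """A fragmentation blueprint for one compound family.

    ``cascade`` names neutral losses (keys into the loss library) applied
    successively from the precursor; ``diagnostic_mz`` is the conserved
    terminal building-block ion; ``secondary_mzs`` are further conserved
    fragments of the same substructure (they give family spectra enough
    shared peaks for network edges but sit outside any library-loss
    distance of the diagnostic ion, so cascades terminate cleanly).
    """

    name: str
    precursor_mz: float
    cascade: tuple[str, ...]
    diagnostic_mz: Optional[float] = None
    base_intensity: float = 1.0e5
    secondary_mzs: tuple[float, ...] = ()
    losses: dict = field(default_factory=lambda: dict(_LOSS_BY_LABEL))

    def __post_init__(self) -> None:
        unknown = [l for l in self.cascade if l not in self.losses]
        if unknown:
            raise ValueError(f"cascade losses not in library: {unknown}")
        if self.diagnostic_mz is not None:
            total = sum(self.losses[l].mass for l in self.cascade)
            if abs((self.precursor_mz - self.diagnostic_mz) - total) > 0.05:
                raise ValueError(
                    f"scaffold {self.name!r}: cascade losses ({total:.4f} Da) do not "
                    f"reach the diagnostic ion "
                    f"({self.precursor_mz - self.diagnostic_mz:.4f} Da away)"
                )

    def cascade_masses(self) -> tuple[float, ...]:
        return tuple(self.losses[l].mass for l in self.cascade)


def _phaeosphaeride() -> Scaffold:
    # protonated parent of C15H23NO5 at full precision (prints 298.1654)
    parent = monoisotopic_mass(parse_formula("C15H23NO5")) + HYDROGEN_MASS
    return Scaffold(
        name="phaeosphaeride",
        precursor_mz=parent,
        cascade=("H2O", "CH2O", "C5H10"),
        diagnostic_mz=180.0671,
        base_intensity=1.0e5,
        secondary_mzs=(153.0546, 135.0441),
    )


#: Default scaffold: the phaeosphaeride A cascade (298 -> 280 -> 250 -> 180).
PHAEOSPHAERIDE_A: Scaffold = _phaeosphaeride()


@dataclass(frozen=True)
class SimConfig:
    """Dataset-level simulation parameters.

    ``analog_shifts`` are precursor-mass offsets cycled over the family
    members; the defaults (0, +O, +H2O) mimic hydroxylation/hydration
    analog series.  ``mz_sigma`` is Gaussian m/z jitter in Da applied to
    every real fragment; noise peaks land at uniform random m/z with
    intensity strictly below the 1.0E4 area threshold.
    """

    seed: int = 0
    n_family: int = 6
    n_decoys: int = 10
    mz_sigma: float = 0.005
    intensity_cv: float = 0.2
    n_noise_peaks: int = 10
    analog_shifts: tuple[float, ...] = (
        0.0,
        15.9949146,   # +O
        18.0105647,   # +H2O
    )

    def __post_init__(self) -> None:
        if self.mz_sigma < 0 or self.intensity_cv < 0:
            raise ValueError("mz_sigma and intensity_cv must be non-negative")
        if min(self.n_family, self.n_decoys, self.n_noise_peaks) < 0:
            raise ValueError("counts must be non-negative")
        if not self.analog_shifts:
            raise ValueError("need at least one analog shift")


def _jitter_mz(rng: np.random.Generator, mz: float, sigma: float) -> float:
    return mz + float(rng.normal(0.0, sigma)) if sigma > 0 else mz


def _intensity(rng: np.random.Generator, base: float, rel: float, cv: float) -> float:
    value = base * rel * max(0.2, 1.0 + float(rng.normal(0.0, cv)))
    return max(value, _MIN_REAL_INTENSITY)


def _ladder_peaks(scaffold: Scaffold, precursor: float) -> list[tuple[float, float]]:
    """(m/z, relative intensity) for the cascade ladder plus conserved ions.

    The terminal ladder ion is replaced by the scaffold's measured
    diagnostic m/z when the two agree within the scaffold tolerance
    (shift-0 members); otherwise the unshifted diagnostic ion is emitted
    in addition to the shifted ladder.  The diagnostic ion is the base
    peak — characteristic building-block ions are abundant and stable.
    """
    masses = scaffold.cascade_masses()
    n = len(masses)
    peaks: list[tuple[float, float]] = []
    mz = precursor
    for i, loss in enumerate(masses):
        mz -= loss
        rel = 0.5 + 0.5 * (i + 1) / n
        peaks.append((mz, rel))
    if scaffold.diagnostic_mz is not None:
        terminal, rel = peaks[-1]
        if abs(terminal - scaffold.diagnostic_mz) <= _GUARD:
            peaks[-1] = (scaffold.diagnostic_mz, rel)
        else:
            peaks.append((scaffold.diagnostic_mz, 1.0))
    for k, smz in enumerate(scaffold.secondary_mzs):
        peaks.append((smz, 0.35 / (1 + k)))
    return peaks


def _noise_peaks(
    rng: np.random.Generator,
    n: int,
    precursor: float,
    reserved: Sequence[float],
) -> list[tuple[float, float]]:
    """Sub-threshold noise at uniform m/z, avoiding reserved windows
    (diagnostic ions and the retro-[2+2] half-mass point)."""
    out = []
    lo, hi = 50.0, max(60.0, precursor - 20.0)
    for _ in range(n):
        for _attempt in range(100):
            mz = float(rng.uniform(lo, hi))
            if all(abs(mz - r) > _GUARD for r in reserved):
                break
        intensity = float(rng.uniform(1.0e3, _NOISE_MAX_INTENSITY))
        out.append((mz, intensity))
    return out


def _reserved_mzs(scaffold: Scaffold, precursor: float) -> list[float]:
    reserved = [(precursor + HYDROGEN_MASS) / 2.0]
    if scaffold.diagnostic_mz is not None:
        reserved.append(scaffold.diagnostic_mz)
    reserved.extend(scaffold.secondary_mzs)
    return reserved


def gen_monomer_spectrum(
    scaffold: Scaffold,
    shift: float,
    rng: np.random.Generator,
    *,
    mz_sigma: float = 0.005,
    intensity_cv: float = 0.2,
    n_noise_peaks: int = 10,
    spec_id: str = "family_01",
) -> MsmsSpectrum:
    """One family-member spectrum: shifted precursor, shifted cascade
    ladder, unshifted diagnostic/secondary ions, plus noise."""
    precursor = scaffold.precursor_mz + shift
    peaks = []
    for mz, rel in _ladder_peaks(scaffold, precursor):
        peaks.append(
            (
                _jitter_mz(rng, mz, mz_sigma),
                _intensity(rng, scaffold.base_intensity, rel, intensity_cv),
            )
        )
    peaks += _noise_peaks(rng, n_noise_peaks, precursor, _reserved_mzs(scaffold, precursor))
    rt = float(rng.uniform(60.0, 1500.0))
    return MsmsSpectrum(
        id=spec_id,
        precursor_mz=round(precursor, 4),
        peaks=[(round(mz, 4), round(i, 1)) for mz, i in peaks],
        retention_time=round(rt, 2),
    )


def gen_dimer_spectrum(
    scaffold: Scaffold,
    rng: np.random.Generator,
    *,
    mz_sigma: float = 0.005,
    intensity_cv: float = 0.2,
    n_noise_peaks: int = 10,
    spec_id: str = "dimer_01",
) -> MsmsSpectrum:
    """A symmetric [2+2] dimer spectrum.

    The precursor is 2M+H of the monomer.  Fragments: the retro-[2+2]
    half-mass ion at the monomer's protonated m/z; water, CO and
    formaldehyde losses from the precursor (the water loss doubles as the
    McLafferty-type -H2O channel); and the full monomer cascade below the
    retro fragment, ending in the conserved diagnostic ion.
    """
    monomer = scaffold.precursor_mz
    precursor = 2.0 * (monomer - HYDROGEN_MASS) + HYDROGEN_MASS
    peaks: list[tuple[float, float]] = []
    for label, rel in (("H2O", 0.5), ("CO", 0.4), ("CH2O", 0.4)):
        peaks.append((precursor - _LOSS_BY_LABEL[label].mass, rel))
    peaks.append((monomer, 0.9))  # retro-[2+2] fragment
    peaks += _ladder_peaks(scaffold, monomer)
    jittered = [
        (
            _jitter_mz(rng, mz, mz_sigma),
            _intensity(rng, scaffold.base_intensity, rel, intensity_cv),
        )
        for mz, rel in peaks
    ]
    reserved = _reserved_mzs(scaffold, precursor) + [monomer]
    jittered += _noise_peaks(rng, n_noise_peaks, precursor, reserved)
    rt = float(rng.uniform(60.0, 1500.0))
    return MsmsSpectrum(
        id=spec_id,
        precursor_mz=round(precursor, 4),
        peaks=[(round(mz, 4), round(i, 1)) for mz, i in jittered],
        retention_time=round(rt, 2),
    )


def gen_decoy_spectrum(
    rng: np.random.Generator,
    *,
    diagnostic_mzs: Sequence[float] = (),
    mz_tol: float = 0.02,
    spec_id: str = "decoy_01",
) -> MsmsSpectrum:
    """A random unrelated spectrum guaranteed to miss every diagnostic
    ion: no peak lands within 2x ``mz_tol`` of any listed diagnostic m/z."""
    precursor = float(rng.uniform(200.0, 700.0))
    n_peaks = int(rng.integers(8, 16))
    peaks = []
    for _ in range(n_peaks):
        for _attempt in range(100):
            mz = float(rng.uniform(50.0, precursor - 20.0))
            if all(abs(mz - d) > 2.0 * mz_tol for d in diagnostic_mzs):
                break
        intensity = float(10.0 ** rng.uniform(3.0, 5.5))
        peaks.append((round(mz, 4), round(intensity, 1)))
    rt = float(rng.uniform(60.0, 1500.0))
    return MsmsSpectrum(
        id=spec_id,
        precursor_mz=round(precursor, 4),
        peaks=peaks,
        retention_time=round(rt, 2),
    )


def gen_dataset(
    config: SimConfig, scaffold: Scaffold = PHAEOSPHAERIDE_A
) -> tuple[list[MsmsSpectrum], pd.DataFrame]:
    """A full labeled dataset: family members cycled over the analog
    shifts, one dimer, then decoys.

    Returns the spectra and a labels table with columns ``spectrum_id``,
    ``label`` (family/dimer/decoy), ``scaffold`` and ``shift``.
    Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    spectra: list[MsmsSpectrum] = []
    labels: list[dict] = []
    for i in range(config.n_family):
        shift = config.analog_shifts[i % len(config.analog_shifts)]
        sid = f"family_{i + 1:02d}"
        spectra.append(
            gen_monomer_spectrum(
                scaffold,
                shift,
                rng,
                mz_sigma=config.mz_sigma,
                intensity_cv=config.intensity_cv,
                n_noise_peaks=config.n_noise_peaks,
                spec_id=sid,
            )
        )
        labels.append(
            {"spectrum_id": sid, "label": "family", "scaffold": scaffold.name, "shift": shift}
        )
    dimer = gen_dimer_spectrum(
        scaffold,
        rng,
        mz_sigma=config.mz_sigma,
        intensity_cv=config.intensity_cv,
        n_noise_peaks=config.n_noise_peaks,
        spec_id="dimer_01",
    )
    spectra.append(dimer)
    labels.append(
        {"spectrum_id": "dimer_01", "label": "dimer", "scaffold": scaffold.name, "shift": 0.0}
    )
    diag = [scaffold.diagnostic_mz] if scaffold.diagnostic_mz is not None else []
    for j in range(config.n_decoys):
        sid = f"decoy_{j + 1:02d}"
        spectra.append(
            gen_decoy_spectrum(rng, diagnostic_mzs=diag, spec_id=sid)
        )
        labels.append({"spectrum_id": sid, "label": "decoy", "scaffold": "", "shift": 0.0})
    return spectra, pd.DataFrame(labels, columns=["spectrum_id", "label", "scaffold", "shift"])


def write_dataset(
    config: SimConfig,
    mgf_path: Union[str, Path],
    labels_path: Union[str, Path],
    scaffold: Scaffold = PHAEOSPHAERIDE_A,
) -> None:
    """Generate and write the dataset MGF and labels TSV."""
    spectra, labels = gen_dataset(config, scaffold)
    write_mgf(spectra, mgf_path)
    labels.to_csv(labels_path, sep="\t", index=False)
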