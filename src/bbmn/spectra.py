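"""Centroided MS2 spectrum model and MGF (Mascot Generic Format) I/O.

MGF is the sole interchange format: BEGIN IONS / END IONS blocks with
PEPMASS, optional CHARGE / RTINSECONDS / TITLE headers and m/z-intensity
peak lines.  Reading is delegated to :mod:`pyteomics.mgf`; writing uses a
deterministic serializer (4-decimal m/z, 1-decimal intensity, fixed key
order) so that identical inputs always produce identical bytes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, NamedTuple, Optional, Sequence, Union

from pyteomics import mgf as _mgf
from pyteomics.auxiliary import PyteomicsError

__all__ = ["Peak", "MsmsSpectrum", "MgfParseError", "read_mgf", "write_mgf", "base_peak"]


class MgfParseError(ValueError):
    """Raised when an MGF stream violates the expected dialect."""


class Peak(NamedTuple):
    """A single centroided peak: m/z in Da and intensity (area) in
    arbitrary units."""

    mz: float
    intensity: float


def _normalize_peaks(peaks: Iterable[tuple[float, float]]) -> tuple[Peak, ...]:
    """Sort by m/z and merge exact duplicates by summing intensity."""
    merged: dict[float, float] = {}
    for mz, inten in peaks:
        mz = float(mz)
        inten = float(inten)
        if mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {mz}")
        if inten < 0:
            raise ValueError(f"peak intensity must be non-negative, got {inten}")
        merged[mz] = merged.get(mz, 0.0) + inten
    return tuple(Peak(mz, merged[mz]) for mz in sorted(merged))


@dataclass(frozen=True)
class MsmsSpectrum:
    """One centroided MS2 scan.

    Peaks are kept strictly sorted by m/z; duplicate m/z values are merged
    on construction by summing their intensities (centroid assumption).
    ``charge`` defaults to 1+ (singly protonated ions); ``retention_time``
    is optional seconds.  ``extra`` carries unrecognized MGF header keys
    so they survive a read/write round-trip.
    """

    id: str
    precursor_mz: float
    peaks: tuple[Peak, ...] = ()
    charge: int = 1
    retention_time: Optional[float] = None
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        object.__setattr__(self, "peaks", _normalize_peaks(self.peaks))
        object.__setattr__(self, "extra", dict(self.extra))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(p.intensity for p in self.peaks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MsmsSpectrum):
            return NotImplemented
        return (
            self.id == other.id
            and self.precursor_mz == other.precursor_mz
            and self.peaks == other.peaks
            and self.charge == other.charge
            and self.retention_time == other.retention_time
            and dict(self.extra) == dict(other.extra)
        )


_KNOWN_PARAMS = {"title", "pepmass", "rtinseconds", "charge"}


def read_mgf(source: Union[str, Path, IO[str]]) -> list[MsmsSpectrum]:
    """Read all spectra from an MGF file path or text stream.

    The spectrum id comes from TITLE, or is synthesized as
    ``scan_<ordinal>`` (1-based) when TITLE is absent.  A block without a
    PEPMASS line is an error naming the block's ordinal; a malformed peak
    line is an error citing that line.  Charge defaults to 1+.
    """
    if isinstance(source, (str, Path)):
        stream: IO[str] = open(source)
        close = True
    else:
        stream, close = source, False
    spectra: list[MsmsSpectrum] = []
    seen_ids: set[str] = set()
    try:
        reader = _mgf.MGF(stream, convert_arrays=0)
        for ordinal, entry in enumerate(reader, start=1):
            params = entry["params"]
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise MgfParseError(f"MGF block {ordinal} has no PEPMASS line")
            precursor_mz = pepmass[0] if isinstance(pepmass, (tuple, list)) else float(pepmass)
            if precursor_mz is None or precursor_mz <= 0:
                raise MgfParseError(f"MGF block {ordinal}: invalid PEPMASS {pepmass!r}")
            title = params.get("title")
            spec_id = str(title) if title else f"scan_{ordinal}"
            if spec_id in seen_ids:
                raise MgfParseError(f"duplicate spectrum id {spec_id!r} (block {ordinal})")
            seen_ids.add(spec_id)
            charge_val = params.get("charge")
            charge = int(charge_val[0]) if charge_val else 1
            rt = params.get("rtinseconds")
            extra = {
                k.upper(): str(v) for k, v in params.items() if k not in _KNOWN_PARAMS
            }
            spectra.append(
                MsmsSpectrum(
                    id=spec_id,
                    precursor_mz=float(precursor_mz),
                    peaks=list(zip(entry["m/z array"], entry["intensity array"])),
                    charge=charge,
                    retention_time=float(rt) if rt is not None else None,
                    extra=extra,
                )
            )
    except PyteomicsError as exc:
        raise MgfParseError(f"malformed MGF content: {exc.message}") from exc
    finally:
        if close:
            stream.close()
    return spectra


def write_mgf(
    spectra: Sequence[MsmsSpectrum],
    sink: Union[str, Path, IO[str], None] = None,
) -> str:
    """Serialize spectra to MGF text; optionally write to a path/stream.

    Output is deterministic: fixed header order (TITLE, PEPMASS,
    RTINSECONDS, CHARGE, then extra keys sorted), m/z to 4 decimals,
    intensity to 1 decimal.  ``read_mgf(write_mgf(s))`` reproduces the
    collection at that precision.
    """
    buf = io.StringIO()
    for spec in spectra:
        buf.write("BEGIN IONS\n")
        buf.write(f"TITLE={spec.id}\n")
        buf.write(f"PEPMASS={spec.precursor_mz:.4f}\n")
        if spec.retention_time is not None:
            buf.write(f"RTINSECONDS={spec.retention_time:.2f}\n")
        buf.write(f"CHARGE={spec.charge}+\n")
        for key in sorted(spec.extra):
            buf.write(f"{key}={spec.extra[key]}\n")
        for peak in spec.peaks:
            buf.write(f"{peak.mz:.4f} {peak.intensity:.1f}\n")
        buf.write("END IONS\n\n")
    text = buf.getvalue()
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text)
        else:
            sink.write(text)
    return text


def base_peak(spectrum: MsmsSpectrum) -> Peak:
    """The most intense peak; ties break toward the lowest m/z."""
    if not spectrum.peaks:
        raise ValueError(f"spectrum {spectrum.id!r} has no peaks")
    return max(spectrum.peaks, key=lambda p: (p.intensity, -p.mz))
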