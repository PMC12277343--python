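"""Diagnostic-ion and neutral-loss filtering of MS2 spectra.

This is the building-block extraction step: given one or more diagnostic
product-ion m/z values (fragments of a conserved substructure shared by a
compound family), select every spectrum containing such an ion above an
intensity ("peak area") threshold and rank the hits by intensity.  The
same machinery filters on precursor-relative neutral losses, annotates
full fragmentation cascades against a neutral-loss library, and detects
the half-mass fragment signature of retro-[2+2] dimer cleavage.

Intensity thresholding operates on the MS2 fragment-peak intensity as
recorded in the MGF; no MS1 feature areas are involved.  Tolerances are
absolute Daltons by default (0.02 Da); a ppm mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .formula import DEFAULT_NEUTRAL_LOSSES, HYDROGEN_MASS, NeutralLossEntry
from .spectra import MsmsSpectrum, base_peak

__all__ = [
    "DiagnosticQuery",
    "FilterHit",
    "CascadeStep",
    "CascadeAnnotation",
    "filter_spectra",
    "filter_by_neutral_loss",
    "annotate_cascade",
    "detect_retro_cycloaddition",
    "hits_to_table",
    "write_hits_tsv",
    "hit_spectra",
]


@dataclass(frozen=True)
class DiagnosticQuery:
    """A diagnostic-ion / neutral-loss query.

    ``target_mzs`` are product-ion m/z values to look for directly;
    ``neutral_losses`` are precursor-relative loss masses.  At least one
    of the two must be non-empty.  ``mz_tol`` is in Da unless ``ppm`` is
    set, in which case it is parts-per-million of the target.
    """

    target_mzs: tuple[float, ...] = ()
    mz_tol: float = 0.02
    min_area: float = 1.0e4
    neutral_losses: tuple[float, ...] = ()
    ppm: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_mzs", tuple(self.target_mzs))
        object.__setattr__(self, "neutral_losses", tuple(self.neutral_losses))
        if self.mz_tol <= 0:
            raise ValueError(f"mz_tol must be positive, got {self.mz_tol}")
        if self.min_area < 0:
            raise ValueError(f"min_area must be non-negative, got {self.min_area}")
        if not self.target_mzs and not self.neutral_losses:
            raise ValueError("query needs at least one target m/z or neutral loss")

    def tol_at(self, mz: float) -> float:
        return self.mz_tol * mz * 1e-6 if self.ppm else self.mz_tol


class FilterHit(NamedTuple):
    """One (spectrum, target) match.

    ``deviation`` is observed minus target for product-ion targets, and
    observed loss minus target loss for neutral-loss targets.  ``area`` is
    the matched fragment peak's intensity.
    """

    spectrum_id: str
    precursor_mz: float
    matched_target: float
    observed_mz: float
    deviation: float
    area: float


def _best_match(candidates: list[tuple[float, float, float]]) -> Optional[tuple[float, float, float]]:
    """Pick (observed_mz, deviation, area): highest area, tie smallest
    |deviation|, then lowest m/z."""
    if not candidates:
        return None
    return min(candidates, key=lambda c: (-c[2], abs(c[1]), c[0]))


def _rank(hits: list[FilterHit]) -> list[FilterHit]:
    return sorted(hits, key=lambda h: (-h.area, h.spectrum_id, h.matched_target))


def filter_spectra(
    spectra: Iterable[MsmsSpectrum], query: DiagnosticQuery
) -> list[FilterHit]:
    """All (spectrum, target) hits, ranked by matched-peak area descending.

    A hit requires a peak within tolerance of the target with intensity at
    least ``min_area``; of several qualifying peaks the most intense (tie:
    smallest deviation) is reported.  A spectrum matching k targets yields
    k hits.  No hits is an empty list, not an error.
    """
    hits: list[FilterHit] = []
    for spec in spectra:
        for target in query.target_mzs:
            tol = query.tol_at(target)
            cands = [
                (p.mz, p.mz - target, p.intensity)
                for p in spec.peaks
                if abs(p.mz - target) <= tol and p.intensity >= query.min_area
            ]
            best = _best_match(cands)
            if best is not None:
                hits.append(
                    FilterHit(spec.id, spec.precursor_mz, target, best[0], best[1], best[2])
                )
        for loss in query.neutral_losses:
            tol = query.tol_at(loss)
            cands = [
                (p.mz, (spec.precursor_mz - p.mz) - loss, p.intensity)
                for p in spec.peaks
                if abs((spec.precursor_mz - p.mz) - loss) <= tol
                and p.intensity >= query.min_area
            ]
            best = _best_match(cands)
            if best is not None:
                hits.append(
                    FilterHit(spec.id, spec.precursor_mz, loss, best[0], best[1], best[2])
                )
    return _rank(hits)


def filter_by_neutral_loss(
    spectra: Iterable[MsmsSpectrum],
    loss_mass: float,
    tol: float = 0.02,
    min_area: float = 1.0e4,
) -> list[FilterHit]:
    """Hits for a single precursor-relative neutral loss."""
    if loss_mass <= 0:
        raise ValueError(f"loss mass must be positive, got {loss_mass}")
    query = DiagnosticQuery(neutral_losses=(loss_mass,), mz_tol=tol, min_area=min_area)
    return filter_spectra(spectra, query)


class CascadeStep(NamedTuple):
    from_mz: float
    to_mz: float
    loss_label: str  # library label or "unassigned"
    deviation: float  # observed difference minus library loss mass


@dataclass(frozen=True)
class CascadeAnnotation:
    """A linear fragmentation cascade walked down from the precursor."""

    spectrum_id: str
    steps: tuple[CascadeStep, ...]
    terminal_mz: float

    @property
    def loss_labels(self) -> tuple[str, ...]:
        return tuple(s.loss_label for s in self.steps)


def annotate_cascade(
    spectrum: MsmsSpectrum,
    library: Sequence[NeutralLossEntry] = DEFAULT_NEUTRAL_LOSSES,
    tol: float = 0.02,
    min_rel_intensity: float = 0.01,
) -> CascadeAnnotation:
    """Greedy linear cascade annotation against a neutral-loss library.

    Starting at the precursor m/z, repeatedly steps to the highest-m/z
    peak (among peaks of relative intensity >= ``min_rel_intensity``)
    whose mass difference from the current node matches a library loss
    within ``tol``.  Stops when no peak matches; an empty cascade leaves
    ``terminal_mz`` at the precursor.  The walk is strictly linear —
    branched fragmentation trees are out of scope.
    """
    if not spectrum.peaks:
        raise ValueError(f"spectrum {spectrum.id!r} has no peaks")
    if not (0 <= min_rel_intensity < 1):
        raise ValueError(f"min_rel_intensity must be in [0, 1), got {min_rel_intensity}")
    floor = base_peak(spectrum).intensity * min_rel_intensity
    eligible = [p for p in spectrum.peaks if p.intensity >= floor]
    current = spectrum.precursor_mz
    steps: list[CascadeStep] = []
    while True:
        nxt = None
        for p in sorted(eligible, key=lambda p: -p.mz):
            if p.mz >= current - tol:
                continue
            delta = current - p.mz
            best, best_dev = None, None
            for entry in library:
                dev = delta - entry.mass
                if abs(dev) <= tol and (best is None or abs(dev) < abs(best_dev)):
                    best, best_dev = entry, dev
            if best is not None:
                nxt = CascadeStep(current, p.mz, best.label, best_dev)
                break
        if nxt is None:
            break
        steps.append(nxt)
        current = nxt.to_mz
    return CascadeAnnotation(spectrum.id, tuple(steps), current)


def detect_retro_cycloaddition(
    spectrum: MsmsSpectrum, tol: float = 0.02
) -> list[tuple[float, float]]:
    """Flag fragments consistent with a symmetric dimer splitting in two.

    For a singly protonated precursor, a retro-[2+2] cleavage of a
    head-to-head dimer yields a fragment whose neutral complement
    (precursor_mz - fragment_mz) equals the fragment's own neutral mass
    (fragment_mz - 1.00783): the ion is half the molecule.  Returns
    (fragment_mz, complement_mass) pairs meeting this within ``tol``.
    """
    flagged: list[tuple[float, float]] = []
    for p in spectrum.peaks:
        complement = spectrum.precursor_mz - p.mz
        if abs(complement - (p.mz - HYDROGEN_MASS)) <= tol:
            flagged.append((p.mz, complement))
    return flagged


def hits_to_table(hits: Sequence[FilterHit]) -> pd.DataFrame:
    """Hits as a ranked DataFrame (rank 1 = most intense)."""
    df = pd.DataFrame(
        [
            {
                "spectrum_id": h.spectrum_id,
                "precursor_mz": round(h.precursor_mz, 4),
                "target_mz": round(h.matched_target, 4),
                "observed_mz": round(h.observed_mz, 4),
                "deviation": round(h.deviation, 4),
                "area": h.area,
            }
            for h in hits
        ],
        columns=["spectrum_id", "precursor_mz", "target_mz", "observed_mz", "deviation", "area"],
    )
    df["rank"] = range(1, len(df) + 1)
    return df


def write_hits_tsv(hits: Sequence[FilterHit], sink: Union[str, Path, IO[str]]) -> None:
    hits_to_table(hits).to_csv(sink, sep="\t", index=False)


def hit_spectra(
    spectra: Sequence[MsmsSpectrum], hits: Sequence[FilterHit]
) -> list[MsmsSpectrum]:
    """The subset of spectra with at least one hit, in input order."""
    ids = {h.spectrum_id for h in hits}
    return [s for s in spectra if s.id in ids]
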