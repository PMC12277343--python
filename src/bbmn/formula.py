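"""Elemental-formula parsing and exact-mass arithmetic.

Supports the mass bookkeeping used throughout the toolkit: Hill-notation
formula parsing, monoisotopic masses, singly protonated m/z values
([M+H]+), ring-plus-double-bond equivalents (RDBE), and a small library
of named neutral losses for fragmentation-cascade annotation.

Only neutral, singly protonated, monoisotopic species are modelled:
no isotopologues, no multiply charged ions, no adducts other than [M+H]+.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "ElementalFormula",
    "FormulaError",
    "NeutralLossEntry",
    "DEFAULT_NEUTRAL_LOSSES",
    "HYDROGEN_MASS",
    "PROTON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "rdbe",
    "match_neutral_loss",
    "load_loss_library",
]

# IUPAC monoisotopic masses of the light elements that occur in the
# small-molecule natural products this toolkit targets.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
    "P": 30.9737615,
    "Si": 27.9769265,
    "F": 18.9984032,
    "Cl": 34.96885268,
    "Br": 78.9183376,
    "I": 126.904473,
}

# Standard valences used for ring-plus-double-bond counting.
_VALENCE = {
    "C": 4, "Si": 4,
    "N": 3, "P": 3,
    "O": 2, "S": 2,
    "H": 1, "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

#: Monoisotopic mass of a hydrogen atom; adding it to a neutral mass gives
#: the conventional [M+H]+ value as printed in natural-product papers
#: (no electron-mass correction).
HYDROGEN_MASS = 1.0078250319

#: Mass of a bare proton (electron-corrected); available for strict work.
PROTON_MASS = 1.00727646688


class FormulaError(ValueError):
    """Raised for malformed formulas or unsupported elements."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map for a neutral molecular formula.

    Counts are non-negative; zero-count elements are dropped so that
    equality behaves set-wise.  Addition and integer scaling are
    element-wise, which makes dimer arithmetic (2 x monomer) explicit.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
            if n > 0:
                cleaned[el] = int(n)
        object.__setattr__(self, "counts", cleaned)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            return NotImplemented
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def hill(self) -> str:
        """Render in Hill notation: C first, H second, the rest
        alphabetical (all-alphabetical when no carbon is present)."""
        if not self.counts:
            return ""
        parts = []
        if "C" in self.counts:
            order = ["C"] + (["H"] if "H" in self.counts else [])
            order += sorted(el for el in self.counts if el not in ("C", "H"))
        else:
            order = sorted(self.counts)
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``"C30H46N2O10"``.

    An element symbol without a trailing number has implicit count 1.
    Isotope labels, charges and parentheses are not supported.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic (exact) mass of a neutral formula, in Da."""
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in f.counts.items())


def protonated_mz(f: Union[ElementalFormula, str], *, strict_proton: bool = False) -> float:
    """m/z of the singly protonated ion [M+H]+, rounded to 4 decimals.

    By default the hydrogen-atom mass (1.00783) is added, the convention
    natural-product HR-ESI-MS tables use; ``strict_proton=True`` adds the
    electron-corrected proton mass (1.007276) instead.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    adduct = PROTON_MASS if strict_proton else HYDROGEN_MASS
    return round(monoisotopic_mass(f) + adduct, 4)


def rdbe(f: Union[ElementalFormula, str]) -> float:
    """Ring-plus-double-bond equivalents (degrees of unsaturation).

    Computed from standard valences: 1 + sum(count * (valence - 2)) / 2,
    i.e. C + Si - (H + halogens)/2 + (N + P)/2 + 1.  Integral for neutral
    formulas; may be half-integral for odd-electron/ionic compositions.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    total = 2.0
    for el, n in f.counts.items():
        if el not in _VALENCE:
            raise FormulaError(f"no standard valence for element {el!r}")
        total += n * (_VALENCE[el] - 2)
    return total / 2.0


@dataclass(frozen=True)
class NeutralLossEntry:
    """A named small-molecule neutral loss used in cascade annotation."""

    label: str
    formula: ElementalFormula
    mass: float

    def __post_init__(self) -> None:
        expected = monoisotopic_mass(self.formula)
        if abs(self.mass - expected) > 1e-4:
            raise FormulaError(
                f"neutral loss {self.label!r}: stated mass {self.mass} "
                f"differs from formula mass {expected:.4f} by more than 1e-4 Da"
            )

    @classmethod
    def from_formula(cls, label: str, formula: Union[str, ElementalFormula]) -> "NeutralLossEntry":
        if isinstance(formula, str):
            formula = parse_formula(formula)
        return cls(label=label, formula=formula, mass=monoisotopic_mass(formula))


def _default_losses() -> tuple[NeutralLossEntry, ...]:
    specs = [
        ("H2O", "H2O"),      # water, nominal -18
        ("CH2O", "CH2O"),    # formaldehyde / HCOH, nominal -30
        ("CO", "CO"),        # carbon monoxide, nominal -28
        ("C5H10", "C5H10"),  # pentene, nominal -70
        ("CH3OH", "CH4O"),   # methanol, nominal -32
        ("NH3", "H3N"),      # ammonia, nominal -17
    ]
    return tuple(NeutralLossEntry.from_formula(label, f) for label, f in specs)


#: Built-in neutral-loss library.  The first four entries are the losses
#: that dominate pyranopyrrole natural-product fragmentation (water,
#: formaldehyde, carbon monoxide, pentene); methanol and ammonia are
#: conventional additions.  Fully overridable via :func:`load_loss_library`.
DEFAULT_NEUTRAL_LOSSES: tuple[NeutralLossEntry, ...] = _default_losses()


def match_neutral_loss(
    delta: float,
    library: Iterable[NeutralLossEntry] = DEFAULT_NEUTRAL_LOSSES,
    tol: float = 0.02,
) -> Optional[NeutralLossEntry]:
    """Best library entry for an observed mass difference, or ``None``.

    Returns the entry minimizing ``|delta - mass|`` when that minimum is
    within ``tol`` Da; ties break toward the smaller loss mass, then the
    lexicographically smaller label.
    """
    if delta < 0:
        raise ValueError(f"mass difference must be non-negative, got {delta}")
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    best = None
    best_key = None
    for entry in library:
        key = (abs(delta - entry.mass), entry.mass, entry.label)
        if best_key is None or key < best_key:
            best, best_key = entry, key
    if best is None or best_key[0] > tol:
        return None
    return best


def load_loss_library(path: Union[str, Path]) -> tuple[NeutralLossEntry, ...]:
    """Load a neutral-loss library from a tab-separated file.

    Columns: ``label``, ``formula``, optional ``mass``.  The mass is always
    recomputed from the formula; a stated mass deviating by more than
    1e-3 Da from the recomputed value is rejected as inconsistent.
    Lines starting with ``#`` and a ``label<TAB>formula`` header row are
    skipped.  Labels must be unique.
    """
    entries: list[NeutralLossEntry] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].lower() == "label":
            continue
        if len(fields) < 2:
            raise FormulaError(f"{path}:{lineno}: expected 'label<TAB>formula[<TAB>mass]'")
        label, formula_text = fields[0], fields[1]
        if label in seen:
            raise FormulaError(f"{path}:{lineno}: duplicate loss label {label!r}")
        seen.add(label)
        entry = NeutralLossEntry.from_formula(label, formula_text)
        if len(fields) >= 3 and fields[2]:
            stated = float(fields[2])
            if abs(stated - entry.mass) > 1e-3:
                raise FormulaError(
                    f"{path}:{lineno}: stated mass {stated} inconsistent with "
                    f"formula {formula_text} ({entry.mass:.4f})"
                )
        entries.append(entry)
    return tuple(entries)
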