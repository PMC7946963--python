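"""Monoisotopic phosphopeptide masses and HCD b/y fragment ladders.

All arithmetic is monoisotopic (high-resolution Orbitrap convention).
A phospho mark adds the HPO3 mass, 79.966331 Da.  Ion m/z follows
``(M + z * proton) / z`` with the proton mass 1.007276 Da.  Only the b/y
series is generated (HCD); neutral-loss and a/c/z ions are out of scope.
Full precision is kept internally; round only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Sequence

from .peptides import ModifiedPeptide

# Monoisotopic residue masses (Da), 20 standard amino acids.
RESIDUE_MASS = MappingProxyType(
    {
        "G": 57.02146,
        "A": 71.03711,
        "S": 87.03203,
        "P": 97.05276,
        "V": 99.06841,
        "T": 101.04768,
        "C": 103.00919,
        "L": 113.08406,
        "I": 113.08406,
        "N": 114.04293,
        "D": 115.02694,
        "Q": 128.05858,
        "K": 128.09496,
        "E": 129.04259,
        "M": 131.04049,
        "H": 137.05891,
        "F": 147.06841,
        "R": 156.10111,
        "Y": 163.06333,
        "W": 186.07931,
    }
)

WATER = 18.010565
PROTON = 1.007276
PHOSPHO = 79.966331  # HPO3


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical b- or y-type ion."""

    series: str  # "b" or "y"
    index: int  # 1..n-1
    charge: int
    mz: float
    contains_mod: bool  # ion span includes a phospho site

    @property
    def label(self) -> str:
        sup = "+" * self.charge
        return f"{self.series}{self.index}{sup}"


def _residue_mass(p: ModifiedPeptide, pos: int) -> float:
    aa = p.residues[pos - 1]
    try:
        m = RESIDUE_MASS[aa]
    except KeyError:
        raise KeyError(f"no monoisotopic mass for residue {aa!r}") from None
    return m + (PHOSPHO if p.is_phospho(pos) else 0.0)


def monoisotopic_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residue sum + water + HPO3 per phospho mark."""
    return sum(_residue_mass(p, i) for i in range(1, len(p) + 1)) + WATER


def mz(mass: float, z: int) -> float:
    """m/z of the z-fold protonated ion, (M + z x proton)/z."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON) / z


def fragment_ladder(
    p: ModifiedPeptide, charges: Iterable[int] = (1,)
) -> list[FragmentIon]:
    """All b_i / y_i ions for i in 1..n-1 at the requested charges.

    b_i covers residues 1..i (neutral mass = residue sum); y_i covers the
    C-terminal i residues (neutral mass = residue sum + water).
    ``contains_mod`` is true iff the ion's residue span includes a phospho
    position, which is what makes an ion site-determining.
    """
    n = len(p)
    if n < 2:
        raise ValueError("fragmentation needs at least 2 residues")
    charges = sorted(set(charges))
    if any(z < 1 for z in charges):
        raise ValueError("charges must be positive")

    prefix = [0.0]
    for i in range(1, n + 1):
        prefix.append(prefix[-1] + _residue_mass(p, i))

    ions = []
    for i in range(1, n):
        b_neutral = prefix[i]
        y_neutral = prefix[n] - prefix[n - i] + WATER
        b_mod = any(pos <= i for pos in p.phospho)
        y_mod = any(pos > n - i for pos in p.phospho)
        for z in charges:
            ions.append(FragmentIon("b", i, z, mz(b_neutral, z), b_mod))
            ions.append(FragmentIon("y", i, z, mz(y_neutral, z), y_mod))
    return ions


def _ion_span(ion: FragmentIon, n: int) -> range:
    if ion.series == "b":
        return range(1, ion.index + 1)
    return range(n - ion.index + 1, n + 1)


@dataclass(frozen=True)
class PeakMatch:
    ion: FragmentIon
    peak_mz: float
    intensity: float
    delta_mz: float
    site_determining: bool


def match_peaks(
    ladder: Sequence[FragmentIon],
    peaks: Sequence[tuple[float, float]],
    tol: float = 10.0,
    tol_unit: str = "ppm",
    peptide: ModifiedPeptide | None = None,
) -> list[PeakMatch]:
    """Annotate a peak list against a theoretical ladder.

    Each ion is assigned its nearest peak within tolerance (smallest
    absolute m/z error; ties broken toward higher intensity).  When the
    parent *peptide* is given, matched ions are additionally flagged as
    site-determining: an ion whose residue span separates the assigned
    phospho position from at least one alternative S/T/Y candidate.  The
    site-support count is the number of such matched ions.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if tol_unit not in ("ppm", "Da"):
        raise ValueError(f"unknown tolerance unit {tol_unit!r}")

    candidates: set[int] = set()
    assigned: set[int] = set()
    n = 0
    if peptide is not None:
        n = len(peptide)
        candidates = {
            i + 1 for i, aa in enumerate(peptide.residues) if aa in "STY"
        }
        assigned = set(peptide.phospho)

    matches = []
    for ion in ladder:
        limit = tol * ion.mz * 1e-6 if tol_unit == "ppm" else tol
        best = None
        for peak_mz, intensity in peaks:
            d = abs(peak_mz - ion.mz)
            if d > limit:
                continue
            key = (d, -intensity)
            if best is None or key < best[0]:
                best = (key, peak_mz, intensity)
        if best is None:
            continue
        site_det = False
        if peptide is not None and assigned:
            span = set(_ion_span(ion, n))
            for alt in candidates - assigned:
                if any((p in span) != (alt in span) for p in assigned):
                    site_det = True
                    break
        matches.append(
            PeakMatch(ion, best[1], best[2], best[1] - ion.mz, site_det)
        )
    return matches


def site_support(matches: Sequence[PeakMatch]) -> int:
    """Number of matched ions that discriminate the assigned phospho site."""
    return sum(1 for m in matches if m.site_determining)


__all__ = [
    "RESIDUE_MASS",
    "WATER",
    "PROTON",
    "PHOSPHO",
    "FragmentIon",
    "PeakMatch",
    "monoisotopic_mass",
    "mz",
    "fragment_ladder",
    "match_peaks",
    "site_support",
]
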