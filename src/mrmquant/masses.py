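"""Monoisotopic residue masses and the constants behind every m/z in the package.

A single :class:`ResidueMassTable` instance is threaded through all mass
arithmetic (peptide masses, precursor m/z, fragment series) so that there is
exactly one source of mass constants in a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

STANDARD_AA: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic mass of H2O (Da), added once per peptide chain.
WATER_MONOISOTOPIC = 18.010565

#: Mass of a proton (Da), added once per positive charge.
PROTON_MASS = 1.007276


def _standard_monoisotopic_masses() -> Mapping[str, float]:
    # pyteomics ships the canonical monoisotopic residue masses
    from pyteomics import mass as _pmass

    return {aa: _pmass.std_aa_mass[aa] for aa in sorted(STANDARD_AA)}


@dataclass(frozen=True)
class ResidueMassTable:
    """Map of residue letter -> monoisotopic residue mass (Da).

    Parameters
    ----------
    masses:
        One entry per standard amino acid. All 20 letters must be present
        and strictly positive.
    water, proton:
        Terminal-water and proton masses used in peptide/ion mass formulas.
    """

    masses: Mapping[str, float]
    water: float = WATER_MONOISOTOPIC
    proton: float = PROTON_MASS

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.masses)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        bad = [aa for aa, m in self.masses.items() if m <= 0]
        if bad:
            raise ValueError(f"non-positive residue masses for: {sorted(bad)}")
        object.__setattr__(self, "masses", MappingProxyType(dict(self.masses)))

    def __getitem__(self, residue: str) -> float:
        try:
            return self.masses[residue]
        except KeyError:
            raise KeyError(f"unknown residue letter {residue!r}") from None

    @classmethod
    def monoisotopic(cls) -> "ResidueMassTable":
        """Standard monoisotopic table (the package default)."""
        return cls(_standard_monoisotopic_masses())


_DEFAULT: ResidueMassTable | None = None


def default_mass_table() -> ResidueMassTable:
    """Shared default :class:`ResidueMassTable` (monoisotopic)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ResidueMassTable.monoisotopic()
    return _DEFAULT
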