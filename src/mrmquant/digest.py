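"""In-silico tryptic digestion.

Trypsin cleaves C-terminal of lysine and arginine. The default rule also
suppresses cleavage when the next residue is proline (the Keil rule), which
is what mainstream transition-design software applies; a "strict KR"
alternative (no proline exception) is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .proteome import ProteinRecord

CLEAVAGE_RULES = ("keil", "strict")


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide located in its parent protein (1-based inclusive)."""

    sequence: str
    parent_id: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.sequence!r}: span {self.start}..{self.end} "
                f"inconsistent with length {len(self.sequence)}"
            )
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str, rule: str = "keil") -> list[int]:
    """0-based indices i such that the bond after ``sequence[i]`` is cleaved."""
    if rule not in CLEAVAGE_RULES:
        raise ValueError(f"rule must be one of {CLEAVAGE_RULES}, got {rule!r}")
    sites = []
    for i, letter in enumerate(sequence[:-1]):  # terminal residue: no bond after
        if letter in "KR":
            if rule == "keil" and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def tryptic_digest(
    protein: ProteinRecord, missed_cleavages: int = 0, rule: str = "keil"
) -> list[Peptide]:
    """Enumerate tryptic peptides with up to ``missed_cleavages`` internal sites.

    The zero-missed-cleavage products concatenate back to the protein
    sequence; with ``missed_cleavages = m`` every product spanning 0..m
    uncleaved internal sites is returned, ordered by start position then by
    missed-cleavage count.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be non-negative")
    seq = protein.sequence
    sites = cleavage_sites(seq, rule)
    # fragment boundaries as 0-based half-open [lo, hi)
    cuts = [0] + [i + 1 for i in sites] + [len(seq)]
    peptides = []
    for i in range(len(cuts) - 1):
        for m in range(missed_cleavages + 1):
            j = i + 1 + m
            if j >= len(cuts):
                break
            lo, hi = cuts[i], cuts[j]
            peptides.append(
                Peptide(
                    sequence=seq[lo:hi],
                    parent_id=protein.id,
                    start=lo + 1,
                    end=hi,
                    missed_cleavages=m,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def digest_to_tsv(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Dump a digest as TSV (peptide, parent, start, end, missed_cleavages)."""
    with Path(path).open("w") as fh:
        fh.write("peptide\tparent_id\tstart\tend\tmissed_cleavages\n")
        for p in peptides:
            fh.write(f"{p.sequence}\t{p.parent_id}\t{p.start}\t{p.end}\t{p.missed_cleavages}\n")
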