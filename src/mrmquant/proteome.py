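"""Protein sequence I/O and chain (signal/pro/mature) handling.

Secreted bacterial proteases are synthesised as pre-pro-proteins: an
N-terminal signal peptide routes the protein through the Sec machinery, a
propeptide chaperones folding and is removed during maturation, and only the
mature chain circulates in the culture supernatant. Assay design must
therefore run on the mature chain, not the gene product. Chain boundaries
are supplied as 1-based inclusive ranges through the run configuration (no
FASTA-header dialect is assumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .masses import STANDARD_AA

CHAIN_KINDS = ("signal", "propeptide", "mature")


@dataclass(frozen=True)
class ChainAnnotation:
    """One chain of a precursor protein, 1-based inclusive coordinates."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in CHAIN_KINDS:
            raise ValueError(
                f"chain kind must be one of {CHAIN_KINDS}, got {self.kind!r}"
            )
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid chain range {self.start}..{self.end} (1-based inclusive)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _validate_sequence(record_id: str, sequence: str) -> None:
    for pos, letter in enumerate(sequence, start=1):
        if letter not in STANDARD_AA:
            raise ValueError(
                f"record {record_id!r}: non-standard residue {letter!r} "
                f"at position {pos}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional chain annotations.

    The sequence is restricted to the 20 standard residue letters;
    ambiguity codes (B, J, O, U, X, Z) are rejected with the offending
    position named, because every downstream mass is computed from the
    letters.
    """

    id: str
    description: str
    sequence: str
    chains: tuple[ChainAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        _validate_sequence(self.id, self.sequence)
        object.__setattr__(self, "chains", tuple(self.chains))
        for chain in self.chains:
            if chain.end > len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: chain {chain.kind} ends at "
                    f"{chain.end} beyond sequence length {len(self.sequence)}"
                )
        # Chains must tile without overlap; a single shared boundary residue
        # is tolerated (mature chains are sometimes annotated as starting on
        # the propeptide's last residue).
        ordered = sorted(self.chains, key=lambda c: (c.start, c.end))
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"record {self.id!r}: chains {a.kind} and {b.kind} overlap "
                    f"by more than one boundary residue"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_chains(
        self, ranges: Mapping[str, tuple[int, int]] | Iterable[ChainAnnotation]
    ) -> "ProteinRecord":
        """Return a copy with chain annotations attached.

        ``ranges`` is either a mapping ``kind -> (start, end)`` (the config
        format) or an iterable of :class:`ChainAnnotation`.
        """
        if isinstance(ranges, Mapping):
            chains = tuple(
                ChainAnnotation(kind, int(lo), int(hi))
                for kind, (lo, hi) in ranges.items()
            )
        else:
            chains = tuple(ranges)
        return replace(self, chains=chains)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (multi-entry) FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased; order is preserved; chain annotations are
    left empty (they are attached separately from the run config).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        description = entry.description
        if description.startswith(entry.id):
            description = description[len(entry.id):].strip()
        records.append(
            ProteinRecord(
                id=entry.id,
                description=description,
                sequence=str(entry.seq).upper(),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def extract_chain(protein: ProteinRecord, kind: str) -> ProteinRecord:
    """Slice out the protein's single chain of the requested kind.

    The returned record's id is suffixed with the chain kind; its length is
    ``end - start + 1`` (inclusive coordinates).
    """
    matches = [c for c in protein.chains if c.kind == kind]
    if not matches:
        raise ValueError(f"record {protein.id!r} has no {kind!r} chain annotation")
    if len(matches) > 1:
        raise ValueError(f"record {protein.id!r} has multiple {kind!r} chain annotations")
    chain = matches[0]
    return ProteinRecord(
        id=f"{protein.id}|{kind}",
        description=f"{protein.description} [{kind} {chain.start}-{chain.end}]".strip(),
        sequence=protein.sequence[chain.start - 1 : chain.end],
    )
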