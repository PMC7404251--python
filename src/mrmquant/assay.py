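"""MRM assay design: proteotypic-peptide selection and transition building.

The computational chain is: tryptic digest -> candidate filtering (length
8-25, no Cys/Met, optional proteotypicity against a background digest) ->
doubly protonated precursor m/z -> singly charged b/y fragment series ->
product-ion picks -> per-precursor collision energy (CE) and declustering
potential (DP) from a linear instrument model -> exportable transition list.

Mass formulas (monoisotopic, masses from :class:`~mrmquant.masses.ResidueMassTable`):

* peptide mass        M = sum(residue masses) + H2O
* precursor m/z       (M + z * proton) / z
* b_i (1+)            sum of the i N-terminal residues + proton
* y_i (1+)            sum of the i C-terminal residues + H2O + proton

so b_i + y_{n-i} = M + 2 * proton for every split point i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digest import Peptide, tryptic_digest
from .masses import ResidueMassTable, default_mass_table
from .proteome import ProteinRecord


# ---------------------------------------------------------------------------
# mass arithmetic


def peptide_monoisotopic_mass(
    sequence: str, masses: ResidueMassTable | None = None
) -> float:
    """Monoisotopic neutral mass of a peptide (Da)."""
    masses = masses or default_mass_table()
    if not sequence:
        raise ValueError("empty peptide sequence")
    return sum(masses[aa] for aa in sequence) + masses.water


def precursor_mz(
    sequence: str, charge: int, masses: ResidueMassTable | None = None
) -> float:
    """m/z of the [M + zH]^z+ precursor ion."""
    if charge < 1:
        raise ValueError(f"precursor charge must be >= 1, got {charge}")
    masses = masses or default_mass_table()
    return (peptide_monoisotopic_mass(sequence, masses) + charge * masses.proton) / charge


@dataclass(frozen=True)
class FragmentIon:
    """A singly charged backbone fragment ion (b or y series)."""

    series: str
    index: int
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"fragment series must be 'b' or 'y', got {self.series!r}")
        if self.index < 1:
            raise ValueError("fragment index must be >= 1")
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}"


def fragment_series(
    sequence: str, masses: ResidueMassTable | None = None
) -> list[FragmentIon]:
    """All singly charged b_i and y_i ions, i = 1..n-1."""
    if len(sequence) < 2:
        raise ValueError("fragment series requires a peptide of length >= 2")
    masses = masses or default_mass_table()
    n = len(sequence)
    ions: list[FragmentIon] = []
    prefix = 0.0
    for i in range(1, n):
        prefix += masses[sequence[i - 1]]
        ions.append(FragmentIon("b", i, 1, prefix + masses.proton))
    suffix = 0.0
    for i in range(1, n):
        suffix += masses[sequence[n - i]]
        ions.append(FragmentIon("y", i, 1, suffix + masses.water + masses.proton))
    return ions


def fragment_by_label(
    sequence: str, label: str, masses: ResidueMassTable | None = None
) -> FragmentIon:
    """Look up one ion of the b/y series by label, e.g. ``"y8"``."""
    series, index = label[0], int(label[1:])
    for ion in fragment_series(sequence, masses):
        if ion.series == series and ion.index == index:
            return ion
    raise ValueError(f"no fragment {label!r} for peptide of length {len(sequence)}")


# ---------------------------------------------------------------------------
# candidate filtering


def filter_candidates(
    peptides: Iterable[Peptide],
    min_len: int = 8,
    max_len: int = 25,
    excluded_residues: frozenset[str] | set[str] = frozenset("CM"),
    background: Iterable[Peptide] | None = None,
) -> list[Peptide]:
    """Keep peptides suitable as proteotypic MRM surrogates.

    Rules: length within ``[min_len, max_len]``; none of
    ``excluded_residues`` (Cys and Met by default — both are prone to
    artefactual modification during sample handling); and, when a
    background digest is supplied, the peptide string must occur in exactly
    one background protein (exact string match, I and L kept distinct).
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    excluded = set(excluded_residues)
    parents_by_seq: dict[str, set[str]] | None = None
    if background is not None:
        parents_by_seq = {}
        for pep in background:
            parents_by_seq.setdefault(pep.sequence, set()).add(pep.parent_id)
    kept = []
    for pep in peptides:
        if not (min_len <= len(pep) <= max_len):
            continue
        if excluded & set(pep.sequence):
            continue
        if parents_by_seq is not None:
            if len(parents_by_seq.get(pep.sequence, set())) != 1:
                continue
        kept.append(pep)
    return kept


# ---------------------------------------------------------------------------
# product-ion selection

#: m/z half-window around the precursor inside which products are skipped
#: (they would co-transmit with the precursor and carry no selectivity).
PRECURSOR_EXCLUSION_TH = 3.0


def select_product_ions(
    peptide: Peptide | str,
    n: int = 3,
    policy: str = "y-prefer",
    explicit: Sequence[str] | None = None,
    precursor_charge: int = 2,
    masses: ResidueMassTable | None = None,
) -> list[FragmentIon]:
    """Pick ``n`` product ions for a peptide.

    ``"y-prefer"`` (default): y ions with index >= 3, ranked by descending
    m/z, skipping ions within +-3 Th of the precursor m/z. High-index y ions
    are the usual first choice on a triple quadrupole: they retain the
    C-terminal K/R and tend to dominate tryptic CID spectra.

    ``"explicit"``: return the user-supplied ion labels in the given order
    (how an experimentally refined assay is reproduced).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if policy == "explicit":
        if not explicit:
            raise ValueError("explicit policy requires a list of ion labels")
        return [fragment_by_label(seq, label, masses) for label in explicit]
    if policy != "y-prefer":
        raise ValueError(f"unknown product-ion policy {policy!r}")
    prec = precursor_mz(seq, precursor_charge, masses)
    candidates = [
        ion
        for ion in fragment_series(seq, masses)
        if ion.series == "y"
        and ion.index >= 3
        and abs(ion.mz - prec) > PRECURSOR_EXCLUSION_TH
    ]
    candidates.sort(key=lambda ion: -ion.mz)
    if len(candidates) < n:
        warnings.warn(
            f"peptide {seq!r}: only {len(candidates)} product-ion candidates "
            f"for requested {n}",
            stacklevel=2,
        )
        return candidates
    return candidates[:n]


# ---------------------------------------------------------------------------
# instrument model (CE / DP linear in precursor m/z)


@dataclass(frozen=True)
class InstrumentModel:
    """Linear CE/DP model for doubly charged precursors.

    ``CE = ce_slope * mz + ce_intercept`` and likewise for DP. Residual
    reports (observed - fitted, in fit order) are carried for diagnostics.
    """

    ce_slope: float
    ce_intercept: float
    dp_slope: float
    dp_intercept: float
    ce_residuals: tuple[float, ...] = ()
    dp_residuals: tuple[float, ...] = ()


def _fit_line(pairs: Sequence[tuple[float, float]], what: str) -> tuple[float, float, tuple[float, ...]]:
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if len(set(x.tolist())) < 2:
        raise ValueError(f"cannot fit {what} model: need >= 2 distinct m/z values")
    slope, intercept = np.polyfit(x, y, 1)
    residuals = tuple((y - (slope * x + intercept)).tolist())
    return float(slope), float(intercept), residuals


def fit_instrument_model(
    pairs_ce: Sequence[tuple[float, float]],
    pairs_dp: Sequence[tuple[float, float]],
) -> InstrumentModel:
    """Ordinary least-squares lines for CE and DP versus precursor m/z."""
    ce_slope, ce_intercept, ce_res = _fit_line(pairs_ce, "CE")
    dp_slope, dp_intercept, dp_res = _fit_line(pairs_dp, "DP")
    return InstrumentModel(ce_slope, ce_intercept, dp_slope, dp_intercept, ce_res, dp_res)


_DEFAULT_MODEL: InstrumentModel | None = None


def default_instrument_model() -> InstrumentModel:
    """Instrument model fitted to the bundled published reference assay.

    The six reference precursors give CE ~ 0.036*mz + 8.82 and
    DP ~ 0.0729*mz + 31.13, i.e. the familiar vendor defaults for 2+
    precursors on a QTRAP — consistent with the reference CE/DP values
    having been computed from precursor m/z alone.
    """
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        from .reference_data import REFERENCE_PEPTIDES

        pairs_ce = [(p.precursor_mz, p.collision_energy) for p in REFERENCE_PEPTIDES]
        pairs_dp = [(p.precursor_mz, p.declustering_potential) for p in REFERENCE_PEPTIDES]
        _DEFAULT_MODEL = fit_instrument_model(pairs_ce, pairs_dp)
    return _DEFAULT_MODEL


def predict_params(model: InstrumentModel, mz: float) -> tuple[float, float]:
    """(CE, DP) in volts for a precursor m/z, rounded to 0.1 V for export."""
    ce = model.ce_slope * mz + model.ce_intercept
    dp = model.dp_slope * mz + model.dp_intercept
    return round(ce, 1), round(dp, 1)


# ---------------------------------------------------------------------------
# transitions


@dataclass(frozen=True)
class Transition:
    """One Q1/Q3 pair with instrument parameters."""

    peptide: Peptide
    precursor_mz: float
    precursor_charge: int
    product: FragmentIon
    declustering_potential: float
    collision_energy: float
    retention_time: float | None = None  # measured metadata, minutes
    quantifier: bool = False
    product_rank: int = 0

    def __post_init__(self) -> None:
        if self.collision_energy <= 0 or self.declustering_potential <= 0:
            raise ValueError("CE and DP must be strictly positive")

    @property
    def protein_id(self) -> str:
        return self.peptide.parent_id

    @property
    def key(self) -> tuple[str, str]:
        """(peptide sequence, product-ion label) — the trace key."""
        return (self.peptide.sequence, self.product.label)


@dataclass(frozen=True)
class DesignSettings:
    """Everything :func:`build_transition_table` needs besides sequences."""

    precursor_charge: int = 2
    product_charge: int = 1
    min_len: int = 8
    max_len: int = 25
    excluded_residues: frozenset[str] = frozenset("CM")
    n_products: int = 3
    policy: str = "y-prefer"
    missed_cleavages: int = 0
    cleavage_rule: str = "keil"
    #: peptide sequence -> ordered product-ion labels (forces policy "explicit"
    #: for that peptide)
    explicit_ions: Mapping[str, Sequence[str]] = field(default_factory=dict)
    #: peptide sequence -> quantifier ion label (default: top-ranked product)
    quantifier_ions: Mapping[str, str] = field(default_factory=dict)
    #: peptide sequence -> measured retention time (min)
    retention_times: Mapping[str, float] = field(default_factory=dict)
    instrument_model: InstrumentModel | None = None


def build_transition_table(
    proteins: Sequence[ProteinRecord],
    settings: DesignSettings = DesignSettings(),
    background: Iterable[Peptide] | None = None,
    masses: ResidueMassTable | None = None,
) -> list[Transition]:
    """Design transitions for the given (mature-chain) protein records.

    Proteins are digested as given — pass mature chains, since only those
    are present in the supernatant. Exactly one transition per peptide is
    flagged as quantifier.
    """
    masses = masses or default_mass_table()
    model = settings.instrument_model or default_instrument_model()
    background_list = list(background) if background is not None else None
    transitions: list[Transition] = []
    for protein in proteins:
        peptides = tryptic_digest(
            protein, settings.missed_cleavages, settings.cleavage_rule
        )
        candidates = filter_candidates(
            peptides,
            settings.min_len,
            settings.max_len,
            settings.excluded_residues,
            background_list,
        )
        if not candidates:
            warnings.warn(f"protein {protein.id!r} yields no candidate peptides")
            continue
        for pep in candidates:
            prec = precursor_mz(pep.sequence, settings.precursor_charge, masses)
            ce, dp = predict_params(model, prec)
            if pep.sequence in settings.explicit_ions:
                products = select_product_ions(
                    pep, policy="explicit",
                    explicit=settings.explicit_ions[pep.sequence], masses=masses,
                )
            else:
                products = select_product_ions(
                    pep, n=settings.n_products, policy=settings.policy,
                    precursor_charge=settings.precursor_charge, masses=masses,
                )
            if not products:
                continue
            quant_label = settings.quantifier_ions.get(
                pep.sequence, products[0].label
            )
            if quant_label not in {ion.label for ion in products}:
                quant_label = products[0].label  # keep exactly one quantifier
            for rank, ion in enumerate(products):
                transitions.append(
                    Transition(
                        peptide=pep,
                        precursor_mz=prec,
                        precursor_charge=settings.precursor_charge,
                        product=ion,
                        declustering_potential=dp,
                        collision_energy=ce,
                        retention_time=settings.retention_times.get(pep.sequence),
                        quantifier=(ion.label == quant_label),
                        product_rank=rank,
                    )
                )
    return transitions


def read_transition_list(path: str | Path) -> list[Transition]:
    """Read a transition-list CSV written by :func:`export_transition_list`.

    Peptide positions within the parent are not stored in the CSV, so the
    reconstructed :class:`~mrmquant.digest.Peptide` spans 1..len(sequence).
    """
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    transitions = []
    for _, row in df.iterrows():
        seq = str(row["peptide"])
        label = str(row["product_ion"])
        rt = row["rt_min"]
        transitions.append(
            Transition(
                peptide=Peptide(seq, str(row["protein_id"]), 1, len(seq)),
                precursor_mz=float(row["precursor_mz"]),
                precursor_charge=int(row["precursor_charge"]),
                product=FragmentIon(
                    label[0], int(label[1:]), int(row["product_charge"]),
                    float(row["product_mz"]),
                ),
                declustering_potential=float(row["dp_volts"]),
                collision_energy=float(row["ce_volts"]),
                retention_time=None if pd.isna(rt) else float(rt),
                quantifier=bool(int(row["quantifier"])),
            )
        )
    return transitions


TRANSITION_CSV_COLUMNS = (
    "protein_id,peptide,precursor_mz,precursor_charge,product_ion,product_mz,"
    "product_charge,dp_volts,ce_volts,rt_min,quantifier"
)


def export_transition_list(
    transitions: Sequence[Transition],
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write the transition list as CSV (importable into acquisition software).

    m/z to two decimals, voltages to one; empty rt field when no measured
    retention time is attached; stable row order (protein, peptide start,
    product rank), so identical inputs yield byte-identical files.
    """
    if not transitions:
        raise ValueError("refusing to export an empty transition list")
    ordered = sorted(
        transitions, key=lambda t: (t.protein_id, t.peptide.start, t.product_rank)
    )
    lines = []
    if provenance:
        for key in sorted(provenance):
            lines.append(f"# {key}: {provenance[key]}")
    lines.append(TRANSITION_CSV_COLUMNS)
    for t in ordered:
        rt = "" if t.retention_time is None else f"{t.retention_time:.2f}"
        lines.append(
            f"{t.protein_id},{t.peptide.sequence},{t.precursor_mz:.2f},"
            f"{t.precursor_charge},{t.product.label},{t.product.mz:.2f},"
            f"{t.product.charge},{t.declustering_potential:.1f},"
            f"{t.collision_energy:.1f},{rt},{int(t.quantifier)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
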