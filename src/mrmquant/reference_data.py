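"""Published reference values for the B. pumilus protease MRM assay.

The package was built around a published label-free MRM study of two
secreted *Bacillus pumilus* serine proteases — the subtilisin-like protease
AprBp (381-residue precursor, mature chain 108-381) and the glutamyl
endopeptidase GseBp (303-residue precursor, mature chain 89-303) — expressed
natively and from recombinant *B. subtilis* strains. Two kinds of reported
values are bundled here as plain data:

* the final QTRAP 6500 transition list (six proteotypic peptides, three
  singly charged y-ion products each, with declustering potential, collision
  energy and measured retention time), and
* the reported strain-panel quantification (total supernatant protein,
  target concentration in the measurement vial and back-calculated
  supernatant concentration, per strain and inducer state).

These are inputs for instrument-model fitting, for the synthetic strain
panel, and for regression tests; nothing in this module is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median


@dataclass(frozen=True)
class ReferencePeptide:
    protein: str
    peptide: str
    precursor_mz: float  # Q1, doubly protonated
    precursor_charge: int
    products: tuple[tuple[str, float], ...]  # (y-ion label, Q3 m/z), charge 1+
    quantifier: str  # label of the quantifier product ion
    declustering_potential: float  # V
    collision_energy: float  # V
    retention_time: float  # min


REFERENCE_PEPTIDES: tuple[ReferencePeptide, ...] = (
    ReferencePeptide(
        "AprBp", "APAVHAQGYK", 521.27, 2,
        (("y7", 802.42), ("y6", 703.35), ("y5", 566.29)),
        "y7", 69.1, 27.6, 1.03,
    ),
    ReferencePeptide(
        "AprBp", "NAVDTANNR", 487.73, 2,
        (("y8", 860.42), ("y6", 690.31), ("y5", 575.28)),
        "y8", 66.7, 26.4, 0.79,
    ),
    ReferencePeptide(
        "AprBp", "LENTATPLGNSFYYGK", 887.93, 2,
        (("y10", 1145.56), ("y9", 1048.50), ("y8", 935.42)),
        "y10", 95.8, 40.8, 5.62,
    ),
    ReferencePeptide(
        "GseBp", "TDTNIGNTVGYR", 655.82, 2,
        (("y9", 993.51), ("y7", 766.38), ("y6", 709.36)),
        "y9", 78.9, 32.5, 1.39,
    ),
    ReferencePeptide(
        "GseBp", "ISGYPGDK", 418.71, 2,
        (("y7", 723.33), ("y6", 636.29), ("y4", 416.21)),
        "y7", 61.6, 23.9, 1.11,
    ),
    ReferencePeptide(
        "GseBp", "ATAAFVEFINYAK", 722.87, 2,
        (("y9", 1130.58), ("y8", 983.51), ("y7", 884.45)),
        "y9", 83.8, 34.9, 6.46,
    ),
)

#: Peptides whose top transition is the quantifier for each protein.
QUANTIFIER_PEPTIDES: dict[str, str] = {"AprBp": "NAVDTANNR", "GseBp": "TDTNIGNTVGYR"}

#: Reported calibration behaviour per target: serial dilution 0.0033-3.3
#: ug/mL; upper linearity bound and lower limit of quantification (ug/mL).
CALIBRATION_LEVELS: tuple[float, ...] = (0.0033, 0.0165, 0.033, 0.165, 0.33, 1.65, 3.3)
REPORTED_LINEAR_MAX = {"AprBp": 3.3, "GseBp": 1.65}
REPORTED_LLOQ = {"AprBp": 0.0033, "GseBp": 0.003}


@dataclass(frozen=True)
class StrainQuantRow:
    """One reported (strain, target, inducer-state) quantification."""

    strain: str
    target: str
    induced: bool
    total_protein_sn: float  # ug/mL total protein in supernatant
    vial_conc: float  # ug/mL target in the measurement vial
    sn_conc: float  # ug/mL target back-calculated in supernatant


STRAIN_QUANT_ROWS: tuple[StrainQuantRow, ...] = (
    StrainQuantRow("B. pumilus 3-19", "AprBp", False, 4.5, 6.0, 1.63),
    StrainQuantRow("B. subtilis AT1", "AprBp", False, 0.32, 0.0, 0.0),
    StrainQuantRow("B. subtilis MRB044", "AprBp", False, 2.0, 0.2, 0.024),
    StrainQuantRow("B. subtilis MRB044", "AprBp", True, 5.0, 5.0, 1.5),
    StrainQuantRow("B. subtilis MRB046", "AprBp", False, 1.3, 0.45, 0.005),
    StrainQuantRow("B. subtilis MRB046", "AprBp", True, 1.8, 0.25, 0.03),
    StrainQuantRow("B. pumilus 3-19", "GseBp", False, 4.5, 5.0, 1.3),
    StrainQuantRow("B. subtilis AT1", "GseBp", False, 0.32, 0.0, 0.0),
    StrainQuantRow("B. subtilis MRB047", "GseBp", False, 1.2, 0.005, 0.00036),
    StrainQuantRow("B. subtilis MRB047", "GseBp", True, 1.65, 0.05, 0.005),
    StrainQuantRow("B. subtilis MRB049", "GseBp", False, 2.06, 0.05, 0.006),
    StrainQuantRow("B. subtilis MRB049", "GseBp", True, 3.2, 0.3, 0.06),
)


def derive_vial_total_constant(
    rows: tuple[StrainQuantRow, ...] = STRAIN_QUANT_ROWS,
) -> float:
    """Robustly derive the vial total-protein concentration C (ug/mL).

    The reported supernatant concentration follows
    ``sn = vial * total_sn / C`` where C — the total-protein concentration of
    the measurement vial — was not reported. Each nonzero row implies a
    candidate ``C = vial * total_sn / sn``; the median over rows is used
    because one row is a clear outlier. The derived value is 50/3 ~ 16.67.
    """
    implied = [
        r.vial_conc * r.total_protein_sn / r.sn_conc
        for r in rows
        if r.sn_conc > 0
    ]
    if not implied:
        raise ValueError("no rows with nonzero supernatant concentration")
    return float(median(implied))


#: Default vial total-protein concentration used for vial->SN conversion.
VIAL_TOTAL_CONC = derive_vial_total_constant()

#: Rows consistent with VIAL_TOTAL_CONC to within 0.01 ug/mL (0.0001 for
#: sub-0.001 rows). Two rows are not: MRB046 uninduced (AprBp) and
#: B. pumilus 3-19 (GseBp); they are carried as reported, not corrected.
INCONSISTENT_ROWS: tuple[tuple[str, str, bool], ...] = (
    ("B. subtilis MRB046", "AprBp", False),
    ("B. pumilus 3-19", "GseBp", False),
)


def consistent_rows() -> list[StrainQuantRow]:
    """Nonzero rows whose sn/vial values satisfy the derived constant."""
    skip = set(INCONSISTENT_ROWS)
    return [
        r
        for r in STRAIN_QUANT_ROWS
        if r.sn_conc > 0 and (r.strain, r.target, r.induced) not in skip
    ]
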