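"""Synthetic MRM chromatograms, calibration series and a strain panel.

The generator emulates what the quantification stages assume about a triple
quadrupole acquisition: each transition of a detectable peptide elutes as a
single Gaussian peak whose *area* is proportional to the analyte
concentration (area = response_factor * concentration), riding on a flat
baseline with additive Gaussian noise. Retention time is drawn once per
trace around the transition's nominal value (run-to-run jitter). Optional
ingredients: an area plateau above a saturation level (loss of linearity at
the top of a calibration curve), per-trace multiplicative response
variability, an additive area noise floor, and a contaminant interference
peak.

Everything is seeded; identical seed + inputs give identical traces.

The module also bundles a fully synthetic stand-in proteome: precursor
sequences with the chain layout of the AprBp (381 aa; mature 108-381) and
GseBp (303 aa; mature 89-303) proteases whose mature chains yield the six
published proteotypic peptides on tryptic digestion. The real precursor
sequences were not republished with the study, so filler tryptic peptides
(including deliberately filter-failing ones) make up the remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import DesignSettings, Transition, build_transition_table
from .digest import tryptic_digest
from .proteome import ProteinRecord, extract_chain
from .reference_data import (
    CALIBRATION_LEVELS,
    QUANTIFIER_PEPTIDES,
    REFERENCE_PEPTIDES,
    STRAIN_QUANT_ROWS,
    VIAL_TOTAL_CONC,
)

# ---------------------------------------------------------------------------
# traces


@dataclass(frozen=True)
class ChromatogramTrace:
    """Time/intensity series of one transition in one sample."""

    sample_id: str
    transition_key: tuple[str, str]  # (peptide sequence, product-ion label)
    times: np.ndarray  # minutes, uniform grid
    intensities: np.ndarray  # counts, >= 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        if times.shape != intensities.shape or times.ndim != 1:
            raise ValueError("times and intensities must be 1-D and equal length")
        if len(times) < 2:
            raise ValueError("trace needs at least two points")
        steps = np.diff(times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("times must be strictly increasing on a uniform grid")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)

    @property
    def grid_step(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the chromatogram generator.

    Units: concentrations ug/mL, times minutes, intensities counts;
    ``response_factor`` is peak area (counts * min) per ug/mL, either a
    scalar or a per-transition-key mapping.
    """

    response_factor: float | Mapping[tuple[str, str], float] = 1e5
    rt_mean: float = 1.0  # fallback when a transition has no nominal RT
    rt_jitter_sd: float = 0.01
    peak_sigma: float = 0.05
    baseline_level: float = 20.0
    baseline_noise_sd: float = 4.0
    #: per-trace multiplicative response variability (relative SD of area)
    response_cv: float = 0.05
    #: additive area noise floor (area units), e.g. chemical background
    area_noise_sd: float = 0.0
    interference_probability: float = 0.0
    interference_offset: float = 0.3  # min, relative to the analyte RT
    interference_area: float = 0.0
    grid_step: float = 0.005  # min; ~ the 20 ms dwell-cycle sampling
    run_length: float = 15.0  # min
    saturation_level: float | None = None  # ug/mL; area plateaus above

    def __post_init__(self) -> None:
        if isinstance(self.response_factor, (int, float)):
            if self.response_factor <= 0:
                raise ValueError("response_factor must be positive")
        if self.peak_sigma <= 0 or self.grid_step <= 0 or self.run_length <= 0:
            raise ValueError("peak_sigma, grid_step and run_length must be positive")

    def response_for(self, key: tuple[str, str]) -> float:
        if isinstance(self.response_factor, Mapping):
            return float(self.response_factor[key])
        return float(self.response_factor)


Seed = "int | np.random.SeedSequence | np.random.Generator"


def simulate_trace(
    transition_key: tuple[str, str],
    concentration: float,
    config: SimulationConfig,
    seed,
    rt_mean: float | None = None,
    sample_id: str = "",
) -> ChromatogramTrace:
    """One Gaussian-peak trace at the given analyte concentration."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if config.peak_sigma * 4 < 8 * config.grid_step:
        raise ValueError(
            "grid too coarse: need >= 8 points across +-2 peak sigma "
            f"(sigma {config.peak_sigma} min, step {config.grid_step} min)"
        )
    rng = np.random.default_rng(seed)
    rt_nominal = config.rt_mean if rt_mean is None else rt_mean
    times = np.arange(0.0, config.run_length + config.grid_step / 2, config.grid_step)

    rt = rng.normal(rt_nominal, config.rt_jitter_sd) if config.rt_jitter_sd > 0 else rt_nominal
    conc_eff = concentration
    if config.saturation_level is not None:
        conc_eff = min(conc_eff, config.saturation_level)
    area = config.response_for(transition_key) * conc_eff
    if config.response_cv > 0:
        area *= math.exp(rng.normal(0.0, config.response_cv))
    if config.area_noise_sd > 0:
        area += rng.normal(0.0, config.area_noise_sd)
    area = max(area, 0.0)

    signal = area / (config.peak_sigma * math.sqrt(2 * math.pi)) * np.exp(
        -((times - rt) ** 2) / (2 * config.peak_sigma**2)
    )
    if config.interference_probability > 0 and rng.random() < config.interference_probability:
        irt = rt + config.interference_offset
        signal += config.interference_area / (
            config.peak_sigma * math.sqrt(2 * math.pi)
        ) * np.exp(-((times - irt) ** 2) / (2 * config.peak_sigma**2))

    intensities = signal + config.baseline_level
    if config.baseline_noise_sd > 0:
        intensities = intensities + rng.normal(0.0, config.baseline_noise_sd, times.shape)
    intensities = np.clip(intensities, 0.0, None)
    return ChromatogramTrace(sample_id, tuple(transition_key), times, intensities)


def simulate_calibration_series(
    levels: Sequence[float] | None = None,
    replicates: int = 3,
    config: SimulationConfig = SimulationConfig(),
    seed=0,
    transition_key: tuple[str, str] = ("NAVDTANNR", "y8"),
    rt_mean: float | None = None,
) -> list[ChromatogramTrace]:
    """Traces of a serial-dilution calibration series, level x replicate.

    Default levels span the published serial dilution 0.0033-3.3 ug/mL
    (decade steps plus midpoints). Each trace gets independent noise from a
    spawned child seed.
    """
    levels = list(CALIBRATION_LEVELS) if levels is None else list(levels)
    if any(level <= 0 for level in levels):
        raise ValueError("calibration levels must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    children = np.random.SeedSequence(seed).spawn(len(levels) * replicates)
    traces = []
    i = 0
    for level in levels:
        for rep in range(1, replicates + 1):
            traces.append(
                simulate_trace(
                    transition_key,
                    level,
                    config,
                    children[i],
                    rt_mean=rt_mean,
                    sample_id=f"cal_{level:g}_r{rep}",
                )
            )
            i += 1
    return traces


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleRow:
    """One sample: a culture supernatant prepared for MRM measurement."""

    sample_id: str
    strain: str
    induced: bool
    total_protein_sn: float  # ug/mL total protein in the supernatant
    vial_conc: Mapping[str, float]  # target id -> true ug/mL in the vial
    dilution_factor: float = 1.0  # vial -> reported scale, kept at 1 here

    def __post_init__(self) -> None:
        if self.total_protein_sn < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative total protein")
        if any(v < 0 for v in self.vial_conc.values()):
            raise ValueError(f"sample {self.sample_id!r}: negative vial concentration")
        object.__setattr__(self, "vial_conc", dict(self.vial_conc))


@dataclass(frozen=True)
class SampleSheet:
    rows: tuple[SampleRow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def targets(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self.rows:
            for t in row.vial_conc:
                seen.setdefault(t, None)
        return list(seen)

    def to_csv(self, path: str | Path) -> None:
        targets = self.targets
        records = []
        for r in self.rows:
            rec = {
                "sample_id": r.sample_id,
                "strain": r.strain,
                "induced": int(r.induced),
                "total_protein_sn": r.total_protein_sn,
                "dilution_factor": r.dilution_factor,
            }
            for t in targets:
                rec[f"vial_conc_{t}"] = r.vial_conc.get(t, "")
            records.append(rec)
        pd.DataFrame.from_records(records).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, comment="#")
        target_cols = [c for c in df.columns if c.startswith("vial_conc_")]
        rows = []
        for _, rec in df.iterrows():
            vial = {
                c[len("vial_conc_"):]: float(rec[c])
                for c in target_cols
                if pd.notna(rec[c]) and rec[c] != ""
            }
            rows.append(
                SampleRow(
                    sample_id=str(rec["sample_id"]),
                    strain=str(rec["strain"]),
                    induced=bool(int(rec["induced"])),
                    total_protein_sn=float(rec["total_protein_sn"]),
                    vial_conc=vial,
                    dilution_factor=float(rec.get("dilution_factor", 1.0)),
                )
            )
        return cls(tuple(rows))


def reference_sample_sheet(vial_total_conc: float = VIAL_TOTAL_CONC) -> SampleSheet:
    """The bundled strain panel: 10 samples mirroring the published study.

    Ground truth is anchored on the *reported supernatant concentrations*
    (the quantities the published fold-changes are ratios of); the true vial
    concentration of each sample is back-derived as
    ``sn * C / total_protein_sn`` with the derived vial-total constant C.
    For most rows this reproduces the reported vial value; for the one
    internally inconsistent row (MRB046 uninduced) the supernatant value
    wins, keeping the panel self-consistent end to end.
    """
    grouped: dict[tuple[str, bool], dict] = {}
    order: list[tuple[str, bool]] = []
    for row in STRAIN_QUANT_ROWS:
        key = (row.strain, row.induced)
        if key not in grouped:
            grouped[key] = {"total": row.total_protein_sn, "vial": {}}
            order.append(key)
        entry = grouped[key]
        if row.sn_conc > 0:
            entry["vial"][row.target] = (
                row.sn_conc * vial_total_conc / row.total_protein_sn
            )
        else:
            entry["vial"][row.target] = 0.0
    rows = []
    for strain, induced in order:
        entry = grouped[(strain, induced)]
        short = strain.replace("B. pumilus ", "Bp").replace("B. subtilis ", "")
        rows.append(
            SampleRow(
                sample_id=f"{short}{'+' if induced else '-'}",
                strain=strain,
                induced=induced,
                total_protein_sn=entry["total"],
                vial_conc=entry["vial"],
            )
        )
    return SampleSheet(tuple(rows))


# ---------------------------------------------------------------------------
# study simulation


def target_of(transition: Transition) -> str:
    """Protein target id of a transition (chain suffixes stripped)."""
    return transition.protein_id.split("|")[0]


def simulate_study(
    sheet: SampleSheet,
    assay: Sequence[Transition],
    config: SimulationConfig = SimulationConfig(),
    seed=0,
) -> list[ChromatogramTrace]:
    """One trace per sample x transition of that sample's targets.

    Negative-control samples (true concentration 0) give baseline-only
    traces. Transitions carry their nominal retention time into the
    simulation when present.
    """
    assay_targets = {target_of(t) for t in assay}
    sheet_targets = set(sheet.targets)
    missing = sheet_targets - assay_targets
    if missing:
        raise ValueError(f"sample-sheet targets not covered by assay: {sorted(missing)}")
    tasks = [
        (sample, transition)
        for sample in sheet
        for transition in assay
        if target_of(transition) in sample.vial_conc
    ]
    children = np.random.SeedSequence(seed).spawn(len(tasks))
    traces = []
    for child, (sample, transition) in zip(children, tasks):
        conc = sample.vial_conc[target_of(transition)]
        traces.append(
            simulate_trace(
                transition.key,
                conc,
                config,
                child,
                rt_mean=transition.retention_time,
                sample_id=sample.sample_id,
            )
        )
    return traces


def traces_to_csv(
    traces: Iterable[ChromatogramTrace], path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Long-format CSV: sample_id, peptide, product_ion, time_min, intensity."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": tr.sample_id,
                    "peptide": tr.transition_key[0],
                    "product_ion": tr.transition_key[1],
                    "time_min": tr.times,
                    "intensity": tr.intensities,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    with Path(path).open("w") as fh:
        if provenance:
            for key in sorted(provenance):
                fh.write(f"# {key}: {provenance[key]}\n")
        df.to_csv(fh, index=False)


def traces_from_csv(path: str | Path) -> list[ChromatogramTrace]:
    df = pd.read_csv(path, comment="#")
    traces = []
    for (sample_id, pep, ion), grp in df.groupby(
        ["sample_id", "peptide", "product_ion"], sort=False
    ):
        traces.append(
            ChromatogramTrace(
                str(sample_id),
                (str(pep), str(ion)),
                grp["time_min"].to_numpy(),
                grp["intensity"].to_numpy(),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# synthetic stand-in proteome

_APR_FILLERS_BEFORE = (
    "GASTLVNDQEGHFWSYLTNVAGER",  # clean filler, passes design filters
    "VLDNGSTAEK",  # shared with the GseBp stand-in -> non-proteotypic
    "ACDEFGHIWK",  # contains Cys -> excluded by residue filter
)
_APR_FILLERS_MIDDLE = (
    "TMLNGAQSVHEK",  # contains Met -> excluded
    "AGK",  # too short
    "VVSHELDNTAGTQFWYSGVNDQSTLAEK",  # 28 aa, too long
)
_APR_FILLERS_AFTER = (
    "HNEQTSGLVADFYWSTR",
    "QDSTVNLAGHEWFYSR",
)

_GSE_FILLERS_BEFORE = (
    "ESTVLNDAGQHWFYSR",
    "VLDNGSTAEK",  # shared with the AprBp stand-in
)
_GSE_FILLERS_MIDDLE = (
    "FYWSTNVLDAGQEHR",
    "NGK",  # too short
)
_GSE_FILLERS_AFTER = (
    "GQDNSTVLAEHWFYTR",
)

_PAD_ALPHABET = "LSTVAGNDEQHFYW"  # no K/R/P/C/M: inert between cleavage sites


def _pad(prefix: str, length: int) -> str:
    s = prefix
    while len(s) < length:
        s += _PAD_ALPHABET
    return s[:length]


def _mature_chain(
    real_peptides: Sequence[str],
    before: Sequence[str],
    middle: Sequence[str],
    after: Sequence[str],
    length: int,
) -> str:
    units = [*before, real_peptides[0], *middle, real_peptides[1], *after, real_peptides[2]]
    body = "".join(units)
    remaining = length - len(body)
    if remaining < 0:
        raise ValueError("filler layout longer than requested mature length")
    if remaining:
        # trailing segment; needs no terminal K/R (protein C-terminus)
        body += _pad("Q", remaining)
    return body


def demo_proteins() -> list[ProteinRecord]:
    """Synthetic stand-in precursors for AprBp and GseBp.

    Chain layout matches the published annotation (AprBp: signal 1-29,
    propeptide 30-107, mature 108-381; GseBp: signal 1-26, propeptide 27-88,
    mature 89-303) and the mature chains release the six published
    proteotypic peptides on tryptic digestion. All other residues are
    synthetic filler.
    """
    apr_real = [p.peptide for p in REFERENCE_PEPTIDES if p.protein == "AprBp"]
    gse_real = [p.peptide for p in REFERENCE_PEPTIDES if p.protein == "GseBp"]

    apr_signal = _pad("MKWLSAVVTLALSVTGAFA", 28) + "K"  # 29 aa
    apr_pro = _pad("SEQHNVLDAGT", 77) + "R"  # 78 aa
    apr_mature = _mature_chain(
        apr_real, _APR_FILLERS_BEFORE, _APR_FILLERS_MIDDLE, _APR_FILLERS_AFTER, 274
    )
    apr = ProteinRecord(
        id="AprBp",
        description="synthetic stand-in precursor, subtilisin-like protease layout",
        sequence=apr_signal + apr_pro + apr_mature,
    ).with_chains({"signal": (1, 29), "propeptide": (30, 107), "mature": (108, 381)})

    gse_signal = _pad("MKLNSVVAGLSLTAFA", 25) + "K"  # 26 aa
    gse_pro = _pad("ADQHNSLVGT", 61) + "R"  # 62 aa
    gse_mature = _mature_chain(
        gse_real, _GSE_FILLERS_BEFORE, _GSE_FILLERS_MIDDLE, _GSE_FILLERS_AFTER, 215
    )
    gse = ProteinRecord(
        id="GseBp",
        description="synthetic stand-in precursor, glutamyl endopeptidase layout",
        sequence=gse_signal + gse_pro + gse_mature,
    ).with_chains({"signal": (1, 26), "propeptide": (27, 88), "mature": (89, 303)})

    for record, expected in ((apr, 381), (gse, 303)):
        if len(record) != expected:
            raise AssertionError(
                f"stand-in {record.id} has {len(record)} residues, expected {expected}"
            )
    return [apr, gse]


def demo_background() -> list[ProteinRecord]:
    """Synthetic background proteome: the two targets plus decoys.

    One decoy shares the filler peptide VLDNGSTAEK with both targets, so
    that peptide fails the proteotypicity (uniqueness) rule.
    """
    decoy1 = ProteinRecord(
        id="decoy1",
        description="synthetic background protein sharing a filler peptide",
        sequence="MSTQHAGLVNDEFYWRVLDNGSTAEKGHQSTLVNDAEFYWSR",
    )
    decoy2 = ProteinRecord(
        id="decoy2",
        description="synthetic background protein",
        sequence="MGTNDSLVAQEHYFWKSTLNVDAGQEHFYWR",
    )
    return demo_proteins() + [decoy1, decoy2]


def reference_design_settings() -> DesignSettings:
    """Design settings that reproduce the published assay's explicit picks."""
    return DesignSettings(
        explicit_ions={
            p.peptide: tuple(label for label, _ in p.products)
            for p in REFERENCE_PEPTIDES
        },
        quantifier_ions={p.peptide: p.quantifier for p in REFERENCE_PEPTIDES},
        retention_times={p.peptide: p.retention_time for p in REFERENCE_PEPTIDES},
    )


def reference_assay(background: bool = True) -> list[Transition]:
    """The 18-transition published assay, rebuilt from the stand-in proteome.

    Designs on the mature chains, then keeps the six published peptides.
    Quantifier peptides per protein follow the published choice
    (NAVDTANNR for AprBp, TDTNIGNTVGYR for GseBp).
    """
    matures = [extract_chain(p, "mature") for p in demo_proteins()]
    bg = None
    if background:
        bg = [
            pep
            for prot in [extract_chain(p, "mature") for p in demo_proteins()]
            + [b for b in demo_background() if b.id.startswith("decoy")]
            for pep in tryptic_digest(prot)
        ]
        # uniqueness is judged on the base protein id, not the chain slice
        bg = [replace(p, parent_id=p.parent_id.split("|")[0]) for p in bg]
    transitions = build_transition_table(matures, reference_design_settings(), background=bg)
    wanted = {p.peptide for p in REFERENCE_PEPTIDES}
    return [t for t in transitions if t.peptide.sequence in wanted]


def study_response_factors(
    base: float = 1e5, quantifier_boost: float = 1.0
) -> dict[tuple[str, str], float]:
    """Per-transition response factors for the reference assay.

    Confirmatory transitions respond at fixed fractions of the quantifier
    (secondary fragments are less intense); the exact fractions are
    arbitrary but deterministic.
    """
    factors = {}
    for p in REFERENCE_PEPTIDES:
        for rank, (label, _) in enumerate(p.products):
            scale = 1.0 if label == p.quantifier else (0.6, 0.45, 0.3)[min(rank, 2)]
            factors[(p.peptide, label)] = base * scale * (
                quantifier_boost if label == p.quantifier else 1.0
            )
    return factors
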