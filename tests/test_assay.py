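"""Mass arithmetic, candidate filtering, instrument model, transition table."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmquant.assay import (
    DesignSettings,
    InstrumentModel,
    build_transition_table,
    export_transition_list,
    filter_candidates,
    fit_instrument_model,
    fragment_by_label,
    fragment_series,
    peptide_monoisotopic_mass,
    precursor_mz,
    predict_params,
    read_transition_list,
    select_product_ions,
)
from mrmquant.digest import Peptide, tryptic_digest
from mrmquant.masses import PROTON_MASS

peptide_strings = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=30)


# ---------------------------------------------------------------------------
# masses and fragments


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("G", 75.032),  # glycine + water
        ("GGGGGGGG", 474.182),  # 8 * 57.02146 + water
        ("NAVDTANNR", 973.458),
    ],
)
def test_peptide_monoisotopic_mass(seq, expected, masses):
    assert peptide_monoisotopic_mass(seq, masses) == pytest.approx(expected, abs=1e-3)


def test_precursor_mz_charge_relation(masses):
    m1 = precursor_mz("NAVDTANNR", 1, masses)
    m2 = precursor_mz("NAVDTANNR", 2, masses)
    assert m1 == pytest.approx(peptide_monoisotopic_mass("NAVDTANNR", masses) + PROTON_MASS, abs=1e-9)
    assert m2 == pytest.approx((m1 + PROTON_MASS) / 2, abs=1e-9)


def test_precursor_mz_rejects_zero_charge():
    with pytest.raises(ValueError):
        precursor_mz("NAVDTANNR", 0)


def test_fragment_series_requires_two_residues():
    with pytest.raises(ValueError):
        fragment_series("G")


@settings(derandomize=True, max_examples=200)
@given(seq=peptide_strings)
def test_by_mass_conservation_identity(masses, seq):
    """b_i + y_(n-i) = M + 2*proton at machine precision, for every i."""
    total = peptide_monoisotopic_mass(seq, masses)
    ions = {(f.series, f.index): f.mz for f in fragment_series(seq, masses)}
    n = len(seq)
    for i in range(1, n):
        assert ions[("b", i)] + ions[("y", n - i)] == pytest.approx(
            total + 2 * PROTON_MASS, abs=1e-9
        )


@settings(derandomize=True, max_examples=100)
@given(seq=peptide_strings)
def test_fragments_match_pyteomics_fast_mass(masses, seq):
    """Independent oracle: pyteomics' ion mass calculator."""
    from pyteomics import mass as pmass

    n = len(seq)
    ours = {(f.series, f.index): f.mz for f in fragment_series(seq, masses)}
    for i in (1, n - 1):
        assert ours[("b", i)] == pytest.approx(
            pmass.fast_mass(seq[:i], ion_type="b", charge=1), abs=1e-4
        )
        assert ours[("y", i)] == pytest.approx(
            pmass.fast_mass(seq[n - i :], ion_type="y", charge=1), abs=1e-4
        )


# ---------------------------------------------------------------------------
# candidate filtering


def _pep(seq):
    return Peptide(seq, "p", 1, len(seq))


def test_filter_rules():
    peps = [_pep("NAVDTANNR"), _pep("AK"), _pep("ACDEFGHIK")]
    assert [p.sequence for p in filter_candidates(peps)] == ["NAVDTANNR"]
    # 26-mer rejected, 25-mer kept
    assert filter_candidates([_pep("A" * 26)]) == []
    assert len(filter_candidates([_pep("A" * 24 + "K")])) == 1


def test_filter_background_uniqueness():
    background = [
        Peptide("NAVDTANNR", "target", 1, 9),
        Peptide("VLDNGSTAEK", "target", 10, 19),
        Peptide("VLDNGSTAEK", "other", 1, 10),
    ]
    kept = filter_candidates([_pep("NAVDTANNR"), _pep("VLDNGSTAEK")], background=background)
    assert [p.sequence for p in kept] == ["NAVDTANNR"]
    # absent from the background entirely -> also non-proteotypic
    assert filter_candidates([_pep("WWWWWWWWW")], background=background) == []


def test_filter_is_idempotent(demo_matures):
    peps = [p for m in demo_matures for p in tryptic_digest(m)]
    once = filter_candidates(peps)
    assert filter_candidates(once) == once


def test_filter_bad_bounds():
    with pytest.raises(ValueError):
        filter_candidates([], min_len=10, max_len=8)


# ---------------------------------------------------------------------------
# product-ion selection


def test_explicit_policy_reproduces_published_picks(ref_peptides, masses):
    for ref in ref_peptides:
        labels = [label for label, _ in ref.products]
        ions = select_product_ions(ref.peptide, policy="explicit", explicit=labels, masses=masses)
        for ion, (label, published_mz) in zip(ions, ref.products):
            assert ion.label == label
            assert ion.mz == pytest.approx(published_mz, abs=0.01)


def test_default_policy_prefers_high_mz_y_ions(masses):
    ions = select_product_ions("NAVDTANNR", n=3, masses=masses)
    assert all(f.series == "y" and f.index >= 3 for f in ions)
    assert ions[0].mz > ions[1].mz > ions[2].mz
    prec = precursor_mz("NAVDTANNR", 2, masses)
    assert all(abs(f.mz - prec) > 3 for f in ions)


def test_default_policy_warns_when_short_of_candidates(masses):
    with pytest.warns(UserWarning, match="candidates"):
        ions = select_product_ions("AGAGK", n=5, masses=masses)
    assert 0 < len(ions) < 5


# ---------------------------------------------------------------------------
# instrument model


def _ref_pairs(ref_peptides):
    ce = [(p.precursor_mz, p.collision_energy) for p in ref_peptides]
    dp = [(p.precursor_mz, p.declustering_potential) for p in ref_peptides]
    return ce, dp


def test_exact_line_fit():
    model = fit_instrument_model([(100, 10), (200, 20)], [(100, 10), (200, 20)])
    assert model.ce_slope == pytest.approx(0.1, abs=1e-12)
    assert model.ce_intercept == pytest.approx(0.0, abs=1e-9)


def test_fit_requires_distinct_mz():
    with pytest.raises(ValueError):
        fit_instrument_model([(100, 10), (100, 12)], [(100, 10), (200, 20)])


def test_published_assay_fit_coefficients(ref_peptides):
    """The six published (m/z, CE/DP) pairs define near-perfect lines."""
    from scipy.stats import linregress

    ce, dp = _ref_pairs(ref_peptides)
    model = fit_instrument_model(ce, dp)
    assert model.ce_slope == pytest.approx(0.03605, abs=5e-4)
    assert model.ce_intercept == pytest.approx(8.820, abs=0.05)
    assert model.dp_slope == pytest.approx(0.07284, abs=5e-4)
    assert model.dp_intercept == pytest.approx(31.135, abs=0.05)
    # cross-check against an independent regression routine
    lr = linregress([x for x, _ in ce], [y for _, y in ce])
    assert model.ce_slope == pytest.approx(lr.slope, abs=1e-9)
    assert model.ce_intercept == pytest.approx(lr.intercept, abs=1e-9)
    assert max(abs(r) for r in model.ce_residuals) < 0.15


def test_predict_params_reproduces_published_values(ref_peptides):
    ce, dp = _ref_pairs(ref_peptides)
    model = fit_instrument_model(ce, dp)
    for ref in ref_peptides:
        pce, pdp = predict_params(model, ref.precursor_mz)
        assert pce == pytest.approx(ref.collision_energy, abs=0.1 + 1e-6)
        assert pdp == pytest.approx(ref.declustering_potential, abs=0.1 + 1e-6)


def test_degenerate_constant_model():
    model = InstrumentModel(0.0, 25.0, 0.0, 70.0)
    assert predict_params(model, 400.0) == (25.0, 70.0)
    assert predict_params(model, 900.0) == (25.0, 70.0)


# ---------------------------------------------------------------------------
# transition table and export


def test_reference_assay_reproduces_every_published_mz(ref_assay, ref_peptides):
    assert len(ref_assay) == 18  # 6 peptides x 3 products
    by_pep = {}
    for t in ref_assay:
        by_pep.setdefault(t.peptide.sequence, []).append(t)
    for ref in ref_peptides:
        mine = by_pep[ref.peptide]
        assert mine[0].precursor_mz == pytest.approx(ref.precursor_mz, abs=0.01)
        got = {t.product.label: t.product.mz for t in mine}
        for label, published_mz in ref.products:
            assert got[label] == pytest.approx(published_mz, abs=0.01)


def test_exactly_one_quantifier_per_peptide(ref_assay):
    by_pep = {}
    for t in ref_assay:
        by_pep.setdefault(t.peptide.sequence, []).append(t.quantifier)
    for flags in by_pep.values():
        assert sum(flags) == 1


def test_protein_without_cleavage_sites_yields_whole_chain(masses):
    from mrmquant.proteome import ProteinRecord

    prot = ProteinRecord("tiny", "", "AGSTVNDEQH")  # no K/R anywhere
    table = build_transition_table([prot], DesignSettings())
    peptides = {t.peptide.sequence for t in table}
    assert peptides == {"AGSTVNDEQH"}


def test_protein_with_no_candidates_warns():
    from mrmquant.proteome import ProteinRecord

    prot = ProteinRecord("short", "", "AGKVLK")  # all peptides below min length
    with pytest.warns(UserWarning, match="no candidate"):
        table = build_transition_table([prot], DesignSettings())
    assert table == []


def test_export_roundtrip_and_determinism(tmp_path, ref_assay):
    path1 = tmp_path / "t1.csv"
    path2 = tmp_path / "t2.csv"
    export_transition_list(ref_assay, path1)
    export_transition_list(list(reversed(ref_assay)), path2)
    assert path1.read_bytes() == path2.read_bytes()  # stable ordering
    back = read_transition_list(path1)
    assert len(back) == len(ref_assay)
    assert {t.key for t in back} == {t.key for t in ref_assay}
    assert sum(t.quantifier for t in back) == sum(t.quantifier for t in ref_assay)


def test_export_missing_rt_is_empty_field(tmp_path, masses):
    from mrmquant.proteome import ProteinRecord

    prot = ProteinRecord("tiny", "", "AGSTVNDEQH")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = build_transition_table([prot], DesignSettings())
    path = tmp_path / "t.csv"
    export_transition_list(table, path)
    data_row = path.read_text().splitlines()[1]
    assert ",," in data_row  # rt field empty, not zero
    with pytest.raises(ValueError):
        export_transition_list([], tmp_path / "empty.csv")


def test_fragment_by_label_unknown():
    with pytest.raises(ValueError):
        fragment_by_label("NAVDTANNR", "y9")  # only y1..y8 exist
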