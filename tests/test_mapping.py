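"""Peak assignment, coverage maps, cleavage-site calling, fold changes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltpdigest import (
    PeakList,
    ProteinRecord,
    assign_peaks,
    call_cleavage_sites,
    compare_conditions,
    coverage_map,
    enumerate_fragments,
    normalize_intensities,
)
from ltpdigest.datasets import (
    WHEAT_OBSERVED_BOUNDARIES,
    wheat_digest_peaklist,
    wheat_digest_profile,
    wheat_ltp1,
)
from ltpdigest.digestion import TheoreticalFragment
from ltpdigest.mapping import PeakAssignment, read_peaklist, write_peaklist


def frag(start, end, mass):
    return TheoreticalFragment(start=start, end=end, mass_avg=mass, mass_mono=mass - 0.6)


def assignment(fragment, intensity=1.0, mz=None):
    return PeakAssignment(
        mz=mz if mz is not None else fragment.mass_avg,
        intensity=intensity,
        fragment=fragment,
        error_ppm=0.0,
        error_da=0.0,
        mass_type_used="average",
        status="assigned",
    )


@pytest.fixture(scope="module")
def wheat_assigned():
    """The published assigned fragment set with 'LTP alone' intensities."""
    profile = wheat_digest_profile()
    protein = wheat_ltp1()
    out = []
    for row in profile.itertuples():
        if not row.fragment:
            continue
        start, end = map(int, row.fragment.split("-"))
        from ltpdigest.digestion import fragment_mass

        f = TheoreticalFragment(
            start, end,
            fragment_mass(protein, start, end, "average"),
            fragment_mass(protein, start, end, "monoisotopic"),
        )
        out.append(
            (
                assignment(f, row.intensity_alone, mz=row.mz_observed),
                None if pd.isna(row.intensity_linoleic) else assignment(f, row.intensity_linoleic, mz=row.mz_observed),
            )
        )
    return out


# ---------------------------------------------------------------------------
# assignment

def test_assignment_within_and_outside_tolerance():
    fragments = [frag(1, 5, 1000.0)]
    tol_da = 1000.0 * 100e-6
    peaks = PeakList(
        peaks=((1000.0 + 0.5 * tol_da, 10.0), (1000.0 + 2 * tol_da, 5.0)),
        acquisition_range=(500.0, 2000.0),
    )
    a, b = assign_peaks(peaks, fragments, tolerance=100.0)
    assert a.status == "assigned" and a.fragment is fragments[0]
    assert b.status == "unassigned" and b.fragment is None


def test_empty_peaklist_gives_empty_assignments():
    peaks = PeakList(peaks=(), acquisition_range=(0, 1))
    assert assign_peaks(peaks, [frag(1, 2, 500.0)], tolerance=100) == []


def test_nearest_candidate_wins_and_ties_are_ambiguous():
    fragments = [frag(1, 5, 1000.0), frag(2, 6, 1000.12)]
    peaks = PeakList(peaks=((1000.05, 1.0),), acquisition_range=(900, 1100))
    (a,) = assign_peaks(peaks, fragments, tolerance=200.0)
    assert a.status == "ambiguous"
    assert a.fragment is fragments[0]  # 0.05 Da beats 0.07 Da
    assert len(a.candidates) == 2


def test_published_80_90_peak_matches_at_250ppm():
    protein = wheat_ltp1()
    fragments = enumerate_fragments(protein, WHEAT_OBSERVED_BOUNDARIES, mode="limited")
    peaks = wheat_digest_peaklist("alone")
    by_mz = {a.mz: a for a in assign_peaks(peaks, fragments, tolerance=250.0)}
    a = by_mz[1277.74]
    assert a.fragment is not None and (a.fragment.start, a.fragment.end) == (80, 90)
    assert a.fragment.mass_avg == pytest.approx(1277.45, abs=0.01)


def test_tolerance_monotonicity():
    """Peaks assigned at tolerance t stay assigned at any larger tolerance."""
    rngs = np.random.default_rng(7)
    fragments = [frag(i, i + 3, 800.0 + 97.0 * i) for i in range(1, 12)]
    mzs = rngs.uniform(780, 2000, size=40)
    peaks = PeakList(peaks=tuple((m, 1.0) for m in mzs), acquisition_range=(700, 2100))
    for t1, t2 in [(50, 150), (150, 400)]:
        s1 = {a.mz for a in assign_peaks(peaks, fragments, tolerance=t1) if a.fragment}
        s2 = {a.mz for a in assign_peaks(peaks, fragments, tolerance=t2) if a.fragment}
        assert s1 <= s2


def test_assignment_stable_under_peak_permutation():
    fragments = [frag(i, i + 2, 900.0 + 111.0 * i) for i in range(1, 8)]
    mzs = [900.05, 1011.2, 1233.1, 1455.0, 1677.2]
    fwd = PeakList(peaks=tuple((m, 1.0) for m in mzs), acquisition_range=(800, 1800))
    rev = PeakList(peaks=tuple((m, 1.0) for m in reversed(mzs)), acquisition_range=(800, 1800))
    res_f = {a.mz: (a.fragment.label if a.fragment else None) for a in assign_peaks(fwd, fragments)}
    res_r = {a.mz: (a.fragment.label if a.fragment else None) for a in assign_peaks(rev, fragments)}
    assert res_f == res_r


def test_nonpositive_tolerance_rejected():
    peaks = PeakList(peaks=((1000.0, 1.0),), acquisition_range=(900, 1100))
    with pytest.raises(ValueError):
        assign_peaks(peaks, [frag(1, 2, 1000.0)], tolerance=0.0)


# ---------------------------------------------------------------------------
# normalisation

def test_total_ion_normalisation():
    peaks = PeakList(peaks=((100.0, 10.0), (200.0, 30.0), (300.0, 60.0)), acquisition_range=(0, 400))
    out = normalize_intensities(peaks, "total_ion", scale=1000.0)
    assert list(out.intensity) == pytest.approx([100.0, 300.0, 600.0])


def test_single_peak_gets_full_scale():
    peaks = PeakList(peaks=((100.0, 7.0),), acquisition_range=(0, 200))
    assert normalize_intensities(peaks, "max_peak", scale=1000.0).intensity[0] == pytest.approx(1000.0)


@given(
    intensities=st.lists(st.floats(0.01, 1e6), min_size=2, max_size=20),
    method=st.sampled_from(["total_ion", "max_peak"]),
)
@settings(max_examples=50, deadline=None)
def test_normalisation_preserves_order(intensities, method):
    peaks = PeakList(
        peaks=tuple((100.0 + i, v) for i, v in enumerate(intensities)),
        acquisition_range=(0, 1000),
    )
    out = normalize_intensities(peaks, method)
    assert list(np.argsort(peaks.intensity, kind="stable")) == list(
        np.argsort(out.intensity, kind="stable")
    )


def test_all_zero_intensities_rejected():
    peaks = PeakList(peaks=((100.0, 0.0), (200.0, 0.0)), acquisition_range=(0, 300))
    with pytest.raises(ValueError):
        normalize_intensities(peaks, "total_ion")


# ---------------------------------------------------------------------------
# coverage

def test_single_fragment_coverage():
    p = ProteinRecord(id="x", sequence="A" * 10)
    cov = coverage_map([assignment(frag(1, 5, 500.0), intensity=7.0)], p)
    assert list(cov.per_residue_intensity) == [7, 7, 7, 7, 7, 0, 0, 0, 0, 0]


def test_overlapping_fragments_are_additive():
    p = ProteinRecord(id="x", sequence="A" * 10)
    cov = coverage_map(
        [assignment(frag(1, 6, 1.0), 2.0), assignment(frag(4, 10, 2.0), 3.0)], p
    )
    assert list(cov.per_residue_intensity) == [2, 2, 2, 5, 5, 5, 3, 3, 3, 3]


def test_coverage_conservation_invariant(wheat_assigned):
    protein = wheat_ltp1()
    assignments = [a for a, _ in wheat_assigned]
    cov = coverage_map(assignments, protein)
    expected = sum(a.intensity * a.fragment.length for a in assignments)
    assert cov.per_residue_intensity.sum() == pytest.approx(expected, rel=1e-12)


def test_msms_confirmed_coverage_peaks_at_c_terminal_peptide(wheat_assigned):
    """Coverage built from the MS/MS-confirmed peptides alone puts its
    maximum on the 80-90 C-terminal region."""
    from ltpdigest.datasets import MSMS_CONFIRMED

    protein = wheat_ltp1()
    confirmed = [
        a for a, _ in wheat_assigned
        if (a.fragment.start, a.fragment.end) in MSMS_CONFIRMED
    ]
    cov = coverage_map(confirmed, protein)
    v = cov.per_residue_intensity
    argmax_residues = set(np.nonzero(v == v.max())[0] + 1)
    assert argmax_residues <= set(range(80, 91)) and argmax_residues


# ---------------------------------------------------------------------------
# cleavage-site calling

def test_intact_only_assignment_yields_no_internal_boundaries():
    p90 = frag(1, 90, 10000.0)
    df = call_cleavage_sites([assignment(p90)], protein_length=90)
    assert len(df) == 0


def test_shared_boundary_ranks_first():
    frags = [frag(1, 10, 1000.0), frag(11, 20, 1100.0), frag(1, 14, 1400.0)]
    df = call_cleavage_sites([assignment(f) for f in frags], protein_length=20)
    assert df.iloc[0].boundary == 10  # supported by two fragments; 14 by one


def test_published_assigned_set_calls_major_sites(wheat_assigned):
    df = call_cleavage_sites([a for a, _ in wheat_assigned], protein_length=90)
    top3 = set(df.head(3).boundary)
    assert top3 == {39, 56, 79}
    assert (df.set_index("boundary").loc[[39, 56, 79], "n_fragments"] >= 2).all()


def test_min_support_filters_weak_boundaries(wheat_assigned):
    df = call_cleavage_sites([a for a, _ in wheat_assigned], min_support=5, protein_length=90)
    assert set(df.boundary) <= {39, 56, 67, 79}


# ---------------------------------------------------------------------------
# condition comparison

def test_published_1_79_fold_change_is_about_eightfold(wheat_assigned):
    a = [x for x, _ in wheat_assigned]
    b = [y for _, y in wheat_assigned if y is not None]
    df = compare_conditions(a, b, "alone", "linoleic").set_index("fragment")
    assert df.loc["1-79", "fold_change"] == pytest.approx(2300 / 270, rel=1e-9)
    assert df.loc["1-79", "fold_change"] >= 8.0


def test_equal_intensities_give_unit_fold_change():
    f = frag(1, 5, 500.0)
    df = compare_conditions([assignment(f, 3.0)], [assignment(f, 3.0)])
    assert df.fold_change.iloc[0] == pytest.approx(1.0)


def test_not_detected_fragments_are_flagged_not_ratioed(wheat_assigned):
    a = [x for x, _ in wheat_assigned]
    b = [y for _, y in wheat_assigned if y is not None]
    df = compare_conditions(a, b, "alone", "linoleic").set_index("fragment")
    row = df.loc["17-56"]  # detected only without lipid
    assert np.isnan(row.fold_change)
    assert row.flag == "not_detected_in_linoleic"


# ---------------------------------------------------------------------------
# I/O

def test_peaklist_round_trip(tmp_path):
    peaks = PeakList(peaks=((1000.5, 10.0), (2000.25, 3.5)), acquisition_range=(900, 2100))
    path = tmp_path / "peaks.tsv"
    write_peaklist(peaks, path)
    back = read_peaklist(path)
    assert list(back.mz) == pytest.approx(list(peaks.mz))
    assert list(back.intensity) == pytest.approx(list(peaks.intensity))
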