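"""Group-contribution susceptibility: derivations, fits, prediction,
SMILES decomposition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import molprof as mp
from molprof.errors import (
    DecompositionParseError,
    IncompleteDecompositionError,
    InvalidInputError,
    MissingFragmentError,
    OverDeterminedUnknownsError,
    SingularSystemError,
    UnderDeterminedError,
)
from molprof.ppfsd import HYDROGEN_SYMBOL, canonical_symbol


# --- hydrogen contribution --------------------------------------------------

@pytest.mark.parametrize(
    "methane, ethane, expected",
    [
        (17.4, 26.8, 4.0),   # experimental magnitudes -> published H value
        (10.0, 20.0, 0.0),   # perfect CH2 additivity leaves no H residual
        (20.0, 30.0, 5.0),
    ],
)
def test_hydrogen_contribution(methane, ethane, expected):
    assert mp.hydrogen_contribution(methane, ethane) == pytest.approx(expected)


def test_hydrogen_contribution_rejects_nonpositive():
    with pytest.raises(InvalidInputError):
        mp.hydrogen_contribution(-1.0, 26.8)
    with pytest.raises(InvalidInputError):
        mp.hydrogen_contribution(17.4, 0.0)


# --- single-unknown derivation ----------------------------------------------

def _library_without(library, symbol):
    return mp.FragmentLibrary.from_specs(
        [s for s in library.entries.values() if s.symbol != symbol]
    )


def test_ether_oxygen_derived_from_diethyl_ether(library):
    """55.10 - 2*13.4 - 2*11.8 = 4.7 for the ether oxygen."""
    lib = _library_without(library, "Phi17")
    ref = mp.ReferenceCompound(
        "diethyl ether", 55.10, {"CH3": 2, "I": 2, "Phi17": 1}
    )
    assert mp.derive_contribution(ref, lib, "Phi17") == pytest.approx(4.7, abs=0.05)


def test_derivation_identity_single_unknown(library):
    ref = mp.ReferenceCompound("pure-X", 42.0, {"X": 1})
    assert mp.derive_contribution(ref, library, "X") == pytest.approx(42.0)


def test_derivation_linear_solve(library):
    ref = mp.ReferenceCompound("ref", 100.0, {"I": 2, "X": 2})
    assert mp.derive_contribution(ref, library, "X") == pytest.approx(38.2)


def test_derivation_requires_exactly_one_unknown(library):
    with pytest.raises(OverDeterminedUnknownsError):
        mp.derive_contribution(
            mp.ReferenceCompound("r", 10.0, {"X": 1, "Y": 1}), library, "X"
        )
    with pytest.raises(OverDeterminedUnknownsError):
        # no unknown at all: every symbol already known
        mp.derive_contribution(
            mp.ReferenceCompound("r", 10.0, {"I": 1}), library, "I"
        )


def test_derivation_round_trip_reproduces_reference(library):
    """Register the derived value, then predict on the same reference."""
    ref = mp.ReferenceCompound("ref", 123.45, {"I": 3, "J": 1, "X": 2}, h_correction=2)
    value = mp.derive_contribution(ref, library, "X")
    extended = mp.register_contribution(library, "X", value)
    assert "X" not in library  # original untouched
    profile = mp.GroupCountProfile("ref", ref.counts, h_correction=ref.h_correction)
    assert mp.predict(profile, extended).chi_pred == pytest.approx(
        ref.chi_exp, abs=1e-12
    )


# --- prediction -------------------------------------------------------------

def test_b134_susceptibility_prediction(library, b134_profile):
    """2F + 6I + 2J + 2P + 2Delta + 2Th + 2Phi17 - 8A = 282.78."""
    pred = mp.predict(b134_profile, library)
    assert pred.chi_pred == pytest.approx(282.78, abs=5e-3)
    assert pred.h_term == pytest.approx(32.0)
    assert sum(pred.per_group_terms.values()) - pred.h_term == pytest.approx(
        pred.chi_pred, abs=1e-12
    )


def test_predict_trivial_profiles(library):
    empty = mp.GroupCountProfile("empty", {})
    assert mp.predict(empty, library).chi_pred == 0.0
    single = mp.GroupCountProfile("one-CH2", {"I": 1})
    assert mp.predict(single, library).chi_pred == pytest.approx(11.8)


def test_predict_unresolvable_symbol(library):
    with pytest.raises(MissingFragmentError, match="Zz"):
        mp.predict(mp.GroupCountProfile("bad", {"Zz": 1}), library)


def test_predict_additivity_and_order_invariance(library):
    c1 = mp.GroupCountProfile("a", {"I": 2, "J": 1}, h_correction=1)
    c2 = mp.GroupCountProfile("b", {"P": 1, "F": 2}, h_correction=3)
    merged = mp.GroupCountProfile(
        "ab", {"I": 2, "J": 1, "P": 1, "F": 2}, h_correction=4
    )
    reordered = mp.GroupCountProfile(
        "ba", {"F": 2, "P": 1, "J": 1, "I": 2}, h_correction=4
    )
    total = mp.predict(c1, library).chi_pred + mp.predict(c2, library).chi_pred
    assert mp.predict(merged, library).chi_pred == pytest.approx(total, abs=1e-12)
    assert mp.predict(reordered, library).chi_pred == pytest.approx(
        mp.predict(merged, library).chi_pred, abs=1e-12
    )


def test_negative_count_rejected():
    with pytest.raises(InvalidInputError):
        mp.GroupCountProfile("bad", {"I": -1})


def test_unicode_glyphs_normalised(library):
    profile = mp.GroupCountProfile("glyphs", {"Δ": 2, "Þ": 2, "Φ17": 2})
    assert profile.counts == {"Delta": 2, "Th": 2, "Phi17": 2}
    assert canonical_symbol(" Δ ") == "Delta"
    assert library["Δ"].contribution == pytest.approx(11.1)


# --- least-squares fitting --------------------------------------------------

def test_fit_exactly_determined_two_by_two(library):
    refs = [
        mp.ReferenceCompound("R1", 30.0, {"X": 1, "Y": 2}),
        mp.ReferenceCompound("R2", 50.0, {"X": 3, "Y": 2}),
    ]
    fit = mp.fit_contributions(refs, library, ["X", "Y"])
    assert fit.contributions["X"] == pytest.approx(10.0, abs=1e-12)
    assert fit.contributions["Y"] == pytest.approx(10.0, abs=1e-12)
    assert all(abs(r) < 1e-10 for r in fit.residuals.values())
    assert fit.stderr is None  # no degrees of freedom left


def test_fit_zero_noise_recovers_generating_library(library):
    spec = mp.RefSetSimulationSpec(
        library=library, n_compounds=15, noise_sd=0.0, seed=11, h_range=(0, 3)
    )
    refs = mp.gen_reference_set(spec)
    empty = mp.FragmentLibrary()
    fit = mp.fit_contributions(refs, empty, library.symbols())
    for sym in library.symbols():
        assert fit.contributions[sym] == pytest.approx(
            library[sym].contribution, abs=1e-9
        )
    assert all(abs(r) < 1e-9 for r in fit.residuals.values())


def test_fit_matches_normal_equations_oracle(library):
    """lstsq route agrees with an explicit normal-equations solve to 1e-9
    on a small overdetermined system (4 unknowns, 6 references)."""
    rng = np.random.default_rng(7)
    unknowns = ["W", "X", "Y", "Z"]
    truth = {"W": 5.0, "X": 11.8, "Y": 26.65, "Z": 4.0}
    refs = []
    counts_matrix = rng.integers(0, 5, size=(6, 4))
    for i in range(6):
        chi = sum(counts_matrix[i, j] * truth[s] for j, s in enumerate(unknowns))
        chi += rng.normal(0, 0.3)
        refs.append(
            mp.ReferenceCompound(
                f"r{i}",
                chi,
                {s: int(counts_matrix[i, j]) for j, s in enumerate(unknowns)},
            )
        )
    fit = mp.fit_contributions(refs, mp.FragmentLibrary(), unknowns)
    X = counts_matrix.astype(float)
    y = np.array([r.chi_exp for r in refs])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    for j, sym in enumerate(unknowns):
        assert fit.contributions[sym] == pytest.approx(beta[j], abs=1e-9)


def test_fit_noisy_recovery_within_standard_errors(library):
    """With Gaussian noise on chi_exp, the fitted contributions sit within
    3 standard errors of truth, and the normal-equations standard error is
    consistent with the empirical spread over 200 replicate fits."""
    unknowns = ["F", "I", "J"]
    known = _library_without(_library_without(_library_without(library, "F"), "I"), "J")
    estimates = []
    reported_se = []
    for rep in range(200):
        spec = mp.RefSetSimulationSpec(
            library=library, n_compounds=20, noise_sd=0.5, seed=1000 + rep
        )
        refs = mp.gen_reference_set(spec)
        fit = mp.fit_contributions(refs, known, unknowns)
        estimates.append([fit.contributions[s] for s in unknowns])
        reported_se.append([fit.stderr[s] for s in unknowns])
    estimates = np.array(estimates)
    reported_se = np.array(reported_se)
    truth = np.array([library[s].contribution for s in unknowns])
    # single-fit criterion on the first replicate
    assert np.all(np.abs(estimates[0] - truth) < 3 * reported_se[0])
    # empirical sd across replicates matches the analytic standard error
    empirical_sd = estimates.std(axis=0, ddof=1)
    assert np.all(np.abs(estimates.mean(axis=0) - truth) < 3 * empirical_sd / np.sqrt(200))
    ratio = empirical_sd / reported_se.mean(axis=0)
    assert np.all((ratio > 0.7) & (ratio < 1.4))


def test_fit_error_conditions(library):
    refs = [mp.ReferenceCompound("r", 10.0, {"X": 1, "Y": 1})]
    with pytest.raises(UnderDeterminedError):
        mp.fit_contributions(refs, library, ["X", "Y"])
    collinear = [
        mp.ReferenceCompound("r1", 10.0, {"X": 1, "Y": 1}),
        mp.ReferenceCompound("r2", 20.0, {"X": 2, "Y": 2}),
    ]
    with pytest.raises(SingularSystemError):
        mp.fit_contributions(collinear, library, ["X", "Y"])


# --- SMILES decomposition ---------------------------------------------------

def test_decompose_diethyl_ether(library):
    profile = mp.decompose("CCOCC", library, compound_id="diethyl ether")
    assert profile.counts == {"CH3": 2, "I": 2, "Phi17": 1}
    assert profile.h_correction == 0  # implied H = formula H = 10
    assert profile.formula_h == 10


def test_decompose_ethanol(library):
    assert mp.decompose("CCO", library).counts == {"CH3": 1, "I": 1, "J": 1}


def test_decompose_b134_matches_manual_counts(library, b134_profile, b134_smiles):
    """Automatic decomposition reproduces the manual fragment multiset; its
    mechanical implied-H correction (6) differs from the published manual
    correction (8), which stays explicit on the packaged profile."""
    auto = mp.decompose(b134_smiles, library, compound_id="B-134-0")
    assert auto.counts == b134_profile.counts
    assert auto.formula_h == 26
    assert auto.h_correction == 6
    assert auto.h_correction != b134_profile.h_correction


def test_decompose_invalid_smiles(library):
    with pytest.raises(DecompositionParseError):
        mp.decompose("not-a-smiles((", library)


def test_decompose_incomplete_is_flagged_not_dropped(library):
    # nitro nitrogen/oxygens have no library fragment
    with pytest.raises(IncompleteDecompositionError) as excinfo:
        mp.decompose("CC[N+](=O)[O-]", library)
    err = excinfo.value
    assert len(err.unassigned) == 3
    assert err.profile is not None
    assert err.profile.counts.get("CH3") == 1


# --- additivity property ----------------------------------------------------

count_maps = st.dictionaries(
    st.sampled_from(["F", "I", "J", "P", "Delta", "Th", "Phi17", "CH3"]),
    st.integers(min_value=0, max_value=6),
    max_size=5,
)


@given(count_maps, count_maps, st.integers(-4, 4), st.integers(-4, 4))
def test_prediction_is_additive(counts_a, counts_b, h_a, h_b):
    library = mp.default_library()
    merged = {
        s: counts_a.get(s, 0) + counts_b.get(s, 0)
        for s in set(counts_a) | set(counts_b)
    }
    pa = mp.predict(mp.GroupCountProfile("a", counts_a, h_correction=h_a), library)
    pb = mp.predict(mp.GroupCountProfile("b", counts_b, h_correction=h_b), library)
    pm = mp.predict(
        mp.GroupCountProfile("m", merged, h_correction=h_a + h_b), library
    )
    assert pm.chi_pred == pytest.approx(pa.chi_pred + pb.chi_pred, abs=1e-9)
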