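"""Group-contribution prediction of molar diamagnetic susceptibility.

The scheme (Property Prediction from Structural Differences, PPFSD) treats
the molar diamagnetic susceptibility magnitude ``-chi_m`` (in units of
1e-6 cm^3/mol; positive numbers, since the physical susceptibility of a
diamagnet is negative) as additive over structural fragments:

    -chi_m(molecule) = sum_g  n_g * c_g  -  h * c_H

``c_g`` is the fragment contribution, ``n_g`` its count, and the final term
corrects for hydrogens counted more than once when the fragment
contributions already include their own hydrogens (``h`` is a signed
integer, ``c_H`` the single-hydrogen contribution, symbol ``A``).

New contributions are obtained from reference compounds with known
experimental susceptibility: the hydrogen value itself from the
methane/ethane pair (the unique solution of CH4 = C + 4H, C2H6 = 2C + 6H),
single unknowns by direct subtraction, and several unknowns at once by
ordinary least squares over a set of references.

Fragment symbols are short ASCII identifiers.  The canonical library uses
one-letter symbols plus the aliases ``Delta`` (imine C=NH), ``Th``
(methoxy, glyph: thorn) and ``Phi17`` (ether oxygen); Unicode glyphs on
input are normalised to these aliases.  They are entirely separate from
the ``I``/``A`` symbols of :mod:`molprof.cdft` — the two registries never
mix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    IncompleteDecompositionError,
    InvalidInputError,
    MissingFragmentError,
    OverDeterminedUnknownsError,
    SingularSystemError,
    UnderDeterminedError,
    DecompositionParseError,
)

__all__ = [
    "FragmentSpec",
    "FragmentLibrary",
    "GroupCountProfile",
    "ReferenceCompound",
    "SusceptibilityPrediction",
    "ContributionFit",
    "HYDROGEN_SYMBOL",
    "canonical_symbol",
    "hydrogen_contribution",
    "derive_contribution",
    "register_contribution",
    "fit_contributions",
    "predict",
    "decompose",
    "default_library",
]

#: symbol of the single-hydrogen fragment used in the overcount correction
HYDROGEN_SYMBOL = "A"

# Unicode glyphs accepted on input, normalised to ASCII-safe aliases.
_GLYPH_ALIASES = {
    "Δ": "Delta",   # capital delta, imine C=NH
    "δ": "Delta",
    "Þ": "Th",      # capital thorn, methoxy
    "þ": "Th",
    "Φ17": "Phi17",  # capital phi + "17", ether oxygen
    "φ17": "Phi17",
}


def canonical_symbol(symbol: str) -> str:
    """Normalise a fragment symbol: strip whitespace, map glyphs to ASCII."""
    s = symbol.strip()
    return _GLYPH_ALIASES.get(s, s)


@dataclass(frozen=True)
class FragmentSpec:
    """One fragment: symbol, display name, contribution, H bookkeeping.

    ``contribution`` is the -chi_m magnitude in 1e-6 cm^3/mol.
    ``implied_h`` is the number of hydrogens whose contribution is already
    folded into this fragment's value (e.g. 5 for a monosubstituted phenyl
    counted as C6H5).  ``smarts`` enables automatic decomposition.
    """

    symbol: str
    group_name: str
    contribution: float
    implied_h: int = 0
    smarts: str | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.contribution):
            raise InvalidInputError(
                f"contribution for {self.symbol!r} must be finite"
            )
        if self.implied_h < 0:
            raise InvalidInputError(
                f"implied_h for {self.symbol!r} must be >= 0"
            )


@dataclass(frozen=True)
class FragmentLibrary:
    """Immutable symbol -> :class:`FragmentSpec` registry.

    Derivation operations never mutate a library; they return a new
    versioned copy so the provenance of every value is preserved.
    """

    entries: dict[str, FragmentSpec] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for key, spec in self.entries.items():
            if key != spec.symbol:
                raise InvalidInputError(
                    f"library key {key!r} != spec symbol {spec.symbol!r}"
                )

    def __contains__(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self.entries

    def __getitem__(self, symbol: str) -> FragmentSpec:
        key = canonical_symbol(symbol)
        try:
            return self.entries[key]
        except KeyError:
            raise MissingFragmentError(
                f"fragment symbol {symbol!r} not in library "
                f"({self.provenance or 'unnamed'})"
            ) from None

    def __len__(self) -> int:
        return len(self.entries)

    def symbols(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def with_entry(self, spec: FragmentSpec, note: str = "") -> "FragmentLibrary":
        """New library with ``spec`` added (or replaced)."""
        entries = dict(self.entries)
        entries[spec.symbol] = spec
        prov = self.provenance
        if note:
            prov = f"{prov}; {note}" if prov else note
        return FragmentLibrary(entries=entries, provenance=prov)

    @staticmethod
    def from_specs(specs, provenance: str = "") -> "FragmentLibrary":
        entries: dict[str, FragmentSpec] = {}
        for spec in specs:
            if spec.symbol in entries:
                raise InvalidInputError(f"duplicate symbol {spec.symbol!r}")
            entries[spec.symbol] = spec
        return FragmentLibrary(entries=entries, provenance=provenance)


@dataclass(frozen=True)
class GroupCountProfile:
    """Fragment multiset of one molecule plus its hydrogen correction.

    ``h_correction`` multiplies the hydrogen contribution and is
    *subtracted* from the additive sum; it is explicit (never silently
    inferred) because published decompositions do not always match any
    mechanical implied-H bookkeeping.  ``formula_h`` optionally records the
    molecule's actual hydrogen count.
    """

    compound_id: str
    counts: dict[str, int] = field(default_factory=dict)
    h_correction: int = 0
    formula_h: int | None = None

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if n < 0:
                raise InvalidInputError(
                    f"negative count {n} for symbol {sym!r} in "
                    f"{self.compound_id!r}"
                )
            if n:
                clean[canonical_symbol(sym)] = int(n)
        object.__setattr__(self, "counts", clean)


@dataclass(frozen=True)
class ReferenceCompound:
    """A compound with experimentally known susceptibility, used to derive
    or fit unknown fragment contributions."""

    name: str
    chi_exp: float  # -chi_m magnitude, 1e-6 cm^3/mol
    counts: dict[str, int] = field(default_factory=dict)
    h_correction: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.chi_exp):
            raise InvalidInputError(f"chi_exp for {self.name!r} must be finite")
        object.__setattr__(
            self,
            "counts",
            {canonical_symbol(s): int(n) for s, n in self.counts.items()},
        )


@dataclass(frozen=True)
class SusceptibilityPrediction:
    """Additive prediction with its per-group breakdown.

    Invariant: ``chi_pred == sum(per_group_terms.values()) - h_term``.
    ``chi_pred`` is the -chi_m magnitude; the physically signed value is
    ``-chi_pred`` and is applied only when formatting output.
    """

    compound_id: str
    chi_pred: float
    per_group_terms: dict[str, float]
    h_term: float


@dataclass(frozen=True)
class ContributionFit:
    """Least-squares fit result for a set of unknown contributions."""

    contributions: dict[str, float]
    residuals: dict[str, float]       # per reference compound
    stderr: dict[str, float] | None   # None when the system is exactly determined
    dof: int


def hydrogen_contribution(chi_methane: float, chi_ethane: float) -> float:
    """Hydrogen-atom contribution from the methane/ethane pair.

    Solving the stoichiometric system CH4 = C + 4H, C2H6 = 2C + 6H for the
    hydrogen term gives ``(2*chi_methane - chi_ethane) / 2``; with the
    experimental magnitudes 17.4 and 26.8 (1e-6 cm^3/mol) this yields 4.0.
    """
    if not (chi_methane > 0 and chi_ethane > 0):
        raise InvalidInputError(
            "susceptibility magnitudes must be positive, got "
            f"{chi_methane!r}, {chi_ethane!r}"
        )
    return (2.0 * chi_methane - chi_ethane) / 2.0


def derive_contribution(
    ref: ReferenceCompound,
    library: FragmentLibrary,
    unknown: str,
) -> float:
    """Contribution of a single unknown symbol from one reference compound.

    The unknown must be the only symbol of ``ref.counts`` missing from the
    library, with count >= 1.  Returns

        (chi_exp - sum_known n*c + h_correction*c_H) / n_unknown

    and does not modify ``library``; see :func:`register_contribution` for
    producing an extended library version.
    """
    unknown = canonical_symbol(unknown)
    missing = [s for s in ref.counts if s not in library]
    if unknown in library:
        raise OverDeterminedUnknownsError(
            f"symbol {unknown!r} is already in the library"
        )
    if missing != [unknown]:
        if not missing:
            raise OverDeterminedUnknownsError(
                f"no unknown symbol found in {ref.name!r}; expected {unknown!r}"
            )
        raise OverDeterminedUnknownsError(
            f"{ref.name!r} has {len(missing)} unknown symbols {missing}; "
            "single-compound derivation needs exactly one"
        )
    n_unknown = ref.counts[unknown]
    if n_unknown == 0:
        raise InvalidInputError(
            f"unknown symbol {unknown!r} has count 0 in {ref.name!r}"
        )
    known_sum = sum(
        n * library[s].contribution for s, n in ref.counts.items() if s != unknown
    )
    h_term = 0.0
    if ref.h_correction:
        h_term = ref.h_correction * library[HYDROGEN_SYMBOL].contribution
    return (ref.chi_exp - known_sum + h_term) / n_unknown


def register_contribution(
    library: FragmentLibrary,
    symbol: str,
    contribution: float,
    *,
    group_name: str = "",
    implied_h: int = 0,
    smarts: str | None = None,
    provenance: str = "",
) -> FragmentLibrary:
    """Companion to :func:`derive_contribution`: a new library version with
    the derived value registered."""
    spec = FragmentSpec(
        symbol=canonical_symbol(symbol),
        group_name=group_name or symbol,
        contribution=contribution,
        implied_h=implied_h,
        smarts=smarts,
        provenance=provenance,
    )
    return library.with_entry(spec, note=f"derived {spec.symbol}")


def fit_contributions(
    refs: list[ReferenceCompound],
    library: FragmentLibrary,
    unknowns,
) -> ContributionFit:
    """Ordinary least-squares fit of several unknown contributions at once.

    Each reference contributes one equation; its response is ``chi_exp``
    minus all known-group terms (the hydrogen correction is moved to the
    known side when ``A`` is known, or kept as a ``-h`` coefficient on the
    ``A`` column when ``A`` itself is being fitted).  Exactly determined
    full-rank systems are solved exactly; overdetermined ones in the
    least-squares sense, with standard errors from the normal-equations
    covariance ``s^2 (X^T X)^-1``.
    """
    unknowns = [canonical_symbol(s) for s in unknowns]
    if len(set(unknowns)) != len(unknowns):
        raise InvalidInputError("duplicate symbols in unknowns")
    already = [s for s in unknowns if s in library]
    if already:
        raise InvalidInputError(f"unknowns {already} already in library")
    if len(refs) < len(unknowns):
        raise UnderDeterminedError(
            f"{len(refs)} references cannot determine {len(unknowns)} unknowns"
        )

    h_known = HYDROGEN_SYMBOL not in unknowns
    rows, y = [], []
    for ref in refs:
        stray = [s for s in ref.counts if s not in library and s not in unknowns]
        if stray:
            raise MissingFragmentError(
                f"{ref.name!r} contains symbols {stray} that are neither in "
                "the library nor among the unknowns"
            )
        coeffs = []
        for sym in unknowns:
            c = ref.counts.get(sym, 0)
            if sym == HYDROGEN_SYMBOL:
                c -= ref.h_correction
            coeffs.append(float(c))
        rows.append(coeffs)
        resp = ref.chi_exp - sum(
            n * library[s].contribution
            for s, n in ref.counts.items()
            if s in library
        )
        if h_known and ref.h_correction:
            resp += ref.h_correction * library[HYDROGEN_SYMBOL].contribution
        y.append(resp)

    X = np.asarray(rows, dtype=float)
    y = np.asarray(y, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < len(unknowns):
        # identify collinear columns by checking rank drop on removal
        collinear = [
            unknowns[j]
            for j in range(len(unknowns))
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise SingularSystemError(
            f"design matrix rank {rank} < {len(unknowns)} unknowns; "
            f"collinear symbols: {collinear or unknowns}"
        )

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    dof = len(refs) - len(unknowns)
    stderr = None
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        stderr = {
            sym: float(np.sqrt(cov[j, j])) for j, sym in enumerate(unknowns)
        }
    return ContributionFit(
        contributions={sym: float(b) for sym, b in zip(unknowns, beta)},
        residuals={ref.name: float(r) for ref, r in zip(refs, resid)},
        stderr=stderr,
        dof=dof,
    )


def predict(
    profile: GroupCountProfile, library: FragmentLibrary
) -> SusceptibilityPrediction:
    """Additive susceptibility prediction for one group-count profile.

    ``chi_pred = sum_s n_s c_s - h_correction * c_H`` (all magnitudes in
    1e-6 cm^3/mol).  Raises :class:`MissingFragmentError` naming the first
    unresolvable symbol.
    """
    terms = {
        sym: n * library[sym].contribution for sym, n in profile.counts.items()
    }
    h_term = 0.0
    if profile.h_correction:
        h_term = profile.h_correction * library[HYDROGEN_SYMBOL].contribution
    return SusceptibilityPrediction(
        compound_id=profile.compound_id,
        chi_pred=sum(terms.values()) - h_term,
        per_group_terms=terms,
        h_term=h_term,
    )


# --- automatic decomposition ------------------------------------------------

def _pattern_info(spec: FragmentSpec):
    from rdkit import Chem

    patt = Chem.MolFromSmarts(spec.smarts)
    if patt is None:
        raise InvalidInputError(
            f"invalid SMARTS {spec.smarts!r} for symbol {spec.symbol!r}"
        )
    n_atoms = patt.GetNumAtoms()
    Chem.FastFindRings(patt)  # query mols lack ring perception by default
    is_ring = patt.GetRingInfo().NumRings() > 0
    return patt, n_atoms, is_ring


def decompose(
    smiles: str,
    library: FragmentLibrary,
    *,
    compound_id: str | None = None,
) -> GroupCountProfile:
    """Decompose a molecule into library fragments by greedy SMARTS matching.

    Every heavy atom must be assigned to exactly one fragment.  Patterns are
    tried in a fixed priority order — aromatic ring systems first, then
    multi-atom groups by descending atom count, then single atoms (ties
    broken alphabetically by symbol) — and a match is accepted only when all
    of its atoms are still unassigned.  The hydrogen correction is computed
    as ``sum(count * implied_h) - formula_h``; published manual corrections
    may differ from this mechanical bookkeeping, which is why
    :class:`GroupCountProfile` keeps the correction explicit.

    Raises
    ------
    DecompositionParseError
        On invalid SMILES.
    IncompleteDecompositionError
        When heavy atoms remain uncovered; the exception carries the
        partial profile and the uncovered atom indices.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DecompositionParseError(f"could not parse SMILES {smiles!r}")

    with_smarts = [
        spec for spec in library.entries.values() if spec.smarts
    ]
    decorated = []
    for spec in with_smarts:
        patt, n_atoms, is_ring = _pattern_info(spec)
        decorated.append((not is_ring, -n_atoms, spec.symbol, spec, patt))
    decorated.sort(key=lambda t: t[:3])

    assigned: set[int] = set()
    counts: dict[str, int] = {}
    for _, _, _, spec, patt in decorated:
        for match in mol.GetSubstructMatches(patt, uniquify=True):
            atoms = set(match)
            if atoms & assigned:
                continue
            assigned |= atoms
            counts[spec.symbol] = counts.get(spec.symbol, 0) + 1

    formula_h = sum(atom.GetTotalNumHs() for atom in mol.GetAtoms())
    implied_total = sum(
        n * library[sym].implied_h for sym, n in counts.items()
    )
    profile = GroupCountProfile(
        compound_id=compound_id or smiles,
        counts=counts,
        h_correction=implied_total - formula_h,
        formula_h=formula_h,
    )

    unassigned = sorted(
        a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in assigned
    )
    if unassigned:
        names = [mol.GetAtomWithIdx(i).GetSymbol() for i in unassigned]
        raise IncompleteDecompositionError(
            f"{len(unassigned)} heavy atom(s) unassigned in {smiles!r}: "
            f"{list(zip(unassigned, names))}",
            profile=profile,
            unassigned=unassigned,
        )
    return profile


def default_library() -> FragmentLibrary:
    """The packaged canonical fragment library (see ``data/`` asset)."""
    from .io import read_fragment_library, packaged_data_path

    return read_fragment_library(packaged_data_path("fragment_library.tsv"))
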