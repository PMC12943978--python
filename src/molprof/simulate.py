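"""Seeded synthetic-data generators for every analysis stage.

Each generator emits data with exactly the statistical structure its
analysis stage assumes, so the whole pipeline is testable without any
external measurement:

* replicate qPCR Ct tables around gene/group means that encode known fold
  changes, with additive Gaussian noise on Ct (the standard qPCR noise
  assumption — Ct is a log-scale quantity, so Gaussian Ct noise means
  log-normal noise on template amount);
* reference-compound susceptibility sets generated from a known fragment
  library with additive Gaussian noise on the experimental value (which
  makes ordinary least squares the maximum-likelihood contribution fit);
* frontier orbital energies inverted from target electronegativity and
  hardness.

All randomness flows through one :class:`numpy.random.Generator` per call,
seeded from the spec, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cdft import FrontierOrbitalEnergies
from .errors import GenerationError, InvalidInputError
from .ppfsd import FragmentLibrary, HYDROGEN_SYMBOL, ReferenceCompound
from .qpcr import CtRecord

__all__ = [
    "CtSimulationSpec",
    "RefSetSimulationSpec",
    "gen_ct_table",
    "gen_reference_set",
    "orbitals_from_descriptors",
]


@dataclass(frozen=True)
class CtSimulationSpec:
    """Ground truth for a two-group qPCR experiment.

    ``true_fold`` maps each gene to its treated-vs-control expression fold
    (reference gene must be 1).  ``baseline_ct`` gives the control-group
    target mean Ct per gene; ``reference_shift`` moves the treated group's
    reference-gene mean (emulating loading/efficiency drift between runs,
    which the ddCt method is designed to cancel).  Replicate noise is
    additive Gaussian on Ct with standard deviation ``noise_sd``.
    """

    genes: tuple[str, ...]
    true_fold: dict[str, float]
    reference_gene: str
    baseline_ct: dict[str, float]
    reference_shift: float = 0.0
    noise_sd: float = 0.25
    n_replicates: int = 8
    seed: int = 0
    control_label: str = "control"
    treated_label: str = "treated"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        if self.reference_gene not in self.genes:
            raise InvalidInputError(
                f"reference gene {self.reference_gene!r} not in genes"
            )
        for gene in self.genes:
            fold = self.true_fold.get(gene)
            if fold is None or not (math.isfinite(fold) and fold > 0):
                raise InvalidInputError(f"true_fold[{gene!r}] must be positive")
            if gene not in self.baseline_ct:
                raise InvalidInputError(f"baseline_ct missing gene {gene!r}")
        if self.true_fold[self.reference_gene] != 1:
            raise InvalidInputError("reference gene must have true_fold == 1")


def gen_ct_table(spec: CtSimulationSpec) -> list[CtRecord]:
    """Replicate Ct records realising the spec's ground truth.

    Mean structure: control target mean is ``baseline_ct[gene]``; the
    treated target mean is ``baseline + reference_shift - log2(fold)``,
    so after ddCt normalisation against the (shifted) reference gene the
    recovered fold equals ``true_fold[gene]`` exactly at zero noise.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[CtRecord] = []
    for gene in spec.genes:
        base = spec.baseline_ct[gene]
        means = {
            spec.control_label: base,
            spec.treated_label: base
            + spec.reference_shift
            - math.log2(spec.true_fold[gene]),
        }
        for group, mean in means.items():
            noise = rng.normal(0.0, spec.noise_sd, size=spec.n_replicates)
            for i in range(spec.n_replicates):
                records.append(
                    CtRecord(
                        group=group,
                        gene=gene,
                        replicate=i + 1,
                        ct=mean + (noise[i] if spec.noise_sd > 0 else 0.0),
                    )
                )
    return records


@dataclass(frozen=True)
class RefSetSimulationSpec:
    """Ground truth for a synthetic reference-compound set.

    Compounds get uniform-random fragment counts within ``count_range``
    (per-symbol ``(low, high)`` inclusive; default (0, 4)) and a hydrogen
    correction drawn from ``h_range``; the noiseless susceptibility is the
    additive sum, perturbed by Gaussian noise of sd ``noise_sd``.
    """

    library: FragmentLibrary
    n_compounds: int
    count_range: dict[str, tuple[int, int]] = field(default_factory=dict)
    default_count_range: tuple[int, int] = (0, 4)
    h_range: tuple[int, int] = (0, 0)
    noise_sd: float = 0.0
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.n_compounds < len(self.library):
            raise InvalidInputError(
                f"n_compounds={self.n_compounds} < {len(self.library)} "
                "library symbols: the set could never determine a full fit"
            )


def gen_reference_set(spec: RefSetSimulationSpec) -> list[ReferenceCompound]:
    """Reference compounds whose chi_exp follows the library exactly
    (plus noise), with a full-column-rank count matrix.

    Regenerates (up to ``max_retries``) if a draw happens to be rank
    deficient, so downstream fits are always well posed.
    """
    rng = np.random.default_rng(spec.seed)
    symbols = list(spec.library.symbols())
    use_h = spec.h_range != (0, 0)

    for _ in range(spec.max_retries):
        counts_matrix = np.empty((spec.n_compounds, len(symbols)), dtype=int)
        h_corrs = np.zeros(spec.n_compounds, dtype=int)
        for i in range(spec.n_compounds):
            for j, sym in enumerate(symbols):
                lo, hi = spec.count_range.get(sym, spec.default_count_range)
                counts_matrix[i, j] = rng.integers(lo, hi + 1)
            if use_h:
                h_corrs[i] = rng.integers(spec.h_range[0], spec.h_range[1] + 1)
        # the fit's design matrix folds -h into the hydrogen column
        design = counts_matrix.astype(float)
        if HYDROGEN_SYMBOL in symbols:
            design[:, symbols.index(HYDROGEN_SYMBOL)] -= h_corrs
        if np.linalg.matrix_rank(design) < len(symbols):
            continue

        noise = rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)
        refs = []
        for i in range(spec.n_compounds):
            clean = float(
                sum(
                    counts_matrix[i, j] * spec.library[sym].contribution
                    for j, sym in enumerate(symbols)
                )
            )
            if h_corrs[i]:
                clean -= h_corrs[i] * spec.library[HYDROGEN_SYMBOL].contribution
            refs.append(
                ReferenceCompound(
                    name=f"synth-{i:03d}",
                    chi_exp=clean + (noise[i] if spec.noise_sd > 0 else 0.0),
                    counts={
                        sym: int(counts_matrix[i, j])
                        for j, sym in enumerate(symbols)
                        if counts_matrix[i, j]
                    },
                    h_correction=int(h_corrs[i]),
                )
            )
        return refs

    raise GenerationError(
        f"could not draw a full-rank reference set in {spec.max_retries} tries"
    )


def orbitals_from_descriptors(
    chi: float, eta: float, *, label: str = ""
) -> FrontierOrbitalEnergies:
    """Invert electronegativity/hardness back to frontier orbital energies.

    With I = chi + eta/2 and A = chi - eta/2, the Koopmans relations give
    e_homo = -I and e_lumo = -A.  Requires eta > 0.
    """
    if not eta > 0:
        raise InvalidInputError(f"hardness must be positive, got {eta!r}")
    I = chi + eta / 2.0
    A = chi - eta / 2.0
    return FrontierOrbitalEnergies(e_homo=-I, e_lumo=-A, label=label)
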