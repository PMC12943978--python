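# Methods

## Reactivity descriptors (`molprof.cdft`)

The descriptor vector is the standard finite-difference approximation of
conceptual DFT, with ionization energy and electron affinity taken from
frontier orbital energies by Koopmans' theorem (I = −E(HOMO),
A = −E(LUMO)). All arithmetic is in eV; no unit conversion is performed —
inputs are declared in eV. Quantum-chemistry log parsing is deliberately
outside the core: orbital energies arrive as declared values (JSON), which
keeps the module dependency-free and directly testable from transcribed
numbers.

Numerical choices:

* **Degenerate hardness.** I = A within 1e−12 raises an error naming the
  inputs: σ and the four electrophilicity-type indices all divide by
  η = I − A.
* **Non-Aufbau input.** E(HOMO) > E(LUMO) is accepted with a warning
  rather than rejected, since transcribed open-shell results can
  legitimately look like this.
* **Display rounding.** Computation keeps full float precision; the
  reporting layer offers `round` (decimal half-up) and `truncate` modes,
  because published tables are frequently consistent only with truncation
  (e.g. σ = 0.18968… printed as 0.189, ω₁ = 1.72358… printed as 1.723).
  Comparisons against printed 3-decimal tables use ±0.001.

The algebraic identities σ·η = 1, ω⁻ − ω⁺ = χ and Δω± = ω⁺ + ω⁻ hold by
construction and are enforced as property tests; they double as a check
that the two published routes to ω₁ (χ²/2η and (I+A)²/8(I−A)) agree.

## Group-contribution susceptibility (`molprof.ppfsd`)

Contributions and predictions are stored as **−χm magnitudes** (positive
numbers, 10⁻⁶ cm³/mol); the physically negative χm appears only in
formatted output. This matches how group-contribution arithmetic for
diamagnetic susceptibility is conventionally tabulated.

The hydrogen contribution is the unique solution of the stoichiometric
pair CH₄ = C + 4H, C₂H₆ = 2C + 6H, i.e. (2χ(CH₄) − χ(C₂H₆))/2, which with
the experimental magnitudes 17.4 and 26.8 gives 4.0. The packaged library
carries eight canonical fragments (H 4.0, Br 26.65, chain CH₂ 11.8,
OH 10.8, phenyl 50.84, imine C=NH 11.1, OCH₃ 17.9, ether O 4.7) plus
CH₃ = 13.4, which the diethyl-ether derivation of the ether oxygen
requires (55.10 − 2·13.4 − 2·11.8 = 4.7).

* **Hydrogen correction is explicit.** The −h·c_H overcount term is a
  signed integer carried on each profile, never silently inferred. For the
  packaged B-134-0 profile the published manual correction is 8, while
  mechanical implied-H bookkeeping (phenyl 5H, C=NH 1H, CH₂ 2H, OCH₃ 3H,
  OH 1H against the C₂₂H₂₆ formula) yields 6; automatic decomposition
  computes its own value and the disagreement stays visible instead of
  being reconciled by fiat.
* **Derivation never mutates.** `derive_contribution` returns a value;
  `register_contribution` returns a new library version with provenance,
  so every derived number is traceable.
* **Multi-unknown fits** are ordinary least squares (`numpy.linalg.lstsq`)
  on the response χ_exp minus all known-group terms; when the hydrogen
  symbol itself is fitted, the correction folds into its design column as
  −h. Rank deficiency is reported with the collinear symbols; standard
  errors come from the normal-equations covariance s²(XᵀX)⁻¹ when degrees
  of freedom remain. Gaussian noise on χ_exp makes this the
  maximum-likelihood fit.
* **Decomposition** (`decompose`) assigns every heavy atom exactly once by
  greedy SMARTS matching in a fixed priority order: aromatic ring systems,
  then multi-atom groups by descending pattern size, then single atoms,
  ties broken alphabetically. Unassignable atoms raise a flagged error
  carrying the partial profile — never a silently truncated count.
* **Symbols** are ASCII aliases (`Delta`, `Th`, `Phi17`); the traditional
  glyphs (Δ, Þ, Φ17) are accepted on input and used for display. The
  fragment-symbol registry is entirely separate from the descriptor
  symbols I/A of the reactivity module.

## ΔΔCt quantification (`molprof.qpcr`)

Amplification efficiency is fixed at 100% (base 2); efficiency correction
is out of scope. The operation accepts either replicate-level Ct tables or
the four per-group mean Cts directly, because published studies often
print only group means. Fold changes are reported at 2 decimals
(round-half-up) by convention; computation keeps full precision. The
two-group comparison is the classical pooled-variance Student's t
(not Welch) on replicate ΔCt values, two-sided, df = n₁+n₂−2; zero pooled
variance with equal means returns (t = 0, p = 1), with unequal means it is
an error. No multiple-testing correction is applied, and the report says
so. ΔΔCt is invariant to any constant Ct shift applied uniformly within a
group — the design property that makes the method robust to loading and
run-to-run drift.

## Synthetic data (`molprof.simulate`)

* **Ct tables.** Control target mean = baseline; treated target mean =
  baseline + reference_shift − log₂(fold). The reference-gene shift
  (default in the packaged example: −4.76 cycles) emulates the large
  between-run drift of the housekeeping gene that ΔΔCt is built to cancel.
  Noise is additive Gaussian on Ct — the standard qPCR assumption (Ct is
  log-scale, so this is log-normal noise on template amount). Defaults:
  sd 0.25 cycles, 8 replicates per group (a typical biological-replicate
  design). Zero noise gives exact closure: the pipeline recovers every
  generating fold bit-exactly.
* **Reference sets.** Fragment counts uniform on [0, 4] per symbol
  (optionally per-symbol ranges and a hydrogen correction on [0, h_max]);
  χ_exp is the exact additive sum plus Gaussian noise. Draws are rejected
  and retried until the design matrix has full column rank, so downstream
  fits are always well posed; a retry budget guards against degenerate
  specifications.
* **Determinism.** One `numpy.random.Generator` per call, seeded from the
  spec; identical specs give bit-identical output, and seeds are written
  into output file headers.

What the generators do **not** emulate: qPCR outliers/dropouts, plate and
position effects, efficiency differences between genes, heteroscedastic Ct
noise, and (for susceptibility) any systematic inadequacy of the
additivity assumption itself. Passing tests therefore demonstrate the
correctness of the estimators under their stated model, not robustness of
the model on real instruments or exotic chemistry.

## Pipeline and I/O

Display rounding lives exclusively in the reporting layer. CSV/TSV are
UTF-8 with `.` decimal and mandatory header; data outputs carry a `#`
provenance header (package version, seed, library) and contain no
timestamps, so identical configurations reproduce byte-identical files.
Configuration objects are plain dataclasses with explicit validation —
at this schema size a validation framework would add a dependency without
adding checks.

## Problem sizes

Monte-Carlo checks use 200 replicate fits (20 compounds, noise sd 0.5) for
contribution recovery and 500 simulation replicates (8 Ct replicates,
noise sd 0.2) for fold-estimator calibration; the descriptor identities
are swept over 1000 random (I, A) pairs. These sizes give Monte-Carlo
standard errors comfortably below the tested tolerances.

## Known limitations

* Koopmans' theorem is itself an approximation; descriptors inherit the
  functional/basis dependence of the orbital energies supplied.
* The susceptibility scheme is strictly additive: no ring-current,
  conformational or neighbouring-group corrections, no paramagnetic terms.
* Greedy decomposition is deterministic but not globally optimal; exotic
  fused-ring systems may decompose differently than a chemist would.
* Replicate-level statistics require replicate data; from published group
  means alone only point folds (no p-values) are recoverable.
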