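"""Readers, writers and the display/reporting layer.

All computation modules keep full float precision; rounding for human
display happens only here.  Two display modes are offered because printed
reference tables in the literature are not always consistent about
round-half-up versus truncation:

* ``round``    — decimal round-half-up (so 0.18968 -> 0.190 at 3 digits);
* ``truncate`` — digits simply cut (0.18968 -> 0.189).

File conventions: CSV/TSV are comma/tab separated, UTF-8, ``.`` decimal,
header row mandatory.  Unicode fragment glyphs are accepted on input and
normalised to ASCII aliases internally.  Data outputs carry a ``#`` header
comment naming the package version and any library/seed provenance, so
re-running an identical configuration yields byte-identical files.
"""

from __future__ import annotations

import json
import math
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .cdft import FrontierOrbitalEnergies, ReactivityDescriptors
from .errors import InvalidInputError, SchemaError
from .ppfsd import (
    FragmentLibrary,
    FragmentSpec,
    GroupCountProfile,
    SusceptibilityPrediction,
    canonical_symbol,
)
from .qpcr import CtRecord, records_to_frame

__all__ = [
    "display_value",
    "packaged_data_path",
    "read_ct_table",
    "write_ct_table",
    "read_ct_means",
    "read_fragment_library",
    "write_fragment_library",
    "read_orbitals",
    "read_group_profile",
    "format_descriptor_table",
    "format_prediction",
    "format_fold_table",
]

_DISPLAY_GLYPHS = {"Delta": "Δ", "Th": "Þ", "Phi17": "Φ17"}


# --- display rounding -------------------------------------------------------

def display_value(x: float, digits: int = 3, mode: str = "round") -> float:
    """Round ``x`` for display.

    ``mode='round'`` uses decimal round-half-up; ``mode='truncate'`` drops
    digits beyond the requested precision (toward zero).
    """
    if digits < 0:
        raise InvalidInputError("digits must be >= 0")
    x = float(x)
    if mode == "round":
        q = Decimal(1).scaleb(-digits)
        return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    if mode == "truncate":
        factor = 10**digits
        return math.trunc(x * factor) / factor
    raise InvalidInputError(f"unknown display mode {mode!r}")


# --- packaged assets --------------------------------------------------------

def packaged_data_path(name: str) -> Path:
    """Filesystem path of a packaged data asset."""
    path = resources.files("molprof.data").joinpath(name)
    return Path(str(path))


def _header_lines(**meta: object) -> str:
    parts = [f"molprof {__version__}"] + [f"{k}={v}" for k, v in meta.items()]
    return "# " + "; ".join(parts) + "\n"


# --- qPCR tables ------------------------------------------------------------

_CT_COLUMNS = ["group", "gene", "replicate", "ct"]


def read_ct_table(path) -> list[CtRecord]:
    """Long-format replicate Ct CSV -> validated records.

    Columns: group, gene, replicate, ct.  Duplicate (group, gene,
    replicate) keys and unparseable values are rejected with the offending
    line numbers.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _CT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            records.append(
                CtRecord(
                    group=str(row["group"]),
                    gene=str(row["gene"]),
                    replicate=int(row["replicate"]),
                    ct=float(row["ct"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path} line {line}: {exc}") from exc
    records_to_frame(records)  # duplicate check
    return records


def write_ct_table(records, path, **meta) -> None:
    df = records_to_frame(records)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(**meta))
        df.to_csv(fh, index=False)


def read_ct_means(path) -> pd.DataFrame:
    """Per-gene mean-Ct CSV (gene, mean_ct_control, mean_ct_treated)."""
    df = pd.read_csv(path, comment="#")
    required = ["gene", "mean_ct_control", "mean_ct_treated"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise SchemaError(f"{path}: duplicate gene(s) {dupes}")
    return df


# --- fragment libraries -----------------------------------------------------

def read_fragment_library(path) -> FragmentLibrary:
    """TSV or JSON fragment library -> :class:`FragmentLibrary`.

    TSV columns: symbol, group_name, contribution_e6_cm3_mol, implied_h,
    smarts (optional: display_symbol, provenance).  Unicode symbols are
    normalised to ASCII aliases.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        rows = payload["entries"] if isinstance(payload, dict) else payload
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep="\t", comment=None)
    if df.empty:
        raise SchemaError(f"{path}: empty fragment library")
    required = ["symbol", "group_name", "contribution_e6_cm3_mol"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    specs = []
    seen = set()
    for idx, row in df.iterrows():
        symbol = canonical_symbol(str(row["symbol"]))
        if symbol in seen:
            raise SchemaError(f"{path}: duplicate symbol {symbol!r}")
        seen.add(symbol)
        try:
            contribution = float(row["contribution_e6_cm3_mol"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"{path} line {idx + 2}: non-numeric contribution "
                f"{row['contribution_e6_cm3_mol']!r}"
            ) from exc
        smarts = row.get("smarts")
        if smarts is not None and (pd.isna(smarts) or str(smarts) == ""):
            smarts = None
        implied_h = row.get("implied_h", 0)
        if pd.isna(implied_h):
            implied_h = 0
        provenance = row.get("provenance", "")
        if pd.isna(provenance):
            provenance = ""
        specs.append(
            FragmentSpec(
                symbol=symbol,
                group_name=str(row["group_name"]),
                contribution=contribution,
                implied_h=int(implied_h),
                smarts=None if smarts is None else str(smarts),
                provenance=str(provenance),
            )
        )
    return FragmentLibrary.from_specs(specs, provenance=str(path))


def write_fragment_library(library: FragmentLibrary, path) -> None:
    path = Path(path)
    rows = [
        {
            "symbol": s.symbol,
            "display_symbol": _DISPLAY_GLYPHS.get(s.symbol, s.symbol),
            "group_name": s.group_name,
            "contribution_e6_cm3_mol": s.contribution,
            "implied_h": s.implied_h,
            "smarts": s.smarts or "",
            "provenance": s.provenance,
        }
        for s in library.entries.values()
    ]
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({"provenance": library.provenance, "entries": rows}, indent=2),
            encoding="utf-8",
        )
    else:
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- orbital energies and group profiles ------------------------------------

def read_orbitals(path) -> FrontierOrbitalEnergies:
    """JSON with fields label, e_homo_ev, e_lumo_ev."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        return FrontierOrbitalEnergies(
            e_homo=float(payload["e_homo_ev"]),
            e_lumo=float(payload["e_lumo_ev"]),
            label=str(payload.get("label", "")),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing field {exc}") from exc


def read_group_profile(path) -> GroupCountProfile:
    """JSON group-count profile (compound_id, counts, h_correction, ...)."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        return GroupCountProfile(
            compound_id=str(payload["compound_id"]),
            counts={str(k): int(v) for k, v in payload["counts"].items()},
            h_correction=int(payload.get("h_correction", 0)),
            formula_h=payload.get("formula_h"),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing field {exc}") from exc


# --- text rendering ---------------------------------------------------------

_DESCRIPTOR_ROWS = [
    ("EHOMO (eV)", lambda d: -d.ionization_energy),
    ("ELUMO (eV)", lambda d: -d.electron_affinity),
    ("Ionization energy (I)", lambda d: d.ionization_energy),
    ("Electron affinity (A)", lambda d: d.electron_affinity),
    ("chi", lambda d: d.electronegativity),
    ("mu", lambda d: d.chemical_potential),
    ("eta", lambda d: d.hardness),
    ("sigma", lambda d: d.softness),
    ("omega_1", lambda d: d.electrophilicity_1),
    ("omega_2", lambda d: d.electrophilicity_2),
    ("omega-", lambda d: d.electrodonating),
    ("omega+", lambda d: d.electroaccepting),
    ("delta_omega+-", lambda d: d.net_electrophilicity),
]


def format_descriptor_table(
    descriptors: ReactivityDescriptors, digits: int = 3, mode: str = "round"
) -> str:
    """Two-column text table of the descriptor vector."""
    lines = [f"Electronic characteristics: {descriptors.label or 'molecule'}"]
    for name, getter in _DESCRIPTOR_ROWS:
        value = display_value(getter(descriptors), digits, mode)
        lines.append(f"{name}\t{value:.{digits}f}")
    return "\n".join(lines) + "\n"


def format_prediction(
    prediction: SusceptibilityPrediction, digits: int = 2, mode: str = "round"
) -> str:
    """Per-group breakdown plus the signed physical susceptibility."""
    lines = [f"Molar diamagnetic susceptibility: {prediction.compound_id}"]
    for sym, term in prediction.per_group_terms.items():
        glyph = _DISPLAY_GLYPHS.get(sym, sym)
        lines.append(f"  {glyph}\t{display_value(term, digits, mode):.{digits}f}")
    if prediction.h_term:
        lines.append(
            f"  -H correction\t-{display_value(prediction.h_term, digits, mode):.{digits}f}"
        )
    chi = display_value(prediction.chi_pred, digits, mode)
    lines.append(f"chi_m = -{chi:.{digits}f} x 10^-6 cm^3/mol")
    return "\n".join(lines) + "\n"


def format_fold_table(folds: pd.DataFrame, digits: int = 2, mode: str = "round") -> str:
    """Gene / ddCt / fold-change text table (fold at 2 dp by convention)."""
    lines = ["Gene\tddCt\tFold Change"]
    for _, row in folds.iterrows():
        fold = display_value(float(row["fold"]), digits, mode)
        lines.append(f"{row['gene']}\t{row['ddct']:.2f}\t{fold:.{digits}f}")
    return "\n".join(lines) + "\n"
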