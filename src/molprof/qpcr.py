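"""Relative gene-expression quantification by the ddCt method.

For a target gene and a reference (housekeeping) gene measured in a control
and a treated group:

    dCt(group)  = mean Ct(target, group) - mean Ct(reference, group)
    ddCt        = dCt(treated) - dCt(control)
    fold change = 2 ** (-ddCt)

The base of 2 assumes 100% amplification efficiency (template doubles each
cycle); efficiency correction is out of scope.  A fold of 1 means no change
relative to the reference gene; folds < 1 mean relative down-regulation.

Input is either a replicate-level Ct table (:class:`CtRecord` collection)
or, when only published group means are available, the four means directly
(:func:`fold_change_from_means`).  The two-group comparison on replicate
dCt values uses the classical pooled-variance Student's t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InvalidDesignError,
    InvalidInputError,
    MissingDataError,
)

__all__ = [
    "CtRecord",
    "FoldChangeResult",
    "TTestResult",
    "records_to_frame",
    "fold_change_from_means",
    "delta_delta_ct",
    "quantify_all",
    "compare_groups_dct",
]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: cycle-threshold value for (group, gene, replicate)."""

    group: str
    gene: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct) and self.ct > 0):
            raise InvalidInputError(
                f"Ct must be finite and > 0, got {self.ct!r} for "
                f"({self.group}, {self.gene}, rep {self.replicate})"
            )
        if self.replicate < 1:
            raise InvalidInputError("replicate index must be >= 1")


@dataclass(frozen=True)
class FoldChangeResult:
    """ddCt quantification for one target gene.

    Invariants: ``fold > 0``; ``log2(fold) == -ddct``.
    """

    gene: str
    dct_control: float
    dct_treated: float
    ddct: float
    fold: float


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: int


def records_to_frame(records: Iterable[CtRecord]) -> pd.DataFrame:
    """Long-format DataFrame (group, gene, replicate, ct) from records.

    Duplicate (group, gene, replicate) keys are rejected.
    """
    df = pd.DataFrame(
        [(r.group, r.gene, r.replicate, r.ct) for r in records],
        columns=["group", "gene", "replicate", "ct"],
    )
    dup = df.duplicated(subset=["group", "gene", "replicate"])
    if dup.any():
        keys = df.loc[dup, ["group", "gene", "replicate"]].values.tolist()
        raise InvalidInputError(f"duplicate (group, gene, replicate) keys: {keys}")
    return df


def fold_change_from_means(
    gene: str,
    target_ct_control: float,
    target_ct_treated: float,
    reference_ct_control: float,
    reference_ct_treated: float,
) -> FoldChangeResult:
    """ddCt from the four group-mean Ct values directly.

    This is the entry point when only published per-group mean Cts are
    available rather than replicate-level data.
    """
    dct_c = target_ct_control - reference_ct_control
    dct_t = target_ct_treated - reference_ct_treated
    ddct = dct_t - dct_c
    return FoldChangeResult(
        gene=gene,
        dct_control=dct_c,
        dct_treated=dct_t,
        ddct=ddct,
        fold=2.0 ** (-ddct),
    )


def _group_gene_mean(df: pd.DataFrame, group: str, gene: str) -> float:
    sel = df[(df["group"] == group) & (df["gene"] == gene)]
    if sel.empty:
        raise MissingDataError(f"no Ct values for gene {gene!r} in group {group!r}")
    return float(sel["ct"].mean())


def delta_delta_ct(
    table,
    target: str,
    reference: str,
    control_label: str = "control",
    treated_label: str = "treated",
) -> FoldChangeResult:
    """ddCt quantification of one target gene from a replicate Ct table.

    ``table`` is a :class:`CtRecord` iterable or an equivalent long-format
    DataFrame.  Group means are taken over replicates before differencing.
    """
    if target == reference:
        raise InvalidDesignError(
            f"reference gene {reference!r} cannot be its own target"
        )
    df = table if isinstance(table, pd.DataFrame) else records_to_frame(table)
    return fold_change_from_means(
        target,
        _group_gene_mean(df, control_label, target),
        _group_gene_mean(df, treated_label, target),
        _group_gene_mean(df, control_label, reference),
        _group_gene_mean(df, treated_label, reference),
    )


def quantify_all(
    table,
    reference: str,
    control_label: str = "control",
    treated_label: str = "treated",
    *,
    with_ttest: bool = False,
) -> pd.DataFrame:
    """ddCt results for every non-reference gene in the table.

    Returns a DataFrame with columns gene, dct_control, dct_treated, ddct,
    fold (and t/p/df per gene when ``with_ttest`` and replicate-level data
    permit).  The reference gene quantified against itself is fold 1 by
    construction and is included as a sanity row.
    """
    df = table if isinstance(table, pd.DataFrame) else records_to_frame(table)
    rows = []
    genes = list(dict.fromkeys(df["gene"]))
    for gene in genes:
        if gene == reference:
            res = FoldChangeResult(gene, 0.0, 0.0, 0.0, 1.0)
        else:
            res = delta_delta_ct(df, gene, reference, control_label, treated_label)
        row = {
            "gene": gene,
            "dct_control": res.dct_control,
            "dct_treated": res.dct_treated,
            "ddct": res.ddct,
            "fold": res.fold,
        }
        if with_ttest and gene != reference:
            t = _dct_ttest(df, gene, reference, control_label, treated_label)
            row.update({"t": t.statistic, "p": t.pvalue, "df": t.df})
        rows.append(row)
    return pd.DataFrame(rows)


def _dct_replicates(df, gene, reference, group):
    tgt = df[(df["group"] == group) & (df["gene"] == gene)]
    ref = df[(df["group"] == group) & (df["gene"] == reference)]
    merged = tgt.merge(ref, on="replicate", suffixes=("_t", "_r"))
    if merged.empty:
        raise MissingDataError(
            f"no paired replicates for {gene!r}/{reference!r} in {group!r}"
        )
    return (merged["ct_t"] - merged["ct_r"]).to_numpy()


def _dct_ttest(df, gene, reference, control_label, treated_label):
    return compare_groups_dct(
        _dct_replicates(df, gene, reference, control_label),
        _dct_replicates(df, gene, reference, treated_label),
    )


def compare_groups_dct(
    control_dct: Sequence[float], treated_dct: Sequence[float]
) -> TTestResult:
    """Pooled-variance two-sample Student's t-test on replicate dCt values.

    Two-sided p-value from the t distribution with n1 + n2 - 2 degrees of
    freedom.  Zero pooled variance with equal means is reported as
    (t=0, p=1); with unequal means it is a degenerate-variance error.
    """
    a = np.asarray(control_dct, dtype=float)
    b = np.asarray(treated_dct, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateVarianceError(
            "need >= 2 replicates per group for a variance estimate "
            f"(got {len(a)} and {len(b)})"
        )
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if pooled == 0.0:
        if a.mean() == b.mean():
            return TTestResult(statistic=0.0, pvalue=1.0, df=df)
        raise DegenerateVarianceError(
            "zero pooled variance with unequal group means: t is undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue), df=df)
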