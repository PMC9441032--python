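"""Interrater-reliability statistics for screening-tool application.

Raters (and a consensus *standard*) each decide, for every dataset x
decision-unit cell, whether an indicator applies.  Comparing a rater with
the standard yields a 2x2 agreement table:

====  =================================================
cell  meaning
====  =================================================
A     both standard and rater applied the indicator
B     standard did not apply, rater did
C     standard applied, rater did not
D     both agreed the indicator did not apply
====  =================================================

From the table we compute Cohen's kappa (chance-corrected agreement),

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = (A + D) / n,
    p_e = [(A + C)(A + B) + (B + D)(C + D)] / n^2,

its large-sample standard error (Fleiss-Cohen-Everitt asymptotic
variance) with a +/- 1.96 SE confidence interval clipped to [-1, 1], and
the Cicchetti-Feinstein specific-agreement proportions

    ppos = 2A / (2A + B + C),    pneg = 2D / (2D + B + C).

Kappa is banded as poor (<= 0.20), fair (0.20, 0.40], moderate
(0.40, 0.60], substantial (0.60, 0.80] or good (0.80, 1.0].

Multiple tables can be pooled either by cellwise summation
(``concatenate``) or as an n-weighted mean of per-table kappas
(``weighted_mean``); the two generally differ and the method used is
recorded in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecisionMatrix", "AgreementTable", "KappaResult", "AgreementProportions",
    "build_agreement_table", "cohen_kappa", "proportion_agreement",
    "interpret_kappa", "pooled_kappa", "read_decisions_csv",
    "UndefinedKappaError",
]

Band = Literal["poor", "fair", "moderate", "substantial", "good"]


class UndefinedKappaError(ZeroDivisionError):
    """Kappa is undefined (both raters constant: expected agreement is 1)."""


@dataclass
class DecisionMatrix:
    """One rater's binary applied/not-applied decisions on a
    dataset x decision-unit grid."""

    rater_id: str
    decisions: pd.DataFrame  # index = dataset ids, columns = unit ids, bool

    def __post_init__(self) -> None:
        self.decisions = self.decisions.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.decisions.shape

    def aligned_with(self, other: "DecisionMatrix") -> bool:
        return (list(self.decisions.index) == list(other.decisions.index)
                and list(self.decisions.columns) == list(other.decisions.columns))


@dataclass(frozen=True)
class AgreementTable:
    a: int  # both applied
    b: int  # standard no / rater yes
    c: int  # standard yes / rater no
    d: int  # both not applied

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("agreement counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def __add__(self, other: "AgreementTable") -> "AgreementTable":
        return AgreementTable(self.a + other.a, self.b + other.b,
                              self.c + other.c, self.d + other.d)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: Optional[float]
    ci95: Optional[tuple[float, float]]
    band: Band
    po: float
    pe: float
    n: int
    method: str = "cohen"


@dataclass(frozen=True)
class AgreementProportions:
    ppos: Optional[float]
    pneg: Optional[float]


def build_agreement_table(standard: DecisionMatrix,
                          rater: DecisionMatrix) -> AgreementTable:
    """Tally the four agreement cells over identical grids."""
    if not standard.aligned_with(rater):
        raise ValueError(
            f"decision grids differ: standard {standard.shape} "
            f"{standard.rater_id!r} vs rater {rater.shape} {rater.rater_id!r}")
    s = standard.decisions.to_numpy()
    r = rater.decisions.to_numpy()
    return AgreementTable(
        a=int(np.sum(s & r)),
        b=int(np.sum(~s & r)),
        c=int(np.sum(s & ~r)),
        d=int(np.sum(~s & ~r)),
    )


def _kappa_point(table: AgreementTable) -> tuple[float, float, float]:
    n = table.n
    if n == 0:
        raise ValueError("empty agreement table")
    po = (table.a + table.d) / n
    pe = ((table.a + table.c) * (table.a + table.b)
          + (table.b + table.d) * (table.c + table.d)) / n**2
    if pe == 1.0:
        raise UndefinedKappaError(
            "both raters are constant; chance agreement is 1 and kappa is undefined")
    return (po - pe) / (1 - pe), po, pe


def _kappa_se(table: AgreementTable) -> Optional[float]:
    """Fleiss-Cohen-Everitt asymptotic standard error for unweighted kappa.

    Returns None when a marginal is degenerate (one rater constant), where
    the asymptotic formula is unreliable.
    """
    n = table.n
    # joint proportions: rows = standard (0 = applied), cols = rater
    p = np.array([[table.a, table.c],
                  [table.b, table.d]], dtype=float) / n
    row = p.sum(axis=1)   # standard marginals p_i.
    col = p.sum(axis=0)   # rater marginals p_.j
    if min(row.min(), col.min()) == 0:
        return None
    po = p[0, 0] + p[1, 1]
    pe = float(row @ col)
    term1 = sum(p[i, i] * ((1 - pe) - (row[i] + col[i]) * (1 - po))**2
                for i in range(2))
    term2 = (1 - po)**2 * sum(p[i, j] * (col[i] + row[j])**2
                              for i in range(2) for j in range(2) if i != j)
    term3 = (po * pe - 2 * pe + po)**2
    var = (term1 + term2 - term3) / (n * (1 - pe)**4)
    return math.sqrt(max(var, 0.0))


def interpret_kappa(kappa: float) -> Band:
    """Agreement band for a kappa value (half-open intervals)."""
    if not -1 <= kappa <= 1:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa <= 0.20:
        return "poor"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "good"


def cohen_kappa(table: AgreementTable) -> KappaResult:
    """Cohen's kappa with asymptotic SE and 95% CI from a 2x2 table."""
    kappa, po, pe = _kappa_point(table)
    se = _kappa_se(table)
    ci = None
    if se is not None:
        ci = (max(kappa - 1.96 * se, -1.0), min(kappa + 1.96 * se, 1.0))
    return KappaResult(kappa=kappa, se=se, ci95=ci, band=interpret_kappa(kappa),
                       po=po, pe=pe, n=table.n)


def proportion_agreement(table: AgreementTable) -> AgreementProportions:
    """Specific positive/negative agreement; an undefined proportion
    (zero denominator) is reported as None rather than raised."""
    pos_denom = 2 * table.a + table.b + table.c
    neg_denom = 2 * table.d + table.b + table.c
    return AgreementProportions(
        ppos=(2 * table.a / pos_denom) if pos_denom > 0 else None,
        pneg=(2 * table.d / neg_denom) if neg_denom > 0 else None,
    )


def pooled_kappa(tables: Sequence[AgreementTable],
                 method: Literal["concatenate", "weighted_mean"] = "concatenate",
                 ) -> KappaResult:
    """Pool several rater-vs-standard tables into one kappa.

    ``concatenate`` sums the cells and computes kappa of the pooled table;
    ``weighted_mean`` averages per-table kappas weighted by table size.
    The method label is recorded in the result.
    """
    if not tables:
        raise ValueError("pooled_kappa requires at least one table")
    if method == "concatenate":
        total = tables[0]
        for t in tables[1:]:
            total = total + t
        base = cohen_kappa(total)
        return KappaResult(kappa=base.kappa, se=base.se, ci95=base.ci95,
                           band=base.band, po=base.po, pe=base.pe, n=base.n,
                           method="pooled_concatenate")
    if method == "weighted_mean":
        results = [cohen_kappa(t) for t in tables]
        weights = np.array([t.n for t in tables], dtype=float)
        kappa = float(np.average([r.kappa for r in results], weights=weights))
        po = float(np.average([r.po for r in results], weights=weights))
        pe = float(np.average([r.pe for r in results], weights=weights))
        return KappaResult(kappa=kappa, se=None, ci95=None,
                           band=interpret_kappa(kappa), po=po, pe=pe,
                           n=int(weights.sum()), method="pooled_weighted_mean")
    raise ValueError(f"unknown pooling method {method!r}")


def read_decisions_csv(path, collapse_reasons: bool = True) -> list[DecisionMatrix]:
    """Read long-format decisions: columns rater_id, dataset_id,
    indicator_id, applied (0/1) and an optional reason code.

    A recorded reason (e.g. "information unavailable") does not change the
    binary decision: statistics treat anything but applied=1 as
    not-applied, honouring the strictly binary design.
    """
    frame = pd.read_csv(path, dtype={"rater_id": str, "dataset_id": str,
                                     "indicator_id": str})
    matrices = []
    for rater_id, group in frame.groupby("rater_id", sort=True):
        grid = (group.pivot(index="dataset_id", columns="indicator_id",
                            values="applied")
                .fillna(0).astype(int).astype(bool))
        grid = grid.sort_index(axis=0).sort_index(axis=1)
        matrices.append(DecisionMatrix(rater_id=str(rater_id), decisions=grid))
    return matrices
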