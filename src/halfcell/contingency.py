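"""2x2 contingency tables and a two-sided Fisher exact test built from the
hypergeometric enumeration.

Used to ask whether RNA regionalization (anterior vs posterior enrichment of
a message) predicts where the corresponding protein accumulates (anterior,
posterior, or the membranellar band). Counts are small, so the exact test is
the right tool; the implementation enumerates every table consistent with the
observed margins and sums, in log space, the probabilities of all tables no
more probable than the observed one — the standard two-sided convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "FisherResult",
    "build_contingency",
    "fisher_exact_two_sided",
]

#: relative tolerance absorbing floating-point ties between point probabilities
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with row labels (RNA side) and column labels
    (protein compartment)."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("Anterior RNA", "Posterior RNA")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValidationError("contingency counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValidationError("contingency table has total 0")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class FisherResult:
    p: float
    point_probability: float
    n_tables: int


def build_contingency(
    rna_side: Mapping[str, str] | pd.Series,
    protein_compartment: Mapping[str, str] | pd.Series,
    columns: Sequence[str] = ("A", "P"),
) -> ContingencyTable2x2:
    """Cross-tabulate per-gene RNA side (A|P) against two protein compartments.

    ``protein_compartment`` values come from {A, P, MB}; genes outside the two
    chosen ``columns`` (or missing from either input) are excluded.
    """
    rna = pd.Series(rna_side)
    prot = pd.Series(protein_compartment)
    if not rna.isin(["A", "P"]).all():
        bad = sorted(set(rna) - {"A", "P"})
        raise ValidationError(f"unknown RNA side labels: {bad}")
    if not prot.isin(["A", "P", "MB"]).all():
        bad = sorted(set(prot) - {"A", "P", "MB"})
        raise ValidationError(f"unknown protein compartment labels: {bad}")
    if len(columns) != 2 or any(c not in {"A", "P", "MB"} for c in columns):
        raise ValidationError(f"columns must name two of A/P/MB, got {columns}")
    shared = rna.index.intersection(prot.index)
    rna, prot = rna[shared], prot[shared]
    keep = prot.isin(columns)
    rna, prot = rna[keep], prot[keep]
    cells = [
        [int(((rna == r) & (prot == c)).sum()) for c in columns] for r in ("A", "P")
    ]
    return ContingencyTable2x2(
        cells[0][0], cells[0][1], cells[1][0], cells[1][1],
        col_labels=(str(columns[0]), str(columns[1])),
    )


def _log_point_probabilities(r1: int, c1: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Log hypergeometric probability of every admissible table with the
    given margins, indexed by the top-left cell value."""
    c2 = n - c1
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    a = np.arange(lo, hi + 1)
    logp = (
        gammaln(c1 + 1) - gammaln(a + 1) - gammaln(c1 - a + 1)
        + gammaln(c2 + 1) - gammaln(r1 - a + 1) - gammaln(c2 - (r1 - a) + 1)
        - (gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    )
    return a, logp


def fisher_exact_two_sided(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher exact p for a 2x2 table.

    Enumerates all tables sharing the observed margins; p is the sum of
    hypergeometric point probabilities of tables whose probability does not
    exceed the observed one (with a small relative tolerance for
    floating-point ties). When any margin is 0 only one table is admissible
    and p = 1 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if min(r1, n - r1, c1, n - c1) == 0:
        return FisherResult(p=1.0, point_probability=1.0, n_tables=1)
    support, logp = _log_point_probabilities(r1, c1, n)
    log_obs = float(logp[support == a][0])
    include = logp <= log_obs + np.log1p(TIE_RTOL)
    # sum in log space for stability
    selected = logp[include]
    p = float(np.exp(selected.max()) * np.sum(np.exp(selected - selected.max())))
    return FisherResult(
        p=min(p, 1.0),
        point_probability=float(np.exp(log_obs)),
        n_tables=int(len(support)),
    )
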