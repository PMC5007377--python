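"""Explant co-culture scoring tables and the exact Fisher test.

Explants are scored *positive* (high-level marker expression throughout
most of the explant), *patchy*, *negative*, or *excluded* (high-level
expression confined to a small patch, possibly contamination — left out
of p-value calculations unless explicitly requested).  For a given marker
and pair of culture conditions the records collapse to a 2x2 table of
positive vs negative counts, tested with the two-tailed Fisher exact
test.  Significance labels: * p<=0.05, ** p<=0.005, *** p<=0.0005.

The two-sided p-value convention is fully pinned down for
reproducibility: sum the hypergeometric point probabilities of every
table with the observed margins whose probability is at most the observed
table's probability times (1 + 1e-7); the tolerance absorbs floating-point
ties.  Probabilities are accumulated via log-factorials, exact to ~1e-12
for totals up to 1000.  When any margin is zero the table carries no
information and p = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import OrgscreenError

__all__ = [
    "ExplantRecord",
    "ContingencyTable",
    "tabulate_explants",
    "fisher_exact_two_sided",
    "significance_label",
    "read_explant_records",
    "write_explant_records",
]

CATEGORIES = ("positive", "patchy", "negative", "excluded")
CONDITIONS = ("treatment", "control", "alone")


@dataclass(frozen=True)
class ExplantRecord:
    """One scored explant culture."""

    experiment_id: str
    condition: str
    marker: str
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise OrgscreenError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = conditions, columns = (positive, negative)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise OrgscreenError("contingency cells must be non-negative integers")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def tabulate_explants(
    records: Iterable[ExplantRecord],
    condition_pair: Sequence[str],
    marker: str,
    patchy_as_positive: bool = False,
    include_excluded: bool = False,
) -> ContingencyTable:
    """Collapse explant records to a 2x2 table for one marker.

    Positive column counts ``positive`` (plus ``patchy`` when
    ``patchy_as_positive``); negative column counts ``negative``.
    ``excluded`` records are dropped unless ``include_excluded``, in which
    case they count as negative.  Both conditions must occur among the
    marker's records.
    """
    cond_a, cond_b = condition_pair
    records = [r for r in records if r.marker == marker]
    if not records:
        raise OrgscreenError(f"no records for marker {marker!r}")
    present = {r.condition for r in records}
    for cond in (cond_a, cond_b):
        if cond not in present:
            raise OrgscreenError(
                f"condition {cond!r} absent from records for marker {marker!r}"
            )

    def count(condition: str) -> tuple[int, int]:
        pos = neg = 0
        for r in records:
            if r.condition != condition:
                continue
            if r.category == "positive":
                pos += 1
            elif r.category == "patchy":
                if patchy_as_positive:
                    pos += 1
                else:
                    neg += 1
            elif r.category == "negative":
                neg += 1
            elif r.category == "excluded" and include_excluded:
                neg += 1
        return pos, neg

    a, b = count(cond_a)
    c, d = count(cond_b)
    return ContingencyTable(a, b, c, d)


def _log_pmf(k: int, row1: int, row2: int, col1: int) -> float:
    """Log hypergeometric point probability of top-left cell = k."""
    n = row1 + row2
    return (
        math.lgamma(row1 + 1)
        - math.lgamma(k + 1)
        - math.lgamma(row1 - k + 1)
        + math.lgamma(row2 + 1)
        - math.lgamma(col1 - k + 1)
        - math.lgamma(row2 - col1 + k + 1)
        - (math.lgamma(n + 1) - math.lgamma(col1 + 1) - math.lgamma(n - col1 + 1))
    )


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-tailed Fisher exact p for a 2x2 table (see module docstring)."""
    a, b, c, d = table.cells
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        return 1.0
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    log_obs = _log_pmf(a, row1, row2, col1)
    cutoff = log_obs + math.log1p(1e-7)
    p = 0.0
    for k in range(lo, hi + 1):
        lp = _log_pmf(k, row1, row2, col1)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(p, 1.0)


def significance_label(p: float) -> str:
    """Star labels: *** p<=0.0005, ** p<=0.005, * p<=0.05, else ns."""
    if not (0 < p <= 1):
        raise OrgscreenError(f"p must lie in (0, 1], got {p}")
    if p <= 0.0005:
        return "***"
    if p <= 0.005:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def read_explant_records(path: str | Path) -> list[ExplantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"experiment_id", "condition", "marker", "category"}
    missing = required - set(df.columns)
    if missing:
        raise OrgscreenError(f"records TSV missing columns: {sorted(missing)}")
    return [
        ExplantRecord(r.experiment_id, r.condition, r.marker, r.category)
        for r in df.itertuples(index=False)
    ]


def write_explant_records(records: Iterable[ExplantRecord], path: str | Path) -> None:
    rows = [
        {
            "experiment_id": r.experiment_id,
            "condition": r.condition,
            "marker": r.marker,
            "category": r.category,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["experiment_id", "condition", "marker", "category"]
    ).to_csv(path, sep="\t", index=False)
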