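"""Deriving the organizer synexpression set and scoring its recovery.

A gene enters the *enriched* signature when its vector of per-comparison
calls satisfies the Boolean expression with every leaf read as
"called enriched here"; the *depleted* signature uses the same expression
with leaves read as "called depleted here".  Under the default
expression the two sets are disjoint: the conjunctive leaves (C1, C4)
would require a gene to be simultaneously enriched and depleted in one
comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import boolean
from .boolean import BooleanExpr, CALL_DEPLETED, CALL_ENRICHED
from .errors import OrgscreenError

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureSet",
    "RecoveryReport",
    "derive_signature",
    "recovery_metrics",
    "read_signature",
    "write_signature",
]


@dataclass(frozen=True)
class SignatureSet:
    """Ordered enriched and depleted gene lists with provenance."""

    enriched: tuple[str, ...]
    depleted: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self):
        overlap = set(self.enriched) & set(self.depleted)
        if overlap:
            logger.warning(
                "signature enriched/depleted sets overlap in %d genes: %s",
                len(overlap),
                sorted(overlap)[:10],
            )

    @property
    def genes(self) -> tuple[str, ...]:
        return self.enriched + self.depleted

    @property
    def overlap(self) -> set[str]:
        return set(self.enriched) & set(self.depleted)

    def __len__(self) -> int:
        return len(self.enriched) + len(self.depleted)


def derive_signature(
    calls: pd.DataFrame,
    expr: BooleanExpr,
    provenance: str = "",
) -> SignatureSet:
    """Apply the Boolean expression to a genes x comparisons call matrix.

    ``calls`` values are 'enriched'/'depleted'/'ns'; columns must cover
    every leaf of ``expr``.  Gene order of the input is preserved.
    """
    missing = boolean.leaves(expr) - set(calls.columns)
    if missing:
        raise OrgscreenError(f"call matrix lacks comparisons {sorted(missing)}")
    if calls.isna().any().any():
        bad = calls.index[calls.isna().any(axis=1)]
        raise OrgscreenError(
            f"genes with missing calls (present in one table but not another): "
            f"{list(bad[:5])}"
        )
    enriched = []
    depleted = []
    records = calls.to_dict("index")
    for gene in calls.index:
        row = records[gene]
        if boolean.evaluate_gene(expr, row, CALL_ENRICHED):
            enriched.append(gene)
        if boolean.evaluate_gene(expr, row, CALL_DEPLETED):
            depleted.append(gene)
    return SignatureSet(tuple(enriched), tuple(depleted), provenance)


@dataclass(frozen=True)
class RecoveryReport:
    """Confusion summary of a derived signature against planted truth.

    ``set_fdr`` is the fraction of reported signature genes that were not
    planted (in the matching direction); fractions with a zero denominator
    are None ("undefined"), never 0.
    """

    sensitivity_enriched: float | None
    sensitivity_depleted: float | None
    set_fdr: float | None
    n_enriched_recovered: int
    n_enriched_planted: int
    n_depleted_recovered: int
    n_depleted_planted: int
    n_false_genes: int
    n_reported: int


def _fraction(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def recovery_metrics(signature: SignatureSet, truth) -> RecoveryReport:
    """Score a signature against a :class:`~orgscreen.simulate.SyntheticTruth`."""
    planted_e = set(truth.planted_enriched)
    planted_d = set(truth.planted_depleted)
    got_e = set(signature.enriched)
    got_d = set(signature.depleted)
    n_e = len(got_e & planted_e)
    n_d = len(got_d & planted_d)
    false_genes = (got_e - planted_e) | (got_d - planted_d)
    n_reported = len(got_e) + len(got_d)
    return RecoveryReport(
        sensitivity_enriched=_fraction(n_e, len(planted_e)),
        sensitivity_depleted=_fraction(n_d, len(planted_d)),
        set_fdr=_fraction(len(false_genes), n_reported),
        n_enriched_recovered=n_e,
        n_enriched_planted=len(planted_e),
        n_depleted_recovered=n_d,
        n_depleted_planted=len(planted_d),
        n_false_genes=len(false_genes),
        n_reported=n_reported,
    )


def write_signature(signature: SignatureSet, path: str | Path) -> None:
    payload = {
        "enriched": list(signature.enriched),
        "depleted": list(signature.depleted),
        "provenance": signature.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_signature(path: str | Path) -> SignatureSet:
    payload = json.loads(Path(path).read_text())
    return SignatureSet(
        tuple(payload["enriched"]),
        tuple(payload["depleted"]),
        payload.get("provenance", ""),
    )
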