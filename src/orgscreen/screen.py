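"""Concordance scoring of candidate regions against the signature.

A candidate embryonic region is described by a presence/absence profile
over the signature genes: each enriched signature gene is scored
*concordant* when detected in the region, each depleted signature gene
when absent.  Genes with unknown status (for example stage-restricted
expression that the profile cannot adjudicate) are excluded from both
numerator and denominator.  The screen ranks regions by their concordant
fraction — the computation that singles out a putative organizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import OrgscreenError
from .signature import SignatureSet

__all__ = [
    "STATUS_DETECTED",
    "STATUS_ABSENT",
    "STATUS_UNKNOWN",
    "CandidateProfile",
    "MatchScore",
    "score_candidate",
    "rank_candidates",
    "read_profiles",
    "write_profiles",
]

STATUS_DETECTED = "detected"
STATUS_ABSENT = "absent"
STATUS_UNKNOWN = "unknown"
_STATUSES = (STATUS_DETECTED, STATUS_ABSENT, STATUS_UNKNOWN)


@dataclass(frozen=True)
class CandidateProfile:
    """Per-gene detected/absent/unknown calls for one region."""

    region_name: str
    status: Mapping[str, str]

    def __post_init__(self):
        bad = {g: s for g, s in self.status.items() if s not in _STATUSES}
        if bad:
            raise OrgscreenError(f"invalid statuses: {bad}")


@dataclass(frozen=True)
class MatchScore:
    """Concordance counts of a candidate profile against the signature."""

    n_enriched_detected: int
    n_enriched_scored: int
    n_depleted_absent: int
    n_depleted_scored: int

    @property
    def n_concordant(self) -> int:
        return self.n_enriched_detected + self.n_depleted_absent

    @property
    def n_scored(self) -> int:
        return self.n_enriched_scored + self.n_depleted_scored

    @property
    def fraction(self) -> float | None:
        """Concordant fraction; None (undefined) when nothing was scored."""
        if self.n_scored == 0:
            return None
        return self.n_concordant / self.n_scored


def score_candidate(signature: SignatureSet, profile: CandidateProfile) -> MatchScore:
    """Count signature-concordant genes in a candidate profile.

    Concordant: enriched gene detected, or depleted gene absent.  Unknown
    statuses are dropped from the denominators; a status for a gene
    outside the signature is an error naming the gene.
    """
    sig_genes = set(signature.genes)
    for gene in profile.status:
        if gene not in sig_genes:
            raise OrgscreenError(
                f"profile {profile.region_name!r} scores gene {gene!r} "
                "which is not in the signature"
            )
    n_ed = n_es = n_da = n_ds = 0
    for gene in signature.enriched:
        status = profile.status.get(gene, STATUS_UNKNOWN)
        if status == STATUS_UNKNOWN:
            continue
        n_es += 1
        if status == STATUS_DETECTED:
            n_ed += 1
    for gene in signature.depleted:
        status = profile.status.get(gene, STATUS_UNKNOWN)
        if status == STATUS_UNKNOWN:
            continue
        n_ds += 1
        if status == STATUS_ABSENT:
            n_da += 1
    return MatchScore(n_ed, n_es, n_da, n_ds)


def rank_candidates(
    signature: SignatureSet, profiles: Iterable[CandidateProfile]
) -> list[tuple[str, MatchScore]]:
    """Rank regions by concordant fraction, descending.

    Ties break by n_scored (more evidence first), then region name;
    regions with an undefined fraction rank last.  Duplicate region names
    are an error; the ordering is independent of input order.
    """
    profiles = list(profiles)
    if not profiles:
        raise OrgscreenError("no candidate profiles to rank")
    names = [p.region_name for p in profiles]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise OrgscreenError(f"duplicate region names: {dups}")
    scored = [(p.region_name, score_candidate(signature, p)) for p in profiles]

    def key(item: tuple[str, MatchScore]):
        name, score = item
        frac = score.fraction
        return (frac is None, -(frac or 0.0), -score.n_scored, name)

    return sorted(scored, key=key)


def read_profiles(path: str | Path) -> list[CandidateProfile]:
    """Read candidate profiles from a TSV with columns region, gene_id, status."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"region", "gene_id", "status"}
    missing = required - set(df.columns)
    if missing:
        raise OrgscreenError(f"profile TSV missing columns: {sorted(missing)}")
    out = []
    for region, sub in df.groupby("region", sort=False):
        if sub["gene_id"].duplicated().any():
            raise OrgscreenError(f"region {region!r} lists a gene twice")
        out.append(
            CandidateProfile(region, dict(zip(sub["gene_id"], sub["status"])))
        )
    return out


def write_profiles(profiles: Iterable[CandidateProfile], path: str | Path) -> None:
    rows = [
        {"region": p.region_name, "gene_id": g, "status": s}
        for p in profiles
        for g, s in p.status.items()
    ]
    pd.DataFrame(rows, columns=["region", "gene_id", "status"]).to_csv(
        path, sep="\t", index=False
    )
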