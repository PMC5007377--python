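"""Synthetic microarray data with a planted organizer signature.

The generator emulates the study design — 9 tissue groups in triplicate —
and plants ground truth for every downstream stage:

* *planted enriched/depleted* genes receive a +/- ``effect`` (log2) group
  offset on the organizer side of every comparison in their planting
  pattern, so that their noise-free call vector satisfies the Boolean
  expression;
* *decoy* genes are differential only in a subset of comparisons chosen
  so the expression still rejects them (the combination algorithm's job);
* *null* genes have no group structure.

Per gene, the baseline is Uniform(baseline_range), the true variance is
drawn from a scaled inverse-chi-square prior (``d0 * s0^2 / chi2_d0``),
and replicate values add independent Normal(0, sigma_g^2) noise.
Everything is deterministic given the seed.

Because comparisons share tissue groups (HH4 PS serves C1 and C2; HH4 HN
serves C1 and C3), effects are planted per *group*, not per comparison:
each on-comparison contributes +/-effect to its organizer-side group, and
the realized call pattern is re-derived from the accumulated group
offsets.  Under the default all-comparisons pattern HH4 HN thus carries
2x effect (from C1 and C3).  A requested pattern whose realized calls
contradict its role (planted gene failing the algebra, decoy passing it)
is group-inconsistent and raises a generation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import boolean
from .boolean import BooleanExpr, CALL_DEPLETED, CALL_ENRICHED, CALL_NS
from .config import DEFAULT_COMPARISONS, ComparisonSpec
from .errors import GenerationError, OrgscreenError
from .io import ExpressionMatrix, SampleSheet
from .screen import CandidateProfile, STATUS_ABSENT, STATUS_DETECTED
from .assay import ExplantRecord
from .signature import SignatureSet

__all__ = [
    "PlantedSignatureParams",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_candidate_profile",
    "simulate_assay_records",
    "write_truth",
    "read_truth",
]

CLASS_ENRICHED = "planted_enriched"
CLASS_DEPLETED = "planted_depleted"
CLASS_DECOY = "decoy"
CLASS_NULL = "null"


@dataclass(frozen=True)
class PlantedSignatureParams:
    """Knobs of the planted-signature simulation.

    Defaults mirror the study scale that matters for recovery tests:
    31 enriched + 17 depleted planted genes in a 10,000-gene universe
    (a paper-scale 32,773-gene run is one parameter away), a 2.0 log2
    planted effect, baselines Uniform(4, 12) log2, a variance prior with
    d0 = 4 and s0^2 = 0.0625 (typical replicate SD 0.25 log2), and 200
    decoys differential in C1 only.
    """

    n_genes: int = 10_000
    n_enriched: int = 31
    n_depleted: int = 17
    effect: float = 2.0
    baseline_range: tuple[float, float] = (4.0, 12.0)
    var_prior_df: float = 4.0
    var_prior_scale: float = 0.0625
    n_decoy: int = 200
    decoy_pattern: tuple[str, ...] = ("C1",)
    planted_pattern: tuple[str, ...] | None = None  # None = every comparison

    def __post_init__(self):
        if min(self.n_genes, self.n_enriched, self.n_depleted, self.n_decoy) < 0:
            raise GenerationError("gene counts must be non-negative")
        if self.n_enriched + self.n_depleted + self.n_decoy > self.n_genes:
            raise GenerationError("planted + decoy genes exceed n_genes")
        if self.effect < 0:
            raise GenerationError("effect must be >= 0")
        if self.var_prior_df <= 0:
            raise GenerationError("var_prior_df must be positive")
        if self.var_prior_scale < 0:
            raise GenerationError("var_prior_scale must be >= 0")
        lo, hi = self.baseline_range
        if not lo <= hi:
            raise GenerationError("baseline_range must be (low, high) with low <= high")


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-gene class labels and noise-free direction patterns."""

    classes: pd.Series = field(repr=False)
    patterns: pd.DataFrame = field(repr=False)  # genes x comparisons, call strings

    @property
    def planted_enriched(self) -> list[str]:
        return list(self.classes.index[self.classes == CLASS_ENRICHED])

    @property
    def planted_depleted(self) -> list[str]:
        return list(self.classes.index[self.classes == CLASS_DEPLETED])

    @property
    def decoys(self) -> list[str]:
        return list(self.classes.index[self.classes == CLASS_DECOY])


def _offsets_for(
    pattern: Sequence[str],
    comparisons: Sequence[ComparisonSpec],
    effect: float,
    sign: int,
) -> dict[str, float]:
    """Accumulate +/-effect onto the organizer-side group of each on-comparison."""
    by_name = {c.name: c for c in comparisons}
    offsets: dict[str, float] = {}
    for name in pattern:
        if name not in by_name:
            raise GenerationError(f"pattern names unknown comparison {name!r}")
        grp = by_name[name].group_a
        offsets[grp] = offsets.get(grp, 0.0) + sign * effect
    return offsets


def _realized_calls(
    offsets: dict[str, float],
    comparisons: Sequence[ComparisonSpec],
    effect: float,
) -> dict[str, str]:
    """Noise-free calls implied by group offsets (ns everywhere if effect=0)."""
    calls = {}
    tol = 1e-9
    for c in comparisons:
        diff = offsets.get(c.group_a, 0.0) - offsets.get(c.group_b, 0.0)
        if effect > 0 and diff >= effect - tol:
            calls[c.name] = CALL_ENRICHED
        elif effect > 0 and diff <= -effect + tol:
            calls[c.name] = CALL_DEPLETED
        else:
            calls[c.name] = CALL_NS
    return calls


def simulate_expression(
    sheet: SampleSheet,
    params: PlantedSignatureParams,
    expr: BooleanExpr,
    seed: int,
    comparisons: Sequence[ComparisonSpec] = DEFAULT_COMPARISONS,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a matrix under the study design with planted truth.

    Planted genes satisfy ``expr`` (in their direction) by construction;
    decoys fail it by construction; both facts are verified against the
    realized group offsets and violations raise
    :class:`~orgscreen.errors.GenerationError`.  The degenerate
    ``effect = 0`` case plants nothing and skips the satisfiability check.
    """
    comp_names = {c.name for c in comparisons}
    missing = boolean.leaves(expr) - comp_names
    if missing:
        raise GenerationError(f"expression references unknown comparisons {sorted(missing)}")
    groups = set(sheet.groups)
    for c in comparisons:
        for g in (c.group_a, c.group_b):
            if g not in groups:
                raise GenerationError(f"sheet lacks group {g!r} needed by {c.name!r}")

    pattern = (
        params.planted_pattern
        if params.planted_pattern is not None
        else tuple(c.name for c in comparisons)
    )
    off_e = _offsets_for(pattern, comparisons, params.effect, +1)
    off_d = _offsets_for(pattern, comparisons, params.effect, -1)
    off_dec_pos = _offsets_for(params.decoy_pattern, comparisons, params.effect, +1)
    off_dec_neg = _offsets_for(params.decoy_pattern, comparisons, params.effect, -1)

    calls_by_kind = {
        "enriched": _realized_calls(off_e, comparisons, params.effect),
        "depleted": _realized_calls(off_d, comparisons, params.effect),
        "decoy+": _realized_calls(off_dec_pos, comparisons, params.effect),
        "decoy-": _realized_calls(off_dec_neg, comparisons, params.effect),
        "null": _realized_calls({}, comparisons, params.effect),
    }
    if params.effect > 0:
        if params.n_enriched and not boolean.evaluate_gene(
            expr, calls_by_kind["enriched"], CALL_ENRICHED
        ):
            raise GenerationError(
                f"planting pattern {pattern} is group-inconsistent: realized "
                "calls do not satisfy the expression (enriched direction)"
            )
        if params.n_depleted and not boolean.evaluate_gene(
            expr, calls_by_kind["depleted"], CALL_DEPLETED
        ):
            raise GenerationError(
                f"planting pattern {pattern} is group-inconsistent: realized "
                "calls do not satisfy the expression (depleted direction)"
            )
        if params.n_decoy:
            for kind in ("decoy+", "decoy-"):
                for direction in (CALL_ENRICHED, CALL_DEPLETED):
                    if boolean.evaluate_gene(expr, calls_by_kind[kind], direction):
                        raise GenerationError(
                            f"decoy pattern {params.decoy_pattern} satisfies the "
                            "expression; decoys must fail it by construction"
                        )

    n = params.n_genes
    width = max(6, len(str(n)))
    gene_ids = [f"G{i:0{width}d}" for i in range(1, n + 1)]
    kinds = np.empty(n, dtype=object)
    classes = np.empty(n, dtype=object)
    i0 = 0
    for count, cls, kind in (
        (params.n_enriched, CLASS_ENRICHED, "enriched"),
        (params.n_depleted, CLASS_DEPLETED, "depleted"),
    ):
        kinds[i0 : i0 + count] = kind
        classes[i0 : i0 + count] = cls
        i0 += count
    for j in range(params.n_decoy):
        kinds[i0 + j] = "decoy+" if j % 2 == 0 else "decoy-"
        classes[i0 + j] = CLASS_DECOY
    i0 += params.n_decoy
    kinds[i0:] = "null"
    classes[i0:] = CLASS_NULL

    group_list = sheet.groups
    offset_vectors = {
        "enriched": off_e,
        "depleted": off_d,
        "decoy+": off_dec_pos,
        "decoy-": off_dec_neg,
        "null": {},
    }
    kind_index = {k: i for i, k in enumerate(offset_vectors)}
    offsets_by_group = np.array(
        [
            [offset_vectors[k].get(g, 0.0) for g in group_list]
            for k in offset_vectors
        ]
    )
    group_of_sample = np.array(
        [group_list.index(g) for g in sheet.samples["group"]]
    )
    gene_kind_idx = np.array([kind_index[k] for k in kinds])
    effect_matrix = offsets_by_group[gene_kind_idx][:, group_of_sample]

    rng = np.random.default_rng(seed)
    lo, hi = params.baseline_range
    baseline = rng.uniform(lo, hi, size=n)
    chi2 = rng.chisquare(params.var_prior_df, size=n)
    sigma2 = params.var_prior_df * params.var_prior_scale / chi2
    noise = rng.standard_normal((n, len(sheet))) * np.sqrt(sigma2)[:, None]
    values = baseline[:, None] + effect_matrix + noise

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                     columns=sheet.sample_ids),
        sheet,
    )
    patterns = pd.DataFrame(
        [calls_by_kind[k] for k in kinds],
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[c.name for c in comparisons],
    )
    truth = SyntheticTruth(
        classes=pd.Series(classes, index=pd.Index(gene_ids, name="gene_id"),
                          name="gene_class"),
        patterns=patterns,
    )
    return matrix, truth


def simulate_candidate_profile(
    signature: SignatureSet,
    p_concordant_enriched: float,
    p_concordant_depleted: float,
    seed: int,
    region_name: str = "synthetic_candidate",
) -> CandidateProfile:
    """Bernoulli concordance profile over the signature genes.

    Each enriched gene is detected with probability
    ``p_concordant_enriched`` (else absent); each depleted gene is absent
    with probability ``p_concordant_depleted`` (else detected).
    """
    for p in (p_concordant_enriched, p_concordant_depleted):
        if not 0 <= p <= 1:
            raise OrgscreenError(f"probability {p} outside [0, 1]")
    if len(signature) == 0:
        raise OrgscreenError("cannot build a profile for an empty signature")
    rng = np.random.default_rng(seed)
    status: dict[str, str] = {}
    for gene in signature.enriched:
        concordant = rng.random() < p_concordant_enriched
        status[gene] = STATUS_DETECTED if concordant else STATUS_ABSENT
    for gene in signature.depleted:
        concordant = rng.random() < p_concordant_depleted
        status[gene] = STATUS_ABSENT if concordant else STATUS_DETECTED
    return CandidateProfile(region_name, status)


def simulate_assay_records(
    n_treat: int,
    n_ctrl: int,
    p_pos_treat: float,
    p_pos_ctrl: float,
    p_patchy: float,
    seed: int,
    marker: str = "MARKER",
) -> list[ExplantRecord]:
    """Bernoulli explant outcomes for a treatment and a control arm.

    Per explant: positive with the arm's ``p_pos``, patchy with
    ``p_patchy``, else negative.  ``p_pos + p_patchy`` must not exceed 1
    in either arm.
    """
    if n_treat < 0 or n_ctrl < 0:
        raise OrgscreenError("explant counts must be non-negative")
    for p in (p_pos_treat, p_pos_ctrl, p_patchy):
        if not 0 <= p <= 1:
            raise OrgscreenError(f"probability {p} outside [0, 1]")
    if p_pos_treat + p_patchy > 1 or p_pos_ctrl + p_patchy > 1:
        raise OrgscreenError("p_pos + p_patchy exceeds 1 in one arm")
    rng = np.random.default_rng(seed)
    records = []
    for condition, count, p_pos in (
        ("treatment", n_treat, p_pos_treat),
        ("control", n_ctrl, p_pos_ctrl),
    ):
        for i in range(count):
            u = rng.random()
            if u < p_pos:
                category = "positive"
            elif u < p_pos + p_patchy:
                category = "patchy"
            else:
                category = "negative"
            records.append(
                ExplantRecord(f"{condition[0].upper()}{i + 1:03d}", condition,
                              marker, category)
            )
    return records


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Truth TSV: gene_id, class, and the non-ns pattern as e.g. ``C1+,C4-``."""
    sign = {CALL_ENRICHED: "+", CALL_DEPLETED: "-"}
    pattern_str = [
        ",".join(
            f"{name}{sign[call]}"
            for name, call in row.items()
            if call != CALL_NS
        )
        for _, row in truth.patterns.iterrows()
    ]
    out = pd.DataFrame(
        {"gene_class": truth.classes, "pattern": pattern_str},
        index=truth.classes.index,
    )
    out.to_csv(path, sep="\t")


def read_truth(path: str | Path, comparisons: Sequence[str] | None = None) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
    names = list(comparisons) if comparisons else [c.name for c in DEFAULT_COMPARISONS]
    sign = {"+": CALL_ENRICHED, "-": CALL_DEPLETED}
    rows = []
    for pat in df["pattern"]:
        calls = dict.fromkeys(names, CALL_NS)
        if isinstance(pat, str) and pat:
            for token in pat.split(","):
                calls[token[:-1]] = sign[token[-1]]
        rows.append(calls)
    patterns = pd.DataFrame(rows, index=df.index, columns=names)
    return SyntheticTruth(classes=df["gene_class"].rename("gene_class"), patterns=patterns)
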