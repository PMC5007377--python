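"""Per-comparison differential expression with empirical-Bayes moderation.

Each comparison is fit independently: per gene, the log2 fold change is
the difference of group means and the residual variance is the pooled
within-group variance on ``n_a + n_b - 2`` degrees of freedom.  Gene-level
variances are shrunk toward a scaled inverse-chi-square prior estimated
from all genes by method of moments on the log-variance scale, and the
resulting moderated t-statistic is referred to a Student t distribution
with ``d0 + df`` degrees of freedom.  This is the classical hierarchical
model behind moderated-t differential expression: conditional on a gene's
true variance sigma^2, the observed ``s^2`` is ``sigma^2 * chi2_df / df``,
and ``sigma^2`` itself follows ``d0 * s0^2 / chi2_d0`` across genes.

Setting ``d0 = 0`` disables moderation (ordinary pooled two-sample t);
``d0 = inf`` fixes every gene's variance at ``s0^2`` (normal tail).

Significance calls follow the screen's rule: a gene is *enriched* in a
comparison when ``log2fc >= tau`` and BH-adjusted ``q <= alpha``,
*depleted* when ``log2fc <= -tau`` and ``q <= alpha``, otherwise *ns*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .boolean import CALL_DEPLETED, CALL_ENRICHED, CALL_NS
from .config import ComparisonSpec, PipelineConfig
from .errors import OrgscreenError
from .io import ExpressionMatrix

__all__ = [
    "ModerationParams",
    "group_stats",
    "estimate_variance_prior",
    "moderated_test",
    "pooled_residual_variance",
    "adjust_bh",
    "call_genes",
    "run_comparison",
    "run_screen",
    "calls_matrix",
]


@dataclass(frozen=True)
class ModerationParams:
    """Scaled inverse-chi-square variance prior.

    ``d0`` is the prior degrees of freedom (0 = no moderation,
    ``inf`` = infinitely strong prior), ``s0_sq`` the prior variance.
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0 or np.isnan(self.d0):
            raise OrgscreenError("d0 must be >= 0 (or inf)")
        if self.d0 > 0 and not self.s0_sq > 0:
            raise OrgscreenError("s0_sq must be positive when d0 > 0")


def group_stats(
    matrix: ExpressionMatrix, comparison: ComparisonSpec
) -> tuple[pd.DataFrame, int, int]:
    """Per-gene (log2fc, s_sq, df) for one pairwise comparison.

    Returns the per-gene table plus the two group sizes.  log2fc is
    mean(group_a) - mean(group_b); s_sq the pooled within-group variance
    on ``n_a + n_b - 2`` degrees of freedom.
    """
    a = matrix.group_values(comparison.group_a).to_numpy()
    b = matrix.group_values(comparison.group_b).to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise OrgscreenError(
            f"comparison {comparison.name!r}: both groups need >=2 replicates "
            f"(got {n_a} and {n_b})"
        )
    df = n_a + n_b - 2
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    ss_a = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_b = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s_sq = (ss_a + ss_b) / df
    table = pd.DataFrame(
        {"log2fc": log2fc, "s_sq": s_sq, "df": df}, index=matrix.values.index
    )
    table.index.name = "gene_id"
    return table, n_a, n_b


def pooled_residual_variance(matrix: ExpressionMatrix) -> tuple[pd.Series, int]:
    """Per-gene residual variance pooled across *all* tissue groups.

    This is the residual of the one-way design fit (one mean per group):
    df = n_samples - n_groups (18 under the default 9x3 design).  Sharing
    one variance per gene across every comparison mirrors a joint linear
    model over the whole design and is markedly better powered than the
    per-pair pooled variance on 4 df; the screen uses it by default
    (``variance_pooling: "pair"`` restores per-pair variances).
    """
    vals = matrix.values.to_numpy()
    sheet = matrix.sheet
    ss = np.zeros(vals.shape[0])
    df = 0
    col = {s: i for i, s in enumerate(sheet.sample_ids)}
    for g in sheet.groups:
        idx = [col[s] for s in sheet.group_samples(g)]
        sub = vals[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(idx) - 1
    if df == 0:
        raise OrgscreenError("no residual degrees of freedom in the design")
    return pd.Series(ss / df, index=matrix.values.index, name="s_sq"), df


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s_sq, df: int) -> ModerationParams:
    """Method-of-moments fit of the variance prior on the log scale.

    With ``z = log(s^2)``, ``e = z - digamma(df/2) + log(df/2)`` has mean
    ``log(s0^2) + digamma(d0/2) - log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` beyond the sampling term ``trigamma(df/2)``; solving
    the trigamma relation gives ``d0`` and back-substitution gives
    ``s0^2``.  When the observed spread does not exceed the sampling term
    the prior is degenerate: ``d0 = inf`` with ``s0^2`` the mean variance.

    Requires at least 50 genes with positive variance.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    pos = s_sq[s_sq > 0]
    if pos.size == 0:
        raise OrgscreenError("all gene variances are zero; prior not estimable")
    if pos.size < 50:
        raise OrgscreenError(
            f"need >=50 genes with positive variance to estimate the prior, got {pos.size}"
        )
    half_df = df / 2.0
    e = np.log(pos) - special.digamma(half_df) + np.log(half_df)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    rhs = e_var - special.polygamma(1, half_df)
    if rhs <= 0:
        return ModerationParams(d0=np.inf, s0_sq=float(pos.mean()))
    d0 = 2.0 * _trigamma_inverse(rhs)
    log_s0 = e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    return ModerationParams(d0=float(d0), s0_sq=float(np.exp(log_s0)))


def moderated_test(
    stats_table: pd.DataFrame,
    prior: ModerationParams,
    n_a: int,
    n_b: int,
) -> pd.DataFrame:
    """Moderated t and two-sided p per gene.

    Posterior variance ``s~^2 = (d0 s0^2 + df s^2) / (d0 + df)``;
    ``t = log2fc / (s~ sqrt(1/n_a + 1/n_b))`` with ``d0 + df`` degrees of
    freedom (normal tail when ``d0 = inf``).  Genes with ``s~ = 0`` and
    zero fold change get t = 0, p = 1; a zero posterior variance with a
    nonzero fold change is only possible without a proper prior and is an
    error.
    """
    lfc = stats_table["log2fc"].to_numpy(dtype=float)
    s_sq = stats_table["s_sq"].to_numpy(dtype=float)
    df = stats_table["df"].to_numpy(dtype=float)
    d0 = prior.d0
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
    elif d0 == 0:
        s_tilde_sq = s_sq.copy()
    else:
        s_tilde_sq = (d0 * prior.s0_sq + df * s_sq) / (d0 + df)
    total_df = d0 + df
    if np.any(total_df == 0) and not np.isinf(d0):
        if d0 == 0 and np.all(df == 0):
            raise OrgscreenError("d0 + df = 0: no degrees of freedom for testing")
    se = np.sqrt(s_tilde_sq * (1.0 / n_a + 1.0 / n_b))
    zero_se = se == 0
    if np.any(zero_se & (lfc != 0)):
        raise OrgscreenError(
            "zero residual variance with nonzero fold change; "
            "a proper prior (d0 > 0) is required to test such genes"
        )
    t = np.zeros_like(lfc)
    nz = ~zero_se
    t[nz] = lfc[nz] / se[nz]
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = stats_table.copy()
    out["t_mod"] = t
    out["p"] = p
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j>=i} m p_(j) / j`` on the sorted p-values, capped at 1
    and mapped back to input order; equal p share a q.  All p must lie in
    (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~(p > 0) | (p > 1)):
        raise OrgscreenError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_genes(table: pd.DataFrame, tau: float, alpha: float) -> pd.DataFrame:
    """Attach enriched/depleted/ns calls given log2FC and FDR thresholds."""
    if "q" not in table:
        raise OrgscreenError("q-values must be computed before calling genes")
    lfc = table["log2fc"].to_numpy(dtype=float)
    q = table["q"].to_numpy(dtype=float)
    call = np.full(len(table), CALL_NS, dtype=object)
    call[(lfc >= tau) & (q <= alpha)] = CALL_ENRICHED
    call[(lfc <= -tau) & (q <= alpha)] = CALL_DEPLETED
    out = table.copy()
    out["call"] = call
    return out


def run_comparison(
    matrix: ExpressionMatrix,
    comparison: ComparisonSpec,
    tau: float,
    alpha: float,
    prior: ModerationParams | None = None,
    residual: tuple[pd.Series, int] | None = None,
) -> pd.DataFrame:
    """Full differential stage for one comparison.

    ``residual`` optionally supplies a shared (s_sq, df) — e.g. from
    :func:`pooled_residual_variance` — replacing the per-pair pooled
    variance (fold changes always come from the pair).  When ``prior`` is
    None it is estimated from the variances used.  Returns the per-gene
    table with columns log2fc, s_sq, df, t_mod, p, q, call.
    """
    stats_table, n_a, n_b = group_stats(matrix, comparison)
    if residual is not None:
        s_sq, df = residual
        stats_table["s_sq"] = s_sq
        stats_table["df"] = df
    if prior is None:
        prior = estimate_variance_prior(
            stats_table["s_sq"], int(stats_table["df"].iloc[0])
        )
    tested = moderated_test(stats_table, prior, n_a, n_b)
    tested["q"] = adjust_bh(tested["p"])
    return call_genes(tested, tau, alpha)


def run_screen(
    matrix: ExpressionMatrix,
    config: PipelineConfig,
    prior: ModerationParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every configured comparison; returns tables keyed by name.

    With the default ``variance_pooling: "global"`` a single per-gene
    residual variance from the full design is shared by all comparisons
    and the prior is estimated once from it.
    """
    config.validate_against(matrix.sheet)
    tau = config.effective_lfc_threshold
    residual = None
    if config.variance_pooling == "global":
        residual = pooled_residual_variance(matrix)
        if prior is None:
            prior = estimate_variance_prior(residual[0], residual[1])
    return {
        c.name: run_comparison(matrix, c, tau, config.fdr_threshold, prior, residual)
        for c in config.comparisons
    }


def calls_matrix(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes x comparisons matrix of calls from per-comparison tables.

    All tables must cover the same genes (a gene present in one table but
    not another is a consistency error).
    """
    names = list(tables)
    base = tables[names[0]].index
    for name in names[1:]:
        if not tables[name].index.equals(base):
            only_a = set(base) - set(tables[name].index)
            only_b = set(tables[name].index) - set(base)
            raise OrgscreenError(
                f"comparison tables cover different genes "
                f"(e.g. {sorted(only_a | only_b)[:5]})"
            )
    return pd.DataFrame({name: tables[name]["call"] for name in names}, index=base)
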