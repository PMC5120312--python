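"""Integrated miRNA/mRNA interaction calling with a permutation null.

Candidate interactions are pairs of a differentially expressed miRNA and a
differentially expressed gene whose target-prediction score reaches a
threshold (default 0.8). For each candidate, Spearman correlation is
computed across the paired per-sample profiles; since a repressive miRNA
lowers its target's transcript level, the default test is one-sided for
negative correlation (a two-sided mode is available). P-values are BH
-adjusted across all candidates.

The global validity check permutes the identities of the expressed miRNAs
among their expression rows — breaking the identity-to-target link while
preserving the correlation structure — and recounts significant
interactions. With ``b`` of ``N`` permutations reaching the observed count,
the permutation p-value is ``(b + 1) / (N + 1)`` (the observed data counts
as one permutation, so the p-value can never be 0), and an exact
Clopper-Pearson binomial confidence interval is put on the exceedance
proportion ``b / N``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def spearman_rho(x, y, sidedness: str = "two") -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Ties get midranks; the p-value uses ``t = rho * sqrt((n-2)/(1-rho^2))``
    with ``n - 2`` degrees of freedom. ``sidedness="one"`` tests for
    negative correlation (repression); ``"two"`` is the symmetric test.
    Raises on constant input (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValidationError("inputs must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    p = _rho_pvalue(np.array([rho]), x.size, sidedness)[0]
    return rho, float(p)


def _rho_pvalue(rho: np.ndarray, n: int, sidedness: str) -> np.ndarray:
    if sidedness not in ("one", "two"):
        raise ValidationError(f"unknown sidedness {sidedness!r}")
    df = n - 2
    denom = np.sqrt(np.maximum(1.0 - rho**2, 1e-15))
    t = rho * np.sqrt(df) / denom
    if sidedness == "one":
        p = stats.t.cdf(t, df)  # lower tail: negative correlation
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _rank_normalize(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midrank each row, center and scale to unit norm.

    Returns the normalized matrix and a boolean mask of usable (non-constant)
    rows; the dot product of two normalized rows is the Spearman rho.
    """
    ranks = stats.rankdata(rows, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    usable = norms > 0
    safe = np.where(usable, norms, 1.0)
    return centered / safe[:, None], usable


@dataclass
class PermutationResult:
    observed_count: int
    n_permutations: int
    perm_counts: list[int] = field(repr=False)
    b: int = 0
    p_perm: float = 1.0
    ci_low: float = 0.0
    ci_high: float = 1.0

    def summary(self) -> dict:
        return {
            "observed_count": self.observed_count,
            "n_permutations": self.n_permutations,
            "exceedances": self.b,
            "p_perm": self.p_perm,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def clopper_pearson_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta-distribution quantiles.

    The lower bound is 0 when ``successes = 0`` and the upper bound 1 when
    ``successes = trials``; e.g. 0 of 100 at 95% gives an upper bound of
    ``1 - 0.025**(1/100) ≈ 0.036``.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValidationError("need 0 <= successes <= trials and trials >= 1")
    if not 0 < level < 1:
        raise ValidationError("level must lie in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    high = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return low, high


def _candidate_universe(
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    targets: pd.DataFrame,
    score_threshold: float,
):
    if mirna_expr.sample_ids != mrna_expr.sample_ids:
        raise ValidationError(
            "miRNA and mRNA matrices must share an identical ordered sample set"
        )
    n = mirna_expr.n_samples
    if n < 4:
        raise ValidationError("need at least 4 paired samples")

    de_m = [
        f
        for f in mirna_de.loc[mirna_de["significant"], "feature_id"]
        if f in set(mirna_expr.feature_ids)
    ]
    de_g = [
        f
        for f in mrna_de.loc[mrna_de["significant"], "feature_id"]
        if f in set(mrna_expr.feature_ids)
    ]
    de_m_set, de_g_set = set(de_m), set(de_g)
    cand = targets[
        targets["mirna_id"].isin(de_m_set)
        & targets["gene_id"].isin(de_g_set)
        & (targets["score"] >= score_threshold)
    ].reset_index(drop=True)

    zm, m_ok = _rank_normalize(mirna_expr.values.loc[de_m].to_numpy(dtype=float)) if de_m else (np.zeros((0, n)), np.zeros(0, bool))
    zg, g_ok = _rank_normalize(mrna_expr.values.loc[de_g].to_numpy(dtype=float)) if de_g else (np.zeros((0, n)), np.zeros(0, bool))
    n_const = int((~m_ok).sum() + (~g_ok).sum())
    if n_const:
        logger.warning("skipping pairs involving %d constant feature(s)", n_const)

    m_pos = {f: i for i, f in enumerate(de_m)}
    g_pos = {f: i for i, f in enumerate(de_g)}
    mi = cand["mirna_id"].map(m_pos).to_numpy(dtype=int) if len(cand) else np.zeros(0, int)
    gi = cand["gene_id"].map(g_pos).to_numpy(dtype=int) if len(cand) else np.zeros(0, int)
    ok = m_ok[mi] & g_ok[gi] if len(cand) else np.zeros(0, bool)
    cand = cand.loc[ok].reset_index(drop=True)
    mi, gi = mi[ok], gi[ok]
    return cand, zm, zg, mi, gi, n, len(de_m), len(de_g)


def call_interactions(
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    targets: pd.DataFrame,
    score_threshold: float = 0.8,
    alpha: float = 0.05,
    sidedness: str = "one",
) -> pd.DataFrame:
    """Call miRNA-mRNA interactions on paired per-sample profiles.

    Returns the candidate table with (mirna_id, gene_id, score, rho, p,
    p_adj, significant), BH-adjusted across all candidates; summary counts
    are stored in ``DataFrame.attrs``.
    """
    cand, zm, zg, mi, gi, n, n_de_m, n_de_g = _candidate_universe(
        mirna_de, mrna_de, mirna_expr, mrna_expr, targets, score_threshold
    )
    out = cand.copy()
    if len(cand) == 0:
        out["rho"] = pd.Series(dtype=float)
        out["p"] = pd.Series(dtype=float)
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    else:
        rho = np.einsum("ij,ij->i", zm[mi], zg[gi])
        rho = np.clip(rho, -1.0, 1.0)
        p = _rho_pvalue(rho, n, sidedness)
        from .diffexpr import benjamini_hochberg

        p_adj = benjamini_hochberg(p)
        out["rho"] = rho
        out["p"] = p
        out["p_adj"] = p_adj
        out["significant"] = p_adj < alpha
    out.attrs.update(
        {
            "n_de_mirna": n_de_m,
            "n_recognized_genes": n_de_g,
            "n_candidates": len(out),
            "n_significant": int(out["significant"].sum()) if len(out) else 0,
            "alpha": alpha,
            "score_threshold": score_threshold,
            "sidedness": sidedness,
            "n_samples": n,
        }
    )
    return out


def permutation_null(
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    targets: pd.DataFrame,
    score_threshold: float = 0.8,
    alpha: float = 0.05,
    sidedness: str = "one",
    n_permutations: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the significant-interaction count.

    Each permutation shuffles the assignment of expressed (differentially
    expressed) miRNA identities to miRNA expression rows, re-calls
    interactions under identical settings, and records the significant
    count. ``p_perm = (b + 1) / (N + 1)`` with ``b`` the number of
    permutations reaching the observed count; the exact binomial CI is on
    ``b / N``.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    cand, zm, zg, mi, gi, n, _, _ = _candidate_universe(
        mirna_de, mrna_de, mirna_expr, mrna_expr, targets, score_threshold
    )

    def count_significant(row_of: np.ndarray) -> int:
        if len(cand) == 0:
            return 0
        rho = np.einsum("ij,ij->i", zm[row_of[mi]], zg[gi])
        rho = np.clip(rho, -1.0, 1.0)
        p = _rho_pvalue(rho, n, sidedness)
        from .diffexpr import benjamini_hochberg

        return int((benjamini_hochberg(p) < alpha).sum())

    identity = np.arange(zm.shape[0])
    observed = count_significant(identity)
    rng = np.random.default_rng(seed)
    perm_counts = [
        count_significant(rng.permutation(identity)) for _ in range(n_permutations)
    ]
    b = int(sum(c >= observed for c in perm_counts))
    p_perm = (b + 1) / (n_permutations + 1)
    ci_low, ci_high = clopper_pearson_ci(b, n_permutations)
    logger.info(
        "permutation null: observed=%d, max(perm)=%s, b=%d/%d, p=%.4g, CI=[%.4g, %.4g]",
        observed, max(perm_counts) if perm_counts else None, b, n_permutations,
        p_perm, ci_low, ci_high,
    )
    return PermutationResult(
        observed_count=observed,
        n_permutations=n_permutations,
        perm_counts=perm_counts,
        b=b,
        p_perm=p_perm,
        ci_low=ci_low,
        ci_high=ci_high,
    )
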