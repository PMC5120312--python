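"""qPCR validation statistics: censoring, ΔCt, Mann-Whitney, NormFinder.

Ct values above the censor threshold (default 35 cycles) are "not detected"
and excluded. Expression is normalized by the ΔCt method against the
arithmetic mean Ct of the reference probes (equivalent to the geometric
mean of their linear quantities); relative expression is ``2**(-ΔCt)``.
Group comparisons use the Mann-Whitney U test — exact by enumeration for
small tie-free samples, otherwise the normal approximation with tie
correction. Reference-probe choice is supported by a NormFinder-style
model-based stability value combining each candidate's intergroup deviation
with its sampling-error-corrected intragroup variation (lower = more
stable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

logger = logging.getLogger(__name__)

EXACT_MAX_N = 20  # combined size up to which the exact U distribution is used


def censor_table(table: pd.DataFrame, censor_threshold: float = 35.0) -> pd.DataFrame:
    """Drop not-detected wells (Ct above the threshold), logging the count."""
    detected = table["ct"] <= censor_threshold
    n_censored = int((~detected).sum())
    if n_censored:
        logger.info("censoring %d well(s) with Ct > %g", n_censored, censor_threshold)
    out = table.loc[detected].reset_index(drop=True)
    out.attrs["n_censored"] = n_censored
    return out


@dataclass
class DeltaCtResult:
    per_sample: pd.DataFrame   # sample_id, group, probe_id, delta_ct, rel_expr
    per_target: pd.DataFrame   # probe_id, n_case, n_control, medians, U, p
    n_dropped_samples: int
    references: list[str]


def delta_ct(
    table: pd.DataFrame,
    references: list[str],
    censor_threshold: float = 35.0,
) -> DeltaCtResult:
    """ΔCt normalization against the mean Ct of the reference probes.

    Samples missing any detected reference value are dropped with a logged
    count. Returns per-sample ΔCt (``ct_target - mean(ct_references)``) and
    relative expression ``2**(-ΔCt)``, plus per-target group summaries with
    Mann-Whitney two-sided p-values.
    """
    if not references:
        raise ValidationError("reference probe list must be non-empty")
    detected = censor_table(table, censor_threshold)
    refs = detected[detected["probe_id"].isin(references)]
    ref_counts = refs.groupby("sample_id")["probe_id"].nunique()
    complete = set(ref_counts[ref_counts == len(references)].index)
    all_samples = set(table["sample_id"])
    n_dropped = len(all_samples - complete)
    if n_dropped:
        logger.warning(
            "dropping %d sample(s) missing a detected reference probe", n_dropped
        )
    ref_mean = (
        refs[refs["sample_id"].isin(complete)]
        .groupby("sample_id")["ct"]
        .mean()
    )
    targets = detected[
        detected["sample_id"].isin(complete)
        & ~detected["probe_id"].isin(references)
    ].copy()
    targets["delta_ct"] = targets["ct"] - targets["sample_id"].map(ref_mean)
    targets["rel_expr"] = np.exp2(-targets["delta_ct"])
    per_sample = targets[
        ["sample_id", "group", "probe_id", "delta_ct", "rel_expr"]
    ].reset_index(drop=True)

    rows = []
    for probe, sub in per_sample.groupby("probe_id"):
        case = sub.loc[sub["group"] == "case", "delta_ct"].to_numpy()
        ctrl = sub.loc[sub["group"] == "control", "delta_ct"].to_numpy()
        if len(case) and len(ctrl):
            u, p, method = mann_whitney_exact(case, ctrl, return_method=True)
        else:
            u, p, method = np.nan, np.nan, "na"
        rows.append(
            {
                "probe_id": probe,
                "n_case": len(case),
                "n_control": len(ctrl),
                "median_dct_case": float(np.median(case)) if len(case) else np.nan,
                "median_dct_control": float(np.median(ctrl)) if len(ctrl) else np.nan,
                "mean_dct_case": float(case.mean()) if len(case) else np.nan,
                "mean_dct_control": float(ctrl.mean()) if len(ctrl) else np.nan,
                "U": u,
                "p": p,
                "method": method,
            }
        )
    per_target = pd.DataFrame(rows).sort_values("probe_id", ignore_index=True)
    return DeltaCtResult(per_sample, per_target, n_dropped, list(references))


def mann_whitney_exact(group_a, group_b, return_method: bool = False):
    """Mann-Whitney U with a two-sided p-value.

    Exact (full permutation distribution of U) when the combined sample size
    is at most 20 and the pooled data are tie-free; otherwise the normal
    approximation with tie correction and continuity correction. Returns
    ``(U_a, p)`` (or ``(U_a, p, method)``), where ``U_a`` counts pairs won
    by ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and pooled.size <= EXACT_MAX_N:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    if return_method:
        return float(res.statistic), float(res.pvalue), method
    return float(res.statistic), float(res.pvalue)


def normfinder_stability(
    x: pd.DataFrame, groups: pd.Series | dict
) -> pd.DataFrame:
    """Model-based reference-gene stability for candidate normalizers.

    ``x`` holds log-scale expression (candidate genes in rows, samples in
    columns; for qPCR, ``-Ct`` is a natural choice since Ct is inversely
    log-linear in abundance). Each sample is first centered across the
    candidates, removing per-sample loading; the model then decomposes each
    candidate's variation into a group-dependent deviation (its expression
    shift relative to the candidate panel, per group) and an intragroup
    variance estimated per group with a sampling-error correction. The
    stability value averages ``|intergroup deviation| + sqrt(intragroup
    variance / n_group)`` over groups; lower is more stable. Returns a table
    sorted by stability with the per-group components.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = groups.reindex(x.columns)
    if groups.isna().any():
        raise ValidationError("every sample needs a group label")
    n_genes = x.shape[0]
    if n_genes < 3:
        raise ValidationError("need at least 3 candidate genes")
    level_counts = groups.value_counts()
    if (level_counts < 2).any() or len(level_counts) < 2:
        raise ValidationError("need >= 2 groups with >= 2 samples each")

    vals = x.to_numpy(dtype=float)
    centered = vals - vals.mean(axis=0, keepdims=True)  # remove sample effects

    levels = sorted(level_counts.index)
    inter = {}
    intra = {}
    overall_gene_mean = centered.mean(axis=1)
    for lev in levels:
        cols = np.asarray(groups == lev)
        sub = centered[:, cols]
        n_k = sub.shape[1]
        gene_mean = sub.mean(axis=1)
        inter[lev] = gene_mean - overall_gene_mean
        # two-way residuals within the group (gene and sample effects removed)
        resid = (
            sub
            - gene_mean[:, None]
            - sub.mean(axis=0, keepdims=True)
            + sub.mean()
        )
        s2 = (resid**2).sum(axis=1) / (n_k - 1)
        # sampling-error correction: E[s2_g] = sigma2_g (G-2)/G + sigma2_bar / G
        sbar2 = s2.mean()
        sigma_bar2 = sbar2 * n_genes / (n_genes - 1)
        sigma2 = (n_genes * s2 - sigma_bar2) / (n_genes - 2)
        intra[lev] = np.maximum(sigma2, 0.0)

    stability = np.zeros(n_genes)
    rows = {"candidate": list(x.index)}
    for lev in levels:
        n_k = int(level_counts[lev])
        comp = np.abs(inter[lev]) + np.sqrt(intra[lev] / n_k)
        stability += comp / len(levels)
        rows[f"intergroup_{lev}"] = inter[lev]
        rows[f"intragroup_var_{lev}"] = intra[lev]
    rows["stability"] = stability
    out = pd.DataFrame(rows).sort_values(
        ["stability", "candidate"], ignore_index=True
    )
    out["rank"] = np.arange(1, n_genes + 1)
    return out
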