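"""Two-group differential expression with BH-FDR and group-structure views.

The per-feature test is Welch's unequal-variance t-test: the groups here
(surgically explanted diseased valves vs post-mortem controls) differ in size
and plausibly in variance, so the pooled-variance form is not assumed.
Fold change is reported both as the signed log2 difference of group means
(case minus control) and as the linear ratio ``2**log2fc``; "more than
2-fold up" is equivalent to ``log2fc > 1``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io import ExpressionMatrix, ValidationError, validate_metadata

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised when a statistical routine receives an unusable input."""


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns ``(t, p)`` where ``t`` is signed (positive when ``group_a`` has
    the larger mean) and ``p`` is the two-sided probability from the t
    distribution with Welch-Satterthwaite degrees of freedom. If both groups
    have zero variance and equal means, ``(0.0, 1.0)`` is returned by
    convention; zero variance with unequal means gives ``p = 0``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} min(1, p_(j) * m / j)`` on the sorted scale,
    mapped back to the input order; monotone in the ranks and always at
    least the raw p-value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def differential_expression(
    x: ExpressionMatrix, meta: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature Welch test of case vs control with BH adjustment.

    Returns one row per feature with columns (feature_id, mean_case,
    mean_control, log2fc, fold_change, t, p, p_adj, direction, significant).
    ``direction`` is "up" iff ``log2fc > 0``. Features with zero variance in
    both groups and equal means receive ``t = 0, p = 1``.
    """
    meta = validate_metadata(meta)
    labelled = set(meta["sample_id"])
    missing = [s for s in x.sample_ids if s not in labelled]
    if missing:
        raise ValidationError(f"samples without group labels: {missing}")
    group = meta.set_index("sample_id")["group"].reindex(x.sample_ids)
    case_cols = group[group == "case"].index.tolist()
    ctrl_cols = group[group == "control"].index.tolist()
    if not case_cols or not ctrl_cols:
        raise ValidationError("both groups must be non-empty")

    a = x.values[case_cols].to_numpy(dtype=float)
    b = x.values[ctrl_cols].to_numpy(dtype=float)
    mean_case = a.mean(axis=1)
    mean_ctrl = b.mean(axis=1)
    log2fc = mean_case - mean_ctrl

    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: nan from the vectorized test
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        eq = degenerate & (log2fc == 0)
        ne = degenerate & (log2fc != 0)
        t[eq], p[eq] = 0.0, 1.0
        t[ne] = np.sign(log2fc[ne]) * np.inf
        p[ne] = 0.0
    p_adj = benjamini_hochberg(p)

    table = pd.DataFrame(
        {
            "feature_id": x.feature_ids,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2fc": log2fc,
            "fold_change": np.exp2(log2fc),
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(log2fc > 0, "up", "down"),
            "significant": p_adj < alpha,
        }
    )
    n_sig = int(table["significant"].sum())
    n_up = int((table["significant"] & (table["direction"] == "up")).sum())
    logger.info(
        "%s: %d/%d features significant at BH<%g (%d up, %d down)",
        x.kind, n_sig, len(table), alpha, n_up, n_sig - n_up,
    )
    return table


def collapse_probes(x: ExpressionMatrix, probe_to_gene: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe rows sharing a gene identifier, keeping the probe with
    the highest mean expression per gene (unmapped probes are dropped)."""
    df = x.values
    genes = pd.Series({p: probe_to_gene.get(p) for p in df.index})
    df = df.loc[genes.dropna().index]
    means = df.mean(axis=1)
    keep = (
        pd.DataFrame({"gene": genes.loc[df.index], "mean": means})
        .sort_values(["gene", "mean"], ascending=[True, False], kind="stable")
        .drop_duplicates("gene")
    )
    collapsed = df.loc[keep.index]
    collapsed.index = keep["gene"].values
    return ExpressionMatrix(collapsed.sort_index(), x.kind)


def pca_projection(x: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Project samples onto principal components of the feature space.

    Components are ordered by decreasing explained variance; signs are fixed
    deterministically (largest-magnitude loading positive). Returns a sample
    x component table with an ``explained_variance_ratio`` attribute row
    stored in ``DataFrame.attrs``.
    """
    from sklearn.decomposition import PCA

    if x.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    max_rank = min(len(x.feature_ids), x.n_samples)
    if n_components > max_rank:
        raise ValidationError(
            f"n_components={n_components} exceeds min(features, samples)={max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x.values.to_numpy(dtype=float).T)
    out = pd.DataFrame(
        coords,
        index=x.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return out


def hierarchical_order(x: ExpressionMatrix) -> tuple[list[str], list[str]]:
    """Deterministic leaf orderings for heatmap-style display.

    Features: average linkage on correlation distance (1 - Pearson r);
    samples: average linkage on Euclidean distance. Rows are pre-sorted by
    feature ID so the result is invariant to input row order (ties broken
    by ID). Zero-variance features get correlation distance treated as 0 to
    duplicated rows of the same constant.
    """
    if len(x.feature_ids) < 2 or x.n_samples < 2:
        raise ValidationError("need at least 2 features and 2 samples")
    df = x.values.sort_index(kind="stable")
    vals = df.to_numpy(dtype=float)

    centered = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    # zero-variance rows: identical constants are at distance 0, else 1
    zero = norms == 0
    if zero.any():
        corr[zero, :] = 0.0
        corr[:, zero] = 0.0
        for i in np.flatnonzero(zero):
            same = zero & (vals[:, 0] == vals[i, 0]) & (np.ptp(vals, axis=1) == 0)
            corr[i, same] = 1.0
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    feat_link = hierarchy.average(squareform(dist, checks=False))
    feat_order = [df.index[i] for i in hierarchy.leaves_list(feat_link)]

    samp_link = hierarchy.average(pdist(vals.T, metric="euclidean"))
    samp_order = [df.columns[i] for i in hierarchy.leaves_list(samp_link)]
    return feat_order, samp_order
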