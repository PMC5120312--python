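"""Synthetic paired miRNA/mRNA study generator with known ground truth.

Emulates the statistical structure of a two-group (diseased vs control)
valve-tissue expression study: a minority of miRNAs differentially expressed
with most of them down-regulated, correlated co-expression clusters among the
differentially expressed miRNAs, repressive miRNA->target couplings that show
up as negative Spearman correlation in paired samples, a target-prediction
score table separating true from decoy pairs, gene sets, a drug-gene
interaction table with a planted druggable hub, and a qPCR Ct table.

Every downstream stage of the pipeline has a recovery test against the
ground truth emitted here. All randomness flows from a single seed through a
named numpy Generator; there is no global random state.

Construction notes
------------------
* Cluster correlation uses one latent factor per cluster,
  ``x = sqrt(rho) * z_cluster + sqrt(1 - rho) * eps``, which gives pairwise
  Pearson correlation exactly ``rho`` in expectation.
* Repression couples a target gene to its miRNA(s) through a negative linear
  slope on the (approximately Gaussian) miRNA values. The slope is the
  Gaussian-copula inverse of the requested Spearman magnitude,
  ``r = 2 sin(pi * rho_s / 6)``, so the population Spearman correlation of a
  coupled pair is close to ``-repression_strength``; in the noise-free limit
  the coupling is strictly monotone and the sample Spearman is exactly -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, write_expression, write_gmt, write_tsv


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design this generator emulates: 15 diseased vs
    16 control arrays, a minority of miRNAs differentially expressed with
    ~75% of them down-regulated, five co-expression clusters with
    within-cluster correlation 0.7, and repressive couplings strong enough
    to be seen at a 10+10 paired-sample integration subset.
    """

    n_case: int = 15
    n_control: int = 16
    n_mirna: int = 300
    n_mrna: int = 1000
    n_de_mirna: int = 106
    fraction_down: float = 80 / 106
    n_clusters: int = 5
    within_cluster_rho: float = 0.7
    de_effect: float = 1.5          # log2 shift of DE features in cases
    noise_sd: float = 1.0           # within-group log2 SD of every feature
    n_de_mrna: int = 200            # directly shifted (non-target) DE genes
    mrna_fraction_down: float = 0.5
    n_repressive_pairs: int = 150
    n_hub_targets: int = 10         # target genes repressed by several miRNAs
    hub_parents: int = 3
    repression_strength: float = 0.8   # |population Spearman| of coupled pairs
    target_extra_shift: float = 0.75   # extra direct log2 disease shift of targets
    n_decoy_pairs: int = 600
    true_score_range: tuple[float, float] = (0.85, 1.0)
    false_score_range: tuple[float, float] = (0.5, 0.95)
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_case=self.n_case, n_control=self.n_control, n_mirna=self.n_mirna,
            n_mrna=self.n_mrna, n_clusters=self.n_clusters,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive (got {v})")
        for name, v in dict(
            n_de_mirna=self.n_de_mirna, n_de_mrna=self.n_de_mrna,
            n_repressive_pairs=self.n_repressive_pairs,
            n_decoy_pairs=self.n_decoy_pairs, n_hub_targets=self.n_hub_targets,
        ).items():
            if v < 0:
                raise ConfigError(f"{name} must be non-negative (got {v})")
        if self.n_de_mirna > self.n_mirna:
            raise ConfigError("n_de_mirna exceeds n_mirna")
        if self.n_repressive_pairs > self.n_de_mirna * self.n_mrna:
            raise ConfigError("n_repressive_pairs exceeds n_de_mirna * n_mrna")
        if not 0 <= self.fraction_down <= 1:
            raise ConfigError("fraction_down must lie in [0, 1]")
        if not 0 < self.within_cluster_rho < 1:
            raise ConfigError("within_cluster_rho must lie in (0, 1)")
        if not 0 < self.repression_strength < 1:
            raise ConfigError("repression_strength must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for rng_name, (lo, hi) in (
            ("true_score_range", self.true_score_range),
            ("false_score_range", self.false_score_range),
        ):
            if not (0 <= lo <= hi <= 1):
                raise ConfigError(f"{rng_name} must be an interval within [0, 1]")
        if self.n_hub_targets * self.hub_parents > self.n_repressive_pairs:
            raise ConfigError("hub pairs exceed n_repressive_pairs")


@dataclass
class GroundTruth:
    """Planted truth for recovery tests.

    ``de_mirna`` / ``de_mrna`` map feature id -> direction ("up"/"down" in
    cases relative to controls); ``cluster_membership`` maps DE miRNA id ->
    planted cluster label; ``repressive_pairs`` lists (mirna_id, gene_id)
    couplings; ``druggable_hubs`` are the hub target genes given qualifying
    drugs in the synthetic drug table.
    """

    de_mirna: dict[str, str]
    cluster_membership: dict[str, int]
    repressive_pairs: list[tuple[str, str]]
    de_mrna: dict[str, str]
    druggable_hubs: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fid, d in self.de_mirna.items():
            rows.append(("de_mirna", fid, d))
        for fid, c in self.cluster_membership.items():
            rows.append(("cluster", fid, str(c)))
        for m, g in self.repressive_pairs:
            rows.append(("repressive_pair", m, g))
        for fid, d in self.de_mrna.items():
            rows.append(("de_mrna", fid, d))
        for g in self.druggable_hubs:
            rows.append(("druggable_hub", g, ""))
        return pd.DataFrame(rows, columns=["record", "key", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruth":
        df = df.fillna("")
        sel = lambda rec: df[df["record"] == rec]  # noqa: E731
        return cls(
            de_mirna=dict(zip(sel("de_mirna")["key"], sel("de_mirna")["value"])),
            cluster_membership={
                k: int(v) for k, v in zip(sel("cluster")["key"], sel("cluster")["value"])
            },
            repressive_pairs=[
                (m, g)
                for m, g in zip(
                    sel("repressive_pair")["key"], sel("repressive_pair")["value"]
                )
            ],
            de_mrna=dict(zip(sel("de_mrna")["key"], sel("de_mrna")["value"])),
            druggable_hubs=list(sel("druggable_hub")["key"]),
        )


def _spearman_to_pearson(rho_s: float) -> float:
    # Gaussian-copula inversion; keeps the induced Spearman at the target.
    return min(0.999, 2.0 * np.sin(np.pi * rho_s / 6.0))


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def simulate_expression(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate paired miRNA/mRNA matrices, sample metadata and ground truth.

    Returns log2-scale matrices (features x samples), a metadata table with
    columns (sample_id, group, age, sex), and the :class:`GroundTruth`.
    Case samples come first in column order. Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    p_case = config.n_case / n

    sample_ids = [f"AS{i + 1:02d}" for i in range(config.n_case)] + [
        f"PM{i + 1:02d}" for i in range(config.n_control)
    ]
    is_case = np.array([1] * config.n_case + [0] * config.n_control, dtype=float)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": ["case"] * config.n_case + ["control"] * config.n_control,
            # Age structure mirrors the emulated study (older diseased group).
            "age": np.round(
                np.concatenate(
                    [
                        rng.normal(78.0, 6.0, config.n_case),
                        rng.normal(55.0, 14.0, config.n_control),
                    ]
                )
            ).astype(int),
            "sex": rng.choice(["M", "F"], size=n, p=[0.7, 0.3]),
        }
    )

    mirna_ids = [f"miR-syn-{i + 1:04d}" for i in range(config.n_mirna)]
    gene_ids = [f"GENE{i + 1:05d}" for i in range(config.n_mrna)]

    # --- miRNA layer ------------------------------------------------------
    de_idx = np.sort(rng.choice(config.n_mirna, size=config.n_de_mirna, replace=False))
    n_down = int(round(config.fraction_down * config.n_de_mirna))
    order = rng.permutation(config.n_de_mirna)
    down_mask = np.zeros(config.n_de_mirna, dtype=bool)
    down_mask[order[:n_down]] = True
    directions = np.where(down_mask, -1.0, 1.0)

    # Clusters are direction-homogeneous where possible (a mixed cluster
    # would be split by the disease shift anyway); the cluster count is
    # divided between the direction groups in proportion to their sizes,
    # with at least one cluster per non-empty group. With a single cluster
    # and both directions present, the cluster is shared.
    member_groups = [
        m for m in (np.flatnonzero(down_mask), np.flatnonzero(~down_mask)) if m.size
    ]
    if member_groups and config.n_clusters < len(member_groups):
        member_groups = [np.concatenate(member_groups)]
    total_members = sum(m.size for m in member_groups)
    alloc: list[int] = []
    remaining = config.n_clusters
    for i, m in enumerate(member_groups):
        if i == len(member_groups) - 1:
            k = remaining
        else:
            still_needed = len(member_groups) - 1 - i
            k = max(
                1,
                min(
                    remaining - still_needed,
                    round(config.n_clusters * m.size / total_members),
                ),
            )
        alloc.append(k)
        remaining -= k

    cluster_of = np.zeros(config.n_de_mirna, dtype=int)
    next_cluster = 1
    for members, k in zip(member_groups, alloc):
        sizes = _split_counts(len(members), k)
        pos = 0
        for sz in sizes:
            if sz == 0:
                continue
            cluster_of[members[pos : pos + sz]] = next_cluster
            next_cluster += 1
            pos += sz

    base_m = rng.uniform(4.0, 12.0, config.n_mirna)
    eps = rng.standard_normal((config.n_mirna, n))
    z = rng.standard_normal((next_cluster, n))  # latent factor per cluster
    signal = eps.copy()
    rho = config.within_cluster_rho
    for j, i in enumerate(de_idx):
        c = cluster_of[j]
        signal[i] = np.sqrt(rho) * z[c] + np.sqrt(1.0 - rho) * eps[i]
    x_mirna = base_m[:, None] + config.noise_sd * signal
    shift_m = np.zeros(config.n_mirna)
    shift_m[de_idx] = directions * config.de_effect
    x_mirna += shift_m[:, None] * is_case[None, :]

    de_mirna_ids = [mirna_ids[i] for i in de_idx]
    truth_de_mirna = {
        mirna_ids[i]: ("down" if d < 0 else "up")
        for i, d in zip(de_idx, directions)
    }
    truth_clusters = {mirna_ids[i]: int(c) for i, c in zip(de_idx, cluster_of)}

    # Theoretical pooled moments of each DE miRNA (two-group Gaussian mixture),
    # used to standardize parents when coupling targets.
    pooled_mean = base_m + shift_m * p_case
    pooled_sd = np.sqrt(
        config.noise_sd**2 + shift_m**2 * p_case * (1.0 - p_case)
    )

    # --- mRNA layer -------------------------------------------------------
    n_targets = config.n_repressive_pairs - config.n_hub_targets * config.hub_parents
    n_special = config.n_de_mrna + n_targets + config.n_hub_targets
    if n_special > config.n_mrna:
        raise ConfigError("n_mrna too small for requested DE genes and targets")
    special = rng.choice(config.n_mrna, size=n_special, replace=False)
    direct_idx = special[: config.n_de_mrna]
    singleton_idx = special[config.n_de_mrna : config.n_de_mrna + n_targets]
    hub_idx = special[config.n_de_mrna + n_targets :]

    base_g = rng.uniform(4.0, 12.0, config.n_mrna)
    x_mrna = base_g[:, None] + config.noise_sd * rng.standard_normal((config.n_mrna, n))

    truth_de_mrna: dict[str, str] = {}
    n_g_down = int(round(config.mrna_fraction_down * config.n_de_mrna))
    g_dirs = np.ones(config.n_de_mrna)
    g_dirs[: n_g_down] = -1.0
    g_dirs = g_dirs[rng.permutation(config.n_de_mrna)]
    for i, d in zip(direct_idx, g_dirs):
        x_mrna[i] += d * config.de_effect * is_case
        truth_de_mrna[gene_ids[i]] = "down" if d < 0 else "up"

    # Repressive couplings: singleton targets (one parent miRNA) plus hub
    # targets repressed by several direction-concordant parent miRNAs.
    r_p = _spearman_to_pearson(config.repression_strength)
    pairs: list[tuple[str, str]] = []
    down_parents = [i for i, d in zip(de_idx, directions) if d < 0]
    up_parents = [i for i, d in zip(de_idx, directions) if d > 0]

    def couple(gene_i: int, parent_is: list[int]) -> None:
        k = len(parent_is)
        parents_std = np.stack(
            [
                (x_mirna[pi] - pooled_mean[pi]) / max(pooled_sd[pi], 1e-12)
                for pi in parent_is
            ]
        )
        combo = parents_std.sum(axis=0) / np.sqrt(k)
        resid = rng.standard_normal(n)
        x_mrna[gene_i] = base_g[gene_i] + config.noise_sd * (
            -r_p * combo + np.sqrt(max(0.0, 1.0 - r_p**2)) * resid
        )
        # Net parent direction; the target is de-repressed in the opposite one.
        parent_dir = np.sign(sum(shift_m[pi] for pi in parent_is)) or 1.0
        g_dir = -parent_dir
        x_mrna[gene_i] += g_dir * config.target_extra_shift * is_case
        truth_de_mrna[gene_ids[gene_i]] = "down" if g_dir < 0 else "up"
        for pi in parent_is:
            pairs.append((mirna_ids[pi], gene_ids[gene_i]))

    if n_targets and de_idx.size:
        parent_choice = rng.choice(de_idx, size=n_targets, replace=True)
        for gi, pi in zip(singleton_idx, parent_choice):
            couple(int(gi), [int(pi)])
    hub_genes: list[str] = []
    for gi in hub_idx:
        pool = down_parents if (rng.random() < config.fraction_down and len(down_parents) >= config.hub_parents) else up_parents
        if len(pool) < config.hub_parents:
            pool = down_parents if len(down_parents) >= config.hub_parents else list(de_idx)
        parent_is = list(rng.choice(pool, size=config.hub_parents, replace=False))
        couple(int(gi), [int(p) for p in parent_is])
        hub_genes.append(gene_ids[int(gi)])

    truth = GroundTruth(
        de_mirna=truth_de_mirna,
        cluster_membership=truth_clusters,
        repressive_pairs=pairs,
        de_mrna=truth_de_mrna,
        druggable_hubs=hub_genes,
    )

    em_mirna = ExpressionMatrix(
        pd.DataFrame(x_mirna, index=mirna_ids, columns=sample_ids), "miRNA"
    )
    em_mrna = ExpressionMatrix(
        pd.DataFrame(x_mrna, index=gene_ids, columns=sample_ids), "mRNA"
    )
    return em_mirna, em_mrna, meta, truth


def simulate_target_scores(config: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Target-prediction score table containing every planted pair plus decoys.

    Planted repressive pairs score inside ``true_score_range``; decoy pairs
    (predicted targets with no expression coupling) score inside
    ``false_score_range``. Decoys are drawn between direction-concordant DE
    features: a non-coupled pair whose members shift in opposite directions
    with disease is statistically confounded with true repression in a
    two-group design, so concordant decoys are the class against which a
    false-positive rate is identifiable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    rows: list[tuple[str, str, float]] = []
    lo, hi = config.true_score_range
    for m, g in truth.repressive_pairs:
        rows.append((m, g, float(rng.uniform(lo, hi))))
    planted = set(truth.repressive_pairs)

    by_dir = {"down": [], "up": []}
    for m, d in truth.de_mirna.items():
        by_dir[d].append(m)
    genes_by_dir = {"down": [], "up": []}
    target_genes = {g for _, g in truth.repressive_pairs}
    for g, d in truth.de_mrna.items():
        if g not in target_genes:  # decoys never reuse coupled targets
            genes_by_dir[d].append(g)

    flo, fhi = config.false_score_range
    attempts = 0
    while len(rows) - len(planted) < config.n_decoy_pairs and attempts < 50 * config.n_decoy_pairs:
        attempts += 1
        d = "down" if rng.random() < config.fraction_down else "up"
        if not by_dir[d] or not genes_by_dir[d]:
            d = "down" if by_dir["down"] and genes_by_dir["down"] else "up"
            if not by_dir[d] or not genes_by_dir[d]:
                break
        m = by_dir[d][rng.integers(len(by_dir[d]))]
        g = genes_by_dir[d][rng.integers(len(genes_by_dir[d]))]
        if (m, g) in planted:
            continue
        rows.append((m, g, float(rng.uniform(flo, fhi))))
    df = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score"])
    return (
        df.groupby(["mirna_id", "gene_id"], as_index=False)["score"]
        .mean()
        .sort_values(["mirna_id", "gene_id"], ignore_index=True)
    )


def simulate_gene_sets(
    config: SynthConfig,
    truth: GroundTruth,
    n_random_sets: int = 20,
    random_set_size: int = 40,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT-style collection: one set equal to the planted repressed-target
    genes (the recoverable signal) plus random sets drawn from all genes."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    all_genes = [f"GENE{i + 1:05d}" for i in range(config.n_mrna)]
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    target_genes = sorted({g for _, g in truth.repressive_pairs})
    if target_genes:
        sets["PLANTED_TARGET_SET"] = set(target_genes)
        descriptions["PLANTED_TARGET_SET"] = "genes repressed by planted miRNAs"
    for i in range(n_random_sets):
        name = f"RANDOM_SET_{i + 1:02d}"
        sets[name] = set(rng.choice(all_genes, size=random_set_size, replace=False))
        descriptions[name] = "random background set"
    return sets, descriptions


DRUG_TYPES_DECOY = ("agonist", "activator", "cofactor")


def simulate_drug_table(config: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Drug-gene interaction table with qualifying drugs on planted hubs.

    Every hub target gene gets at least one drug of an actionable type
    (inhibitor/antagonist/antibody); background genes get drugs of
    non-actionable types, and a few unknown genes are included to exercise
    the unknown-gene handling of the ranking stage.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    rows: list[tuple[str, str, str]] = []
    actionable = ("inhibitor", "antagonist", "antibody")
    for i, g in enumerate(truth.druggable_hubs):
        rows.append((g, f"drug-hub-{i + 1:02d}", actionable[i % len(actionable)]))
    # some singleton targets are druggable too (peripheral candidates)
    singles = sorted({g for _, g in truth.repressive_pairs} - set(truth.druggable_hubs))
    for i, g in enumerate(singles[: max(5, len(singles) // 10)]):
        rows.append((g, f"drug-peri-{i + 1:02d}", actionable[i % len(actionable)]))
    # decoy rows: non-actionable interaction types on DE genes
    de_genes = sorted(truth.de_mrna)
    for i in range(min(30, len(de_genes))):
        g = de_genes[int(rng.integers(len(de_genes)))]
        rows.append((g, f"drug-decoy-{i + 1:02d}", DRUG_TYPES_DECOY[i % len(DRUG_TYPES_DECOY)]))
    for i in range(3):
        rows.append((f"UNKNOWNGENE{i}", f"drug-x-{i}", "inhibitor"))
    return pd.DataFrame(
        rows, columns=["gene_id", "drug_name", "interaction_type"]
    ).drop_duplicates(ignore_index=True)


def simulate_qpcr(
    n_case: int = 16,
    n_control: int = 36,
    de_fold: float = 2.0,
    seed: int = 0,
    *,
    noise_sd: float = 0.5,
    n_null_targets: int = 2,
    include_undetected_probe: bool = True,
) -> pd.DataFrame:
    """Simulate a long-format qPCR Ct table.

    Probes: two stable reference miRNAs (``ref-miR-A``, ``ref-miR-B``), one
    planted target ``target-miR-DE`` whose expression differs ``de_fold``-fold
    between groups (cases higher, so case Ct is ``log2(de_fold)`` cycles
    lower), ``n_null_targets`` unchanged targets, and optionally one
    low-abundance probe whose Ct falls around the usual detection limit.

    Ct values share a per-sample loading offset that the reference-probe
    normalization removes. ``de_fold`` must be positive; ``de_fold=1`` plants
    no difference. With ``noise_sd=0`` the group mean difference in
    normalized cycles equals exactly ``-log2(de_fold)``.
    """
    if de_fold <= 0:
        raise ConfigError("de_fold must be positive")
    if n_case < 2 or n_control < 2:
        raise ConfigError("group sizes must be at least 2")
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    sample_ids = [f"Q{'AS' if i < n_case else 'PM'}{i + 1:02d}" for i in range(n)]
    groups = ["case"] * n_case + ["control"] * n_control
    is_case = np.array([1.0] * n_case + [0.0] * n_control)
    loading = rng.normal(0.0, 0.8, n)  # per-sample RNA input offset

    probes: dict[str, np.ndarray] = {}
    for ref in ("ref-miR-A", "ref-miR-B"):
        probes[ref] = 20.0 + loading + rng.normal(0.0, noise_sd, n)
    probes["target-miR-DE"] = (
        28.0 + loading - np.log2(de_fold) * is_case + rng.normal(0.0, noise_sd, n)
    )
    for i in range(n_null_targets):
        probes[f"target-miR-null{i + 1}"] = (
            27.0 + i + loading + rng.normal(0.0, noise_sd, n)
        )
    if include_undetected_probe:
        probes["target-miR-low"] = 35.5 + loading + rng.normal(0.0, noise_sd, n)

    rows = []
    for probe_id, ct in probes.items():
        for sid, grp, c in zip(sample_ids, groups, ct):
            rows.append((sid, grp, probe_id, round(float(c), 4)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "probe_id", "ct"])


def write_dataset(
    config: SynthConfig, out_dir: str | Path, *, meta_header: dict | None = None
) -> dict[str, Path]:
    """Generate the full synthetic study and write every input file the
    pipeline consumes. Returns a name -> path mapping."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    em_mirna, em_mrna, meta, truth = simulate_expression(config)
    scores = simulate_target_scores(config, truth)
    sets, descriptions = simulate_gene_sets(config, truth)
    drugs = simulate_drug_table(config, truth)
    qpcr = simulate_qpcr(seed=config.seed)

    paths = {
        "mirna_expression": out / "mirna_expression.tsv",
        "mrna_expression": out / "mrna_expression.tsv",
        "metadata": out / "sample_metadata.tsv",
        "target_scores": out / "target_scores.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "drug_table": out / "drug_gene.tsv",
        "qpcr": out / "qpcr_ct.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    hdr = meta_header or {}
    write_expression(em_mirna, paths["mirna_expression"], meta=hdr)
    write_expression(em_mrna, paths["mrna_expression"], meta=hdr)
    write_tsv(meta, paths["metadata"], meta=hdr)
    write_tsv(scores, paths["target_scores"], meta=hdr)
    write_gmt(sets, paths["gene_sets"], descriptions)
    write_tsv(drugs, paths["drug_table"], meta=hdr)
    write_tsv(qpcr, paths["qpcr"], meta=hdr)
    write_tsv(truth.to_frame(), paths["ground_truth"], meta=hdr)
    return paths


def config_to_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    d["true_score_range"] = list(d["true_score_range"])
    d["false_score_range"] = list(d["false_score_range"])
    return d
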