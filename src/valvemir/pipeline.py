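"""End-to-end pipeline orchestration with a reproducible run manifest.

Stage order: differential expression -> miRNA co-expression network + MCL ->
integrated interaction calling with permutation null -> gene-set
over-representation -> drug-target prioritization. Every output file starts
with comment headers recording the tool version, the configuration hash and
the seed; the manifest contains no wall-clock information, so a rerun with
the same config and seed reproduces every byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .conet import correlation_graph, degree_table, edge_list, mcl
from .diffexpr import differential_expression
from .drugrank import (
    DEFAULT_ALLOWED_TYPES,
    build_full_network,
    qualifying_subnetwork,
    rank_drug_targets,
)
from .enrich import GeneSetCollection, enrich_genes
from .integrate import call_interactions, permutation_null
from .io import (
    ValidationError,
    read_drug_table,
    read_expression,
    read_gmt,
    read_metadata,
    read_target_scores,
    write_tsv,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Inputs and parameters of a full run (flat, text-serializable)."""

    mirna_expression: str
    mrna_expression: str
    metadata: str
    target_scores: str
    gene_sets: str
    drug_table: str
    out_dir: str
    alpha: float = 0.05
    correlation_threshold: float = 0.5
    correlation_mode: str = "positive"
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_prune_below: float = 1e-5
    mcl_max_iter: int = 100
    mcl_tol: float = 1e-6
    score_threshold: float = 0.8
    sidedness: str = "one"
    n_permutations: int = 100
    integration_subset: int = 10  # paired cases/controls used for integration
    min_fold: float = 2.0
    min_degree: int = 2
    allowed_types: tuple[str, ...] = tuple(sorted(DEFAULT_ALLOWED_TYPES))
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not -1 <= self.correlation_threshold <= 1:
            raise ValidationError("correlation_threshold must lie in [-1, 1]")
        if not 0 <= self.score_threshold <= 1:
            raise ValidationError("score_threshold must lie in [0, 1]")
        if self.mcl_inflation <= 1:
            raise ValidationError("mcl_inflation must exceed 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a flat ``key = value`` config file; keyword overrides win."""
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key = value")
            key, _, raw = line.partition("=")
            values[key.strip()] = _coerce(raw.strip())
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "allowed_types" in values and isinstance(values["allowed_types"], str):
        values["allowed_types"] = tuple(
            t.strip() for t in str(values["allowed_types"]).split(",") if t.strip()
        )
    return PipelineConfig(**values)  # type: ignore[arg-type]


def _coerce(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Structural validation of pipeline input files.

    Returns a report (list of dicts with file, line, message); an empty
    report means every file parsed. Malformed records are reported, never
    silently dropped.
    """
    report: list[dict] = []

    def flag(path, line, message):
        report.append({"file": str(path), "line": line, "message": message})

    for key, reader in (
        ("mirna_expression", lambda p: read_expression(p, "miRNA")),
        ("mrna_expression", lambda p: read_expression(p, "mRNA")),
        ("metadata", read_metadata),
        ("target_scores", read_target_scores),
        ("drug_table", read_drug_table),
    ):
        path = paths.get(key)
        if path is None:
            continue
        if not Path(path).exists():
            flag(path, 0, "file not found")
            continue
        try:
            reader(path)
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            flag(path, 0, str(exc))
    gmt = paths.get("gene_sets")
    if gmt is not None:
        if not Path(gmt).exists():
            flag(gmt, 0, "file not found")
        else:
            with open(gmt) as fh:
                for lineno, line in enumerate(fh, start=1):
                    stripped = line.rstrip("\n")
                    if stripped and not stripped.startswith("#"):
                        if len(stripped.split("\t")) < 3:
                            flag(gmt, lineno, "GMT line has < 3 fields")
            try:
                read_gmt(gmt)
            except ValidationError as exc:
                flag(gmt, 0, str(exc))
    return report


def _integration_subset(meta: pd.DataFrame, k: int) -> list[str]:
    case = meta.loc[meta["group"] == "case", "sample_id"].tolist()[:k]
    ctrl = meta.loc[meta["group"] == "control", "sample_id"].tolist()[:k]
    return case + ctrl


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage, write artifacts and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = {
        "tool": f"valvemir {__version__}",
        "config_sha256": config.config_hash(),
        "seed": config.seed,
    }
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "warnings": {},
    }

    def stage(name):
        def deco(fn):
            try:
                counts = fn()
            except Exception as exc:
                (out / "FAILED").write_text(f"{name}: {exc}\n")
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = counts
            logger.info("stage %s: %s", name, counts)
        return deco

    inputs = {
        "mirna_expression": config.mirna_expression,
        "mrna_expression": config.mrna_expression,
        "metadata": config.metadata,
        "target_scores": config.target_scores,
        "gene_sets": config.gene_sets,
        "drug_table": config.drug_table,
    }
    for key, p in inputs.items():
        if not Path(p).exists():
            raise StageError(f"stage 'inputs' failed: missing {key} file: {p}")
    problems = validate_inputs(inputs)
    if problems:
        raise StageError(f"stage 'inputs' failed: {problems}")

    mirna = read_expression(config.mirna_expression, "miRNA")
    mrna = read_expression(config.mrna_expression, "mRNA")
    meta = read_metadata(config.metadata)
    targets = read_target_scores(config.target_scores)
    collection = GeneSetCollection.from_gmt(config.gene_sets)
    drugs = read_drug_table(config.drug_table)

    state: dict = {}

    @stage("de")
    def _de():
        state["mirna_de"] = differential_expression(mirna, meta, config.alpha)
        state["mrna_de"] = differential_expression(mrna, meta, config.alpha)
        write_tsv(state["mirna_de"], out / "mirna_de.tsv", meta=hdr)
        write_tsv(state["mrna_de"], out / "mrna_de.tsv", meta=hdr)
        t = state["mirna_de"]
        return {
            "mirna_features": len(t),
            "mirna_significant": int(t["significant"].sum()),
            "mirna_sig_down": int(
                (t["significant"] & (t["direction"] == "down")).sum()
            ),
            "mrna_features": len(state["mrna_de"]),
            "mrna_significant": int(state["mrna_de"]["significant"].sum()),
        }

    @stage("network")
    def _network():
        de_ids = state["mirna_de"].loc[
            state["mirna_de"]["significant"], "feature_id"
        ].tolist()
        cg = correlation_graph(
            mirna, de_ids, config.correlation_threshold, config.correlation_mode
        )
        clusters = mcl(
            cg,
            inflation=config.mcl_inflation,
            expansion=config.mcl_expansion,
            prune_below=config.mcl_prune_below,
            max_iter=config.mcl_max_iter,
            tol=config.mcl_tol,
        )
        state["graph"], state["clusters"] = cg, clusters
        write_tsv(edge_list(cg), out / "mirna_edges.tsv", meta=hdr)
        write_tsv(clusters.as_frame(), out / "mirna_clusters.tsv", meta=hdr)
        write_tsv(degree_table(cg), out / "mirna_degree.tsv", meta=hdr)
        nx.write_graphml(cg.graph, out / "mirna_network.graphml")
        sizes = pd.Series(list(clusters.assignment.values())).value_counts()
        return {
            "nodes": cg.graph.number_of_nodes(),
            "edges": cg.graph.number_of_edges(),
            "dropped_constant": len(cg.dropped_features),
            "clusters": clusters.n_clusters,
            "clusters_multi_member": int((sizes >= 2).sum()),
            "mcl_converged": clusters.converged,
            "mcl_iterations": clusters.iterations,
        }

    @stage("integrate")
    def _integrate():
        subset = _integration_subset(meta, config.integration_subset)
        m_sub = mirna.subset_samples(subset)
        g_sub = mrna.subset_samples(subset)
        inter = call_interactions(
            state["mirna_de"], state["mrna_de"], m_sub, g_sub, targets,
            config.score_threshold, config.alpha, config.sidedness,
        )
        perm = permutation_null(
            state["mirna_de"], state["mrna_de"], m_sub, g_sub, targets,
            config.score_threshold, config.alpha, config.sidedness,
            config.n_permutations, config.seed,
        )
        state["interactions"], state["permutation"] = inter, perm
        write_tsv(inter, out / "interactions.tsv", meta=hdr)
        write_tsv(
            pd.DataFrame(
                {
                    "permutation": range(1, perm.n_permutations + 1),
                    "significant_count": perm.perm_counts,
                }
            ),
            out / "permutation_counts.tsv",
            meta=hdr,
        )
        with open(out / "permutation_summary.json", "w") as fh:
            json.dump(perm.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {
            "paired_samples": len(subset),
            "candidates": inter.attrs["n_candidates"],
            "recognized_genes": inter.attrs["n_recognized_genes"],
            "significant_interactions": inter.attrs["n_significant"],
            "permutation_p": perm.p_perm,
            "permutation_ci": [perm.ci_low, perm.ci_high],
        }

    @stage("enrich")
    def _enrich():
        inter = state["interactions"]
        sig = inter[inter["significant"]]
        query = set(sig["gene_id"])
        universe = set(mrna.feature_ids)
        result = enrich_genes(query, collection, universe, config.alpha)
        state["enrichment"] = result
        write_tsv(result, out / "enrichment.tsv", meta=hdr)
        return {
            "query_genes": len(query),
            "sets_tested": len(result),
            "sets_significant": int(result["significant"].sum()) if len(result) else 0,
        }

    @stage("drugs")
    def _drugs():
        inter = state["interactions"]
        sig = inter[inter["significant"]]
        if len(sig) == 0:
            report = pd.DataFrame(
                columns=["gene_id", "fold_change", "p_adj", "degree", "drugs", "connected"]
            )
        else:
            network = build_full_network(inter)
            report = rank_drug_targets(
                state["mrna_de"], network, drugs,
                config.min_fold, config.min_degree,
                set(config.allowed_types),
            )
            nx.write_graphml(
                qualifying_subnetwork(network, report), out / "drug_subnetwork.graphml"
            )
        state["drug_report"] = report
        write_tsv(report, out / "drug_targets.tsv", meta=hdr)
        return {
            "qualifying_genes": len(report),
            "connected_genes": int(report["connected"].sum()) if len(report) else 0,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
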