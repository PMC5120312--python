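"""Drug-target prioritization over the integrated miRNA/mRNA network.

Builds the bipartite interaction network from significant miRNA-mRNA
interactions, then filters for up-regulated genes with linear fold change
above a ratio (default 2), at least one drug of an actionable interaction
type (default inhibitor/antagonist/antibody, matched case-insensitively),
splitting hits into "connected" (network degree at or above a threshold,
default 2) and "peripheral" candidates.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .io import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ALLOWED_TYPES = frozenset({"inhibitor", "antagonist", "antibody"})


def build_full_network(interactions: pd.DataFrame) -> nx.Graph:
    """Bipartite miRNA/gene graph with one edge per significant interaction."""
    if len(interactions) == 0:
        raise ValidationError("interaction table is empty")
    sig = interactions[interactions["significant"]] if "significant" in interactions else interactions
    g = nx.Graph()
    for m, gene in zip(sig["mirna_id"], sig["gene_id"]):
        g.add_node(m, kind="miRNA")
        g.add_node(gene, kind="mRNA")
        g.add_edge(m, gene)
    return g


def rank_drug_targets(
    mrna_de: pd.DataFrame,
    network: nx.Graph,
    drugs: pd.DataFrame,
    min_fold: float = 2.0,
    min_degree: int = 2,
    allowed_types: frozenset[str] | set[str] = DEFAULT_ALLOWED_TYPES,
) -> pd.DataFrame:
    """Prioritize druggable up-regulated genes in the interaction network.

    A gene qualifies when it is a node of the network, up-regulated with
    linear fold change above ``min_fold``, and has at least one drug whose
    interaction type (lower-cased exact token) is in ``allowed_types``.
    Returns rows sorted by degree then fold change (both descending) with a
    ``connected`` flag for degree >= ``min_degree``. Drug rows naming genes
    absent from the expression table are ignored with a logged count.
    """
    allowed = {t.lower() for t in allowed_types}
    known = set(mrna_de["feature_id"])
    unknown = drugs[~drugs["gene_id"].isin(known)]
    if len(unknown):
        logger.warning(
            "ignoring %d drug row(s) naming unknown genes", len(unknown)
        )
    usable = drugs[
        drugs["gene_id"].isin(known)
        & drugs["interaction_type"].str.lower().isin(allowed)
    ]
    drugs_by_gene = usable.groupby("gene_id")["drug_name"].apply(
        lambda s: sorted(set(s))
    )

    de = mrna_de.set_index("feature_id")
    rows = []
    gene_nodes = [
        v for v, data in network.nodes(data=True) if data.get("kind") == "mRNA"
    ]
    for gene in gene_nodes:
        if gene not in de.index or gene not in drugs_by_gene.index:
            continue
        rec = de.loc[gene]
        if rec["direction"] != "up" or rec["fold_change"] <= min_fold:
            continue
        degree = network.degree(gene)
        rows.append(
            {
                "gene_id": gene,
                "fold_change": float(rec["fold_change"]),
                "p_adj": float(rec["p_adj"]),
                "degree": int(degree),
                "drugs": ";".join(drugs_by_gene.loc[gene]),
                "connected": degree >= min_degree,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "fold_change", "p_adj", "degree", "drugs", "connected"],
    )
    return out.sort_values(
        ["degree", "fold_change", "gene_id"],
        ascending=[False, False, True],
        ignore_index=True,
    )


def qualifying_subnetwork(network: nx.Graph, report: pd.DataFrame) -> nx.Graph:
    """Subgraph of qualifying genes plus their immediate neighbours."""
    keep: set[str] = set()
    for gene in report["gene_id"]:
        keep.add(gene)
        keep.update(network.neighbors(gene))
    return network.subgraph(keep).copy()
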