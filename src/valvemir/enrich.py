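"""Gene-set over-representation with a two-sided hypergeometric test.

Sets are read from GMT files and trimmed to the analysis universe before
testing (standard over-representation practice). The two-sided p-value is
the doubled smaller tail, capped at 1 — the conventional construction when
both enrichment and depletion are of interest. BH adjustment is applied
across the tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .io import ValidationError, read_gmt


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets, desc = read_gmt(path)
        return cls(sets, desc)

    def trimmed_to(self, universe: set[str]) -> dict[str, set[str]]:
        return {
            name: members & universe
            for name, members in self.sets.items()
        }


def hypergeometric_test(
    overlap: int, query: int, set_size: int, universe: int
) -> float:
    """Two-sided hypergeometric p for an overlap of ``overlap`` between a
    query of size ``query`` and a set of size ``set_size`` drawn from
    ``universe`` genes: ``min(1, 2 * min(P(X <= k), P(X >= k)))``."""
    if universe < 1:
        raise ValidationError("universe must be positive")
    if not (0 <= overlap <= min(query, set_size)):
        raise ValidationError("overlap exceeds min(query, set_size) or is negative")
    if query > universe or set_size > universe:
        raise ValidationError("query/set size exceed universe")
    hg = stats.hypergeom(universe, set_size, query)
    lower = float(hg.cdf(overlap))
    upper = float(hg.sf(overlap - 1))
    return min(1.0, 2.0 * min(lower, upper))


def enrich_genes(
    query_genes: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
    include_depleted: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``query_genes`` in each set of the collection.

    Sets are trimmed to the universe; by default only sets overlapping the
    query are tested (``include_depleted=True`` tests every non-empty
    trimmed set so depletion can be detected). Returns rows sorted by
    adjusted p then set name, with columns (set_name, overlap, set_size,
    query_size, universe_size, expected, direction, p, p_adj, significant).
    """
    if not universe:
        raise ValidationError("universe must be non-empty")
    query = set(query_genes)
    if not query <= universe:
        raise ValidationError("query genes must be a subset of the universe")
    trimmed = collection.trimmed_to(universe)
    n_u = len(universe)
    n_q = len(query)

    rows = []
    for name in sorted(trimmed):
        members = trimmed[name]
        if not members:
            continue
        k = len(query & members)
        if k == 0 and not include_depleted:
            continue
        expected = n_q * len(members) / n_u
        p = hypergeometric_test(k, n_q, len(members), n_u)
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(members),
                "query_size": n_q,
                "universe_size": n_u,
                "expected": expected,
                "direction": "enriched" if k >= expected else "depleted",
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap", "set_size", "query_size",
            "universe_size", "expected", "direction", "p",
        ],
    )
    if len(out):
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
        out = out.sort_values(["p_adj", "set_name"], ignore_index=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
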