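"""Module expansion with globally co-expressed and protein-interaction partners.

The interaction source is any weighted undirected edge table (gene_a, gene_b,
edge_type in {coexpression, ppi}, weight in (0, 1]). Non-member genes with at
least ``min_edges`` edges into the module are ranked by summed edge weight
(ties by edge count, then identifier) and the top ``max_added`` are appended.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError
from .gene_sets import GeneSet
from .prioritize import EnrichmentRecord, enrich_module

__all__ = [
    "load_edge_table",
    "ExpandedModule",
    "expand_module",
    "enrichment_improvement",
]

EDGE_TYPES = frozenset({"coexpression", "ppi"})


def load_edge_table(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Validate and canonicalise an interaction edge table.

    Self-edges are dropped; gene pairs are ordered lexicographically so the
    table is explicitly undirected; exact duplicate edges are removed.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = ["gene_a", "gene_b", "edge_type", "weight"]
    if list(table.columns[:4]) != required:
        raise ConfigurationError(f"edge table must have columns {required}")
    bad_type = ~table["edge_type"].isin(EDGE_TYPES)
    if bad_type.any():
        raise ConfigurationError(f"unknown edge types: {sorted(table.loc[bad_type, 'edge_type'].unique())}")
    w = pd.to_numeric(table["weight"], errors="coerce")
    if w.isna().any() or (w <= 0).any() or (w > 1).any():
        raise ConfigurationError("edge weights must lie in (0, 1]")
    table = table[table["gene_a"] != table["gene_b"]].copy()
    swap = table["gene_a"] > table["gene_b"]
    table.loc[swap, ["gene_a", "gene_b"]] = table.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    table = table.drop_duplicates(subset=["gene_a", "gene_b", "edge_type"])
    return table.reset_index(drop=True)


@dataclass
class ExpandedModule:
    """A module plus ranked interaction partners and their edge support."""

    name: str
    original_members: frozenset[str]
    added_members: tuple[str, ...]
    support: dict[str, tuple[int, float]]  # gene -> (edge count into module, summed weight)

    @property
    def expanded_set(self) -> GeneSet:
        return GeneSet(
            f"{self.name} expanded",
            self.original_members | set(self.added_members),
            description=f"{len(self.original_members)} original + {len(self.added_members)} added",
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "original_members": sorted(self.original_members),
                "added_members": list(self.added_members),
                "support": {g: {"edges": c, "weight": w} for g, (c, w) in self.support.items()},
            },
            indent=1,
        )

    def node_edge_tables(self, edges: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Node/edge tables for a network diagram of the expanded module."""
        members = self.original_members | set(self.added_members)
        nodes = pd.DataFrame(
            {
                "node": sorted(members),
                "origin": ["module" if g in self.original_members else "added" for g in sorted(members)],
            }
        )
        keep = edges["gene_a"].isin(members) & edges["gene_b"].isin(members)
        return nodes, edges[keep].reset_index(drop=True)


def expand_module(
    module: GeneSet,
    edges: pd.DataFrame,
    min_edges: int = 2,
    max_added: int = 12,
) -> ExpandedModule:
    """Append the best-supported interaction partners to a module.

    Candidates are non-members with >= ``min_edges`` edges into the module,
    ranked by summed edge weight (descending), then edge count, then gene
    identifier; the top ``max_added`` are added. Deterministic and invariant
    to edge-row order.
    """
    edges = load_edge_table(edges)
    if edges.empty:
        warnings.warn("empty edge table: no genes added", RuntimeWarning, stacklevel=2)
        return ExpandedModule(module.name, module.members, (), {})
    members = module.members
    touching = edges[edges["gene_a"].isin(members) ^ edges["gene_b"].isin(members)]
    partner = touching["gene_a"].where(~touching["gene_a"].isin(members), touching["gene_b"])
    stats = (
        pd.DataFrame({"partner": partner, "weight": touching["weight"].to_numpy()})
        .groupby("partner")["weight"]
        .agg(["count", "sum"])
        .reset_index()
    )
    stats = stats[stats["count"] >= min_edges]
    ranked = stats.sort_values(
        by=["sum", "count", "partner"], ascending=[False, False, True], kind="stable"
    )
    added = tuple(ranked["partner"].iloc[:max_added])
    by_gene = ranked.set_index("partner")
    support = {g: (int(by_gene.loc[g, "count"]), float(by_gene.loc[g, "sum"])) for g in added}
    return ExpandedModule(module.name, members, added, support)


def enrichment_improvement(
    original: GeneSet,
    expanded: GeneSet,
    sets: list[GeneSet],
    universe: GeneSet,
) -> list[dict]:
    """Before/after Fisher enrichment per assessment set with an improvement flag."""
    if not expanded.members >= original.members:
        raise ConfigurationError("expanded module must contain the original module")
    out = []
    for s in sets:
        before: EnrichmentRecord = enrich_module(original, s, universe)
        after: EnrichmentRecord = enrich_module(expanded, s, universe)
        out.append(
            {
                "set_name": s.name,
                "p_before": before.p_value,
                "p_after": after.p_value,
                "overlap_before": before.overlap,
                "overlap_after": after.overlap,
                "improved": after.p_value < before.p_value,
            }
        )
    return out
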