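"""Module prioritisation by enrichment against assessment gene sets.

Each seeded module is scored against the three assessment sets (motor-neuron
duration, lymphoblastoid progression, GWAS) with a one-sided Fisher test on
the measured-gene universe. Selection uses raw p < alpha (the screens report
unadjusted thresholds); Benjamini-Hochberg adjusted values are reported
alongside. Modules enriched with all three sets are "triple-enriched".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_stats import ContingencyTable, bh_adjust, fisher_enrichment
from .errors import ConfigurationError
from .gene_sets import GeneSet, GeneSetCollection
from .network import ModulePartition
from .study import ExpressionStudy

__all__ = [
    "EnrichmentRecord",
    "PriorityReport",
    "module_gene_sets",
    "enrich_module",
    "prioritize_modules",
    "negative_control_compare",
    "functional_enrichment",
]


@dataclass
class EnrichmentRecord:
    """One module-versus-set Fisher test."""

    module: str
    set_name: str
    overlap: int
    module_genes_in_universe: int
    set_genes_in_universe: int
    universe_size: int
    p_value: float
    adjusted_p: float = float("nan")
    is_control: bool = False


@dataclass
class PriorityReport:
    records: list[EnrichmentRecord]
    triple_enriched_modules: list[str]
    alpha: float
    control_comparison: list[EnrichmentRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records + self.control_comparison])

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "triple_enriched_modules": self.triple_enriched_modules,
                "records": [asdict(r) for r in self.records],
                "control_comparison": [asdict(r) for r in self.control_comparison],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PriorityReport":
        d = json.loads(text)
        return cls(
            records=[EnrichmentRecord(**r) for r in d["records"]],
            triple_enriched_modules=list(d["triple_enriched_modules"]),
            alpha=d["alpha"],
            control_comparison=[EnrichmentRecord(**r) for r in d["control_comparison"]],
        )

    def write(self, stem: str | Path) -> None:
        stem = Path(stem)
        self.to_frame().to_csv(stem.with_suffix(".tsv"), sep="\t", index=False)
        stem.with_suffix(".json").write_text(self.to_json())


def module_gene_sets(partition: ModulePartition, study: ExpressionStudy) -> dict[str, GeneSet]:
    """Collapse each module's transcripts to a gene set (module 0 excluded)."""
    out = {}
    for m in partition.module_numbers:
        genes = study.genes_for(partition.members(m))
        out[str(m)] = GeneSet(f"module {m}", genes)
    return out


def enrich_module(module_genes: GeneSet, assessment: GeneSet, universe: GeneSet) -> EnrichmentRecord:
    """One-sided Fisher enrichment of a module against one assessment set.

    Both sets are intersected with the universe before counting. An empty
    intersection yields overlap 0 and p = 1 with a warning.
    """
    m = module_genes.intersect(universe.members)
    s = assessment.intersect(universe.members)
    if not m or not s:
        warnings.warn(
            f"empty intersection with universe for {module_genes.name} vs {assessment.name}",
            RuntimeWarning,
            stacklevel=2,
        )
        return EnrichmentRecord(
            module_genes.name, assessment.name, 0, len(m), len(s), len(universe), 1.0
        )
    table = ContingencyTable.from_sets(m, s, universe.members)
    res = fisher_enrichment(table)
    return EnrichmentRecord(
        module_genes.name,
        assessment.name,
        table.overlap,
        table.module_size,
        table.set_size,
        table.universe_size,
        res.p_value,
    )


def prioritize_modules(
    partition: ModulePartition,
    study: ExpressionStudy,
    sets: list[GeneSet],
    universe: GeneSet | None = None,
    alpha: float = 0.05,
) -> PriorityReport:
    """Score every seeded module against the three assessment sets.

    BH adjustment is applied within each assessment set across modules and
    reported alongside the raw p; selection (triple enrichment) uses raw
    p < alpha for all three sets. Triple-enriched modules are ranked by their
    best per-set p-value.
    """
    if len(sets) != 3:
        raise ConfigurationError("exactly three assessment sets are required")
    if universe is None:
        universe = GeneSet("measured genes", study.measured_genes, "platform")
    modules = module_gene_sets(partition, study)
    records: list[EnrichmentRecord] = []
    for set_obj in sets:
        batch = [enrich_module(mg, set_obj, universe) for mg in modules.values()]
        if batch:
            adj = bh_adjust([r.p_value for r in batch])
            for r, a in zip(batch, adj):
                r.adjusted_p = float(a)
        records.extend(batch)
    by_module: dict[str, list[EnrichmentRecord]] = {}
    for r in records:
        by_module.setdefault(r.module, []).append(r)
    triple = [
        m
        for m, rs in by_module.items()
        if len(rs) == 3 and all(r.p_value < alpha or alpha >= 1.0 for r in rs)
    ]
    triple.sort(key=lambda m: min(r.p_value for r in by_module[m]))
    return PriorityReport(records, triple, alpha)


def negative_control_compare(
    control_set: GeneSet, sets: list[GeneSet], universe: GeneSet
) -> list[EnrichmentRecord]:
    """Enrichment records for a cell-identity control module, flagged for reporting."""
    if not control_set.members:
        raise ConfigurationError("control set is empty")
    out = []
    for s in sets:
        rec = enrich_module(control_set, s, universe)
        rec.is_control = True
        out.append(rec)
    return out


def functional_enrichment(
    module_genes: GeneSet, collections: GeneSetCollection, universe: GeneSet
) -> list[EnrichmentRecord]:
    """Fisher enrichment against every set in a collection, BH adjusted and sorted."""
    if len(collections) == 0:
        raise ConfigurationError("empty gene-set collection")
    records = [enrich_module(module_genes, s, universe) for s in collections]
    adj = bh_adjust([r.p_value for r in records])
    for r, a in zip(records, adj):
        r.adjusted_p = float(a)
    records.sort(key=lambda r: (r.adjusted_p, r.p_value, r.set_name))
    return records
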