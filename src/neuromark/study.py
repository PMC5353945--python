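"""The in-memory expression-study container shared by all stages."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError


@dataclass
class ExpressionStudy:
    """Normalised transcripts x samples expression with clinical annotations.

    ``matrix``: DataFrame indexed by transcript id, one column per sample.
    ``gene_map``: Series mapping transcript id -> gene id (many-to-one allowed).
    ``samples``: DataFrame indexed by sample id; recognised columns are
    ``pathology_count`` (inclusion-bearing motor neurons per unit area),
    ``duration_years``, ``onset_age``, ``sex`` and ``progression_label``.
    """

    matrix: pd.DataFrame
    gene_map: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.matrix.index.is_unique:
            raise ConfigurationError("duplicate transcript identifiers")
        missing = self.matrix.index.difference(self.gene_map.index)
        if len(missing):
            raise ConfigurationError(f"{len(missing)} transcripts missing from gene_map")
        extra = self.samples.index.difference(self.matrix.columns)
        if len(extra):
            raise ConfigurationError(f"annotated samples without expression columns: {list(extra)[:5]}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def genes_for(self, transcripts) -> frozenset[str]:
        """Collapse transcript identifiers to the genes they map to."""
        present = [t for t in transcripts if t in self.gene_map.index]
        return frozenset(self.gene_map.loc[present].dropna())

    @property
    def measured_genes(self) -> frozenset[str]:
        return frozenset(self.gene_map.dropna())


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write transcripts x samples expression as (optionally gzipped) TSV."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            matrix.to_csv(fh, sep="\t", index_label="transcript_id")
    else:
        matrix.to_csv(path, sep="\t", index_label="transcript_id")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript_id")
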