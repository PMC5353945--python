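"""Pathology-covariate transcriptome screens and assessment gene sets.

Four gene lists feed module prioritisation:

* the pathology screen (Spearman of each transcript against the per-sample
  inclusion count, p < 0.01 unadjusted) whose hits become network seeds;
* the motor-neuron assessment set (duration-correlated transcripts, p < 0.05);
* the lymphoblastoid assessment set (rapid-vs-slow differential transcripts,
  Mann-Whitney p < 0.05);
* the genetic assessment set (GWAS genes below 5e-8, consumed as a table).

No multiple-testing correction is applied in any screen: selection uses the
unadjusted thresholds, which is surfaced in all reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_stats
from .errors import ConfigurationError, DegenerateInputError, InsufficientDataError
from .gene_sets import GeneSet
from .study import ExpressionStudy

__all__ = [
    "ScreenResult",
    "screen_pathology_correlates",
    "screen_to_frame",
    "derive_duration_set",
    "derive_progression_set",
    "load_gwas_set",
    "classify_progression",
]


@dataclass(frozen=True)
class ScreenResult:
    transcript_id: str
    rho: float
    p_value: float
    selected: bool
    degenerate: bool = False


def _correlation_screen(study: ExpressionStudy, covariate: pd.Series, alpha: float, covariate_name: str):
    if not 0 <= alpha <= 1:
        raise ConfigurationError("alpha must be in [0, 1]")
    cov = covariate.dropna()
    if len(cov) < 3:
        raise InsufficientDataError(f"{covariate_name} present for fewer than 3 samples")
    X = study.matrix[cov.index].to_numpy()
    y = cov.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateInputError(f"degenerate covariate: {covariate_name} constant across samples")
    n = len(y)
    if n >= 10:
        rho, p = core_stats.spearman_screen(X, y)
    else:
        # small-sample path: per-transcript exact/approximate Spearman
        rho = np.full(X.shape[0], np.nan)
        p = np.full(X.shape[0], np.nan)
        for i in range(X.shape[0]):
            try:
                r = core_stats.spearman(X[i], y)
            except DegenerateInputError:
                continue
            rho[i], p[i] = r.statistic, r.p_value
    results = []
    for tid, r_i, p_i in zip(study.transcript_ids, rho, p):
        degenerate = not np.isfinite(p_i)
        # alpha = 1 admits every usable transcript (p is capped at exactly 1)
        selected = bool(np.isfinite(p_i) and (p_i < alpha or alpha >= 1.0))
        results.append(ScreenResult(tid, float(r_i) if np.isfinite(r_i) else np.nan,
                                    float(p_i) if np.isfinite(p_i) else np.nan,
                                    selected, degenerate))
    return results


def screen_pathology_correlates(study: ExpressionStudy, alpha: float = 0.01) -> list[ScreenResult]:
    """Per-transcript Spearman against the pathology count; hits seed the network.

    Constant transcript rows are reported unselected with the degenerate flag.
    """
    if "pathology_count" not in study.samples.columns:
        raise ConfigurationError("study has no pathology_count annotation")
    return _correlation_screen(study, study.samples["pathology_count"], alpha, "pathology counts")


def derive_duration_set(study: ExpressionStudy, alpha: float = 0.05) -> GeneSet:
    """Duration-correlated transcripts collapsed to genes: the motor neuron assessment set."""
    if "duration_years" not in study.samples.columns:
        raise ConfigurationError("study has no duration_years annotation")
    res = _correlation_screen(study, study.samples["duration_years"], alpha, "durations")
    hits = [r.transcript_id for r in res if r.selected]
    return GeneSet(
        "motor neuron assessment set",
        study.genes_for(hits),
        description=f"duration-correlated transcripts, p<{alpha} unadjusted",
    )


def derive_progression_set(study: ExpressionStudy, alpha: float = 0.05) -> GeneSet:
    """Rapid-vs-slow differential transcripts collapsed to genes: the lymphoblastoid assessment set.

    Intermediate samples (duration in the 2-4 year band) are excluded.
    """
    if "progression_label" in study.samples.columns:
        labels = study.samples["progression_label"]
    elif "duration_years" in study.samples.columns:
        labels = study.samples["duration_years"].map(classify_progression)
    else:
        raise ConfigurationError("group definition error: no progression labels or durations")
    keep = labels.isin(["rapid", "slow"])
    if (labels[keep] == "rapid").sum() < 2 or (labels[keep] == "slow").sum() < 2:
        raise ConfigurationError("group definition error: need >= 2 rapid and >= 2 slow samples")
    X = study.matrix.loc[:, keep[keep].index].to_numpy()
    mask = (labels[keep] == "rapid").to_numpy()
    _, p = core_stats.mann_whitney_screen(X, mask)
    hits = [
        tid
        for tid, p_i in zip(study.transcript_ids, p)
        if np.isfinite(p_i) and (p_i < alpha or alpha >= 1.0)
    ]
    return GeneSet(
        "lymphoblastoid assessment set",
        study.genes_for(hits),
        description=f"rapid-vs-slow differential transcripts, p<{alpha} unadjusted",
    )


def load_gwas_set(table: pd.DataFrame | str | Path, threshold: float = 5e-8) -> GeneSet:
    """Genes below the genome-wide significance threshold: the genetic assessment set.

    ``table`` needs ``gene`` and ``p`` columns; malformed rows are skipped and
    counted in the set description.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    cols = {c.lower(): c for c in table.columns}
    if "gene" not in cols or "p" not in cols:
        raise ConfigurationError("GWAS table must have 'gene' and 'p' columns")
    genes = table[cols["gene"]].astype(str)
    p = pd.to_numeric(table[cols["p"]], errors="coerce")
    ok = p.notna() & (p > 0) & (p <= 1) & genes.notna() & (genes.str.len() > 0)
    skipped = int((~ok).sum())
    members = frozenset(genes[ok & (p < threshold)])
    return GeneSet(
        "genetic assessment set",
        members,
        description=f"GWAS genes p<{threshold:g}; {skipped} malformed rows skipped",
    )


def classify_progression(duration_years: float) -> str:
    """Rapid (< 2 y), slow (> 4 y) or intermediate; boundary durations are intermediate."""
    if not np.isfinite(duration_years) or duration_years <= 0:
        raise ConfigurationError(f"non-positive disease duration: {duration_years}")
    if duration_years < 2.0:
        return "rapid"
    if duration_years > 4.0:
        return "slow"
    return "intermediate"


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "rho": [r.rho for r in results],
            "p_value": [r.p_value for r in results],
            "selected": [r.selected for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
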