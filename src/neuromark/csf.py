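"""CSF soluble-TREM2 biomarker analysis: group comparison and disease-course staging.

The packaged fixture is a verbatim transcription of a published clinical
table: 46 sporadic ALS patients and 20 controls with sex, onset age,
onset-to-death duration, percent of the disease course elapsed at CSF
sampling, and the CSF soluble-TREM2 concentration (ng/ml). One ALS subject
has unavailable duration and staging; control ages are kept as printed but
cannot be parsed consistently and are excluded from every computation.

Statistics are rank-based to be robust to the heavy right tail (one subject
at 309.6 ng/ml is retained, never excluded). The two confirmatory analyses
are directional by design — soluble TREM2 is hypothesised to be *elevated*
in ALS, and *positively* associated with duration late in the course — so
one-sided tests are primary and two-sided values are reported alongside.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_stats
from .core_stats import TestResult
from .errors import ConfigurationError, FixtureError, InsufficientDataError

__all__ = [
    "CsfTable",
    "load_csf_fixture",
    "load_csf_table",
    "GroupComparison",
    "compare_groups",
    "StageAssignment",
    "assign_stage",
    "stage_summary",
    "stage_stratified_association",
]

FIXTURE_SHA256 = "15cc6ea825db3773ed02dbb6acf85631b1df919fa08748852067ded303edb78c"
_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "onset_age_years",
    "duration_years",
    "sampling_age_printed",
    "percent_course",
    "strem2_ng_ml",
]
STAGES = ("early", "middle", "late", "unstaged")


@dataclass
class CsfTable:
    """One row per subject; see the packaged schema file for column semantics."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"CSF table missing columns: {sorted(missing)}")
        f = self.frame
        if not f["group"].isin(["ALS", "Control"]).all():
            raise ConfigurationError("group must be ALS or Control")
        if (f["strem2_ng_ml"] <= 0).any() or f["strem2_ng_ml"].isna().any():
            raise ConfigurationError("sTREM2 concentrations must be positive")
        ctl = f[f["group"] == "Control"]
        if ctl[["onset_age_years", "duration_years", "percent_course"]].notna().any().any():
            raise ConfigurationError("controls must not carry onset/duration/staging")
        pc = f["percent_course"].dropna()
        if ((pc < 0) | (pc > 100)).any():
            raise ConfigurationError("percent_course must lie in [0, 100]")

    @property
    def cases(self) -> pd.DataFrame:
        return self.frame[self.frame["group"] == "ALS"]

    @property
    def controls(self) -> pd.DataFrame:
        return self.frame[self.frame["group"] == "Control"]

    @property
    def staged_cases(self) -> pd.DataFrame:
        return self.cases[self.cases["percent_course"].notna()]


def load_csf_table(path: str | Path) -> CsfTable:
    """Load a CSF table CSV with the fixture's schema."""
    frame = pd.read_csv(path, dtype={"sampling_age_printed": str})
    return CsfTable(frame)


def load_csf_fixture() -> CsfTable:
    """Load the packaged clinical table (46 ALS + 20 controls), checksum-verified."""
    ref = resources.files("neuromark").joinpath("data/csf_strem2_table.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256:
        raise FixtureError(f"fixture corruption: sha256 {digest} != {FIXTURE_SHA256}")
    import io

    table = load_csf_table(io.BytesIO(raw))
    if len(table.cases) != 46 or len(table.controls) != 20:
        raise FixtureError("fixture corruption: unexpected row counts")
    return table


@dataclass
class GroupComparison:
    mean_case: float
    mean_control: float
    mw: TestResult  # directional: ALS > control
    mw_two_sided: TestResult
    n_case: int
    n_control: int


def compare_groups(table: CsfTable) -> GroupComparison:
    """Group means and the rank-based case-vs-control comparison.

    The primary Mann-Whitney test is one-sided (ALS elevated over controls,
    the stated biomarker hypothesis); the two-sided value is carried
    alongside for reference.
    """
    a = table.cases["strem2_ng_ml"].to_numpy()
    b = table.controls["strem2_ng_ml"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    return GroupComparison(
        mean_case=float(a.mean()),
        mean_control=float(b.mean()),
        mw=core_stats.mann_whitney(a, b, alternative="greater"),
        mw_two_sided=core_stats.mann_whitney(a, b, alternative="two-sided"),
        n_case=len(a),
        n_control=len(b),
    )


@dataclass
class StageAssignment:
    """Subject -> stage in {early, middle, late, unstaged} (ALS rows only)."""

    stages: pd.Series  # index: subject_id
    centile: float

    def subjects(self, stage: str) -> list[str]:
        return list(self.stages.index[self.stages == stage])

    @property
    def n_staged(self) -> int:
        return int((self.stages != "unstaged").sum())


def assign_stage(table: CsfTable, centile: float = 0.25) -> StageAssignment:
    """Quartile staging of ALS subjects by percent of disease course at sampling.

    Staged subjects are ranked by percent_course ascending (ties by subject
    identifier); the lowest floor(centile * n_staged) are early disease, the
    highest floor(centile * n_staged) late, the remainder middle. Subjects
    without staging information are "unstaged". The floor convention with the
    default quartile gives 11 early and 11 late of the fixture's 45 staged
    subjects, which reproduces the published stage means.
    """
    if not (0 < centile < 0.5):
        raise ConfigurationError("centile must lie in (0, 0.5)")
    cases = table.cases
    staged = cases[cases["percent_course"].notna()].sort_values(
        ["percent_course", "subject_id"], kind="stable"
    )
    n = len(staged)
    stages = pd.Series("unstaged", index=cases["subject_id"], name="stage")
    if n:
        k = max(1, int(np.floor(centile * n)))
        ids = staged["subject_id"].to_numpy()
        stages.loc[ids] = "middle"
        stages.loc[ids[:k]] = "early"
        stages.loc[ids[n - k :]] = "late"
    return StageAssignment(stages, centile)


def stage_summary(table: CsfTable, stages: StageAssignment) -> pd.DataFrame:
    """Mean and standard error of sTREM2 within each stage (empty stages omitted)."""
    cases = table.cases.set_index("subject_id")
    rows = []
    for stage in STAGES:
        ids = stages.subjects(stage)
        if not ids:
            continue
        vals = cases.loc[ids, "strem2_ng_ml"].to_numpy()
        rows.append(
            {
                "stage": stage,
                "n": len(vals),
                "mean_strem2_ng_ml": float(vals.mean()),
                "sem_strem2_ng_ml": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def stage_stratified_association(
    table: CsfTable,
    stages: StageAssignment,
    alternative: str = "greater",
    min_subjects: int = 4,
) -> dict[str, TestResult | str]:
    """Per-stage Spearman association of sTREM2 with disease duration.

    Directional by default ("greater": positive association, the late-stage
    hypothesis); stages with fewer than ``min_subjects`` known-duration
    subjects yield an "insufficient data" record.
    """
    cases = table.cases.set_index("subject_id")
    out: dict[str, TestResult | str] = {}
    for stage in ("early", "middle", "late"):
        ids = stages.subjects(stage)
        sub = cases.loc[ids].dropna(subset=["duration_years"])
        if len(sub) < min_subjects:
            out[stage] = "insufficient data"
            continue
        out[stage] = core_stats.spearman(
            sub["strem2_ng_ml"].to_numpy(),
            sub["duration_years"].to_numpy(),
            alternative=alternative,
        )
    return out
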