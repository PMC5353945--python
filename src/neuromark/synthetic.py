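"""Synthetic-study generator with planted co-expression structure.

The generator emulates the two study designs the pipeline consumes:

* a CNS (laser-captured motor neuron) microarray over ~11 samples with a
  per-sample pathology count (p62-positive inclusions per unit area) coupled
  to one planted module, and disease durations coupled to the same module;
* a blood (lymphoblastoid) microarray over ~26 samples carrying rapid/slow
  progression labels (duration < 2 y / > 4 y) with planted group shifts.

Each planted module is one latent factor plus independent Gaussian noise;
the loading is chosen so that the expected within-module pairwise Pearson
correlation equals ``within_module_correlation``. The pathology-linked
module doubles as the "immune-like" module: its factor drives the pathology
counts (Poisson, log link), the CNS durations (inversely), the blood
rapid/slow shift, and most of the GWAS-like truth set, so that end-to-end
discovery has a module that can be triple-enriched. The progression-linked
module carries a blood group shift only, and the control-identity module is
coupled to nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gene_sets import GeneSet
from .study import ExpressionStudy

__all__ = ["SimConfig", "SyntheticStudy", "generate_study", "generate_edge_table", "generate_csf_table"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated designs: a microarray-scale transcriptome,
    11 CNS samples, 26 blood samples, one immune-like module of 65
    transcripts plus a second progression module and a cell-identity
    negative control.
    """

    n_transcripts: int = 54_675
    n_samples_cns: int = 11
    n_samples_blood: int = 26
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (65, 50, 45)
    pathology_linked_module: int = 0
    progression_linked_module: int = 1
    control_identity_module: int = 2
    within_module_correlation: float = 0.7
    pathology_effect: float = 1.0
    group_effect: float = 1.5
    noise_sd: float = 1.0
    duration_range_years: tuple[float, float] = (0.4, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ConfigurationError("configuration error: module_sizes length != n_modules")
        if sum(self.module_sizes) > self.n_transcripts:
            raise ConfigurationError("configuration error: modules larger than transcriptome")
        idx = (self.pathology_linked_module, self.progression_linked_module, self.control_identity_module)
        if len(set(idx)) != 3 or any(i >= self.n_modules or i < 0 for i in idx):
            raise ConfigurationError("configuration error: module indices must be distinct and < n_modules")
        if not (0 < self.within_module_correlation < 1):
            raise ConfigurationError("configuration error: within_module_correlation must be in (0,1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("configuration error: noise_sd must be positive")
        if self.duration_range_years[0] <= 0 or self.duration_range_years[1] <= self.duration_range_years[0]:
            raise ConfigurationError("configuration error: invalid duration range")


@dataclass
class SyntheticStudy:
    """A generated study pair (CNS + blood) with planted ground truth.

    ``truth`` keys: ``modules`` (module index -> transcript list),
    ``assignment`` (transcript -> module index), ``seed_transcripts``
    (the pathology-linked module's transcripts), ``gwas_like`` (GeneSet),
    ``immune_like_genes`` and ``control_identity_genes`` (gene-level sets).
    """

    config: SimConfig
    cns: ExpressionStudy
    blood: ExpressionStudy
    truth: dict

    def write(self, outdir: str | Path) -> None:
        from .study import write_expression_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression_tsv(self.cns.matrix, outdir / "cns_expression.tsv.gz")
        write_expression_tsv(self.blood.matrix, outdir / "blood_expression.tsv.gz")
        self.cns.samples.to_csv(outdir / "cns_clinical.csv")
        self.blood.samples.to_csv(outdir / "blood_clinical.csv")
        self.gene_map_frame().to_csv(outdir / "gene_map.csv", index=False)
        truth = {
            "modules": {str(k): v for k, v in self.truth["modules"].items()},
            "seed_transcripts": self.truth["seed_transcripts"],
            "gwas_like": sorted(self.truth["gwas_like"].members),
            "config": asdict(self.config),
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))

    def gene_map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"transcript_id": self.cns.gene_map.index, "gene_id": self.cns.gene_map.values}
        )


def _module_loading(cfg: SimConfig) -> float:
    # corr(a*f + sd*eps, a*f + sd*eps') = a^2 / (a^2 + sd^2) = r  =>  a = sd*sqrt(r/(1-r))
    r = cfg.within_module_correlation
    return cfg.noise_sd * np.sqrt(r / (1.0 - r))


def _make_ids(cfg: SimConfig) -> tuple[list[str], pd.Series]:
    ids = [f"T{i:06d}" for i in range(cfg.n_transcripts)]
    n_planted = sum(cfg.module_sizes)
    genes = []
    for i in range(cfg.n_transcripts):
        if i >= n_planted and i % 20 == 19:
            # every 20th background transcript shares its predecessor's gene:
            # keeps the transcript->gene map genuinely many-to-one
            genes.append(f"G{i - 1:06d}")
        else:
            genes.append(f"G{i:06d}")
    return ids, pd.Series(genes, index=ids, name="gene_id")


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a reproducible CNS + blood study pair from ``config``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ids, gene_map = _make_ids(cfg)
    a = _module_loading(cfg)

    bounds = np.cumsum((0,) + tuple(cfg.module_sizes))
    modules = {m: ids[bounds[m] : bounds[m + 1]] for m in range(cfg.n_modules)}
    assignment = {t: m for m, ts in modules.items() for t in ts}
    baseline = rng.normal(8.0, 1.0, size=cfg.n_transcripts)  # log-intensity level

    def expression(
        n_samples: int,
        factors: np.ndarray,
        raw_shifts: dict[int, np.ndarray] | None = None,
    ) -> np.ndarray:
        # factor-driven modules get a * f; group-shifted modules in blood get
        # the additive per-gene shift directly (their co-expression then
        # reflects the group structure, and genes stay conditionally
        # independent given the group so multi-gene panels gain power)
        X = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_transcripts, n_samples))
        raw_shifts = raw_shifts or {}
        for m in range(cfg.n_modules):
            rows = slice(bounds[m], bounds[m + 1])
            if m in raw_shifts:
                X[rows] += raw_shifts[m]
            else:
                X[rows] += a * factors[m]
        return X + baseline[:, None]

    def _orthogonal_factors(n_samples: int) -> np.ndarray:
        # exactly uncorrelated in-sample unit-variance factors: distinct
        # planted processes stay distinct even at microarray sample sizes
        F = rng.normal(size=(n_samples, cfg.n_modules))
        F = F - F.mean(axis=0, keepdims=True)
        Q, _ = np.linalg.qr(F)
        return (Q * np.sqrt(n_samples - 1)).T

    # ---- CNS arm -------------------------------------------------------
    f_cns = _orthogonal_factors(cfg.n_samples_cns)
    cns_X = expression(cfg.n_samples_cns, f_cns, {})
    fp = f_cns[cfg.pathology_linked_module]
    lam = np.exp(np.log(20.0) + cfg.pathology_effect * fp)
    pathology = rng.poisson(lam)
    # durations: inversely coupled to the immune-like factor, mapped onto the
    # configured range through ranks so the coupling is purely monotone; the
    # noise is residualised against every factor so no other planted module
    # acquires a chance duration association in-sample
    eps = rng.normal(size=cfg.n_samples_cns)
    eps = eps - f_cns.T @ np.linalg.lstsq(f_cns.T, eps, rcond=None)[0]
    z = -cfg.pathology_effect * fp + eps
    q = (np.argsort(np.argsort(z)) + 1) / (cfg.n_samples_cns + 1)
    lo, hi = cfg.duration_range_years
    cns_dur = lo + q * (hi - lo)
    cns_samples = pd.DataFrame(
        {"pathology_count": pathology, "duration_years": cns_dur},
        index=[f"CNS{j:02d}" for j in range(cfg.n_samples_cns)],
    )
    cns = ExpressionStudy(
        pd.DataFrame(cns_X, index=ids, columns=cns_samples.index), gene_map, cns_samples
    )

    # ---- blood arm -----------------------------------------------------
    nb = cfg.n_samples_blood
    n_rapid = max(2, int(round(0.4 * nb)))
    n_slow = max(2, int(round(0.4 * nb)))
    n_mid = nb - n_rapid - n_slow
    labels = np.array(["rapid"] * n_rapid + ["slow"] * n_slow + ["intermediate"] * n_mid)
    rng.shuffle(labels)
    lo, hi = cfg.duration_range_years
    dur = np.where(
        labels == "rapid",
        rng.uniform(max(lo, 0.3), 1.9, size=nb),
        np.where(labels == "slow", rng.uniform(4.1, max(hi, 4.6), size=nb), rng.uniform(2.1, 3.9, size=nb)),
    )
    shift = np.where(labels == "rapid", cfg.group_effect / 2.0, np.where(labels == "slow", -cfg.group_effect / 2.0, 0.0))
    f_blood = _orthogonal_factors(nb)
    # factors orthogonal to the group contrast: only planted shifts separate
    # rapid from slow
    contrast = np.where(labels == "rapid", 1.0, np.where(labels == "slow", -1.0, 0.0))
    if np.ptp(contrast) > 0:
        c = contrast - contrast.mean()
        c /= np.linalg.norm(c)
        f_blood = f_blood - np.outer(f_blood @ c, c)
    linked = (cfg.pathology_linked_module, cfg.progression_linked_module)
    blood_X = expression(nb, f_blood, {m: shift for m in linked})
    blood_samples = pd.DataFrame(
        {
            "duration_years": dur,
            "onset_age": np.clip(rng.normal(58.0, 10.0, size=nb), 25, 85),
            "sex": rng.choice(["M", "F"], size=nb),
            "progression_label": labels,
        },
        index=[f"LB{j:02d}" for j in range(nb)],
    )
    blood = ExpressionStudy(
        pd.DataFrame(blood_X, index=ids, columns=blood_samples.index), gene_map, blood_samples
    )

    # ---- truth ---------------------------------------------------------
    immune_genes = sorted(gene_map.loc[modules[cfg.pathology_linked_module]])
    control_genes = sorted(gene_map.loc[modules[cfg.control_identity_module]])
    n_half = max(1, len(immune_genes) // 2)
    background_genes = sorted(set(gene_map.iloc[bounds[-1] :]) - set(immune_genes))
    gwas_members = set(rng.choice(immune_genes, size=n_half, replace=False)) | set(
        rng.choice(background_genes, size=n_half, replace=False)
    )
    truth = {
        "modules": modules,
        "assignment": assignment,
        "seed_transcripts": modules[cfg.pathology_linked_module],
        "gwas_like": GeneSet("gwas_like", frozenset(gwas_members), description="planted GWAS-like set"),
        "immune_like_genes": frozenset(immune_genes),
        "control_identity_genes": frozenset(control_genes),
        # generating signals: the group-shift pattern for linked modules in
        # blood, the latent factor otherwise
        "cns_module_factors": f_cns,
        "blood_module_factors": np.vstack(
            [shift if m in linked else f_blood[m] for m in range(cfg.n_modules)]
        ),
    }
    return SyntheticStudy(cfg, cns, blood, truth)


def generate_edge_table(
    study: SyntheticStudy,
    n_partners: int,
    noise_edges: int,
    module_index: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit a weighted interaction edge table with planted partner genes.

    Each of ``n_partners`` out-of-module genes receives 2-4 edges into the
    target module (the immune-like module by default), labelled
    ``coexpression`` or ``ppi`` with weights in (0, 1]; ``noise_edges``
    additional random edges are appended. Planted partner genes are recorded
    in ``study.truth['partners']``.
    """
    if n_partners < 0 or noise_edges < 0:
        raise ConfigurationError("configuration error: counts must be non-negative")
    cfg = study.config
    m = cfg.pathology_linked_module if module_index is None else module_index
    rng = np.random.default_rng(cfg.seed + 101 if seed is None else seed)
    gene_map = study.cns.gene_map
    module_genes = sorted(set(gene_map.loc[study.truth["modules"][m]]))
    all_genes = sorted(set(gene_map))
    outside = [g for g in all_genes if g not in set(module_genes)]
    partners = sorted(rng.choice(outside, size=n_partners, replace=False)) if n_partners else []
    rows = []
    for g in partners:
        k = int(rng.integers(2, 5))
        targets = rng.choice(module_genes, size=min(k, len(module_genes)), replace=False)
        for t in targets:
            rows.append((g, t, rng.choice(["coexpression", "ppi"]), float(rng.uniform(0.3, 1.0))))
    for _ in range(noise_edges):
        ga, gb = rng.choice(all_genes, size=2, replace=False)
        rows.append((ga, gb, rng.choice(["coexpression", "ppi"]), float(rng.uniform(0.05, 1.0))))
    study.truth["partners"] = list(partners)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "edge_type", "weight"])


def generate_csf_table(
    n_cases: int = 46,
    n_controls: int = 20,
    effect_profile: str = "paper_like",
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a CSF biomarker table with the fixture's schema.

    ``paper_like`` draws control concentrations from a right-skewed
    (lognormal) distribution around ~7 ng/ml and case concentrations from a
    higher baseline with (i) an early-stage elevation — concentration
    decreasing in percent-of-course over the first quartile — and (ii) a
    positive duration association in the last quartile. ``null`` draws both
    groups from the control distribution.
    """
    if n_cases < 2 or n_controls < 2:
        raise ConfigurationError("configuration error: need >= 2 cases and controls")
    if effect_profile not in ("null", "paper_like"):
        raise ConfigurationError(f"configuration error: unknown profile {effect_profile!r}")
    rng = np.random.default_rng(seed)
    pc = rng.uniform(2.0, 100.0, size=n_cases)
    duration = np.clip(rng.lognormal(np.log(3.5), 0.6, size=n_cases), 0.4, 18.0)
    onset = np.clip(rng.normal(58.0, 11.0, size=n_cases), 28.0, 82.0)

    control_conc = rng.lognormal(np.log(6.0), 0.45, size=n_controls)
    if effect_profile == "null":
        case_conc = rng.lognormal(np.log(6.0), 0.45, size=n_cases)
    else:
        base = rng.lognormal(np.log(9.0), 0.55, size=n_cases)
        early_boost = 1.0 + 5.0 * np.clip(25.0 - pc, 0.0, None) / 25.0
        late = pc > 75.0
        late_assoc = np.where(late, (duration / 3.5) ** 0.9, 1.0)
        case_conc = base * early_boost * late_assoc

    rows = []
    for i in range(n_cases):
        rows.append(
            {
                "subject_id": f"SIMALS{i:02d}",
                "group": "ALS",
                "sex": rng.choice(["M", "F"]),
                "onset_age_years": round(float(onset[i]), 1),
                "duration_years": round(float(duration[i]), 1),
                "sampling_age_printed": round(float(onset[i] + duration[i] * pc[i] / 100.0), 1),
                "percent_course": round(float(pc[i]), 1),
                "strem2_ng_ml": round(float(case_conc[i]), 1),
            }
        )
    for i in range(n_controls):
        rows.append(
            {
                "subject_id": f"SIMCTL{i:02d}",
                "group": "Control",
                "sex": rng.choice(["M", "F"]),
                "onset_age_years": np.nan,
                "duration_years": np.nan,
                "sampling_age_printed": np.nan,
                "percent_course": np.nan,
                "strem2_ng_ml": round(float(control_conc[i]), 1),
            }
        )
    return pd.DataFrame(rows)
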