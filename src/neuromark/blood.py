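"""Blood-derived prognostic evaluation of a gene module.

Two complementary assessments mirror how a candidate module is vetted in
lymphoblastoid expression data:

* survival: a Cox proportional-hazards fit of onset-to-death duration on the
  module's leading expression principal components, adjusted for onset age
  and sex, with a likelihood-ratio test of the PC block against the
  covariates-only null (Efron handling of the ties produced by half-year
  rounding of durations);
* classification: per-gene binomial logistic screens of rapid vs slow
  progressors, and leave-one-out cross-validation of a small gene panel with
  an exact binomial test against coin-flip chance.

Logistic fits fall back to a small-ridge penalised fit when the groups are
perfectly separated, so screening never aborts at microarray sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import core_stats
from .errors import ConfigurationError, InsufficientDataError
from .gene_sets import GeneSet
from .study import ExpressionStudy

__all__ = [
    "SurvivalDesign",
    "CoxFit",
    "PanelFit",
    "module_pc_features",
    "make_survival_design",
    "fit_ph_model",
    "per_gene_logistic_screen",
    "loocv_panel_accuracy",
]


def module_pc_features(study: ExpressionStudy, module: GeneSet, k: int = 15) -> pd.DataFrame:
    """Sample scores on the top ``k`` principal components of module expression.

    The module-restricted matrix is collapsed to genes (mean over a gene's
    transcripts), standardised per gene, and decomposed; ``k`` is truncated
    to n_samples - 1 with a warning when necessary.
    """
    in_module = study.gene_map[study.gene_map.isin(module.members)]
    if in_module.empty:
        raise ConfigurationError(f"no genes of {module.name!r} are measured in the study")
    expr = study.matrix.loc[in_module.index]
    by_gene = expr.groupby(in_module).mean()  # genes x samples
    X = by_gene.to_numpy().T  # samples x genes
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    k_max = X.shape[0] - 1
    if k > k_max:
        warnings.warn(f"k={k} exceeds n_samples-1={k_max}; truncating", RuntimeWarning, stacklevel=2)
        k = k_max
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # rank deficiency handled upstream
        scores, _ = core_stats.principal_components(X, k)
    cols = [f"PC{j + 1}" for j in range(scores.shape[1])]
    return pd.DataFrame(scores, index=study.matrix.columns, columns=cols)


@dataclass
class SurvivalDesign:
    """Durations (the outcome), event flags and the feature/covariate blocks."""

    duration_years: pd.Series  # event time, rounded to nearest half-year
    event_observed: pd.Series
    features: pd.DataFrame  # the block under test (module PCs)
    covariates: pd.DataFrame | None = None  # onset age, sex

    def __post_init__(self) -> None:
        if (self.duration_years <= 0).any():
            raise ConfigurationError("durations must be positive")
        for block in (self.features, self.covariates):
            if block is not None and block.isna().any().any():
                raise ConfigurationError("feature columns must be complete")


def make_survival_design(
    study: ExpressionStudy,
    module: GeneSet,
    n_pcs: int = 15,
    event_column: str | None = None,
) -> SurvivalDesign:
    """Survival design with half-year-rounded durations and module PC features.

    All events are treated as observed (onset-to-death durations) unless an
    ``event_column`` of the sample table supplies censoring flags.
    """
    samples = study.samples
    for col in ("duration_years", "onset_age", "sex"):
        if col not in samples.columns:
            raise ConfigurationError(f"study lacks {col} annotation")
    duration = (samples["duration_years"] * 2).round() / 2
    duration = duration.clip(lower=0.5)
    events = (
        samples[event_column].astype(bool)
        if event_column
        else pd.Series(True, index=samples.index)
    )
    covariates = pd.DataFrame(
        {
            "onset_age": samples["onset_age"].astype(float),
            "sex_male": (samples["sex"] == "M").astype(float),
        }
    )
    features = module_pc_features(study, module, k=n_pcs)
    return SurvivalDesign(duration, events, features.loc[samples.index], covariates)


@dataclass
class CoxFit:
    coefficients: pd.Series
    lr_chi2: float
    lr_df: int
    p_value: float
    n: int
    ridge_used: bool = False
    dropped_features: tuple[str, ...] = field(default=())


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str, penalizer: float):
    from lifelines import CoxPHFitter

    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def fit_ph_model(design: SurvivalDesign) -> CoxFit:
    """Cox proportional-hazards fit with a likelihood-ratio test of the feature block.

    The global significance is 2*(ll_full - ll_null) ~ chi^2 with df equal to
    the number of (non-constant) features, where the null model carries only
    the covariates. Ties in event times use Efron's handling. Non-convergent
    or collinear fits are retried with a small ridge penalty and flagged.
    """
    if design.duration_years.nunique() < 2:
        raise InsufficientDataError("need >= 2 distinct event times")
    feats = design.features.copy()
    dropped = tuple(c for c in feats.columns if feats[c].nunique() <= 1 or feats[c].std() == 0)
    feats = feats.drop(columns=list(dropped))
    cov = design.covariates if design.covariates is not None else pd.DataFrame(index=feats.index)
    cov = cov.loc[:, [c for c in cov.columns if cov[c].nunique() > 1]]

    base = pd.DataFrame(
        {"T": design.duration_years.to_numpy(), "E": design.event_observed.astype(int).to_numpy()},
        index=design.duration_years.index,
    )
    if feats.shape[1] == 0:
        return CoxFit(pd.Series(dtype=float), 0.0, 0, 1.0, len(base), False, dropped)

    full_df = pd.concat([base, cov, feats], axis=1)
    null_df = pd.concat([base, cov], axis=1)
    ridge_used = False
    try:
        full = _fit_cox(full_df, "T", "E", penalizer=0.0)
        null = (
            _fit_cox(null_df, "T", "E", penalizer=0.0) if cov.shape[1] else None
        )
    except Exception:
        ridge_used = True
        full = _fit_cox(full_df, "T", "E", penalizer=0.1)
        null = _fit_cox(null_df, "T", "E", penalizer=0.1) if cov.shape[1] else None
    ll_full = full.log_likelihood_
    if null is not None:
        ll_null = null.log_likelihood_
    else:
        # no covariates: the null is the empty Cox model
        ll_null = _null_partial_loglik(null_df["T"].to_numpy(), null_df["E"].to_numpy())
    lr = max(0.0, 2.0 * (ll_full - ll_null))
    df_lr = feats.shape[1]
    p = float(stats.chi2.sf(lr, df_lr)) if df_lr else 1.0
    return CoxFit(full.params_, float(lr), df_lr, p, len(base), ridge_used, dropped)


def _null_partial_loglik(t: np.ndarray, e: np.ndarray) -> float:
    """Efron partial log-likelihood of the covariate-free Cox model.

    With no covariates all relative hazards are 1, so each of the d tied
    events at a time with n at risk contributes -log(n - j) for j = 0..d-1.
    """
    ll = 0.0
    for ut in np.unique(t[e == 1]):
        d = int(((t == ut) & (e == 1)).sum())
        n_risk = int((t >= ut).sum())
        for j in range(d):
            ll -= np.log(n_risk - j)
    return ll


# ---------------------------------------------------------------------------
# logistic fits


def _neg_loglik_logistic(beta: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float):
    eta = X @ beta
    # log(1 + exp(eta)) computed stably
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    pen = 0.5 * ridge * float(beta[1:] @ beta[1:])  # intercept unpenalised
    from scipy.special import expit

    mu = expit(eta)
    grad = X.T @ (y - mu)
    grad[1:] -= ridge * beta[1:]
    return -ll + pen, -grad


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> tuple[np.ndarray, float]:
    """Maximum (optionally ridge-penalised) likelihood logistic fit.

    Returns (beta, unpenalised log-likelihood at beta). ``X`` must include an
    intercept column first.
    """
    beta0 = np.zeros(X.shape[1])
    res = optimize.minimize(
        _neg_loglik_logistic, beta0, args=(X, y, ridge), jac=True, method="L-BFGS-B",
        options={"maxiter": 500},
    )
    beta = res.x
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return beta, ll


def _logistic_lrt(x: np.ndarray, y: np.ndarray, ridge_on_separation: float = 1.0):
    """LR test of a one-feature logistic model against intercept-only.

    Returns (p, beta1, separated). On (quasi-)separation both models are
    refitted with a small ridge and flagged.
    """
    X = np.column_stack([np.ones_like(x), x])
    beta, ll1 = _fit_logistic(X, y)
    # (quasi-)separation: the likelihood approaches its supremum of 0 as the
    # coefficient diverges, or the optimiser has already run far out
    separated = bool(ll1 > -1e-3 or np.abs(beta[1]) > 30)
    if separated:
        beta, ll1 = _fit_logistic(X, y, ridge=ridge_on_separation)
        _, ll0 = _fit_logistic(np.ones((len(y), 1)), y, ridge=ridge_on_separation)
    else:
        _, ll0 = _fit_logistic(np.ones((len(y), 1)), y)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, 1))
    return p, float(beta[1]), separated


def _rapid_slow_labels(study: ExpressionStudy) -> pd.Series:
    from .screen import classify_progression

    if "progression_label" in study.samples.columns:
        labels = study.samples["progression_label"]
    else:
        labels = study.samples["duration_years"].map(classify_progression)
    labels = labels[labels.isin(["rapid", "slow"])]
    if (labels == "rapid").sum() < 2 or (labels == "slow").sum() < 2:
        raise ConfigurationError("need >= 2 rapid and >= 2 slow samples")
    return labels


def per_gene_logistic_screen(
    study: ExpressionStudy, module: GeneSet, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene logistic screens of rapid vs slow within a module.

    Each measured module gene is tested by likelihood ratio against the
    intercept-only null; rows carry the p-value, coefficient sign, separation
    flag and whether the gene passes ``alpha``. Constant genes are skipped.
    """
    labels = _rapid_slow_labels(study)
    y = (labels == "rapid").to_numpy(dtype=float)
    in_module = study.gene_map[study.gene_map.isin(module.members)]
    if in_module.empty:
        raise ConfigurationError(f"no genes of {module.name!r} are measured")
    expr = study.matrix.loc[in_module.index, labels.index]
    by_gene = expr.groupby(in_module).mean()
    rows = []
    for gene, profile in by_gene.iterrows():
        x = profile.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        x = (x - x.mean()) / x.std()
        p, beta1, separated = _logistic_lrt(x, y)
        rows.append(
            {"gene": gene, "p_value": p, "coefficient": beta1, "separated": separated,
             "significant": p < alpha}
        )
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)


@dataclass
class PanelFit:
    """Leave-one-out cross-validated classification of a gene panel."""

    gene_list: tuple[str, ...]
    predictions: pd.DataFrame  # sample, true_label, predicted_label, prob_rapid, degenerate_fold
    accuracy: float
    chance_p: float
    majority_baseline: float


def loocv_panel_accuracy(
    study: ExpressionStudy, panel: list[str], ridge: float = 1e-2
) -> PanelFit:
    """Leave-one-out CV of a logistic panel classifier at threshold 0.5.

    A small ridge stabilises each training fit (the panels are few-gene and
    near-separable at these sample sizes). ``chance_p`` is the exact binomial
    tail P(X >= correct | n, 0.5). Folds whose training set loses a class
    predict the majority class and are flagged.
    """
    labels = _rapid_slow_labels(study)
    in_panel = study.gene_map[study.gene_map.isin(panel)]
    missing = set(panel) - set(in_panel)
    if missing:
        raise ConfigurationError(f"panel genes not measured: {sorted(missing)}")
    expr = study.matrix.loc[in_panel.index, labels.index]
    by_gene = expr.groupby(in_panel).mean().loc[sorted(set(panel))]
    X_all = by_gene.to_numpy().T  # samples x genes
    y_all = (labels == "rapid").to_numpy(dtype=float)
    n = len(y_all)
    rows = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        ytr = y_all[train]
        degenerate = len(np.unique(ytr)) < 2
        if degenerate:
            prob = float(ytr.mean())
        else:
            from scipy.special import expit

            Xtr = X_all[train]
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            xte = (X_all[i] - mu) / sd
            beta, _ = _fit_logistic(np.column_stack([np.ones(train.sum()), Xtr]), ytr, ridge=ridge)
            prob = float(expit(beta[0] + xte @ beta[1:]))
        pred = "rapid" if prob > 0.5 else "slow"
        rows.append(
            {
                "sample": labels.index[i],
                "true_label": labels.iloc[i],
                "predicted_label": pred,
                "prob_rapid": prob,
                "degenerate_fold": degenerate,
            }
        )
    preds = pd.DataFrame(rows)
    correct = int((preds["true_label"] == preds["predicted_label"]).sum())
    accuracy = correct / n
    chance_p = float(stats.binom.sf(correct - 1, n, 0.5))
    majority = float(max((labels == "rapid").mean(), (labels == "slow").mean()))
    return PanelFit(tuple(sorted(set(panel))), preds, accuracy, chance_p, majority)
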