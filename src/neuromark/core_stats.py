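"""Rank-based and exact statistical kernels used by every pipeline stage.

All tests are reported as :class:`TestResult` records carrying the method
actually used (``exact`` enumeration or ``normal_approx`` asymptotics) so that
downstream reports retain provenance. Missing values are pairwise-deleted and
the effective sample size is reported as ``n_eff``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Literal

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError

Alternative = Literal["two-sided", "greater", "less"]

__all__ = [
    "ContingencyTable",
    "TestResult",
    "spearman",
    "spearman_screen",
    "mann_whitney",
    "mann_whitney_screen",
    "fisher_enrichment",
    "bh_adjust",
    "principal_components",
]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table for a module-versus-gene-set enrichment test.

    ``overlap`` genes are in both the module and the assessment set,
    ``set_only`` / ``module_only`` in exactly one, ``neither`` in the
    universe but in none; the four counts partition the gene universe.
    """

    overlap: int
    set_only: int
    module_only: int
    neither: int

    def __post_init__(self) -> None:
        for name in ("overlap", "set_only", "module_only", "neither"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.overlap + self.set_only + self.module_only + self.neither

    @property
    def set_size(self) -> int:
        return self.overlap + self.set_only

    @property
    def module_size(self) -> int:
        return self.overlap + self.module_only

    @classmethod
    def from_sets(cls, module, assessment, universe) -> "ContingencyTable":
        """Build the table after intersecting both sets with the universe."""
        universe = set(universe)
        m = set(module) & universe
        s = set(assessment) & universe
        ov = len(m & s)
        return cls(
            overlap=ov,
            set_only=len(s) - ov,
            module_only=len(m) - ov,
            neither=len(universe) - len(m | s),
        )


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test with method provenance."""

    statistic: float
    p_value: float
    method: Literal["exact", "normal_approx"]
    n_eff: int
    alternative: Alternative = "two-sided"
    notes: tuple[str, ...] = field(default=())


def _clip_p(p: float) -> float:
    """Keep p in the (0, 1] contract."""
    return float(min(max(p, _TINY), 1.0))


def _drop_missing_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def _t_sf_from_rho(rho: float, n: int, alternative: Alternative) -> float:
    """Two- or one-sided p for a correlation via the t approximation."""
    denom = 1.0 - rho * rho
    if denom <= 0:
        p_greater = 0.0 if rho > 0 else 1.0
    else:
        t = rho * math.sqrt((n - 2) / denom)
        p_greater = stats.t.sf(t, df=n - 2)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return 1.0 - p_greater
    return 2.0 * min(p_greater, 1.0 - p_greater)


def spearman(x, y, alternative: Alternative = "two-sided") -> TestResult:
    """Spearman rank correlation with tie-corrected rho.

    rho is the Pearson correlation of midranks. The p-value uses the
    t approximation for n >= 10; for n < 10 the null distribution is
    enumerated exactly over all n! orderings of the midranks. Pairs with
    missing entries are dropped before ranking.
    """
    x, y = _drop_missing_pairs(x, y)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"insufficient data: {n} usable pairs (need >= 3)")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise DegenerateInputError("degenerate input: zero variance in ranked vector")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))

    notes: list[str] = []
    if n < 10:
        # exact enumeration of the permutation null of rho (midranks make
        # this valid under ties: the null conditions on the tie pattern)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        obs = float(rx_c @ ry_c) / denom
        perms = np.array(list(permutations(ry_c)))
        null = perms @ rx_c / denom
        eps = 1e-12
        if alternative == "greater":
            p = np.mean(null >= obs - eps)
        elif alternative == "less":
            p = np.mean(null <= obs + eps)
        else:
            p = np.mean(np.abs(null) >= abs(obs) - eps)
        method = "exact"
    else:
        p = _t_sf_from_rho(rho, n, alternative)
        method = "normal_approx"
    return TestResult(rho, _clip_p(p), method, n, alternative, tuple(notes))


def spearman_screen(matrix, y) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-row Spearman against one covariate (t approximation).

    Returns (rho, p) arrays, one entry per row of ``matrix``; rows with zero
    rank variance get NaN. Agrees with :func:`spearman` whenever that function
    takes its asymptotic path (the screens run on >= 10 samples). Rows are
    ranked jointly with no missing-value handling: the transcriptome screens
    operate on complete matrices.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[1]
    if n != len(y):
        raise ValueError("matrix columns and covariate length differ")
    if n < 3:
        raise InsufficientDataError("insufficient data: need >= 3 samples")
    ry = stats.rankdata(y)
    if np.ptp(ry) == 0:
        raise DegenerateInputError("degenerate covariate: constant ranks")
    RX = stats.rankdata(X, axis=1)
    RXc = RX - RX.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    sx = np.sqrt((RXc**2).sum(axis=1))
    sy = math.sqrt(float(ryc @ ryc))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (RXc @ ryc) / (sx * sy)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), _TINY, p)
    p[~np.isfinite(rho)] = np.nan
    rho = np.where(np.isfinite(rho), rho, np.nan)
    return rho, np.where(np.isfinite(p), np.clip(p, _TINY, 1.0), np.nan)


def mann_whitney(a, b, alternative: Alternative = "two-sided") -> TestResult:
    """Mann-Whitney U test (U of the first sample).

    Exact enumeration over all C(n_a + n_b, n_a) group labelings when the
    combined sample is <= 20 without ties; otherwise the normal approximation
    with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("insufficient data: each group needs >= 2 observations")
    n = len(a) + len(b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < n
    method = "exact" if (n <= 20 and not has_ties) else "normal_approx"
    res = stats.mannwhitneyu(
        a,
        b,
        alternative=alternative,
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return TestResult(float(res.statistic), _clip_p(float(res.pvalue)), method, n, alternative)


def mann_whitney_screen(matrix, group_a_mask) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-row Mann-Whitney U (normal approximation, tie and
    continuity corrected) between columns in ``group_a_mask`` and the rest.

    Matches :func:`mann_whitney` on its asymptotic path; the lymphoblastoid
    screens involve > 20 samples so the exact path never applies there.
    """
    X = np.asarray(matrix, dtype=float)
    mask = np.asarray(group_a_mask, dtype=bool)
    n1 = int(mask.sum())
    n2 = int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("insufficient data: each group needs >= 2 observations")
    n = n1 + n2
    R = stats.rankdata(X, axis=1)
    r1 = R[:, mask].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per row
    tie_term = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(X[i], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)
    sd = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0))))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(sd > 0, np.clip(p, _TINY, 1.0), np.nan)
    return u1, p


def fisher_enrichment(table: ContingencyTable) -> TestResult:
    """One-sided (over-enrichment) Fisher/hypergeometric test.

    p = P(X >= overlap) for X hypergeometric with the table's margins.
    The statistic reported is the observed overlap count.
    """
    N = table.universe_size
    K = table.set_size
    m = table.module_size
    if K > N or m > N:
        raise ValueError("inconsistent universe: set larger than universe")
    p = float(stats.hypergeom.sf(table.overlap - 1, N, K, m))
    return TestResult(float(table.overlap), _clip_p(p), "exact", N, "greater")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def principal_components(m, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of a samples x features matrix.

    Columns (features) are centred internally. Returns sample scores on the
    ``k`` leading components and the fraction of total variance each retained
    component explains. Sign convention: the largest-magnitude loading of each
    component is made positive. If ``k`` exceeds the matrix rank the available
    components are returned with a warning.
    """
    M = np.asarray(m, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-d samples x features matrix")
    n_samples, n_features = M.shape
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return np.empty((n_samples, 0)), np.array([], dtype=float)
    Xc = M - M.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(n_samples, n_features) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int(np.sum(S > tol))
    if k > rank:
        warnings.warn(
            f"rank deficient: requested {k} components, rank is {rank}; returning {rank}",
            RuntimeWarning,
            stacklevel=2,
        )
        k = rank
    total_var = float(np.sum(S**2))
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k]
    # sign convention: largest-|loading| entry positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i_max] < 0:
            scores[:, j] = -scores[:, j]
            loadings[j] = -loadings[j]
    var_frac = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return scores, var_frac
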