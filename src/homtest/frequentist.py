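"""Frequentist homogeneity tests for a 2x3 case-control genotype table.

Three chi-square statistics are provided:

``genotypic_chisq``
    The ordinary 2-df homogeneity test of the genotype table (null:
    gamma = pi, expected counts from the pooled MLE).

``usual_allelic_chisq``
    The traditional 1-df test applied to the derived 2x2 allele table,
    which treats the 2n + 2m alleles as independent observations.  It is
    implemented deliberately as the biased comparator: its null
    distribution is chi-square only when *both* groups are in
    Hardy-Weinberg equilibrium, so every result carries a warning.

``corrected_allelic_chisq``
    A 1-df test of equal allele frequencies that stays in the genotype
    sample space and is therefore valid without HWE.  The null
    {gamma_AA + gamma_AB/2 = pi_AA + pi_AB/2} is three-dimensional; the
    statistic compares observed genotype counts with expected counts at
    the constrained MLE.  p-values come from the chi2(1) approximation or
    from a parametric bootstrap at the constrained MLE ("exact" test),
    with the constrained MLE re-fit on every bootstrap replicate.

The constrained MLE is computed by profiling: for a fixed common
allele-A frequency ``lam`` the within-group maximiser over gamma_AB (and
pi_AB) solves a quadratic in closed form, so only a one-dimensional
search over ``lam`` remains.  The search (coarse grid + golden section)
is vectorised across bootstrap replicates, which is what makes the
100,000-replicate exact test run in seconds.

Also here: per-group Hardy-Weinberg goodness-of-fit chi-square, the
Cochran-Armitage trend test (the corrected test's asymptotic twin), and
the generic Monte-Carlo exact p-value engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .tables import (
    GenotypeTable,
    Hypothesis,
    HypothesisSpec,
    ParamPoint,
    allele_table_from_genotypes,
)

__all__ = [
    "FittedNull",
    "TestResult",
    "fit_pooled_genotypic",
    "fit_constrained_allelic",
    "fit_allelic_batch",
    "genotypic_chisq",
    "usual_allelic_chisq",
    "corrected_allelic_chisq",
    "armitage_trend",
    "hwe_chisq",
    "asymptotic_pvalue",
    "mc_exact_pvalue",
    "chisq_statistic",
]

HWE_WARNING = (
    "the doubled-sample allelic test is valid if and only if both groups are "
    "in Hardy-Weinberg equilibrium; prefer the corrected allelic test"
)


@dataclass(frozen=True)
class FittedNull:
    """A null-hypothesis fit: constrained parameter estimates plus the
    expected counts they imply for the observed sample sizes."""

    hypothesis: HypothesisSpec
    estimate: ParamPoint
    expected_case: np.ndarray
    expected_control: np.ndarray
    log_likelihood: float
    converged: bool = True
    boundary: bool = False


@dataclass(frozen=True)
class TestResult:
    """Outcome of one test: statistic, degrees of freedom and p-value.

    ``method`` is ``"asymptotic"`` (chi-square tail) or ``"monte_carlo"``
    (parametric bootstrap); Monte-Carlo results also carry the replicate
    count, the 95% normal-approximation CI of the p-value and the seed.
    """

    statistic: float
    df: int
    p_value: float
    method: str
    n_reps: Optional[int] = None
    mc_ci: Optional[Tuple[float, float]] = None
    seed: Optional[int] = None
    warning: Optional[str] = None
    flags: tuple = ()

    def to_dict(self) -> dict:
        d = {
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "method": self.method,
        }
        if self.method == "monte_carlo":
            d["n_reps"] = self.n_reps
            d["mc_ci"] = list(self.mc_ci) if self.mc_ci is not None else None
            d["seed"] = self.seed
        if self.warning:
            d["warning"] = self.warning
        if self.flags:
            d["flags"] = list(self.flags)
        return d


# ---------------------------------------------------------------------------
# chi-square machinery


def chisq_statistic(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Sum of (O - E)^2 / E over the trailing axis.

    Cells with E = 0 contribute 0 when O = 0 and +inf when O > 0 (the
    standard convention for boundary fits).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (observed - expected) ** 2 / expected
    terms = np.where((expected == 0) & (observed == 0), 0.0, terms)
    terms = np.where((expected == 0) & (observed > 0), np.inf, terms)
    return terms.sum(axis=-1)


def asymptotic_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if statistic < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {statistic}")
    return float(stats.chi2.sf(statistic, df))


def _mc_ci(phat: float, n_reps: int) -> Tuple[float, float]:
    """95% normal-approximation binomial CI, clipped to [0, 1]."""
    se = np.sqrt(phat * (1.0 - phat) / n_reps)
    return (float(max(0.0, phat - 1.96 * se)), float(min(1.0, phat + 1.96 * se)))


def mc_exact_pvalue(
    observed_stat: float,
    statistic_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    gamma: np.ndarray,
    pi: np.ndarray,
    n: int,
    m: int,
    n_reps: int = 10_000,
    seed: Optional[int] = None,
    chunk: int = 16_384,
) -> Tuple[float, Tuple[float, float]]:
    """Parametric-bootstrap p-value for an arbitrary table statistic.

    Replicate tables are drawn as Multinomial(n, gamma) x Multinomial(m, pi)
    at the supplied null fit; ``statistic_fn`` must map count arrays of
    shape (R, 3) to a vector of R statistics.  Ties count as exceedances
    (replicates with statistic >= observed), which is conservative.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a meaningful Monte-Carlo p-value")
    rng = np.random.default_rng(seed)
    gamma = np.asarray(gamma, dtype=float)
    pi = np.asarray(pi, dtype=float)
    exceed = 0
    done = 0
    # tiny slack so that exact ties survive floating-point noise
    thresh = observed_stat - 1e-9
    while done < n_reps:
        r = min(chunk, n_reps - done)
        x = rng.multinomial(n, gamma, size=r)
        y = rng.multinomial(m, pi, size=r)
        stat = np.asarray(statistic_fn(x, y))
        exceed += int(np.count_nonzero(stat >= thresh))
        done += r
    phat = exceed / n_reps
    return phat, _mc_ci(phat, n_reps)


# ---------------------------------------------------------------------------
# pooled (genotypic-homogeneity) fit and test


def fit_pooled_genotypic(t: GenotypeTable) -> FittedNull:
    """MLE under gamma = pi: the pooled relative frequencies."""
    x, y = t.case, t.control
    theta = (x + y) / (t.n + t.m)
    ll = float(_wlog(x, theta) + _wlog(y, theta))
    point = ParamPoint(tuple(theta), tuple(theta))
    return FittedNull(
        hypothesis=Hypothesis.GENOTYPIC_HOM.spec,
        estimate=point,
        expected_case=t.n * theta,
        expected_control=t.m * theta,
        log_likelihood=ll,
        boundary=bool(np.any(theta == 0)),
    )


def genotypic_chisq(
    t: GenotypeTable,
    method: str = "asymptotic",
    n_reps: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """2-df chi-square test of genotypic homogeneity (gamma = pi)."""
    fit = fit_pooled_genotypic(t)
    q = float(chisq_statistic(t.case, fit.expected_case) + chisq_statistic(t.control, fit.expected_control))
    flags = ("infinite_statistic",) if np.isinf(q) else ()
    if method == "asymptotic":
        p = 0.0 if np.isinf(q) else asymptotic_pvalue(q, 2)
        return TestResult(q, 2, p, "asymptotic", flags=flags)
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    theta = fit.estimate.gamma_arr
    n, m = t.n, t.m

    def stat(xr, yr):
        pooled = (xr + yr) / (n + m)
        return chisq_statistic(xr, n * pooled) + chisq_statistic(yr, m * pooled)

    phat, ci = mc_exact_pvalue(q, stat, theta, theta, n, m, n_reps=n_reps, seed=seed)
    return TestResult(q, 2, phat, "monte_carlo", n_reps=n_reps, mc_ci=ci, seed=seed, flags=flags)


# ---------------------------------------------------------------------------
# traditional doubled-sample allelic test


def usual_allelic_chisq(
    t: GenotypeTable,
    method: str = "asymptotic",
    n_reps: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """1-df chi-square on the 2x2 allele table (2n + 2m 'observations').

    Kept as the biased comparator; the attached warning states the HWE
    validity condition.
    """
    a = allele_table_from_genotypes(t)
    xa, ya = a.case.astype(float), a.control.astype(float)
    tn, tm = a.total_case, a.total_control
    lam = (xa + ya) / (tn + tm)
    q = float(chisq_statistic(xa, tn * lam) + chisq_statistic(ya, tm * lam))
    flags = ("infinite_statistic",) if np.isinf(q) else ()
    if method == "asymptotic":
        p = 0.0 if np.isinf(q) else asymptotic_pvalue(q, 1)
        return TestResult(q, 1, p, "asymptotic", warning=HWE_WARNING, flags=flags)
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    # bootstrap within the test's own (allele-independence) model:
    # allele counts ~ Binomial(2n, lam) and Binomial(2m, lam)
    rng = np.random.default_rng(seed)
    xr = rng.binomial(tn, lam[0], size=n_reps)
    yr = rng.binomial(tm, lam[0], size=n_reps)
    Xr = np.stack([xr, tn - xr], axis=-1).astype(float)
    Yr = np.stack([yr, tm - yr], axis=-1).astype(float)
    lam_r = (Xr + Yr) / (tn + tm)
    stat = chisq_statistic(Xr, tn * lam_r) + chisq_statistic(Yr, tm * lam_r)
    phat = float(np.mean(stat >= q - 1e-9))
    return TestResult(
        q, 1, phat, "monte_carlo", n_reps=n_reps, mc_ci=_mc_ci(phat, n_reps),
        seed=seed, warning=HWE_WARNING, flags=flags,
    )


# ---------------------------------------------------------------------------
# constrained MLE under equal allele frequencies, and the corrected test

_TINY = 1e-300
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _wlog(w, p):
    """sum_i w_i * log(p_i) over the trailing axis, with 0 * log 0 := 0."""
    w = np.asarray(w, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = w * np.log(p)
    return np.where(w == 0, 0.0, terms).sum(axis=-1)


def _inner_freqs(lam, c):
    """Group genotype frequencies maximising the multinomial log-likelihood
    for counts ``c`` subject to allele-A frequency == ``lam``.

    With u = gamma_AB / 2 the stationarity condition is the quadratic
    N u^2 - B u + C = 0, N = sum(c), B = c_AA (1-lam) + c_AB + c_BB lam,
    C = c_AB lam (1-lam); the objective is strictly concave in u so the
    admissible root (in [0, min(lam, 1-lam)]) is the maximiser.
    Broadcasts over leading axes of ``lam`` and ``c``.
    """
    lam = np.asarray(lam, dtype=float)
    c = np.asarray(c, dtype=float)
    N = c[..., 0] + c[..., 1] + c[..., 2]
    B = c[..., 0] * (1.0 - lam) + c[..., 1] + c[..., 2] * lam
    C = c[..., 1] * lam * (1.0 - lam)
    disc = np.sqrt(np.maximum(B * B - 4.0 * N * C, 0.0))
    umax = np.minimum(lam, 1.0 - lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        u1 = (B - disc) / (2.0 * N)
        u2 = (B + disc) / (2.0 * N)
    u = np.where((u1 >= 0.0) & (u1 <= umax), u1, u2)
    # flat likelihood (all-zero weights): any feasible point; pick mid-curve
    u = np.where(N > 0, u, umax / 2.0)
    u = np.clip(u, 0.0, umax)
    return np.stack([lam - u, 2.0 * u, 1.0 - lam - u], axis=-1)


def _profile_loglik(lam, x, y):
    """Profile log-likelihood of the common allele frequency ``lam``."""
    g = _inner_freqs(lam, x)
    p = _inner_freqs(lam, y)
    return _wlog(x, g) + _wlog(y, p)


def fit_allelic_batch(
    x: np.ndarray,
    y: np.ndarray,
    grid_size: int = 65,
    refine_iters: int = 48,
    extra_lambdas: Optional[np.ndarray] = None,
):
    """Constrained MLE under equal allele frequencies for a batch of tables.

    Parameters
    ----------
    x, y : arrays of shape (..., 3)
        Case and control cell weights (integer counts or real exponents >= 0).
    extra_lambdas : optional array broadcastable to the batch shape
        Additional candidate allele frequencies guaranteed to be considered
        (used to enforce nesting relations exactly).

    Returns
    -------
    lam, gamma, pi, loglik : arrays
        The common allele-A frequency, the two genotype-frequency vectors
        and the achieved log-likelihood (0*log 0 := 0 convention).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    eps = 1e-12
    grid = np.linspace(eps, 1.0 - eps, grid_size)
    ll = _profile_loglik(grid[:, None], x[None], y[None])  # (G, R)
    k = np.argmax(ll, axis=0)
    a = grid[np.maximum(k - 1, 0)]
    b = grid[np.minimum(k + 1, grid_size - 1)]
    for _ in range(refine_iters):
        c = b - _INVPHI * (b - a)
        d = a + _INVPHI * (b - a)
        fc = _profile_loglik(c, x, y)
        fd = _profile_loglik(d, x, y)
        left = fc > fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    lam = 0.5 * (a + b)
    if extra_lambdas is not None:
        cand = np.clip(np.broadcast_to(np.asarray(extra_lambdas, float), lam.shape), eps, 1 - eps)
        better = _profile_loglik(cand, x, y) > _profile_loglik(lam, x, y)
        lam = np.where(better, cand, lam)
    gamma = _inner_freqs(lam, x)
    pi = _inner_freqs(lam, y)
    loglik = _wlog(x, gamma) + _wlog(y, pi)
    return lam, gamma, pi, loglik


def fit_constrained_allelic(t: GenotypeTable, prior_counts: float = 0.0) -> FittedNull:
    """MLE of the genotype frequencies under equal allele frequencies.

    ``prior_counts`` adds a constant pseudo-count to every cell (0 keeps the
    pure MLE); useful for regularised refits on sparse bootstrap tables.
    """
    x = t.case + prior_counts
    y = t.control + prior_counts
    lam, gamma, pi, ll = fit_allelic_batch(x, y)
    gamma, pi = gamma[0], pi[0]
    point = ParamPoint(tuple(gamma), tuple(pi))
    return FittedNull(
        hypothesis=Hypothesis.ALLELIC_HOM.spec,
        estimate=point,
        expected_case=t.n * gamma,
        expected_control=t.m * pi,
        log_likelihood=float(ll[0]),
        boundary=bool(np.any(gamma <= 1e-10) or np.any(pi <= 1e-10)),
    )


def _corrected_stats_batch(xr: np.ndarray, yr: np.ndarray) -> np.ndarray:
    """Corrected allelic statistic for a batch of tables (constrained MLE
    re-fit on every table)."""
    n = xr.sum(axis=-1, keepdims=True)
    m = yr.sum(axis=-1, keepdims=True)
    _, g, p, _ = fit_allelic_batch(xr, yr)
    return chisq_statistic(xr, n * g) + chisq_statistic(yr, m * p)


def corrected_allelic_chisq(
    t: GenotypeTable,
    method: str = "asymptotic",
    n_reps: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """HWE-robust test of equal allele frequencies (1 df).

    ``method="monte_carlo"`` gives the exact parametric-bootstrap p-value:
    replicate tables are drawn at the constrained MLE and the constrained
    MLE is re-fit on each replicate before recomputing the statistic.
    """
    fit = fit_constrained_allelic(t)
    q = float(
        chisq_statistic(t.case, fit.expected_case)
        + chisq_statistic(t.control, fit.expected_control)
    )
    flags = ("infinite_statistic",) if np.isinf(q) else ()
    if fit.boundary:
        flags = flags + ("boundary_fit",)
    if method == "asymptotic":
        p = 0.0 if np.isinf(q) else asymptotic_pvalue(q, 1)
        return TestResult(q, 1, p, "asymptotic", flags=flags)
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    phat, ci = mc_exact_pvalue(
        q,
        _corrected_stats_batch,
        fit.estimate.gamma_arr,
        fit.estimate.pi_arr,
        t.n,
        t.m,
        n_reps=n_reps,
        seed=seed,
    )
    return TestResult(q, 1, phat, "monte_carlo", n_reps=n_reps, mc_ci=ci, seed=seed, flags=flags)


# ---------------------------------------------------------------------------
# Cochran-Armitage trend test and Hardy-Weinberg goodness of fit


def armitage_trend(t: GenotypeTable, scores: Sequence[float] = (0.0, 1.0, 2.0)) -> TestResult:
    """Cochran-Armitage trend test with genotype scores (default 0, 1, 2).

    Asymptotically equivalent to the corrected allelic test; the two-sided
    statistic is invariant to reversing the score orientation.
    """
    s = np.asarray(scores, dtype=float)
    x, y = t.case.astype(float), t.control.astype(float)
    col = x + y
    n, N = t.n, t.n + t.m
    den = t.n * t.m * (N * (s * s * col).sum() - ((s * col).sum()) ** 2)
    if den <= 0:
        raise ValueError(
            "trend statistic undefined: all observations fall in a single genotype column"
        )
    num = N * (N * (s * x).sum() - n * (s * col).sum()) ** 2
    q = float(num / den)
    return TestResult(q, 1, asymptotic_pvalue(q, 1), "asymptotic")


def hwe_chisq(counts: Sequence[int]) -> TestResult:
    """1-df goodness-of-fit chi-square for Hardy-Weinberg equilibrium in one
    group, with expected counts (N p^2, 2 N p q, N q^2) at the estimated
    allele frequency p = (2 AA + AB) / 2N.  No continuity correction."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (3,) or np.any(c < 0):
        raise ValueError("counts must be three non-negative numbers (AA, AB, BB)")
    N = c.sum()
    if N < 1:
        raise ValueError("group is empty")
    p = (2 * c[0] + c[1]) / (2 * N)
    if p in (0.0, 1.0):
        raise ValueError(f"monomorphic group (allele-A frequency {p:g}); HWE test undefined")
    expected = N * np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
    q = float(chisq_statistic(c, expected))
    return TestResult(q, 1, asymptotic_pvalue(q, 1), "asymptotic")
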