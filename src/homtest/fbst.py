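"""Full Bayesian Significance Test (FBST) for the homogeneity and HWE
hypotheses, under a product-Dirichlet model.

With independent Dirichlet priors on the case and control genotype
frequency vectors, the posterior is again a product of Dirichlets with
parameters prior + counts.  The e-value of a sharp hypothesis H is

    ev(H) = 1 - P(theta in T | data),
    T = { theta : f(theta | data) > sup over the null set of f },

i.e. one minus the posterior probability of the tangential set (the
points more probable than anything in H).  Large e-values support H.

The supremum step is closed-form for genotypic homogeneity and for HWE,
and a one-dimensional profile optimisation for allelic homogeneity; the
integration step is plain Monte Carlo over posterior Dirichlet draws.
Density comparisons all use one fixed unnormalised log-density scale
(sum of (alpha_i - 1) log freq_i), on which normalising constants cancel.

Because the genotypic null is contained in the allelic null, the null
supremum for the allelic hypothesis is at least the genotypic one, so
with shared posterior draws ev(genotypic) <= ev(allelic) holds exactly,
draw by draw — e-values can never reject the wider hypothesis while
accepting the narrower one.  The implementation enforces the supremum
ordering explicitly (the genotypic arg-sup is a feasible candidate for
the allelic optimisation), making the coherence guarantee immune to
optimiser tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .frequentist import _wlog, fit_allelic_batch
from .tables import GenotypeTable, Hypothesis, HypothesisSpec, ParamPoint

__all__ = [
    "DirichletPrior",
    "PosteriorModel",
    "EvalueResult",
    "CalibrationRule",
    "posterior_from_counts",
    "log_posterior_density",
    "sup_under_null",
    "evalue",
    "evalues_nested",
    "evalue_cutoff",
    "bayes_factor",
]


@dataclass(frozen=True)
class DirichletPrior:
    """Independent Dirichlet priors: ``a`` for the case group's genotype
    frequencies, ``b`` for the control group's.  All ones (the default) is
    the uniform prior on the product of simplices."""

    a: tuple = (1.0, 1.0, 1.0)
    b: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (3,) or b.shape != (3,):
            raise ValueError("each prior needs exactly 3 hyperparameters")
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("Dirichlet hyperparameters must be strictly positive")
        object.__setattr__(self, "a", tuple(a))
        object.__setattr__(self, "b", tuple(b))

    @classmethod
    def uniform(cls) -> "DirichletPrior":
        return cls()


@dataclass(frozen=True)
class PosteriorModel:
    """Product-Dirichlet posterior; parameters are prior + observed counts."""

    alpha_case: tuple
    alpha_control: tuple

    @property
    def alpha_case_arr(self) -> np.ndarray:
        return np.asarray(self.alpha_case, dtype=float)

    @property
    def alpha_control_arr(self) -> np.ndarray:
        return np.asarray(self.alpha_control, dtype=float)


@dataclass(frozen=True)
class EvalueResult:
    """An FBST e-value with its Monte-Carlo pedigree."""

    hypothesis: HypothesisSpec
    sup_log_density: float
    arg_sup: Optional[ParamPoint]
    evalue: float
    n_draws: int
    mc_se: float
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis.kind.value,
            "evalue": float(self.evalue),
            "sup_log_density": float(self.sup_log_density),
            "n_draws": int(self.n_draws),
            "mc_se": float(self.mc_se),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class CalibrationRule:
    """e-value rejection threshold matched to a frequentist level alpha.

    cutoff = 1 - F_d( F^{-1}_{d-h}(1 - alpha) ) with F_k the chi-square CDF,
    d the ambient dimension and h the null dimension; reject H when
    ev <= cutoff.  The map reflects the asymptotic e-value/p-value
    relationship for sharp hypotheses.
    """

    alpha: float
    d: int
    h_complement: int
    cutoff: float


def posterior_from_counts(t: GenotypeTable, prior: DirichletPrior = DirichletPrior()) -> PosteriorModel:
    """Conjugate update: posterior Dirichlet parameters are prior + counts."""
    return PosteriorModel(
        alpha_case=tuple(np.asarray(prior.a) + t.case),
        alpha_control=tuple(np.asarray(prior.b) + t.control),
    )


def log_posterior_density(post: PosteriorModel, theta: ParamPoint) -> float:
    """Unnormalised log posterior density at ``theta``.

    The scale is sum_i (alpha_i - 1) log(freq_i) over both groups, with
    0 * log 0 := 0; all density comparisons in this module use this same
    scale, so the missing normalising constant is irrelevant.
    """
    wc = post.alpha_case_arr - 1.0
    wk = post.alpha_control_arr - 1.0
    return float(_wlog(wc, theta.gamma_arr) + _wlog(wk, theta.pi_arr))


def _group_log_density(weights: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    return _wlog(weights, freqs)


def _hwe_curve(p: float) -> np.ndarray:
    return np.array([p * p, 2.0 * p * (1.0 - p), (1.0 - p) ** 2])


def _sup_hwe(weights: np.ndarray) -> Tuple[float, float]:
    """Supremum of sum_i w_i log(hwe_i(p)) over p in [0, 1].

    In terms of log p and log(1-p) the exponents are a = 2 w_AA + w_AB and
    b = 2 w_BB + w_AB, so the maximiser is p = a / (a + b) (closed form).
    Negative exponents make the supremum infinite (density unbounded at
    the boundary of the curve).
    """
    a = 2.0 * weights[0] + weights[1]
    b = 2.0 * weights[2] + weights[1]
    if a < 0 or b < 0:
        return (0.0 if a < 0 else 1.0), np.inf
    if a + b == 0:
        p = 0.5
    else:
        p = a / (a + b)
    return float(p), float(_wlog(weights, _hwe_curve(p)))


def sup_under_null(post: PosteriorModel, hyp: Hypothesis) -> Tuple[ParamPoint, float]:
    """Supremum of the (unnormalised log) posterior density over the null set.

    Genotypic homogeneity: on {gamma = pi = p} the exponents pool to
    e_i = alpha_case,i + alpha_control,i - 2 and the maximiser is
    p_i = e_i / sum(e) (closed form).  Allelic homogeneity: profile
    optimisation over the common allele frequency (see ``frequentist``),
    with the genotypic arg-sup injected as a candidate so the nesting
    sup ordering holds exactly.  HWE: closed-form 1-D maximum over the
    Hardy-Weinberg curve of one group's simplex.

    Any strictly negative exponent makes the density unbounded on the
    null set; the supremum is then +inf (e-value 1: the hypothesis can
    never be rejected because its tangential set is empty).
    """
    wc = post.alpha_case_arr - 1.0
    wk = post.alpha_control_arr - 1.0
    if hyp is Hypothesis.GENOTYPIC_HOM:
        e = wc + wk
        if np.any(e < 0):
            return None, np.inf
        if e.sum() == 0:
            p = np.full(3, 1.0 / 3.0)
        else:
            p = e / e.sum()
        return ParamPoint(tuple(p), tuple(p)), float(_wlog(e, p))
    if hyp is Hypothesis.ALLELIC_HOM:
        if np.any(wc < 0) or np.any(wk < 0):
            return None, np.inf
        # candidate from the genotypic sup guarantees sup_A >= sup_G
        e = wc + wk
        lam_g = None
        if not np.any(e < 0) and e.sum() > 0:
            pg = e / e.sum()
            lam_g = pg[0] + pg[1] / 2.0
        lam, g, p, ll = fit_allelic_batch(
            wc, wk, extra_lambdas=None if lam_g is None else np.array([lam_g])
        )
        point = ParamPoint(tuple(g[0]), tuple(p[0]))
        return point, float(ll[0])
    if hyp in (Hypothesis.HWE_CASE, Hypothesis.HWE_CONTROL):
        w = wc if hyp is Hypothesis.HWE_CASE else wk
        p, sup = _sup_hwe(w)
        if not np.isfinite(sup):
            return None, np.inf
        curve = tuple(_hwe_curve(p))
        other = (1.0, 0.0, 0.0)  # unused group; placeholder for the ParamPoint
        if hyp is Hypothesis.HWE_CASE:
            point = ParamPoint(curve, other)
        else:
            point = ParamPoint(other, curve)
        return point, sup
    raise ValueError(f"unknown hypothesis {hyp!r}")


def _draw_group(rng: np.random.Generator, alpha: np.ndarray, n_draws: int) -> np.ndarray:
    return rng.dirichlet(alpha, size=n_draws)


def evalue(
    t: GenotypeTable,
    hyp: Hypothesis,
    prior: DirichletPrior = DirichletPrior(),
    n_draws: int = 100_000,
    seed: Optional[int] = None,
) -> EvalueResult:
    """FBST e-value of ``hyp`` by posterior Monte Carlo.

    For the homogeneity hypotheses the draws live on the product of the
    two simplices; for an HWE hypothesis only that group's posterior is
    involved (the hypothesis constrains a single simplex, matching the
    geometric picture of the HWE curve inside one group's triangle).
    """
    if n_draws < 1_000:
        raise ValueError("n_draws must be >= 1000")
    post = posterior_from_counts(t, prior)
    arg, sup = sup_under_null(post, hyp)
    rng = np.random.default_rng(seed)
    if hyp in (Hypothesis.GENOTYPIC_HOM, Hypothesis.ALLELIC_HOM):
        g = _draw_group(rng, post.alpha_case_arr, n_draws)
        p = _draw_group(rng, post.alpha_control_arr, n_draws)
        ld = _group_log_density(post.alpha_case_arr - 1.0, g) + _group_log_density(
            post.alpha_control_arr - 1.0, p
        )
    else:
        alpha = post.alpha_case_arr if hyp is Hypothesis.HWE_CASE else post.alpha_control_arr
        d = _draw_group(rng, alpha, n_draws)
        ld = _group_log_density(alpha - 1.0, d)
    ev = 1.0 if np.isinf(sup) else float(1.0 - np.mean(ld > sup))
    se = float(np.sqrt(ev * (1.0 - ev) / n_draws))
    return EvalueResult(hyp.spec, sup, arg, ev, n_draws, se, seed)


def evalues_nested(
    t: GenotypeTable,
    prior: DirichletPrior = DirichletPrior(),
    n_draws: int = 100_000,
    seed: Optional[int] = None,
) -> Tuple[EvalueResult, EvalueResult]:
    """Genotypic and allelic e-values from one shared set of posterior draws.

    Sharing draws makes the coherence inequality ev(genotypic) <=
    ev(allelic) hold exactly (not just up to Monte-Carlo error), because
    the two tangential sets are nested and evaluated on the same sample.
    """
    post = posterior_from_counts(t, prior)
    arg_g, sup_g = sup_under_null(post, Hypothesis.GENOTYPIC_HOM)
    arg_a, sup_a = sup_under_null(post, Hypothesis.ALLELIC_HOM)
    sup_a = max(sup_a, sup_g)  # nesting: H0G subset of H0A
    rng = np.random.default_rng(seed)
    g = _draw_group(rng, post.alpha_case_arr, n_draws)
    p = _draw_group(rng, post.alpha_control_arr, n_draws)
    ld = _group_log_density(post.alpha_case_arr - 1.0, g) + _group_log_density(
        post.alpha_control_arr - 1.0, p
    )
    ev_g = 1.0 if np.isinf(sup_g) else float(1.0 - np.mean(ld > sup_g))
    ev_a = 1.0 if np.isinf(sup_a) else float(1.0 - np.mean(ld > sup_a))
    se_g = float(np.sqrt(ev_g * (1.0 - ev_g) / n_draws))
    se_a = float(np.sqrt(ev_a * (1.0 - ev_a) / n_draws))
    return (
        EvalueResult(Hypothesis.GENOTYPIC_HOM.spec, sup_g, arg_g, ev_g, n_draws, se_g, seed),
        EvalueResult(Hypothesis.ALLELIC_HOM.spec, sup_a, arg_a, ev_a, n_draws, se_a, seed),
    )


def evalue_cutoff(alpha: float, d: int, null_dim: int) -> CalibrationRule:
    """e-value rejection cutoff matching a frequentist significance level.

    Uses the asymptotic chi-square link between e-values and p-values:
    cutoff = 1 - F_d(F^{-1}_{d - null_dim}(1 - alpha)).  Reject when the
    e-value is <= the cutoff.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 1 <= null_dim < d:
        raise ValueError(f"need 1 <= null_dim < d, got null_dim={null_dim}, d={d}")
    q = stats.chi2.ppf(1.0 - alpha, d - null_dim)
    cutoff = float(stats.chi2.sf(q, d))
    return CalibrationRule(alpha=alpha, d=d, h_complement=d - null_dim, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Bayes factors under uniform priors


def _log_dirichlet_moment(counts: np.ndarray, alpha: np.ndarray) -> float:
    """log E[prod theta_i^{c_i}] under Dirichlet(alpha)."""
    counts = np.asarray(counts, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    return float(
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        + gammaln(alpha + counts).sum()
        - gammaln(alpha.sum() + counts.sum())
    )


def bayes_factor(
    t: GenotypeTable,
    hyp: Hypothesis,
    n_draws: int = 200_000,
    seed: Optional[int] = None,
) -> float:
    """Bayes factor P(data | H) / P(data | full space) under uniform priors.

    Genotypic homogeneity: both marginal likelihoods are Dirichlet moment
    integrals, so the ratio is closed-form (multinomial coefficients
    cancel).  Allelic homogeneity: the numerator is a Monte-Carlo average
    of the likelihood kernel over the null set, taken Lebesgue-uniform in
    the coordinates (gamma_AB, pi_AA, pi_AB) on the feasible region.  The
    null sets are measure-zero, so a dominating-measure convention must be
    chosen; this one is recorded here and in the methods note — other
    defensible conventions give different numbers.
    """
    x, y = t.case, t.control
    ones = np.ones(3)
    log_den = _log_dirichlet_moment(x, ones) + _log_dirichlet_moment(y, ones)
    if hyp is Hypothesis.GENOTYPIC_HOM:
        log_num = _log_dirichlet_moment(x + y, ones)
        return float(np.exp(log_num - log_den))
    if hyp is not Hypothesis.ALLELIC_HOM:
        raise ValueError(f"Bayes factor implemented for homogeneity hypotheses only, got {hyp!r}")
    rng = np.random.default_rng(seed)
    # uniform on the feasible region of (gamma_AB, pi_AA, pi_AB) by rejection
    kept_logL = []
    kept = 0
    total = 0
    while kept < n_draws and total < 50 * n_draws:
        r = n_draws
        gab = rng.uniform(0.0, 1.0, size=r)
        paa = rng.uniform(0.0, 1.0, size=r)
        pab = rng.uniform(0.0, 1.0, size=r)
        lam = paa + pab / 2.0
        gaa = lam - gab / 2.0
        gbb = 1.0 - gaa - gab
        pbb = 1.0 - paa - pab
        ok = (gaa >= 0) & (gbb >= 0) & (pbb >= 0) & (lam <= 1.0)
        total += r
        kept += int(ok.sum())
        G = np.stack([gaa[ok], gab[ok], gbb[ok]], axis=-1)
        P = np.stack([paa[ok], pab[ok], pbb[ok]], axis=-1)
        kept_logL.append(_wlog(x, G) + _wlog(y, P))
    logL = np.concatenate(kept_logL)
    if logL.size == 0:
        raise RuntimeError("no feasible draws for the allelic null set")
    log_num = float(logsumexp(logL) - np.log(logL.size))
    return float(np.exp(log_num - log_den))
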