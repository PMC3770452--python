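"""Simulation studies: product-multinomial table generators, power and
type-I-error estimation for the five tests, and the coherence audit.

The power design perturbs allelic homogeneity by an offset ``epsilon``:
fixing gamma_AA, gamma_AB and pi_AA, the control heterozygote frequency
is set to

    pi_AB = 2 (gamma_AA + gamma_AB / 2 - pi_AA - epsilon),

so the case and control allele-A frequencies differ by exactly epsilon;
epsilon = 0 is the allelic null.  Three simulation regimes mirror the
qualitative comparison of the tests: (1) full genotypic homogeneity,
(2) allelic homogeneity only (equal allele frequencies with different
genotype distributions, i.e. HWE broken differently in each group), and
(3) neither.

The coherence audit computes all five statistics per table (genotypic p,
usual allelic p, corrected allelic p, genotypic e-value, allelic
e-value), flags p-value incoherences (allelic rejected while genotypic
accepted at the chosen alpha) and verifies that e-value monotonicity
violations never occur — the e-values are computed with shared posterior
draws, for which the nesting inequality holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import frequentist as freq
from . import fbst
from .tables import GenotypeTable, Hypothesis, ParamPoint

__all__ = [
    "PowerScenario",
    "PowerTable",
    "AuditReport",
    "sample_table",
    "build_scenario",
    "table6_regimes",
    "random_theta",
    "power_curve",
    "coherence_audit",
    "standard_tests",
]


@dataclass(frozen=True)
class PowerScenario:
    """One generating configuration of the epsilon-offset power design."""

    gamma_AA: float
    gamma_AB: float
    pi_AA: float
    epsilon: float
    n: int
    m: int
    theta: ParamPoint = field(init=False)

    def __post_init__(self) -> None:
        g_aa, g_ab, p_aa, eps = self.gamma_AA, self.gamma_AB, self.pi_AA, self.epsilon
        p_ab = 2.0 * (g_aa + g_ab / 2.0 - p_aa - eps)
        gamma = (g_aa, g_ab, 1.0 - g_aa - g_ab)
        pi = (p_aa, p_ab, 1.0 - p_aa - p_ab)
        for name, v in (("gamma", gamma), ("pi", pi)):
            for comp, lab in zip(v, ("AA", "AB", "BB")):
                if comp < -1e-12 or comp > 1 + 1e-12:
                    raise ValueError(
                        f"epsilon={eps} infeasible: {name}_{lab} = {comp:.4f} outside [0, 1]"
                    )
        if self.n < 1 or self.m < 1:
            raise ValueError("group sizes must be >= 1")
        object.__setattr__(self, "theta", ParamPoint(gamma, pi))


def build_scenario(
    gamma_AA: float,
    gamma_AB: float,
    pi_AA: float,
    epsilon: float,
    n: int = 100,
    m: int = 100,
) -> PowerScenario:
    """Validate and assemble a power scenario (see module docstring)."""
    return PowerScenario(gamma_AA, gamma_AB, pi_AA, epsilon, n, m)


def sample_table(theta: ParamPoint, n: int, m: int, seed=None) -> GenotypeTable:
    """One product-multinomial draw: case ~ Mult(n, gamma), control ~ Mult(m, pi)."""
    rng = np.random.default_rng(seed)
    x = rng.multinomial(n, theta.gamma_arr)
    y = rng.multinomial(m, theta.pi_arr)
    return GenotypeTable.from_rows(x, y)


def _sample_batch(theta: ParamPoint, n: int, m: int, size: int, rng: np.random.Generator):
    x = rng.multinomial(n, theta.gamma_arr, size=size)
    y = rng.multinomial(m, theta.pi_arr, size=size)
    return x, y


def _base_seed(seed: Optional[int]) -> int:
    """Master seed for substream spawning; fresh entropy when seed is None."""
    if seed is not None:
        return int(seed)
    return int(np.random.SeedSequence().generate_state(1)[0] % 2**31)


def random_theta(rng: np.random.Generator) -> ParamPoint:
    """A generic random parameter point (independent flat Dirichlets)."""
    return ParamPoint(tuple(rng.dirichlet(np.ones(3))), tuple(rng.dirichlet(np.ones(3))))


def table6_regimes(min_margin: float = 0.05) -> Dict[str, Callable[[np.random.Generator], ParamPoint]]:
    """Parameterised generators for the three simulation regimes.

    1. ``genotypic_homogeneity``: gamma = pi (hence equal allele
       frequencies too).
    2. ``allelic_homogeneity_only``: equal allele frequencies but
       different genotype vectors (each group gets its own inbreeding-like
       mix between the HWE point and the extreme same-allele-frequency
       distributions).
    3. ``no_homogeneity``: allele frequencies differ by at least
       ``min_margin``.
    """

    def regime1(rng: np.random.Generator) -> ParamPoint:
        g = tuple(rng.dirichlet(np.ones(3)))
        return ParamPoint(g, g)

    def _group_with_allele_freq(lam: float, rng: np.random.Generator) -> tuple:
        # heterozygote share gamma_AB = 2u with u in [0, min(lam, 1-lam)]
        u = rng.uniform(0.0, min(lam, 1.0 - lam))
        return (lam - u, 2.0 * u, 1.0 - lam - u)

    def regime2(rng: np.random.Generator) -> ParamPoint:
        lam = rng.uniform(0.15, 0.85)
        for _ in range(100):
            g = _group_with_allele_freq(lam, rng)
            p = _group_with_allele_freq(lam, rng)
            if abs(g[0] - p[0]) > 1e-3:  # genuinely different genotype vectors
                return ParamPoint(g, p)
        raise RuntimeError("could not draw distinct genotype vectors")  # pragma: no cover

    def regime3(rng: np.random.Generator) -> ParamPoint:
        lam_case = rng.uniform(0.1, 0.9)
        lo, hi = min(lam_case + min_margin, 0.95), 0.95
        if rng.random() < 0.5 and lam_case - min_margin > 0.05:
            lo, hi = 0.05, max(lam_case - min_margin, 0.05)
        lam_ctrl = rng.uniform(lo, hi)
        return ParamPoint(
            _group_with_allele_freq(lam_case, rng),
            _group_with_allele_freq(lam_ctrl, rng),
        )

    return {
        "genotypic_homogeneity": regime1,
        "allelic_homogeneity_only": regime2,
        "no_homogeneity": regime3,
    }


# ---------------------------------------------------------------------------
# test battery for power studies


def standard_tests(
    mc_reps: int = 2_000,
    n_draws: int = 10_000,
    use_mc_corrected: bool = False,
) -> Dict[str, Callable[[GenotypeTable, float, np.random.Generator], bool]]:
    """Reject/accept deciders at level alpha for the allelic-homogeneity
    power comparison: the usual doubled-sample test, the corrected test
    (asymptotic or Monte-Carlo exact), and the FBST with the calibrated
    e-value cutoff (d = 4, null dimension 3)."""

    def usual(t, alpha, rng):
        return freq.usual_allelic_chisq(t).p_value <= alpha

    def corrected(t, alpha, rng):
        if use_mc_corrected:
            r = freq.corrected_allelic_chisq(
                t, method="monte_carlo", n_reps=mc_reps, seed=int(rng.integers(2**31))
            )
        else:
            r = freq.corrected_allelic_chisq(t)
        return r.p_value <= alpha

    def fbst_allelic(t, alpha, rng):
        cut = fbst.evalue_cutoff(alpha, d=4, null_dim=3).cutoff
        ev = fbst.evalue(
            t, Hypothesis.ALLELIC_HOM, n_draws=n_draws, seed=int(rng.integers(2**31))
        ).evalue
        return ev <= cut

    return {"usual_allelic": usual, "corrected_allelic": corrected, "fbst_allelic": fbst_allelic}


@dataclass
class PowerTable:
    """Rejection rates per (scenario, test) with binomial 95% CIs."""

    frame: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> list:
        return self.frame.to_dict(orient="records")


def power_curve(
    scenarios: Sequence[PowerScenario],
    tests: Optional[Dict[str, Callable]] = None,
    alpha: float = 0.05,
    n_datasets: int = 100,
    seed: Optional[int] = None,
) -> PowerTable:
    """Estimate rejection rates of each test under each scenario.

    ``n_datasets`` defaults to the small headline design (100 datasets);
    calibration assertions need the high-precision mode (>= 2000).  Each
    dataset is re-derivable from (seed, scenario index, dataset index) via
    spawned substreams.
    """
    if tests is None:
        tests = standard_tests()
    base = _base_seed(seed)
    rows = []
    for s_idx, sc in enumerate(scenarios):
        rng_tables = np.random.default_rng(np.random.SeedSequence((base, s_idx)))
        x, y = _sample_batch(sc.theta, sc.n, sc.m, n_datasets, rng_tables)
        decisions = {name: 0 for name in tests}
        failures = {name: 0 for name in tests}
        for d_idx in range(n_datasets):
            try:
                tab = GenotypeTable.from_rows(x[d_idx], y[d_idx])
            except ValueError:
                for name in tests:
                    failures[name] += 1
                continue
            rng_tests = np.random.default_rng(np.random.SeedSequence((base, s_idx, d_idx)))
            for name, decide in tests.items():
                try:
                    if decide(tab, alpha, rng_tests):
                        decisions[name] += 1
                except ValueError:
                    failures[name] += 1
        for name in tests:
            valid = n_datasets - failures[name]
            rate = decisions[name] / valid if valid else np.nan
            se = np.sqrt(rate * (1 - rate) / valid) if valid else np.nan
            rows.append(
                {
                    "gamma_AA": sc.gamma_AA,
                    "gamma_AB": sc.gamma_AB,
                    "pi_AA": sc.pi_AA,
                    "epsilon": sc.epsilon,
                    "n": sc.n,
                    "m": sc.m,
                    "test": name,
                    "alpha": alpha,
                    "rejection_count": decisions[name],
                    "n_datasets": valid,
                    "rejection_rate": rate,
                    "ci_lo": max(0.0, rate - 1.96 * se) if valid else np.nan,
                    "ci_hi": min(1.0, rate + 1.96 * se) if valid else np.nan,
                    "n_failures": failures[name],
                }
            )
    return PowerTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# coherence audit


@dataclass
class AuditReport:
    """Per-table p-values, e-values and incoherence flags.

    ``p_incoherent_usual`` / ``p_incoherent_corrected``: the allelic test
    rejects at alpha while the genotypic test accepts — the logically
    impossible verdict, since equal genotype frequencies force equal
    allele frequencies.  ``e_violation`` marks e-value monotonicity
    failures and must always be all-False.
    """

    frame: pd.DataFrame
    alpha: float

    @property
    def n_p_incoherences(self) -> int:
        return int(
            (self.frame["p_incoherent_usual"] | self.frame["p_incoherent_corrected"]).sum()
        )

    @property
    def n_e_violations(self) -> int:
        return int(self.frame["e_violation"].sum())

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_tables": int(len(self.frame)),
            "n_p_incoherences": self.n_p_incoherences,
            "n_e_violations": self.n_e_violations,
            "tables": self.frame.to_dict(orient="records"),
        }


def coherence_audit(
    tables: Iterable[GenotypeTable],
    alpha: float = 0.10,
    n_draws: int = 10_000,
    corrected_method: str = "asymptotic",
    mc_reps: int = 10_000,
    seed: Optional[int] = None,
) -> AuditReport:
    """Run all five allelic/genotypic statistics on each table and flag
    incoherences.

    e-values for the two nested hypotheses share one set of posterior
    draws per table, so the monotonicity inequality is checked exactly.
    """
    base = _base_seed(seed)
    rows = []
    for idx, t in enumerate(tables):
        rng = np.random.default_rng(np.random.SeedSequence((base, idx)))
        p_g = freq.genotypic_chisq(t).p_value
        p_u = freq.usual_allelic_chisq(t).p_value
        if corrected_method == "monte_carlo":
            p_a = freq.corrected_allelic_chisq(
                t, method="monte_carlo", n_reps=mc_reps, seed=int(rng.integers(2**31))
            ).p_value
        else:
            p_a = freq.corrected_allelic_chisq(t).p_value
        ev_g, ev_a = fbst.evalues_nested(t, n_draws=n_draws, seed=int(rng.integers(2**31)))
        rows.append(
            {
                "index": idx,
                "p_genotypic": p_g,
                "p_usual_allelic": p_u,
                "p_corrected_allelic": p_a,
                "e_genotypic": ev_g.evalue,
                "e_allelic": ev_a.evalue,
                "p_incoherent_usual": (p_u <= alpha) and (p_g > alpha),
                "p_incoherent_corrected": (p_a <= alpha) and (p_g > alpha),
                "e_violation": ev_g.evalue > ev_a.evalue,
            }
        )
    return AuditReport(pd.DataFrame(rows), alpha)
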