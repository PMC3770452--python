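"""Count-table data model and I/O for biallelic case-control studies.

A study of one biallelic locus is summarised by a 2x3 table of genotype
counts: cases and controls in the rows, genotypes AA / AB / BB in the
columns (A is the reference allele).  Every analysis in this package
starts from a validated :class:`GenotypeTable`; the 2x2 allele table used
by the traditional "doubled-sample" allelic test is always derived from
it, never read from a file, so the two representations can never drift
apart.

File dialect: TSV or CSV with a header row ``Group,AA,AB,BB`` (an optional
trailing ``Total`` column is accepted, cross-checked against the recomputed
row sum, and otherwise ignored) and exactly two data rows — first the case
group, then the control group.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPES",
    "GenotypeTable",
    "AlleleTable",
    "ParamPoint",
    "Hypothesis",
    "HypothesisSpec",
    "read_genotype_table",
    "write_genotype_table",
    "allele_table_from_genotypes",
]

GENOTYPES = ("AA", "AB", "BB")


def _check_count(value, cell: str) -> int:
    """Validate a single table cell as a non-negative integer."""
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"cell {cell}: {value!r} is not a number") from None
    if not np.isfinite(f) or f != int(f):
        raise ValueError(f"cell {cell}: {value!r} is not an integer count")
    if f < 0:
        raise ValueError(f"cell {cell}: negative count {value!r}")
    return int(f)


@dataclass(frozen=True)
class GenotypeTable:
    """2x3 genotype counts for a case group and a control group.

    Attributes
    ----------
    x_AA, x_AB, x_BB : int
        Genotype counts in the case group.
    y_AA, y_AB, y_BB : int
        Genotype counts in the control group.
    """

    x_AA: int
    x_AB: int
    x_BB: int
    y_AA: int
    y_AB: int
    y_BB: int

    def __post_init__(self) -> None:
        for name in ("x_AA", "x_AB", "x_BB", "y_AA", "y_AB", "y_BB"):
            object.__setattr__(self, name, _check_count(getattr(self, name), name))
        if self.n < 1:
            raise ValueError("case row is empty (n = 0)")
        if self.m < 1:
            raise ValueError("control row is empty (m = 0)")

    @property
    def n(self) -> int:
        """Number of case individuals (row sum, always recomputed)."""
        return self.x_AA + self.x_AB + self.x_BB

    @property
    def m(self) -> int:
        """Number of control individuals."""
        return self.y_AA + self.y_AB + self.y_BB

    @property
    def case(self) -> np.ndarray:
        return np.array([self.x_AA, self.x_AB, self.x_BB])

    @property
    def control(self) -> np.ndarray:
        return np.array([self.y_AA, self.y_AB, self.y_BB])

    @classmethod
    def from_rows(cls, case: Sequence[int], control: Sequence[int]) -> "GenotypeTable":
        case = list(case)
        control = list(control)
        if len(case) != 3 or len(control) != 3:
            raise ValueError("each group needs exactly three genotype counts (AA, AB, BB)")
        return cls(*case, *control)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[*self.case, self.n], [*self.control, self.m]],
            index=pd.Index(["Case", "Control"], name="Group"),
            columns=[*GENOTYPES, "Total"],
        )

    def to_dict(self) -> dict:
        return {
            "case": {g: int(c) for g, c in zip(GENOTYPES, self.case)},
            "control": {g: int(c) for g, c in zip(GENOTYPES, self.control)},
            "n": self.n,
            "m": self.m,
        }


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele counts derived from a genotype table (2n / 2m alleles)."""

    x_A: int
    x_B: int
    y_A: int
    y_B: int

    @property
    def case(self) -> np.ndarray:
        return np.array([self.x_A, self.x_B])

    @property
    def control(self) -> np.ndarray:
        return np.array([self.y_A, self.y_B])

    @property
    def total_case(self) -> int:
        return self.x_A + self.x_B

    @property
    def total_control(self) -> int:
        return self.y_A + self.y_B


def allele_table_from_genotypes(t: GenotypeTable) -> AlleleTable:
    """Derive the 2x2 allele-count table: each AA contributes two A alleles,
    each heterozygote one of each."""
    return AlleleTable(
        x_A=2 * t.x_AA + t.x_AB,
        x_B=2 * t.x_BB + t.x_AB,
        y_A=2 * t.y_AA + t.y_AB,
        y_B=2 * t.y_BB + t.y_AB,
    )


@dataclass(frozen=True)
class ParamPoint:
    """A point of the parameter space: genotype-frequency vectors for the
    case population (``gamma``) and the control population (``pi``)."""

    gamma: tuple
    pi: tuple

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        p = np.asarray(self.pi, dtype=float)
        for name, v in (("gamma", g), ("pi", p)):
            if v.shape != (3,):
                raise ValueError(f"{name} must have exactly 3 components")
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ValueError(f"{name} has components outside [0, 1]: {v}")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} does not sum to 1: sum = {v.sum()!r}")
        object.__setattr__(self, "gamma", tuple(np.clip(g, 0.0, 1.0)))
        object.__setattr__(self, "pi", tuple(np.clip(p, 0.0, 1.0)))

    @property
    def gamma_arr(self) -> np.ndarray:
        return np.asarray(self.gamma)

    @property
    def pi_arr(self) -> np.ndarray:
        return np.asarray(self.pi)

    @property
    def allele_freq_case(self) -> float:
        """Frequency of allele A in the case population."""
        return self.gamma[0] + self.gamma[1] / 2.0

    @property
    def allele_freq_control(self) -> float:
        return self.pi[0] + self.pi[1] / 2.0


class Hypothesis(enum.Enum):
    """The four sharp hypotheses handled by the package.

    GENOTYPIC_HOM : gamma = pi (all three genotype frequencies equal).
    ALLELIC_HOM   : gamma_AA + gamma_AB/2 = pi_AA + pi_AB/2 (equal allele-A
                    frequencies); implied by GENOTYPIC_HOM.
    HWE_CASE / HWE_CONTROL : one group's genotype frequencies lie on the
                    Hardy-Weinberg curve (p^2, 2p(1-p), (1-p)^2).
    """

    GENOTYPIC_HOM = "genotypic_homogeneity"
    ALLELIC_HOM = "allelic_homogeneity"
    HWE_CASE = "hwe_case"
    HWE_CONTROL = "hwe_control"

    @property
    def spec(self) -> "HypothesisSpec":
        return _HYP_SPECS[self]


@dataclass(frozen=True)
class HypothesisSpec:
    """Dimensional bookkeeping for a hypothesis: ambient dimension ``d`` of
    the parameter space it lives in and dimension ``null_dim`` of the null
    set.  ``d - null_dim`` is the chi-square degrees of freedom."""

    kind: Hypothesis
    d: int
    null_dim: int

    @property
    def df(self) -> int:
        return self.d - self.null_dim


_HYP_SPECS = {
    Hypothesis.GENOTYPIC_HOM: HypothesisSpec(Hypothesis.GENOTYPIC_HOM, d=4, null_dim=2),
    Hypothesis.ALLELIC_HOM: HypothesisSpec(Hypothesis.ALLELIC_HOM, d=4, null_dim=3),
    Hypothesis.HWE_CASE: HypothesisSpec(Hypothesis.HWE_CASE, d=2, null_dim=1),
    Hypothesis.HWE_CONTROL: HypothesisSpec(Hypothesis.HWE_CONTROL, d=2, null_dim=1),
}


def _table_from_frame(df: pd.DataFrame, source: str) -> GenotypeTable:
    cols = {str(c).strip().upper(): c for c in df.columns}
    missing = [g for g in GENOTYPES if g not in cols]
    if missing:
        raise ValueError(
            f"{source}: header must contain columns AA, AB, BB (missing {missing}); "
            f"got {list(df.columns)}"
        )
    if len(df) != 2:
        raise ValueError(f"{source}: expected exactly 2 data rows (case, control), got {len(df)}")

    rows = []
    for ridx, label in zip(range(2), ("case", "control")):
        counts = [
            _check_count(df.iloc[ridx][cols[g]], f"{label}/{g}") for g in GENOTYPES
        ]
        if "TOTAL" in cols:
            stated = _check_count(df.iloc[ridx][cols["TOTAL"]], f"{label}/Total")
            if stated != sum(counts):
                raise ValueError(
                    f"{source}: {label} row Total column says {stated} "
                    f"but the counts sum to {sum(counts)}"
                )
        rows.append(counts)
    return GenotypeTable.from_rows(rows[0], rows[1])


def read_genotype_table(source) -> GenotypeTable:
    """Read a genotype table from a TSV/CSV path or from six inline counts.

    Parameters
    ----------
    source : str, os.PathLike, or sequence of six ints
        A delimited file in the ``Group,AA,AB,BB[,Total]`` dialect, or the
        six counts ``(x_AA, x_AB, x_BB, y_AA, y_AB, y_BB)``.
    """
    if isinstance(source, GenotypeTable):
        return source
    if isinstance(source, (list, tuple, np.ndarray)):
        vals = list(np.asarray(source).ravel())
        if len(vals) != 6:
            raise ValueError(f"inline input needs 6 counts, got {len(vals)}")
        return GenotypeTable(*vals)
    if not isinstance(source, (str, os.PathLike)):
        raise TypeError(f"unsupported source type: {type(source)!r}")
    path = os.fspath(source)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ValueError(f"{path}: could not parse table: {exc}") from exc
    return _table_from_frame(df, path)


def write_genotype_table(t: GenotypeTable, path, sep: str = "\t") -> None:
    """Write the table in the same dialect ``read_genotype_table`` accepts."""
    t.to_frame().to_csv(path, sep=sep)
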