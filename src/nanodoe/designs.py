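"""Two-level Plackett-Burman and three-level Box-Behnken design construction.

Factor levels are handled in *coded* units (-1, 0, +1) internally; a
:class:`FactorSpec` maps each factor between its natural units (mg/mL,
mass ratios, hours, ...) and coded units via ``coded = (natural - center) / step``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "make_pbd",
    "make_bbd",
    "code_levels",
    "uncode_levels",
    "PB12_GENERATOR",
]

# Standard generator row for the 12-run Plackett-Burman design.
PB12_GENERATOR = (+1, +1, -1, +1, +1, +1, -1, -1, -1, +1, -1)


class InvalidSpecError(ValueError):
    """Raised when a factor specification is internally inconsistent."""


@dataclass(frozen=True)
class FactorSpec:
    """Mapping between natural and coded units for one design factor.

    Parameters
    ----------
    name : str
        Factor label, e.g. ``"CS"`` for the chitosan concentration.
    low, high : float
        Natural values at coded -1 and +1.
    center : float, optional
        Natural value at coded 0. Required for three-level designs, where
        the level spacing must be symmetric (``high - center == center - low``).
    units : str
        Unit string, for reporting only.
    """

    name: str
    low: float
    high: float
    center: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise InvalidSpecError(f"{self.name}: require low < high, got {self.low} >= {self.high}")
        if self.center is not None:
            if not (self.low < self.center < self.high):
                raise InvalidSpecError(f"{self.name}: center {self.center} outside ({self.low}, {self.high})")
            if not np.isclose(self.high - self.center, self.center - self.low):
                raise InvalidSpecError(
                    f"{self.name}: asymmetric levels {self.low}/{self.center}/{self.high} "
                    "(three-level designs need equal spacing)"
                )

    @property
    def step(self) -> float:
        """Natural-unit change per coded unit."""
        if self.center is None:
            return (self.high - self.low) / 2.0
        return self.high - self.center

    @property
    def midpoint(self) -> float:
        """Natural value at coded 0 (explicit center, or the low/high mean)."""
        return (self.low + self.high) / 2.0 if self.center is None else self.center

    def code(self, natural):
        step = self.step
        if step == 0:
            raise InvalidSpecError(f"{self.name}: zero level step")
        return (np.asarray(natural, dtype=float) - self.midpoint) / step

    def uncode(self, coded):
        return np.asarray(coded, dtype=float) * self.step + self.midpoint


@dataclass
class DesignMatrix:
    """A coded experimental design: runs x factors with levels in {-1, 0, +1}.

    ``coded`` is a DataFrame indexed by run id. For Plackett-Burman designs
    the columns beyond the real factors are retained as *dummy* columns
    (listed in ``dummy_columns``) so the screening ANOVA can pool them into
    its error estimate.
    """

    kind: str  # "pbd" | "bbd"
    coded: pd.DataFrame
    dummy_columns: list[str] = field(default_factory=list)

    @property
    def factor_names(self) -> list[str]:
        return [c for c in self.coded.columns if c not in self.dummy_columns]

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    def to_natural(self, specs: list[FactorSpec]) -> pd.DataFrame:
        """Translate the real-factor columns into natural units."""
        byname = {s.name: s for s in specs}
        out = {}
        for i, col in enumerate(self.factor_names):
            spec = byname.get(col, specs[i] if i < len(specs) else None)
            if spec is None:
                raise InvalidSpecError(f"no FactorSpec for design column {col!r}")
            out[col] = spec.uncode(self.coded[col].to_numpy())
        return pd.DataFrame(out, index=self.coded.index)


def make_pbd(n_factors: int, factor_names: list[str] | None = None) -> DesignMatrix:
    """Build the 12-run Plackett-Burman screening design.

    Rows 1..11 are cyclic right-rotations of the standard 11-element
    generator row; row 12 is all -1. The first ``n_factors`` columns are
    assigned to real factors (named A, B, C, ... unless ``factor_names``
    is given); the remaining columns are kept as dummy columns for error
    estimation.
    """
    if not 1 <= n_factors <= 11:
        raise ValueError(f"n_factors must be in 1..11, got {n_factors}")
    gen = np.array(PB12_GENERATOR, dtype=int)
    rows = [np.roll(gen, i) for i in range(11)]
    rows.append(-np.ones(11, dtype=int))
    mat = np.array(rows)

    default = [chr(ord("A") + i) for i in range(11)]
    if factor_names is None:
        names = default[:n_factors]
    else:
        if len(factor_names) != n_factors:
            raise ValueError("factor_names length must equal n_factors")
        names = list(factor_names)
    dummies = [f"dummy{i + 1}" for i in range(11 - n_factors)]
    coded = pd.DataFrame(mat, columns=names + dummies, index=pd.RangeIndex(1, 13, name="run"))
    return DesignMatrix(kind="pbd", coded=coded, dummy_columns=dummies)


# Coded (X1, X2, X3) rows of the packaged 17-run BBD, in the fixture's run
# order, so design and response fixtures align row by row.
_BBD17_ROWS = [
    (0, +1, -1), (0, 0, 0), (0, +1, +1), (0, -1, -1), (0, 0, 0),
    (-1, +1, 0), (0, -1, +1), (0, 0, 0), (0, 0, 0), (+1, 0, +1),
    (+1, 0, -1), (-1, -1, 0), (0, 0, 0), (+1, +1, 0), (-1, 0, -1),
    (+1, -1, 0), (-1, 0, +1),
]


def make_bbd(n_center: int = 5, factor_names: list[str] | None = None) -> DesignMatrix:
    """Build the three-factor Box-Behnken design with ``n_center`` center runs.

    The 12 edge runs place each factor pair at its four (+/-1, +/-1)
    combinations with the third factor at 0. With the default five center
    replicates the run order follows the packaged 17-run fixture exactly;
    otherwise edge runs come in lexicographic factor-pair order followed by
    the center runs.
    """
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")
    names = list(factor_names) if factor_names is not None else ["X1", "X2", "X3"]
    if len(names) != 3:
        raise ValueError("the Box-Behnken builder is specific to 3 factors")

    if n_center == 5:
        rows = list(_BBD17_ROWS)
    else:
        rows = []
        for i, j in combinations(range(3), 2):
            for a in (-1, +1):
                for b in (-1, +1):
                    r = [0, 0, 0]
                    r[i], r[j] = a, b
                    rows.append(tuple(r))
        rows.extend([(0, 0, 0)] * n_center)
    coded = pd.DataFrame(np.array(rows, dtype=int), columns=names,
                         index=pd.RangeIndex(1, len(rows) + 1, name="run"))
    return DesignMatrix(kind="bbd", coded=coded)


def code_levels(natural, specs: list[FactorSpec]) -> np.ndarray:
    """Map a vector of natural factor values to coded units, one spec per entry."""
    natural = np.asarray(natural, dtype=float)
    if natural.shape[-1] != len(specs):
        raise ValueError(f"expected {len(specs)} values, got {natural.shape[-1]}")
    return np.stack([s.code(natural[..., i]) for i, s in enumerate(specs)], axis=-1)


def uncode_levels(coded, specs: list[FactorSpec]) -> np.ndarray:
    """Inverse of :func:`code_levels`."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(specs):
        raise ValueError(f"expected {len(specs)} values, got {coded.shape[-1]}")
    return np.stack([s.uncode(coded[..., i]) for i, s in enumerate(specs)], axis=-1)
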