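"""Experimental designs for formulation screening and optimization.

Two designs are provided: the 12-run Plackett-Burman screening design
(two-level, resolution III, used to sieve many candidate factors) and the
inscribed central composite design (CCD) used to fit a full quadratic
response surface on the factors that survive screening.

Factors live on two scales.  The *natural* scale is what the experimenter
sets (e.g. stabilizer concentration in % w/v, ultrasonication time in min);
the *coded* scale places the design center at 0, factorial corners at +/-1
and axial points at +/-alpha.  An inscribed CCD maps the user's natural
bounds onto the axial points, so the factorial corners sit strictly inside
the experimental region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignTable",
    "make_inscribed_ccd",
    "make_plackett_burman",
    "to_coded",
    "to_natural",
    "DEFAULT_SNAP_TOLERANCE",
]

#: Relative tolerance used when snapping re-derived codes to canonical
#: levels {0, +/-1, +/-alpha}.  Published design tables print natural levels
#: rounded to 2-3 significant figures; a rounded level such as 12.9 min on a
#: step of 2.973 min/unit codes to 0.9754, i.e. 2.5% away from +1, so the
#: default must be a little wider than that rounding error.
DEFAULT_SNAP_TOLERANCE = 0.03

# First row of the standard N=12 Plackett-Burman cyclic generator.
_PB12_GENERATOR = (1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1)


@dataclass(frozen=True)
class Factor:
    """One experimental factor and its coding transform.

    ``natural = center + step * coded``; ``step`` is the natural-units width
    of one coded unit and ``alpha`` the coded distance of the axial points.
    """

    name: str
    units: str = ""
    center: float = 0.0
    step: float = 1.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.center) or not np.isfinite(self.step):
            raise ValueError(f"non-finite center/step for factor {self.name!r}")
        if self.step <= 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0")

    @classmethod
    def from_bounds(cls, name: str, low: float, high: float,
                    units: str = "", alpha: float = 1.0) -> "Factor":
        """Build a factor whose coded +/-alpha hits [low, high] exactly."""
        if not (np.isfinite(low) and np.isfinite(high)):
            raise ValueError(f"factor {name!r}: non-finite bounds")
        if low >= high:
            raise ValueError(f"factor {name!r}: low must be < high")
        center = (low + high) / 2.0
        step = (high - low) / (2.0 * alpha)
        return cls(name=name, units=units, center=center, step=step, alpha=alpha)

    def to_natural(self, coded: float) -> float:
        return self.center + self.step * float(coded)

    def to_coded(self, natural: float,
                 snap_tolerance: float = DEFAULT_SNAP_TOLERANCE) -> float:
        return to_coded(self, natural, snap_tolerance)


def to_natural(factor: Factor, coded: float) -> float:
    """Natural level at a coded value: ``center + step * coded``."""
    return factor.to_natural(coded)


def to_coded(factor: Factor, natural: float,
             snap_tolerance: float = DEFAULT_SNAP_TOLERANCE) -> float:
    """Code a natural level, snapping to canonical CCD levels.

    The raw code is ``(natural - center) / step``.  If it falls within
    ``snap_tolerance`` (relative; absolute for the center) of a canonical
    level in {0, -1, +1, -alpha, +alpha} the canonical value is returned
    exactly, so that designs re-read from rounded printed tables regain
    their exact coded structure.
    """
    if snap_tolerance < 0:
        raise ValueError("snap_tolerance must be >= 0")
    raw = (float(natural) - factor.center) / factor.step
    if abs(raw) <= snap_tolerance:
        return 0.0
    for canon in (-1.0, 1.0, -factor.alpha, factor.alpha):
        if abs(raw - canon) <= snap_tolerance * abs(canon):
            return canon
    return raw


@dataclass
class DesignTable:
    """An ordered table of design runs on coded and natural scales.

    ``coded`` is an (n_runs, n_factors) array; ``point_type`` labels each
    run as factorial / axial / center / screening.  ``replicate_groups``
    partitions run indices by identical coded rows and feeds the pure-error
    line of the lack-of-fit ANOVA.
    """

    factors: list[Factor]
    coded: np.ndarray
    point_type: list[str]
    std_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        if self.coded.ndim != 2 or self.coded.shape[1] != len(self.factors):
            raise ValueError("coded matrix shape does not match factors")
        if len(self.point_type) != self.n_runs:
            raise ValueError("point_type length does not match runs")
        if self.std_order is None:
            self.std_order = np.arange(1, self.n_runs + 1)
        self.std_order = np.asarray(self.std_order, dtype=int)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def natural(self) -> np.ndarray:
        centers = np.array([f.center for f in self.factors])
        steps = np.array([f.step for f in self.factors])
        return centers + steps * self.coded

    @property
    def replicate_groups(self) -> list[list[int]]:
        groups: dict[tuple, list[int]] = {}
        for i, row in enumerate(np.round(self.coded, 10)):
            groups.setdefault(tuple(row), []).append(i)
        return list(groups.values())

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: std_order, point_type, then coded/natural columns."""
        data: dict[str, object] = {
            "std_order": self.std_order,
            "point_type": self.point_type,
        }
        nat = self.natural
        for j, f in enumerate(self.factors):
            data[f"{f.name}.coded"] = self.coded[:, j]
            data[f"{f.name}.natural"] = nat[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   factors: list[Factor] | None = None,
                   snap_tolerance: float = DEFAULT_SNAP_TOLERANCE) -> "DesignTable":
        """Rebuild a design from its tabular form.

        If ``.coded`` columns are present they are used directly; otherwise
        natural columns are re-coded through each factor's transform with
        snapping (``factors`` is then required).
        """
        names = [c[:-6] for c in frame.columns if c.endswith(".coded")]
        if names and factors is None:
            raise ValueError("factors are required to rebuild a design")
        if not names:
            if factors is None:
                raise ValueError("factors are required to re-code natural levels")
            names = [f.name for f in factors]
        fmap = {f.name: f for f in (factors or [])}
        cols = []
        for name in names:
            coded_col = f"{name}.coded"
            if coded_col in frame.columns:
                cols.append(frame[coded_col].to_numpy(dtype=float))
            else:
                f = fmap[name]
                cols.append(np.array([
                    to_coded(f, v, snap_tolerance)
                    for v in frame[f"{name}.natural"].to_numpy(dtype=float)
                ]))
        coded = np.column_stack(cols)
        point_type = (list(frame["point_type"]) if "point_type" in frame.columns
                      else _classify_points(coded, [fmap[n].alpha for n in names]))
        std = (frame["std_order"].to_numpy(dtype=int)
               if "std_order" in frame.columns else None)
        return cls(factors=[fmap[n] for n in names], coded=coded,
                   point_type=point_type, std_order=std)

    @classmethod
    def from_csv(cls, path, factors: list[Factor] | None = None,
                 snap_tolerance: float = DEFAULT_SNAP_TOLERANCE) -> "DesignTable":
        return cls.from_frame(pd.read_csv(path), factors, snap_tolerance)


def _classify_points(coded: np.ndarray, alphas: list[float]) -> list[str]:
    types = []
    for row in coded:
        nz = np.nonzero(np.abs(row) > 1e-12)[0]
        if len(nz) == 0:
            types.append("center")
        elif len(nz) == 1 and abs(abs(row[nz[0]]) - alphas[nz[0]]) < 1e-9:
            types.append("axial")
        else:
            types.append("factorial")
    return types


def make_inscribed_ccd(factors_with_bounds, n_center: int = 6,
                       alpha="rotatable") -> DesignTable:
    """Build an inscribed central composite design.

    Parameters
    ----------
    factors_with_bounds
        Sequence of ``(name, low, high)`` or ``(name, low, high, units)``;
        the natural bounds are hit exactly by the axial points.
    n_center
        Number of replicated center runs appended after the axial block.
    alpha
        Axial distance in coded units, or ``"rotatable"`` for 2**(k/4).

    Runs are ordered in the conventional standard order: the 2**k factorial
    corners in Yates order, then the 2k axial points in factor order (low
    before high), then the center replicates.
    """
    k = len(factors_with_bounds)
    if k < 2:
        raise ValueError("a CCD needs at least 2 factors")
    if k > 12:
        raise ValueError(f"{k} factors: full factorial block too large (max 12)")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")
    a = 2.0 ** (k / 4.0) if alpha == "rotatable" else float(alpha)
    if not a > 1.0:
        raise ValueError("alpha must be > 1")

    factors = []
    for spec in factors_with_bounds:
        name, low, high = spec[0], float(spec[1]), float(spec[2])
        units = spec[3] if len(spec) > 3 else ""
        factors.append(Factor.from_bounds(name, low, high, units=units, alpha=a))

    # Yates standard order: the first factor alternates fastest.
    rows: list[list[float]] = [
        [(-1.0, 1.0)[(i >> j) & 1] for j in range(k)] for i in range(2 ** k)
    ]
    types: list[str] = ["factorial"] * 2 ** k
    for j in range(k):
        for sign in (-1.0, 1.0):
            row = [0.0] * k
            row[j] = sign * a
            rows.append(row)
            types.append("axial")
    for _ in range(n_center):
        rows.append([0.0] * k)
        types.append("center")
    return DesignTable(factors=factors, coded=np.array(rows), point_type=types)


def make_plackett_burman(n_factors: int, n_center: int = 0) -> DesignTable:
    """Build the 12-run Plackett-Burman two-level screening design.

    The 11 columns are generated by cyclic rotation of the standard N=12
    generator row plus a final all-minus run.  The first ``n_factors``
    columns are assigned to real factors; the remaining columns are kept as
    dummy columns (their apparent effects estimate error in screening
    analyses).  ``n_center`` all-zero center runs are appended.
    """
    if not (2 <= n_factors <= 11):
        raise ValueError("n_factors must be between 2 and 11")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")
    gen = np.array(_PB12_GENERATOR, dtype=float)
    rows = [np.roll(gen, i) for i in range(11)]
    rows.append(-np.ones(11))
    coded = np.array(rows)
    if n_center:
        coded = np.vstack([coded, np.zeros((n_center, 11))])
    names = [f"X{i + 1}" for i in range(n_factors)]
    names += [f"dummy{i + 1}" for i in range(11 - n_factors)]
    factors = [Factor(name=n, center=0.0, step=1.0, alpha=1.0) for n in names]
    types = ["screening"] * 12 + ["center"] * n_center
    return DesignTable(factors=factors, coded=coded, point_type=types)
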