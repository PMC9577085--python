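"""Polynomial response-surface modelling on coded factors.

The central object is :class:`ResponseSurfaceModel`, a statsmodels-style
model built from a :class:`~nanopk.doe.DesignTable` and a response vector.
``fit()`` returns :class:`RSMResults`, which carries the coded-scale
coefficients, the designed-experiment ANOVA table with its lack-of-fit /
pure-error partition, the R-squared family (ordinary, adjusted, PRESS-based
predicted), per-run residuals and leverages, and a ``summary()`` table.
Hierarchy-preserving backward elimination (``reduce``) and single-response
desirability optimization (``optimize``) hang off the results object.

The ANOVA follows the conventions of designed-experiment software:

* per-term partial (Type III) sums of squares, ``beta_j**2 / [(X'X)^-1]_jj``;
* model SS = corrected total SS - residual SS;
* pure error from replicate groups (runs with identical coded rows), and
  lack of fit as the remainder of the residual;
* F ratios against residual MS (terms, model) or pure-error MS (lack of fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .doe import DesignTable

__all__ = [
    "Term",
    "full_quadratic",
    "build_model_matrix",
    "ResponseSurfaceModel",
    "RSMResults",
    "OptimizationResult",
]


@dataclass(frozen=True, order=True)
class Term:
    """One term of a polynomial response-surface model.

    ``kind`` is one of ``intercept``, ``linear``, ``interaction``,
    ``quadratic``; ``i`` and ``j`` are 0-based factor indices (``i < j``
    for interactions).  The ordering (intercept < linear < interaction <
    quadratic, then by factor index) is the deterministic tie-break used in
    backward elimination.
    """

    rank: int
    i: int
    j: int
    kind: str

    @classmethod
    def intercept(cls) -> "Term":
        return cls(0, -1, -1, "intercept")

    @classmethod
    def linear(cls, i: int) -> "Term":
        return cls(1, i, -1, "linear")

    @classmethod
    def interaction(cls, i: int, j: int) -> "Term":
        if not i < j:
            raise ValueError("interaction requires i < j")
        return cls(2, i, j, "interaction")

    @classmethod
    def quadratic(cls, i: int) -> "Term":
        return cls(3, i, -1, "quadratic")

    def label(self, names: list[str] | None = None) -> str:
        def nm(idx: int) -> str:
            return names[idx] if names else f"x{idx + 1}"

        if self.kind == "intercept":
            return "Intercept"
        if self.kind == "linear":
            return nm(self.i)
        if self.kind == "interaction":
            return f"{nm(self.i)}:{nm(self.j)}"
        return f"{nm(self.i)}^2"

    def involves(self, idx: int) -> bool:
        return idx in (self.i, self.j)

    def evaluate(self, coded: np.ndarray) -> np.ndarray:
        """Evaluate the term columnwise on an (n, k) coded matrix."""
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        if self.kind == "intercept":
            return np.ones(coded.shape[0])
        if self.kind == "linear":
            return coded[:, self.i]
        if self.kind == "interaction":
            return coded[:, self.i] * coded[:, self.j]
        return coded[:, self.i] ** 2


def full_quadratic(k: int) -> list[Term]:
    """The full second-order model in k factors: 1 + k + C(k,2) + k terms."""
    terms = [Term.intercept()]
    terms += [Term.linear(i) for i in range(k)]
    terms += [Term.interaction(i, j) for i in range(k) for j in range(i + 1, k)]
    terms += [Term.quadratic(i) for i in range(k)]
    return terms


def _normalize_terms(terms, k: int) -> list[Term]:
    out = [t for t in terms]
    if len(set(out)) != len(out):
        raise ValueError("duplicate terms in model")
    for t in out:
        for idx in (t.i, t.j):
            if idx >= k:
                raise ValueError(f"term {t.label()} references factor {idx} "
                                 f"but the design has only {k}")
    if Term.intercept() not in out:
        out = [Term.intercept()] + out
    return out


def build_model_matrix(design: DesignTable, terms: list[Term]) -> np.ndarray:
    """One column per term, evaluated on the design's coded levels."""
    terms = _normalize_terms(terms, design.n_factors)
    return np.column_stack([t.evaluate(design.coded) for t in terms])


class ResponseSurfaceModel:
    """OLS polynomial response-surface model on coded factor levels.

    Parameters
    ----------
    design
        The experimental design (provides coded levels, factor transforms
        and replicate groups).
    response
        One observed response per run, in design order.
    terms
        Model terms; the intercept is added if missing.  Defaults to the
        full quadratic in all design factors.
    """

    def __init__(self, design: DesignTable, response, terms=None,
                 response_name: str = "response"):
        self.design = design
        y = np.asarray(response, dtype=float)
        if y.ndim != 1 or y.size != design.n_runs:
            raise ValueError(
                f"response length {y.size} does not match {design.n_runs} runs")
        self.response = y
        self.response_name = response_name
        self.terms = _normalize_terms(
            terms if terms is not None else full_quadratic(design.n_factors),
            design.n_factors)

    @classmethod
    def from_dataframe(cls, design: DesignTable, data: pd.DataFrame,
                       response: str, terms=None) -> "ResponseSurfaceModel":
        """Build from a design plus a response table keyed by ``std_order``."""
        if "std_order" not in data.columns:
            raise ValueError("response table must carry a std_order column")
        keyed = data.set_index("std_order")[response]
        missing = [s for s in design.std_order if s not in keyed.index]
        if missing:
            raise ValueError(f"response table lacks std_order rows: {missing}")
        y = keyed.loc[design.std_order].to_numpy(dtype=float)
        return cls(design, y, terms=terms, response_name=response)

    @property
    def exog(self) -> np.ndarray:
        return build_model_matrix(self.design, self.terms)

    def fit(self) -> "RSMResults":
        X = self.exog
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            labels = [t.label(self._factor_names()) for t in self.terms]
            raise np.linalg.LinAlgError(
                f"model matrix is rank deficient (rank {rank} < {X.shape[1]} "
                f"columns); terms: {labels}")
        ols = sm.OLS(self.response, X).fit()
        return RSMResults(self, ols)

    def _factor_names(self) -> list[str]:
        return [f.name for f in self.design.factors]


class RSMResults:
    """Fitted response-surface model: coefficients, ANOVA, diagnostics."""

    def __init__(self, model: ResponseSurfaceModel, ols):
        self.model = model
        self._ols = ols
        self.terms = model.terms
        self.params = pd.Series(
            ols.params, index=[t.label(model._factor_names()) for t in model.terms])
        self.residuals = np.asarray(ols.resid)
        X = model.exog
        self._xtx_inv = np.linalg.inv(X.T @ X)
        self.leverage = np.einsum("ij,jk,ik->i", X, self._xtx_inv, X)

    # -- basic quantities -------------------------------------------------
    @property
    def nobs(self) -> int:
        return self.model.design.n_runs

    @property
    def df_resid(self) -> int:
        return self.nobs - len(self.terms)

    @property
    def ss_total(self) -> float:
        y = self.model.response
        return float(((y - y.mean()) ** 2).sum())

    @property
    def ss_resid(self) -> float:
        return float((self.residuals ** 2).sum())

    @property
    def ss_model(self) -> float:
        return self.ss_total - self.ss_resid

    # -- R-squared family -------------------------------------------------
    @property
    def r2(self) -> float:
        return 1.0 - self.ss_resid / self.ss_total

    @property
    def adjusted_r2(self) -> float:
        n, p = self.nobs, len(self.terms)
        return 1.0 - (self.ss_resid / (n - p)) / (self.ss_total / (n - 1))

    @property
    def press(self) -> float:
        """Predicted residual sum of squares (leave-one-out, via leverage)."""
        if np.any(self.leverage >= 1.0 - 1e-12):
            raise ZeroDivisionError(
                "a run has leverage 1: PRESS is undefined (the run determines "
                "its own prediction)")
        return float(((self.residuals / (1.0 - self.leverage)) ** 2).sum())

    @property
    def predicted_r2(self) -> float:
        return 1.0 - self.press / self.ss_total

    def r2_diagnostics(self) -> tuple[float, float, float, float]:
        return self.r2, self.adjusted_r2, self.predicted_r2, self.press

    # -- ANOVA ------------------------------------------------------------
    def anova(self) -> pd.DataFrame:
        """Designed-experiment ANOVA with lack-of-fit partition.

        Rows: model, each non-intercept term (partial SS), residual,
        lack_of_fit, pure_error, total.  Lack-of-fit rows are NaN when the
        design has no replicate group of size >= 2 (undefined, not zero).
        """
        names = self.model._factor_names()
        dfres = self.df_resid
        # numpy scalar so a saturated or perfect fit yields inf/nan, not a
        # raised ZeroDivisionError
        msres = np.float64(self.ss_resid) / dfres if dfres > 0 else np.float64("nan")
        rows = []

        df_model = len(self.terms) - 1
        f_model = (np.float64(self.ss_model) / df_model) / msres \
            if df_model > 0 else np.nan
        p_model = scipy.stats.f.sf(f_model, df_model, dfres) if df_model > 0 else np.nan
        rows.append(("model", self.ss_model, df_model,
                     self.ss_model / df_model if df_model else np.nan,
                     f_model, p_model))

        for j, t in enumerate(self.terms):
            if t.kind == "intercept":
                continue
            ss = self.params.iloc[j] ** 2 / self._xtx_inv[j, j]
            f = np.float64(ss) / msres
            rows.append((t.label(names), ss, 1, ss, f,
                         scipy.stats.f.sf(f, 1, dfres)))

        rows.append(("residual", self.ss_resid, dfres, msres, np.nan, np.nan))

        groups = [g for g in self.model.design.replicate_groups if len(g) > 1]
        if groups:
            y = self.model.response
            ss_pe = sum(float(((y[g] - y[g].mean()) ** 2).sum())
                        for g in (np.array(g) for g in groups))
            df_pe = sum(len(g) - 1 for g in groups)
            ss_lof = self.ss_resid - ss_pe
            df_lof = dfres - df_pe
            if df_lof > 0 and df_pe > 0:
                with np.errstate(divide="ignore", invalid="ignore"):
                    f_lof = (np.float64(ss_lof) / df_lof) / (ss_pe / df_pe)
                p_lof = scipy.stats.f.sf(f_lof, df_lof, df_pe)
            else:
                f_lof = p_lof = np.nan
            rows.append(("lack_of_fit", ss_lof, df_lof,
                         ss_lof / df_lof if df_lof else np.nan, f_lof, p_lof))
            rows.append(("pure_error", ss_pe, df_pe,
                         ss_pe / df_pe if df_pe else np.nan, np.nan, np.nan))
        else:
            rows.append(("lack_of_fit", np.nan, np.nan, np.nan, np.nan, np.nan))
            rows.append(("pure_error", np.nan, np.nan, np.nan, np.nan, np.nan))

        rows.append(("total", self.ss_total, self.nobs - 1, np.nan, np.nan, np.nan))
        return pd.DataFrame(
            rows, columns=["source", "sum_of_squares", "df", "mean_square",
                           "F", "p"]).set_index("source")

    # -- prediction -------------------------------------------------------
    def predict(self, coded_point) -> float | np.ndarray:
        """Evaluate the fitted polynomial at coded point(s)."""
        pt = np.atleast_2d(np.asarray(coded_point, dtype=float))
        if pt.shape[1] != self.model.design.n_factors:
            raise ValueError("point dimension does not match the design")
        M = np.column_stack([t.evaluate(pt) for t in self.terms])
        out = M @ self.params.to_numpy()
        return float(out[0]) if np.asarray(coded_point).ndim == 1 else out

    def equation(self, decimals: int = 2) -> str:
        """The fitted model as a human-readable coded-scale equation."""
        names = self.model._factor_names()
        parts = [f"{self.params.iloc[0]:.{decimals}f}"]
        for j, t in enumerate(self.terms):
            if t.kind == "intercept":
                continue
            b = self.params.iloc[j]
            parts.append(f"{'+' if b >= 0 else '-'} {abs(b):.{decimals}f}*"
                         f"{t.label(names)}")
        return f"{self.model.response_name} = " + " ".join(parts)

    # -- model reduction --------------------------------------------------
    def reduce(self, alpha_keep: float = 0.05) -> "RSMResults":
        """Backward elimination preserving model hierarchy.

        Iteratively refits after dropping the non-intercept term with the
        largest partial-F p-value above ``alpha_keep``; a linear term is
        never dropped while its quadratic, or any interaction containing
        its factor, remains.  Ties are broken by term order (linear <
        interaction < quadratic, then factor index).
        """
        current = self
        while True:
            anova = current.anova()
            names = current.model._factor_names()
            droppable = []
            for t in current.terms:
                if t.kind == "intercept":
                    continue
                if t.kind == "linear" and any(
                        o is not t and o.kind != "intercept" and o.involves(t.i)
                        and o.kind in ("interaction", "quadratic")
                        for o in current.terms):
                    continue  # hierarchy: keep supporting linear terms
                droppable.append((anova.loc[t.label(names), "p"], t))
            over = [(p, t) for p, t in droppable if p > alpha_keep]
            if not over:
                return current
            # max p; ties broken by term ordering (reversed so the "latest"
            # term in canonical order goes first among exact ties)
            worst = max(over, key=lambda pt: (pt[0], pt[1]))[1]
            new_terms = [t for t in current.terms if t != worst]
            current = ResponseSurfaceModel(
                current.model.design, current.model.response, new_terms,
                response_name=current.model.response_name).fit()

    # -- optimization -----------------------------------------------------
    def optimize(self, goal: str = "minimize", region=None, target=None,
                 exponent: float = 1.0, n_grid: int = 21) -> "OptimizationResult":
        """Locate optimal factor settings by desirability maximization.

        A Derringer-Suich desirability transform is applied to the model
        prediction: a one-sided ramp for ``minimize``/``maximize`` (anchored
        at the predicted min/max over the search region) or a two-sided tent
        for ``target``.  Desirability is maximized by dense grid search
        refined with a bounded local polish.

        ``region`` is a coded box as (k, 2) array of [low, high]; default is
        the factorial cube [-1, 1]^k.  Factors with no term in the model are
        fixed at the region center and flagged.
        """
        k = self.model.design.n_factors
        if goal not in ("minimize", "maximize", "target"):
            raise ValueError("goal must be minimize, maximize or target")
        if goal == "target" and target is None:
            raise ValueError("goal='target' requires a target value")
        region = (np.tile([-1.0, 1.0], (k, 1)) if region is None
                  else np.asarray(region, dtype=float).reshape(k, 2))
        if np.any(region[:, 0] > region[:, 1]):
            raise ValueError("empty search region")
        center = region.mean(axis=1)

        active = [i for i in range(k)
                  if any(t.involves(i) for t in self.terms if t.kind != "intercept")]
        inactive = [i for i in range(k) if i not in active]

        def full_point(sub: np.ndarray) -> np.ndarray:
            pt = center.copy()
            pt[active] = sub
            return pt

        # anchor the ramp on the predicted range over the region
        grids = [np.linspace(region[i, 0], region[i, 1], n_grid) for i in active]
        if active:
            mesh = np.meshgrid(*grids, indexing="ij")
            pts = np.column_stack([m.ravel() for m in mesh])
            allpts = np.tile(center, (pts.shape[0], 1))
            allpts[:, active] = pts
            preds = self.predict(allpts)
        else:
            allpts = center[None, :]
            preds = np.array([self.predict(center)])
        lo, hi = float(preds.min()), float(preds.max())
        span = hi - lo
        degenerate = not active or span <= 1e-12 * max(1.0, abs(hi))

        def desirability(y):
            y = np.asarray(y, dtype=float)
            if degenerate:
                return np.ones_like(y)
            if goal == "minimize":
                d = (hi - y) / span
            elif goal == "maximize":
                d = (y - lo) / span
            else:
                half = max(target - lo, hi - target)
                d = 1.0 - np.abs(y - target) / half if half > 0 else np.ones_like(y)
            return np.clip(d, 0.0, 1.0) ** exponent

        if degenerate:
            opt = center
        else:
            d = desirability(preds)
            best = allpts[int(np.argmax(d))]
            res = scipy.optimize.minimize(
                lambda s: -float(desirability(self.predict(full_point(s)))),
                best[active], bounds=[tuple(region[i]) for i in active],
                method="L-BFGS-B")
            opt = full_point(res.x)
        pred = float(self.predict(opt))
        nat = np.array([f.to_natural(c)
                        for f, c in zip(self.model.design.factors, opt)])
        return OptimizationResult(
            goal=goal, optimum_coded=opt, optimum_natural=nat,
            predicted_response=pred,
            desirability=float(desirability(np.array([pred]))[0]),
            search_region=region, degenerate=degenerate,
            unconstrained_factors=tuple(inactive))

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"Response-surface fit: {self.model.response_name} "
            f"({self.nobs} runs, {len(self.terms)} terms)",
            self.equation(),
            "",
            self.anova().to_string(
                float_format=lambda v: f"{v:.4g}", na_rep=""),
            "",
            f"R-squared           {self.r2:8.4f}",
            f"Adjusted R-squared  {self.adjusted_r2:8.4f}",
            f"Predicted R-squared {self.predicted_r2:8.4f}",
            f"PRESS               {self.press:8.4g}",
        ]
        return "\n".join(lines)


@dataclass
class OptimizationResult:
    """Outcome of desirability optimization over a coded box."""

    goal: str
    optimum_coded: np.ndarray
    optimum_natural: np.ndarray
    predicted_response: float
    desirability: float
    search_region: np.ndarray
    degenerate: bool = False
    unconstrained_factors: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (math.isnan(self.desirability)
                or 0.0 <= self.desirability <= 1.0):
            raise ValueError("desirability must lie in [0, 1]")
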