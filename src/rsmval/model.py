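"""Second-order response-surface model: OLS fit, ANOVA, adequacy diagnostics.

The response analysed here is the number of analytes (out of a 43-drug
antimicrobial panel) whose mean spike recovery falls in the compliance window
— a count, but modelled as a continuous response, as is standard in
response-surface methodology.  The model is the full second-order polynomial
in three coded factors,

    Y = b0 + bA*A + bB*B + bC*C + bAB*AB + bAC*AC + bBC*BC
        + bAA*A^2 + bBB*B^2 + bCC*C^2,

fitted by ordinary least squares on the coded Box-Behnken design.  The
variance decomposition is the classical DoE ANOVA: per-term Type-III (partial)
sums of squares beta_j^2 / [(X'X)^-1]_jj, a residual split into lack-of-fit
and pure error (the latter from replicated design points), and the adequacy
diagnostics R^2, adjusted R^2, PRESS/predicted R^2 and adequate precision.

Two entry points cover the two data situations:

* raw run data — ``ResponseSurfaceModel(design, y).fit()``;
* published aggregates only (coefficients plus residual and pure-error SS,
  the situation when reproducing a printed ANOVA table without the raw runs)
  — ``ResponseSurfaceResults.from_aggregates(...)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import MODEL_TERMS, DesignTable, model_matrix
from .exceptions import SingularDesignError

__all__ = [
    "QuadraticModel",
    "AnovaTable",
    "AdequacyStats",
    "ResponseSurfaceModel",
    "ResponseSurfaceResults",
    "fit_quadratic",
    "significance_flag",
]

_RANK_TOL = 1e-10  # relative singular-value cutoff for rank detection


def significance_flag(p: float) -> str:
    """DoE-style stars: ``**`` for p < 0.01, ``*`` for p < 0.05, else blank."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class QuadraticModel:
    """The 10 coefficients of the second-order surface, in coded units.

    ``linear``, ``interaction`` and ``quadratic`` follow the factor order
    A, B, C; interactions are ordered AB, AC, BC.
    """

    intercept: float
    linear: tuple[float, float, float]
    interaction: tuple[float, float, float]
    quadratic: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.params)):
            raise ValueError("all 10 coefficients must be finite")

    @classmethod
    def from_params(cls, params: Sequence[float]) -> "QuadraticModel":
        p = np.asarray(params, dtype=float)
        if p.shape != (10,):
            raise ValueError("expected 10 coefficients in MODEL_TERMS order")
        return cls(float(p[0]), tuple(p[1:4]), tuple(p[4:7]), tuple(p[7:10]))

    @property
    def params(self) -> np.ndarray:
        """Coefficients as a length-10 vector in MODEL_TERMS order."""
        return np.concatenate(
            [[self.intercept], self.linear, self.interaction, self.quadratic]
        )

    def predict(self, points: np.ndarray) -> np.ndarray | float:
        """Evaluate the polynomial at coded points (scalar for a single point)."""
        pts = np.asarray(points, dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite prediction point")
        out = model_matrix(pts) @ self.params
        return float(out[0]) if pts.ndim == 1 else out

    def gradient(self, point: np.ndarray) -> np.ndarray:
        """Gradient of the surface at a coded point."""
        x = np.asarray(point, dtype=float)
        return np.asarray(self.linear) + self.hessian() @ x

    def hessian(self) -> np.ndarray:
        """Constant Hessian: H_ii = 2*b_ii, H_ij = b_ij."""
        bab, bac, bbc = self.interaction
        h = np.array(
            [
                [2 * self.quadratic[0], bab, bac],
                [bab, 2 * self.quadratic[1], bbc],
                [bac, bbc, 2 * self.quadratic[2]],
            ]
        )
        return h

    def coef_series(self) -> pd.Series:
        return pd.Series(self.params, index=list(MODEL_TERMS))


class AnovaTable:
    """DoE ANOVA with per-term Type-III SS and the lack-of-fit split.

    Rows: Model, the nine terms, Residual, Lack of fit, Pure error, Cor total.
    Guarantees SS(Residual) = SS(LoF) + SS(PE), df likewise, and
    SS(Model) + SS(Residual) = SS(Cor total).
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        self._check()

    def _check(self) -> None:
        g = self.row
        res, lof, pe = g("Residual"), g("Lack of fit"), g("Pure error")
        tot, mod = g("Cor total"), g("Model")
        if lof is not None and pe is not None:
            assert abs(res["ss"] - lof["ss"] - pe["ss"]) <= 1e-8 * max(1.0, res["ss"])
            assert res["df"] == lof["df"] + pe["df"]
        assert abs(mod["ss"] + res["ss"] - tot["ss"]) <= 1e-6 * max(1.0, tot["ss"])
        if (self.frame["ss"] < -1e-12).any():
            raise ValueError("negative sum of squares")

    def row(self, term: str):
        m = self.frame[self.frame["term"] == term]
        return None if m.empty else m.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def to_string(self) -> str:
        out = self.frame.copy()
        out["p_value"] = [
            ""
            if not np.isfinite(p)
            else ("<0.0001" if p < 1e-4 else f"{p:.4f}")
            for p in out["p_value"]
        ]
        for col in ("ss", "ms", "F"):
            out[col] = [f"{v:.2f}" if np.isfinite(v) else "" for v in out[col]]
        return out.to_string(index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()


@dataclass(frozen=True)
class AdequacyStats:
    """Fit-adequacy diagnostics of the quadratic surface.

    ``pred_r2`` and ``press`` are None when only aggregate sums of squares are
    available (leave-one-out prediction needs the raw runs).
    ``adeq_precision`` is the signal-to-noise ratio (range of fitted values
    over the average prediction SD); values above 4 indicate the surface can
    be used to navigate the design space.
    """

    r2: float
    adj_r2: float
    adeq_precision: float
    pred_r2: float | None = None
    press: float | None = None


def _pure_error(design: DesignTable, y: np.ndarray) -> tuple[float, int]:
    """Pure-error SS and df from replicated design points (the centres)."""
    coded = design.coded()
    keys = [tuple(row) for row in np.round(coded, 12)]
    groups: dict[tuple, list[float]] = {}
    for k, yi in zip(keys, y):
        groups.setdefault(k, []).append(yi)
    ss = 0.0
    df = 0
    for vals in groups.values():
        if len(vals) > 1:
            v = np.asarray(vals)
            ss += float(np.sum((v - v.mean()) ** 2))
            df += len(vals) - 1
    return ss, df


class ResponseSurfaceModel:
    """Second-order response-surface model on a coded design.

    Parameters
    ----------
    design : DesignTable
        Coded run table (typically a Box-Behnken design).
    response : array-like
        Per-run response, here the compliant-analyte count; real values are
        permitted, must be finite and non-negative.

    Examples
    --------
    >>> from rsmval import generate_bbd, FactorSpec
    >>> specs = [FactorSpec("C18", 100, 300), FactorSpec("PSA", 100, 300),
    ...          FactorSpec("ZSep", 25, 75)]
    >>> design = generate_bbd(specs, n_center=5)
    >>> res = ResponseSurfaceModel(design, y).fit()        # doctest: +SKIP
    >>> res.anova()                                        # doctest: +SKIP
    """

    def __init__(self, design: DesignTable, response):
        y = np.asarray(response, dtype=float)
        if y.ndim != 1 or len(y) != len(design):
            raise ValueError(
                f"response length {y.size} does not match design ({len(design)} runs)"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if np.any(y < 0):
            raise ValueError("compliant-count response cannot be negative")
        if len(design) < 10:
            raise ValueError("need at least 10 runs to fit the 10-term model")
        self.design = design
        self.response = y

    def fit(self) -> "ResponseSurfaceResults":
        X = self.design.model_matrix()
        s = np.linalg.svd(X, compute_uv=False)
        if np.sum(s > _RANK_TOL * s[0]) < X.shape[1]:
            raise SingularDesignError(
                "model matrix is rank deficient; the design does not support "
                "the full second-order model"
            )
        # solve through the orthogonal (QR) factorisation, not normal equations
        q, r = np.linalg.qr(X)
        beta = np.linalg.solve(r, q.T @ self.response)
        fitted = X @ beta
        resid = self.response - fitted
        leverage = np.sum(q**2, axis=1)
        return ResponseSurfaceResults(
            model=QuadraticModel.from_params(beta),
            design=self.design,
            response=self.response,
            fitted=fitted,
            residuals=resid,
            leverage=leverage,
        )


def fit_quadratic(design: DesignTable, response) -> "ResponseSurfaceResults":
    """Functional alias for ``ResponseSurfaceModel(design, response).fit()``."""
    return ResponseSurfaceModel(design, response).fit()


class ResponseSurfaceResults:
    """Fitted surface plus everything derived from it.

    Built either from a raw fit (`ResponseSurfaceModel.fit`) or from published
    aggregates (`from_aggregates`).  In the aggregate case residuals, leverage
    and PRESS are unavailable and the corresponding attributes are None.
    """

    def __init__(
        self,
        model: QuadraticModel,
        design: DesignTable,
        response: np.ndarray | None = None,
        fitted: np.ndarray | None = None,
        residuals: np.ndarray | None = None,
        leverage: np.ndarray | None = None,
        residual_ss: float | None = None,
        df_resid: int | None = None,
        pure_error_ss: float | None = None,
        df_pure_error: int | None = None,
    ):
        self.model = model
        self.design = design
        self.response = response
        self.fitted = fitted if fitted is not None else model.predict(design.coded())
        self.residuals = residuals
        self.leverage = leverage
        n = len(design)
        p = len(MODEL_TERMS)
        if residuals is not None:
            self.ss_resid = float(np.sum(residuals**2))
            self.df_resid = n - p
            pe_ss, pe_df = _pure_error(design, response)
            self.ss_pure_error, self.df_pure_error = pe_ss, pe_df
        else:
            if residual_ss is None:
                raise ValueError("need either residuals or residual_ss")
            self.ss_resid = float(residual_ss)
            self.df_resid = n - p if df_resid is None else int(df_resid)
            self.ss_pure_error = pure_error_ss
            self.df_pure_error = df_pure_error
        if self.ss_pure_error is not None and self.ss_pure_error > self.ss_resid + 1e-9:
            raise ValueError("pure-error SS exceeds residual SS")

    # ---------------------------------------------------------------- alt ctor
    @classmethod
    def from_aggregates(
        cls,
        model: QuadraticModel,
        design: DesignTable,
        residual_ss: float,
        pure_error_ss: float | None = None,
        df_resid: int | None = None,
        df_pure_error: int | None = None,
    ) -> "ResponseSurfaceResults":
        """Rebuild results from published coefficients and aggregate SS.

        The per-term Type-III SS, the model SS and every F statistic are
        functions of the coefficients and the design alone, so a printed
        ANOVA table can be reproduced without the raw response.
        """
        if df_pure_error is None and pure_error_ss is not None:
            # replicate df implied by the design's repeated points
            _, df_pure_error = _pure_error(design, np.zeros(len(design)))
        return cls(
            model=model,
            design=design,
            residual_ss=residual_ss,
            df_resid=df_resid,
            pure_error_ss=pure_error_ss,
            df_pure_error=df_pure_error,
        )

    # ------------------------------------------------------------- quantities
    @property
    def params(self) -> pd.Series:
        return self.model.coef_series()

    @property
    def ms_resid(self) -> float:
        if self.df_resid <= 0:
            raise ZeroDivisionError("zero residual degrees of freedom: F undefined")
        return self.ss_resid / self.df_resid

    @property
    def ss_model(self) -> float:
        """Model SS = dispersion of the fitted values about their mean."""
        return float(np.sum((self.fitted - np.mean(self.fitted)) ** 2))

    @property
    def ss_total(self) -> float:
        if self.response is not None:
            return float(np.sum((self.response - np.mean(self.response)) ** 2))
        return self.ss_model + self.ss_resid

    def predict(self, points) -> np.ndarray | float:
        return self.model.predict(points)

    def term_ss(self) -> pd.Series:
        """Type-III (partial) SS per model term: beta_j^2 / [(X'X)^-1]_jj.

        On the BBD(3) coded design this evaluates to 8*beta^2 for linear
        terms, 4*beta^2 for interactions and beta^2/0.2375 for quadratics
        (with 5 centres).
        """
        X = self.design.model_matrix()
        cjj = np.diag(np.linalg.inv(X.T @ X))
        ss = self.model.params**2 / cjj
        return pd.Series(ss[1:], index=list(MODEL_TERMS[1:]))

    # ------------------------------------------------------------------ anova
    def anova(self) -> AnovaTable:
        """Full DoE ANOVA: model, per-term, residual, lack-of-fit, pure error."""
        ms_res = self.ms_resid
        rows = []

        ss_model = self.ss_model
        df_model = len(MODEL_TERMS) - 1
        f_model = (ss_model / df_model) / ms_res
        p_model = float(stats.f.sf(f_model, df_model, self.df_resid))
        rows.append(("Model", ss_model, df_model, ss_model / df_model, f_model, p_model))

        for term, ss in self.term_ss().items():
            f = ss / ms_res
            p = float(stats.f.sf(f, 1, self.df_resid))
            rows.append((term, ss, 1, ss, f, p))

        rows.append(("Residual", self.ss_resid, self.df_resid, ms_res, np.nan, np.nan))

        if self.ss_pure_error is not None and self.df_pure_error and self.df_pure_error > 0:
            ss_pe, df_pe = self.ss_pure_error, self.df_pure_error
            ss_lof = self.ss_resid - ss_pe
            df_lof = self.df_resid - df_pe
            ms_pe = ss_pe / df_pe
            if df_lof > 0 and ms_pe > 0:
                ms_lof = ss_lof / df_lof
                f_lof = ms_lof / ms_pe
                p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
            else:
                ms_lof, f_lof, p_lof = (ss_lof / df_lof if df_lof else np.nan, np.nan, np.nan)
            rows.append(("Lack of fit", ss_lof, df_lof, ms_lof, f_lof, p_lof))
            rows.append(("Pure error", ss_pe, df_pe, ms_pe, np.nan, np.nan))
        else:
            warnings.warn(
                "no replicated design points: lack of fit cannot be separated "
                "from pure error",
                stacklevel=2,
            )
            rows.append(("Lack of fit", self.ss_resid, self.df_resid, ms_res, np.nan, np.nan))
            rows.append(("Pure error", 0.0, 0, np.nan, np.nan, np.nan))

        rows.append(
            ("Cor total", ss_model + self.ss_resid, df_model + self.df_resid, np.nan, np.nan, np.nan)
        )

        frame = pd.DataFrame(rows, columns=["term", "ss", "df", "ms", "F", "p_value"])
        frame["flag"] = [
            significance_flag(p) if t not in ("Residual", "Pure error", "Cor total", "Lack of fit") else ""
            for t, p in zip(frame["term"], frame["p_value"])
        ]
        return AnovaTable(frame)

    # --------------------------------------------------------------- adequacy
    def press(self) -> float:
        """Prediction error sum of squares (leave-one-out), raw data only."""
        if self.residuals is None or self.leverage is None:
            raise ValueError("PRESS requires the raw response")
        if np.any(self.leverage >= 1 - 1e-12):
            raise ZeroDivisionError("a leverage of 1 makes PRESS undefined")
        return float(np.sum((self.residuals / (1 - self.leverage)) ** 2))

    def adequacy(self) -> AdequacyStats:
        ss_tot = self.ss_total
        n = len(self.design)
        p = len(MODEL_TERMS)
        df_tot = self.df_resid + (p - 1)
        r2 = 1 - self.ss_resid / ss_tot
        adj = 1 - (self.ss_resid / self.df_resid) / (ss_tot / df_tot)
        adeq = (np.max(self.fitted) - np.min(self.fitted)) / np.sqrt(
            p * self.ms_resid / n
        )
        press = pred = None
        if self.residuals is not None:
            press = self.press()
            pred = 1 - press / ss_tot
        return AdequacyStats(
            r2=float(r2),
            adj_r2=float(adj),
            adeq_precision=float(adeq),
            pred_r2=None if pred is None else float(pred),
            press=None if press is None else float(press),
        )

    # ---------------------------------------------------------------- summary
    def summary(self) -> str:
        """Human-readable report: coefficients, ANOVA and adequacy."""
        X = self.design.model_matrix()
        cjj = np.diag(np.linalg.inv(X.T @ X))
        se = np.sqrt(self.ms_resid * cjj)
        t = self.model.params / se
        pt = 2 * stats.t.sf(np.abs(t), self.df_resid)
        coef = pd.DataFrame(
            {
                "coef": self.model.params,
                "std err": se,
                "t": t,
                "P>|t|": pt,
            },
            index=list(MODEL_TERMS),
        )
        adq = self.adequacy()
        lines = [
            "Response-surface model (second-order, coded units)",
            "=" * 58,
            coef.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            self.anova().to_string(),
            "",
            f"R-squared            {adq.r2:.4f}",
            f"Adj. R-squared       {adq.adj_r2:.4f}",
        ]
        if adq.pred_r2 is not None:
            lines.append(f"Pred. R-squared      {adq.pred_r2:.4f}")
        lines.append(f"Adeq. precision      {adq.adeq_precision:.3f}")
        return "\n".join(lines)

    # ------------------------------------------------------------ convenience
    def optimize(self, **kwargs):
        """Maximise the fitted surface over the coded cube (see rsmval.optimize)."""
        from .optimize import optimize_in_cube

        return optimize_in_cube(self.model, specs=self.design.factors, **kwargs)

    def plot_surface(self, pair=(0, 1), fixed=0.0, ax=None, n=60):
        """Contour plot of the surface over one factor pair, third factor fixed."""
        import matplotlib.pyplot as plt

        i, j = pair
        k = ({0, 1, 2} - {i, j}).pop()
        g = np.linspace(-1, 1, n)
        gi, gj = np.meshgrid(g, g)
        pts = np.zeros((n * n, 3))
        pts[:, i], pts[:, j] = gi.ravel(), gj.ravel()
        pts[:, k] = fixed
        z = self.model.predict(pts).reshape(n, n)
        if ax is None:
            _, ax = plt.subplots()
        cs = ax.contourf(gi, gj, z, levels=20)
        ax.figure.colorbar(cs, ax=ax)
        names = self.design.factor_names
        ax.set_xlabel(f"{names[i]} (coded)")
        ax.set_ylabel(f"{names[j]} (coded)")
        return ax
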