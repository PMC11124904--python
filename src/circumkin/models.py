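"""Inferential stage over the long-format kinematic table.

Statsmodels-style model/results pairs for the four analysis questions:

* :class:`KinematicsLMM` — Gaussian linear mixed model (REML) with a random
  intercept per plant and an optional random slope for the experimental
  condition; Type-III Wald chi-square tests and Tukey-adjusted pairwise
  contrasts of estimated marginal means (EMMs).
* :class:`CrossIndexGAM` — Gaussian additive model with one penalized
  regression spline for a predictor index plus a ridge-penalized per-plant
  intercept, both smoothing parameters chosen by REML; reports the smooth's
  effective degrees of freedom (edf), an approximate F statistic and p.
* :class:`SwitchCountGLMM` — Poisson generalized linear mixed model (log
  link) for switch counts, random intercept per plant, fitted by Laplace
  approximation.
* :func:`bspline_curve` — descriptive least-squares B-spline fits with a
  fixed, small number of degrees of freedom.

All factors enter with sum-to-zero contrasts (required for the validity of
Type-III tests); responses and GAM predictors are z-scored by default, as
the kinematic indices are standardized before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
from scipy.interpolate import BSpline
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess2
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from ._design import Design, RankDeficientError, build_design
from .kinematics import standardize

__all__ = [
    "ModelSpec",
    "TypeIIITest",
    "ContrastResult",
    "KinematicsLMM",
    "KinematicsLMMResults",
    "CrossIndexGAM",
    "CrossIndexGAMResults",
    "SwitchCountGLMM",
    "SwitchCountGLMMResults",
    "BSplineCurve",
    "fit_lmm",
    "type3_wald",
    "pairwise_contrasts",
    "fit_gam_crossindex",
    "fit_switch_glmm",
    "bspline_curve",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a mixed model over the kinematic table."""

    response: str
    fixed: tuple[str, ...]
    random_intercept: str = "plant_id"
    random_slope: str | None = None
    family: str = "gaussian"  # "gaussian" | "poisson"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class TypeIIITest:
    """Type-III Wald chi-square test of one model term."""

    term: str
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise EMM contrast with familywise-adjusted p."""

    pair: str
    estimate: float
    se: float
    z: float
    p_adjusted: float


def _tukey_p(z: float, n_means: int) -> float:
    """Tukey (studentized-range) adjusted p for a pairwise z statistic.

    Asymptotic version (infinite denominator df), matching multiplicity
    adjustment over ``n_means`` marginal means.
    """
    if n_means < 2:
        raise ValueError("need at least two means")
    q = abs(z) * np.sqrt(2.0)
    return float(np.clip(scipy.stats.studentized_range.sf(q, n_means, 1e6), 0.0, 1.0))


class _FixedEffectsResults:
    """Shared machinery: Type-III tests and EMM contrasts off (params, cov)."""

    params: pd.Series
    cov_params: pd.DataFrame
    design: Design

    def type3(self, term: str, strict: bool = True) -> TypeIIITest:
        """Type-III Wald chi-square for one fixed term.

        ``chi2 = c' V^{-1} c`` over the term's coefficient block; valid
        under the sum-to-zero coding used to build the design.  A singular
        covariance block (e.g. after complete separation of a count cell)
        raises when ``strict``, otherwise yields a NaN test.
        """
        if term not in self.design.term_slices:
            raise KeyError(f"term {term!r} not in model (have {list(self.design.term_slices)})")
        idx = self.design.term_slices[term]
        c = self.params.to_numpy()[idx]
        V = self.cov_params.to_numpy()[np.ix_(idx, idx)]
        df = int(idx.size)
        bad = not np.all(np.isfinite(V)) or np.linalg.cond(V) > 1e12
        if not bad:
            try:
                sol = scipy.linalg.solve(V, c, assume_a="pos")
            except scipy.linalg.LinAlgError:
                bad = True
        if not bad:
            chi2 = float(c @ sol)
            bad = not np.isfinite(chi2) or chi2 < 0
        if bad:
            if strict:
                raise np.linalg.LinAlgError(f"singular covariance block for {term!r}")
            warnings.warn(f"singular covariance block for {term!r}; test is NaN", stacklevel=2)
            return TypeIIITest(term, float("nan"), df, float("nan"))
        return TypeIIITest(term, chi2, df, float(scipy.stats.chi2.sf(chi2, df)))

    def type3_table(self, strict: bool = False) -> pd.DataFrame:
        rows = [self.type3(t, strict=strict) for t in self.design.terms]
        return pd.DataFrame(
            {
                "term": [r.term for r in rows],
                "chi_square": [r.chi_square for r in rows],
                "df": [r.df for r in rows],
                "p_value": [r.p_value for r in rows],
            }
        )

    def emmeans(self, factors: Sequence[str]) -> pd.DataFrame:
        """Estimated marginal means over the cells of ``factors`` (equal
        weights over the levels of every other factor in the model)."""
        grid, L = self.design.emm_rows(list(factors))
        est = L @ self.params.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, self.cov_params.to_numpy(), L))
        out = grid.copy()
        out["emmean"] = est
        out["se"] = se
        return out

    def contrasts(self, factors: Sequence[str]) -> list[ContrastResult]:
        """All pairwise differences of the EMMs of ``factors``, z statistics
        from the fixed-effects covariance, Tukey-family adjustment."""
        grid, L = self.design.emm_rows(list(factors))
        k = len(grid)
        labels = [" ".join(str(v) for v in row) for row in grid.to_numpy()]
        V = self.cov_params.to_numpy()
        beta = self.params.to_numpy()
        results = []
        for i in range(k):
            for j in range(i + 1, k):
                l = L[i] - L[j]
                est = float(l @ beta)
                se = float(np.sqrt(l @ V @ l))
                if se == 0:
                    raise ZeroDivisionError(f"zero SE for contrast {labels[i]} - {labels[j]}")
                z = est / se
                results.append(
                    ContrastResult(
                        pair=f"{labels[i]} - {labels[j]}",
                        estimate=est,
                        se=se,
                        z=z,
                        p_adjusted=_tukey_p(z, k),
                    )
                )
        return results

    def contrast_table(self, factors: Sequence[str]) -> pd.DataFrame:
        rows = self.contrasts(factors)
        return pd.DataFrame(
            {
                "pair": [r.pair for r in rows],
                "estimate": [r.estimate for r in rows],
                "se": [r.se for r in rows],
                "z": [r.z for r in rows],
                "p_adjusted": [r.p_adjusted for r in rows],
            }
        )


# ---------------------------------------------------------------------------
# Gaussian LMM


def _mixedlm_usable(res) -> bool:
    """Whether a MixedLM fit produced a finite, well-scaled covariance."""
    try:
        bse = np.asarray(res.bse_fe, dtype=float)
        cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        return (
            np.all(np.isfinite(bse))
            and float(np.max(bse)) < 1e5
            and np.isfinite(res.llf)
            and np.min(np.linalg.eigvalsh(cov_re)) > 1e-7 * max(np.max(cov_re), 1e-10)
        )
    except Exception:
        return False


def _robust_mixedlm(y, X, groups, exog_re, reml):
    """Fit a MixedLM, cascading through optimizers when the variance sits
    on the boundary (where the default gradient optimizer can fail)."""
    last = None
    for method in (None, "powell", "nm"):
        try:
            model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
            res = model.fit(reml=reml) if method is None else model.fit(
                reml=reml, method=method
            )
        except np.linalg.LinAlgError:
            continue
        if last is None:
            last = res
        if _mixedlm_usable(res):
            return res, True
        last = res
    if last is None:
        raise np.linalg.LinAlgError("mixed-model fit failed with every optimizer")
    return last, False


class KinematicsLMM:
    """Gaussian mixed model for one kinematic index.

    ``response ~ fixed terms + (1 [+ condition] | plant)``, REML estimation.
    The response is z-scored over the rows entering the model unless
    ``scale_response=False``.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        response: str,
        fixed: Sequence[str] = ("condition", "phase", "condition:phase"),
        group: str = "plant_id",
        random_slope: str | None = "condition",
        scale_response: bool = True,
    ) -> None:
        cols = {response, group}
        for term in fixed:
            cols.update(term.split(":"))
        if random_slope is not None:
            cols.add(random_slope)
        data = table.dropna(subset=sorted(cols)).reset_index(drop=True)
        if data[group].nunique() < 2:
            raise ValueError("grouping factor needs at least 2 levels")
        self.table = data
        self.response = response
        self.fixed = list(fixed)
        self.group = group
        self.random_slope = random_slope
        self.scale_response = scale_response
        self.design = build_design(data, self.fixed)

    @classmethod
    def from_spec(cls, table: pd.DataFrame, spec: ModelSpec) -> "KinematicsLMM":
        if spec.family != "gaussian":
            raise ValueError("use SwitchCountGLMM for the poisson family")
        return cls(
            table,
            spec.response,
            fixed=spec.fixed,
            group=spec.random_intercept,
            random_slope=spec.random_slope,
        )

    def fit(self, reml: bool = True) -> "KinematicsLMMResults":
        y = self.table[self.response].to_numpy(dtype=float)
        if self.scale_response:
            y = standardize(y)
        X = self.design.matrix
        groups = self.table[self.group].to_numpy()
        if self.random_slope is not None:
            slope_design = build_design(
                self.table, [self.random_slope], check_rank=False
            )
            exog_re = slope_design.matrix  # intercept + coded slope columns
            re_names = slope_design.names
        else:
            exog_re = np.ones((len(y), 1))
            re_names = ["Intercept"]

        converged = True
        singular = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res, ok = _robust_mixedlm(y, X, groups, exog_re, reml)
            except np.linalg.LinAlgError:
                if exog_re.shape[1] == 1:
                    raise
                res, ok = None, False
            if (not ok) and exog_re.shape[1] > 1:
                # A random slope for a factor that is constant within every
                # plant (the between-plant condition) leaves the
                # intercept/slope split unidentified; the fit sits on a
                # likelihood ridge and its covariance is unusable.  Refit
                # with the random intercept only and flag the singularity.
                singular = True
                exog_re = exog_re[:, :1]
                re_names = re_names[:1]
                res, ok = _robust_mixedlm(y, X, groups, exog_re, reml)
            if not ok:
                converged = False
            for w in caught:
                if issubclass(w.category, ConvergenceWarning):
                    if "singular" in str(w.message).lower():
                        singular = True
        if not res.converged:
            converged = False
        cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        if np.min(np.linalg.eigvalsh(cov_re)) < 1e-8:
            singular = True

        k = X.shape[1]
        params = pd.Series(np.asarray(res.fe_params), index=self.design.names)
        cov_fe = pd.DataFrame(
            np.asarray(res.cov_params())[:k, :k],
            index=self.design.names,
            columns=self.design.names,
        )
        vc = {
            "residual_var": float(res.scale),
            "re_cov": pd.DataFrame(
                np.asarray(res.cov_re) * res.scale, index=re_names, columns=re_names
            ),
        }
        return KinematicsLMMResults(
            model=self,
            params=params,
            cov_params=cov_fe,
            variance_components=vc,
            loglike=float(res.llf),
            converged=converged,
            singular=singular,
            nobs=int(len(y)),
            _sm_results=res,
        )


@dataclass
class KinematicsLMMResults(_FixedEffectsResults):
    model: KinematicsLMM
    params: pd.Series
    cov_params: pd.DataFrame
    variance_components: dict
    loglike: float
    converged: bool
    singular: bool
    nobs: int
    _sm_results: object = field(repr=False, default=None)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def design(self) -> Design:  # type: ignore[override]
        return self.model.design

    def summary(self) -> str:
        lines = [
            f"Linear mixed model (REML), response: {self.model.response}",
            f"Groups: {self.model.group} "
            f"({self.model.table[self.model.group].nunique()}), nobs: {self.nobs}",
            f"Converged: {self.converged}"
            + ("  [singular random-effects covariance]" if self.singular else ""),
            "",
            "Fixed effects (sum-to-zero coding):",
        ]
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": self.params / self.bse}
        )
        lines.append(tab.to_string(float_format=lambda v: f"{v: .4f}"))
        lines += ["", "Type-III Wald tests:", self.type3_table().to_string(index=False)]
        rc = self.variance_components["re_cov"]
        lines += [
            "",
            f"Residual variance: {self.variance_components['residual_var']:.4f}",
            "Random-effects covariance:",
            rc.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.model.response,
            "params": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "type3": self.type3_table().to_dict(orient="records"),
            "residual_var": self.variance_components["residual_var"],
            "converged": self.converged,
            "singular": self.singular,
            "nobs": self.nobs,
        }


# ---------------------------------------------------------------------------
# Penalized-spline additive model (cross-index GAM)


def _bspline_basis(x: np.ndarray, k: int, degree: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """B-spline basis (n, k) with knots at quantiles of x."""
    n_interior = k - degree - 1
    if n_interior < 0:
        raise ValueError(f"basis size {k} too small for degree {degree}")
    xs = np.sort(np.unique(x))
    lo, hi = xs[0], xs[-1]
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(xs, qs)
    else:
        interior = np.empty(0)
    eps = 1e-8 * max(1.0, hi - lo)
    knots = np.concatenate(
        [np.full(degree + 1, lo - eps), interior, np.full(degree + 1, hi + eps)]
    )
    B = BSpline.design_matrix(x, knots, degree).toarray()
    return B, knots


class CrossIndexGAM:
    """Penalized-spline additive model between two kinematic indices.

    ``y = f(x) + controls + a_plant + e`` with ``f`` a cubic regression
    spline (basis dimension ``k``, second-difference penalty) and
    ``a_plant`` a ridge-penalized per-plant intercept (the smoothed random
    intercept).  Both smoothing parameters are selected by REML under the
    model's mixed-model representation.  ``y`` and ``x`` are z-scored by
    default.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        response: str,
        predictor: str,
        group: str = "plant_id",
        controls: Sequence[str] = ("condition", "phase"),
        k: int = 10,
        scale: bool = True,
    ) -> None:
        controls = [c for c in controls if c in table.columns]
        cols = sorted({response, predictor, group, *controls})
        data = table.dropna(subset=cols).reset_index(drop=True)
        self.table = data
        self.response = response
        self.predictor = predictor
        self.group = group
        self.controls = list(controls)
        self.scale = scale
        n_unique = data[predictor].nunique()
        if n_unique < k:
            warnings.warn(
                f"only {n_unique} unique predictor values; reducing basis from {k}",
                stacklevel=2,
            )
            k = max(4, n_unique)
        self.k = k

    def _matrices(self):
        data = self.table
        y = data[self.response].to_numpy(dtype=float)
        x = data[self.predictor].to_numpy(dtype=float)
        if self.scale:
            y = standardize(y)
            x = standardize(x)
        B, knots = _bspline_basis(x, self.k)
        # second-difference penalty; its null space (constant, linear) moves
        # to the unpenalized part as the intercept and the raw x column
        D = np.diff(np.eye(self.k), 2, axis=0)
        S = D.T @ D
        lam, U = np.linalg.eigh(S)
        pos = lam > 1e-8 * lam.max()
        T = U[:, pos] / np.sqrt(lam[pos])
        Zs = B @ T
        X_parts = [np.ones_like(x), x]
        names = ["Intercept", self.predictor]
        if self.controls:
            ctrl = build_design(data, self.controls)
            X_parts.append(ctrl.matrix[:, 1:])
            names += ctrl.names[1:]
        X = np.column_stack(X_parts)
        groups, g_idx = np.unique(data[self.group].to_numpy(), return_inverse=True)
        Zp = np.zeros((len(y), len(groups)))
        Zp[np.arange(len(y)), g_idx] = 1.0
        return y, x, X, names, Zs, Zp, knots, T

    def fit(self) -> "CrossIndexGAMResults":
        y, x, X, names, Zs, Zp, knots, T = self._matrices()
        n, p = X.shape
        qs, qp = Zs.shape[1], Zp.shape[1]
        Z = np.column_stack([Zs, Zp])
        ZtZ = Z.T @ Z
        Zty = Z.T @ y
        ZtX = Z.T @ X
        Xty = X.T @ y
        XtX = X.T @ X
        yty = float(y @ y)

        def neg2_reml(log_gamma: np.ndarray) -> float:
            g = np.exp(np.clip(log_gamma, -30, 30))
            gvec = np.concatenate([np.full(qs, g[0]), np.full(qp, g[1])])
            root = np.sqrt(gvec)
            M = np.eye(qs + qp) + (root[:, None] * ZtZ) * root[None, :]
            try:
                cM = scipy.linalg.cho_factor(M)
            except scipy.linalg.LinAlgError:
                return np.inf
            logdetM = 2.0 * np.sum(np.log(np.diag(cM[0])))
            # V0^{-1} A = A - Z G^{1/2} M^{-1} G^{1/2} Z' A  (Woodbury)
            W_y = scipy.linalg.cho_solve(cM, root * Zty)
            W_X = scipy.linalg.cho_solve(cM, root[:, None] * ZtX)
            A = XtX - ZtX.T @ (root[:, None] * W_X)
            b = Xty - ZtX.T @ (root * W_y)
            r = yty - Zty @ (root * W_y)
            try:
                cA = scipy.linalg.cho_factor(A)
            except scipy.linalg.LinAlgError:
                return np.inf
            logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))
            beta = scipy.linalg.cho_solve(cA, b)
            quad = max(r - b @ beta, 1e-12)
            sigma2 = quad / (n - p)
            return (n - p) * np.log(sigma2) + logdetM + logdetA

        best = None
        for start in ([0.0, 0.0], [5.0, 0.0], [-5.0, 0.0], [2.0, 2.0]):
            opt = scipy.optimize.minimize(
                neg2_reml, np.array(start), method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
            )
            if best is None or opt.fun < best.fun:
                best = opt
        g = np.exp(np.clip(best.x, -30.0, 30.0))

        # penalized least squares at the selected smoothing parameters
        C = np.column_stack([X, Z])
        pen = np.concatenate([np.zeros(p), np.full(qs, 1.0 / g[0]), np.full(qp, 1.0 / g[1])])
        CtC = C.T @ C
        H = CtC + np.diag(pen)
        theta = scipy.linalg.solve(H, C.T @ y, assume_a="pos")
        F = scipy.linalg.solve(H, CtC, assume_a="pos")
        edf_each = np.diag(F)
        # smooth edf: unpenalized linear x column plus the penalized wiggles
        edf_smooth = float(edf_each[1] + edf_each[p : p + qs].sum())
        edf_total = float(edf_each.sum())
        fitted = C @ theta
        rss1 = float(np.sum((y - fitted) ** 2))

        # Significance of the smooth: exact F test of the unpenalized spline
        # basis (linear column + wiggles) against the model without f(x),
        # holding the plant ridge at its selected smoothing.  The penalized
        # edf is reported alongside; using the unpenalized test keeps the
        # null distribution of p exact (uniform) in the Gaussian model.
        pen_p = np.full(qp, 1.0 / g[1])
        C0 = np.column_stack([X[:, [0]], X[:, 2:], Zp])
        H0 = C0.T @ C0 + np.diag(np.concatenate([np.zeros(p - 1), pen_p]))
        theta0 = scipy.linalg.solve(H0, C0.T @ y, assume_a="pos")
        rss0 = float(np.sum((y - C0 @ theta0) ** 2))
        C1 = np.column_stack([X, Zs, Zp])
        H1 = C1.T @ C1 + np.diag(np.concatenate([np.zeros(p + qs), pen_p]))
        theta1 = scipy.linalg.solve(H1, C1.T @ y, assume_a="pos")
        rss1u = float(np.sum((y - C1 @ theta1) ** 2))
        df_num = qs + 1
        df_den_u = max(n - (p + qs) - edf_each[p + qs :].sum(), 1.0)
        f_stat = max(rss0 - rss1u, 0.0) / df_num / (rss1u / df_den_u)
        p_value = float(scipy.stats.f.sf(f_stat, df_num, df_den_u))

        df_den = max(n - edf_total, 1.0)
        sigma2 = rss1 / df_den
        return CrossIndexGAMResults(
            model=self,
            edf=edf_smooth,
            edf_total=edf_total,
            edf_plant=float(edf_each[p + qs :].sum()),
            f_stat=float(f_stat),
            p_value=p_value,
            smoothing=dict(gamma_smooth=float(g[0]), gamma_plant=float(g[1])),
            sigma2=float(sigma2),
            coef=theta,
            fitted=fitted,
            _basis=(knots, T, p, qs, names),
            _xy=(x, y),
        )


@dataclass
class CrossIndexGAMResults:
    model: CrossIndexGAM
    edf: float
    edf_total: float
    edf_plant: float
    f_stat: float
    p_value: float
    smoothing: dict
    sigma2: float
    coef: np.ndarray
    fitted: np.ndarray
    _basis: tuple = field(repr=False, default=None)
    _xy: tuple = field(repr=False, default=None)

    def smooth_curve(self, x_new: np.ndarray) -> np.ndarray:
        """Evaluate the centered smooth f(x) on (standardized) x values."""
        knots, T, p, qs, _ = self._basis
        x_new = np.asarray(x_new, dtype=float)
        xc = np.clip(x_new, knots[3], knots[-4])
        B = BSpline.design_matrix(xc, knots, 3).toarray()
        return x_new * self.coef[1] + (B @ T) @ self.coef[p : p + qs]

    def summary(self) -> str:
        return (
            f"Additive model (REML), {self.model.response} ~ "
            f"s({self.model.predictor}) + {' + '.join(self.model.controls) or '1'} "
            f"+ s({self.model.group})\n"
            f"edf(smooth) = {self.edf:.2f}, F = {self.f_stat:.2f}, "
            f"p = {self.p_value:.3g}\n"
            f"edf(plant intercepts) = {self.edf_plant:.2f}, "
            f"sigma^2 = {self.sigma2:.4f}"
        )

    def to_dict(self) -> dict:
        return {
            "response": self.model.response,
            "predictor": self.model.predictor,
            "edf": self.edf,
            "edf_plant": self.edf_plant,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "smoothing": self.smoothing,
            "sigma2": self.sigma2,
        }


# ---------------------------------------------------------------------------
# Poisson GLMM (Laplace)


class SwitchCountGLMM:
    """Poisson mixed model for switch counts, log link, Laplace fit.

    ``count ~ fixed terms + (1 | plant)``; the per-group random intercept
    is integrated out with a Laplace approximation (the lme4 ``glmer``
    default, nAGQ = 1).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        response: str,
        fixed: Sequence[str],
        group: str = "plant_id",
    ) -> None:
        cols = {response, group}
        for term in fixed:
            cols.update(term.split(":"))
        data = table.dropna(subset=sorted(cols)).reset_index(drop=True)
        y = data[response].to_numpy()
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("counts must be nonnegative integers")
        self.table = data
        self.response = response
        self.fixed = list(fixed)
        self.group = group
        self.design = build_design(data, self.fixed)
        cell_terms = [t for t in self.fixed if ":" not in t]
        if cell_terms:
            cells = data.groupby(cell_terms, observed=True)[response].sum()
            self.all_zero_cells = [str(k) for k, v in cells.items() if v == 0]
        else:
            self.all_zero_cells = []

    def _neg_loglik(self, params: np.ndarray, X, y, group_idx, n_groups) -> float:
        beta, log_tau2 = params[:-1], params[-1]
        tau2 = np.exp(np.clip(log_tau2, -30, 30))
        eta0 = X @ beta
        nll = 0.0
        for i in range(n_groups):
            sel = group_idx == i
            e, yi = eta0[sel], y[sel]
            b = 0.0
            for _ in range(50):  # 1-D Newton for the conditional mode
                mu = np.exp(np.clip(e + b, -30, 30))
                g1 = np.sum(yi - mu) - b / tau2
                g2 = -np.sum(mu) - 1.0 / tau2
                step = g1 / g2
                b -= step
                if abs(step) < 1e-10:
                    break
            mu = np.exp(np.clip(e + b, -30, 30))
            ll = np.sum(yi * (e + b) - mu)
            nll -= ll - b * b / (2 * tau2) - 0.5 * np.log1p(tau2 * np.sum(mu))
        return nll

    def fit(self) -> "SwitchCountGLMMResults":
        if self.all_zero_cells:
            warnings.warn(
                f"all-zero count cells: {self.all_zero_cells}", stacklevel=2
            )
        X = self.design.matrix
        y = self.table[self.response].to_numpy(dtype=float)
        groups, group_idx = np.unique(self.table[self.group].to_numpy(), return_inverse=True)
        n_groups = len(groups)

        start_glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        x0 = np.concatenate([start_glm.params, [np.log(0.1)]])

        obj = lambda p: self._neg_loglik(p, X, y, group_idx, n_groups)
        opt = scipy.optimize.minimize(
            obj, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500}
        )
        if not opt.success:  # polish with Nelder-Mead if BFGS stalls
            opt2 = scipy.optimize.minimize(obj, opt.x, method="Nelder-Mead",
                                           options={"maxiter": 2000, "fatol": 1e-8})
            if opt2.fun <= opt.fun:
                opt = opt2
        hess = approx_hess2(opt.x, obj)
        try:
            cov_all = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov_all = np.linalg.pinv(hess)
        k = X.shape[1]
        params = pd.Series(opt.x[:k], index=self.design.names)
        cov = pd.DataFrame(cov_all[:k, :k], index=self.design.names, columns=self.design.names)
        return SwitchCountGLMMResults(
            model=self,
            params=params,
            cov_params=cov,
            tau2=float(np.exp(opt.x[-1])),
            loglike=float(-opt.fun),
            converged=bool(opt.success or np.isfinite(opt.fun)),
            nobs=int(len(y)),
        )


@dataclass
class SwitchCountGLMMResults(_FixedEffectsResults):
    model: SwitchCountGLMM
    params: pd.Series
    cov_params: pd.DataFrame
    tau2: float
    loglike: float
    converged: bool
    nobs: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def design(self) -> Design:  # type: ignore[override]
        return self.model.design

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": self.params / self.bse}
        )
        return (
            f"Poisson GLMM (Laplace), response: {self.model.response}, "
            f"nobs: {self.nobs}\n"
            f"Random-intercept variance: {self.tau2:.4f}\n\n"
            + tab.to_string(float_format=lambda v: f"{v: .4f}")
            + "\n\nType-III Wald tests:\n"
            + self.type3_table().to_string(index=False)
        )

    def to_dict(self) -> dict:
        return {
            "response": self.model.response,
            "params": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "tau2": self.tau2,
            "type3": self.type3_table().to_dict(orient="records"),
            "converged": self.converged,
            "nobs": self.nobs,
        }


# ---------------------------------------------------------------------------
# descriptive B-splines


@dataclass(frozen=True)
class BSplineCurve:
    """Least-squares cubic B-spline fit with few degrees of freedom."""

    knots: np.ndarray
    coef: np.ndarray  # intercept first, then basis coefficients
    df: int

    def __call__(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        B = BSpline.design_matrix(
            np.clip(x_new, self.knots[3] + 0, self.knots[-4] - 0), self.knots, 3
        ).toarray()[:, 1:]
        return self.coef[0] + B @ self.coef[1:]


def bspline_curve(x: np.ndarray, y: np.ndarray, df: int = 3) -> BSplineCurve:
    """Fit ``y`` on a cubic B-spline basis with ``df`` degrees of freedom.

    Mirrors the usual regression-spline parameterization: ``df`` basis
    columns (beyond the intercept), interior knots at quantiles when
    ``df > 3``.  Needs more points than ``df``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if df < 3:
        raise ValueError("df must be >= 3 for a cubic basis")
    if df >= x.size:
        raise ValueError(f"df={df} requires more than {df} points")
    B, knots = _bspline_basis(x, df + 1)
    A = np.column_stack([np.ones_like(x), B[:, 1:]])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return BSplineCurve(knots=knots, coef=coef, df=df)


# ---------------------------------------------------------------------------
# functional wrappers (spec surface)


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> KinematicsLMMResults:
    """Fit a Gaussian LMM described by ``spec`` (REML)."""
    return KinematicsLMM.from_spec(table, spec).fit()


def type3_wald(fit: _FixedEffectsResults, term: str) -> TypeIIITest:
    """Type-III Wald chi-square test of ``term`` on a fitted model."""
    return fit.type3(term)


def pairwise_contrasts(
    fit: _FixedEffectsResults, factors: Sequence[str]
) -> list[ContrastResult]:
    """Tukey-adjusted pairwise contrasts of the EMMs of ``factors``."""
    return fit.contrasts(factors)


def fit_gam_crossindex(
    table: pd.DataFrame, response: str, predictor: str, **kwargs
) -> CrossIndexGAMResults:
    """REML additive model of one kinematic index on another."""
    return CrossIndexGAM(table, response, predictor, **kwargs).fit()


def fit_switch_glmm(
    table: pd.DataFrame,
    response: str = "n_switches",
    fixed: Sequence[str] = (
        "condition",
        "leaf_rank",
        "switch_direction",
        "condition:leaf_rank",
        "condition:switch_direction",
        "leaf_rank:switch_direction",
    ),
    group: str = "plant_id",
) -> SwitchCountGLMMResults:
    """Poisson GLMM (Laplace) for direction-switch counts."""
    return SwitchCountGLMM(table, response, fixed, group).fit()
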