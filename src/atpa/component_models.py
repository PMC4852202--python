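"""Component regression models for daily active-travel behavior.

Three model families are estimated from cleaned travel-diary data, per
transportation mode (walk / bike) and stratum (working / non-working
adults):

* zero-inflated Poisson (ZIP) models for daily trip counts, mixing a
  logit-governed point mass at zero (probability ``pi``) with a Poisson
  count law ``lambda = exp(x'beta)``;
* multinomial logit models for trip purpose, softmax-normalized relative
  to a declared base outcome;
* log-link estimating-equation (GEE) models for trip duration, with
  trips clustered within persons and an exchangeable working correlation.

The module also provides the Vuong and Lagrange-multiplier specification
tests used to select the zero-inflated form, backward elimination at the
10% level with always-kept controls, and average marginal effects with
delta-method standard errors.

Estimation is delegated to statsmodels; design matrices are built with
patsy formulas so categorical coding and interactions are deterministic
and reproducible at prediction time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
from scipy.special import expit, gammaln
from statsmodels.api import GEE, MNLogit, Poisson
from statsmodels.discrete.count_model import ZeroInflatedPoisson
from statsmodels.genmod.cov_struct import Exchangeable, Independence
from statsmodels.genmod.families import Poisson as PoissonFamily


class ConvergenceError(RuntimeError):
    """Raised when a likelihood maximization fails to converge."""


# ---------------------------------------------------------------------------
# Declarative model designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """One formula term with a selection role.

    ``candidate`` terms are subject to backward elimination; ``control``
    and ``fixed_effect`` terms are always kept.
    """

    expr: str
    role: str = "candidate"

    def __post_init__(self):
        if self.role not in ("candidate", "control", "fixed_effect"):
            raise ValueError(f"unknown term role {self.role!r}")


def cat(variable: str, reference: str) -> str:
    """Patsy expression for a categorical with an explicit reference level."""
    return f"C({variable}, Treatment({reference!r}))"


@dataclass(frozen=True)
class ModelDesign:
    """Response plus an ordered list of terms; builds patsy design matrices."""

    response: str
    terms: tuple[Term, ...]

    def __init__(self, response: str, terms: Sequence[Term | str]):
        object.__setattr__(self, "response", response)
        object.__setattr__(
            self,
            "terms",
            tuple(t if isinstance(t, Term) else Term(t) for t in terms),
        )

    @property
    def formula(self) -> str:
        return " + ".join(t.expr for t in self.terms) if self.terms else "1"

    def matrix(self, data: pd.DataFrame) -> pd.DataFrame:
        """Model matrix for ``data``; column order is deterministic."""
        return patsy.dmatrix(
            self.formula, data, return_type="dataframe", NA_action="raise"
        )

    def candidates(self) -> list[str]:
        return [t.expr for t in self.terms if t.role == "candidate"]

    def drop(self, expr: str) -> "ModelDesign":
        kept = [t for t in self.terms if t.expr != expr]
        if len(kept) == len(self.terms):
            raise ValueError(f"term {expr!r} not in design")
        return ModelDesign(self.response, kept)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": [[t.expr, t.role] for t in self.terms],
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelDesign":
        return ModelDesign(d["response"], [Term(e, r) for e, r in d["terms"]])


def predict_matrix(design_info, data: pd.DataFrame) -> pd.DataFrame:
    """Rebuild a model matrix for new data under a fitted design."""
    (m,) = patsy.build_design_matrices(
        [design_info], data, return_type="dataframe", NA_action="raise"
    )
    return m


# ---------------------------------------------------------------------------
# Friendly coefficient keys <-> patsy column names
# ---------------------------------------------------------------------------

def _token_matches_part(part: str, token: str) -> bool:
    if "=" in token:
        var, lev = token.split("=", 1)
        if not (part.startswith(f"C({var}") or part.startswith(f"{var}[")):
            return False
        return f"[T.{lev}]" in part or part.endswith(f"[{lev}]")
    return part == token


def _key_matches_column(column: str, key: str) -> bool:
    if key == "Intercept":
        return column == "Intercept"
    tokens = key.split(":")
    parts = column.split(":")
    if len(tokens) != len(parts):
        return False
    remaining = list(parts)
    for tok in tokens:
        hit = next((p for p in remaining if _token_matches_part(p, tok)), None)
        if hit is None:
            return False
        remaining.remove(hit)
    return True


def coef_vector(columns: Sequence[str], coef: dict[str, float]) -> np.ndarray:
    """Map friendly coefficient keys onto design-matrix columns.

    Keys are ``Intercept``, numeric column names (``pop_density_k``),
    ``variable=level`` for categorical contrasts, and ``:``-joined products
    for interactions.  Columns not named by any key get coefficient 0.
    Ambiguous or unmatched keys raise.
    """
    out = np.zeros(len(columns))
    for key, value in coef.items():
        hits = [i for i, c in enumerate(columns) if _key_matches_column(c, key)]
        if len(hits) != 1:
            raise ValueError(
                f"coefficient key {key!r} matched {len(hits)} design columns "
                f"(columns: {list(columns)})"
            )
        out[hits[0]] = value
    return out


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _wald_block_p(params: np.ndarray, cov: np.ndarray) -> float:
    """Joint Wald chi-square p-value that a coefficient block is zero."""
    params = np.atleast_1d(params)
    cov = np.atleast_2d(cov)
    stat = float(params @ np.linalg.solve(cov, params))
    return float(sps.chi2.sf(stat, df=len(params)))


def _poisson_ll_obs(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return y * np.log(mu) - mu - gammaln(y + 1)


def _term_slice(design_info, term_expr: str) -> slice:
    slices = design_info.term_name_slices
    if term_expr in slices:
        return slices[term_expr]
    squeezed = {k.replace(" ", ""): v for k, v in slices.items()}
    key = term_expr.replace(" ", "")
    if key in squeezed:
        return squeezed[key]
    raise KeyError(
        f"term {term_expr!r} not in design (have {list(slices)})"
    )


@dataclass
class SpecTestResult:
    """Outcome of a count-model specification test."""

    name: str
    statistic: float
    pvalue: float
    preferred: str

    def __post_init__(self):
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Zero-inflated Poisson trip-count models
# ---------------------------------------------------------------------------

@dataclass
class ZipFit:
    """Fitted zero-inflated Poisson count model.

    Parameters are stored in statsmodels order: inflation (logit) stage
    first, then the count stage.  ``infl_params`` is ``None`` for the
    degenerate no-inflation fit (a plain Poisson), in which case ``pi`` is
    identically zero.
    """

    design: ModelDesign
    infl_design: ModelDesign | None
    count_params: pd.Series
    infl_params: pd.Series | None
    cov: pd.DataFrame
    llf: float
    nobs: int
    robust: bool
    stats: dict = field(default_factory=dict)
    _count_di: object = None
    _infl_di: object = None

    # -- prediction -------------------------------------------------------
    def pi(self, data: pd.DataFrame) -> np.ndarray:
        """Probability of a structural (always) zero."""
        if self.infl_params is None:
            return np.zeros(len(data))
        Xi = predict_matrix(self._infl_di, data).to_numpy()
        return expit(Xi @ self.infl_params.to_numpy())

    def lam(self, data: pd.DataFrame) -> np.ndarray:
        """Poisson rate ``exp(x'beta)`` of the count stage."""
        X = predict_matrix(self._count_di, data).to_numpy()
        return np.exp(np.clip(X @ self.count_params.to_numpy(), -700.0, 30.0))

    def expected_count(self, data: pd.DataFrame) -> np.ndarray:
        return (1.0 - self.pi(data)) * self.lam(data)

    def loglike_obs(self, data: pd.DataFrame) -> np.ndarray:
        y = data[self.design.response].to_numpy(dtype=float)
        lam = self.lam(data)
        pi = self.pi(data)
        with np.errstate(divide="ignore"):
            ll_zero = np.log(pi + (1 - pi) * np.exp(-lam))
            ll_pos = np.log1p(-pi) + _poisson_ll_obs(y, lam)
        return np.where(y == 0, ll_zero, ll_pos)

    def odds_ratios(self) -> dict[str, pd.Series]:
        out = {"count": np.exp(self.count_params)}
        if self.infl_params is not None:
            out["inflation"] = np.exp(self.infl_params)
        return out

    # -- inference --------------------------------------------------------
    def term_pvalue(self, term_expr: str, stage: str = "count") -> float:
        if stage == "count":
            di, offset = self._count_di, self._n_infl
            names = [f"count::{c}" for c in self.count_params.index]
        elif stage == "inflation":
            if self.infl_params is None:
                raise ValueError("fit has no inflation stage")
            di, offset = self._infl_di, 0
            names = [f"infl::{c}" for c in self.infl_params.index]
        else:
            raise ValueError(f"unknown stage {stage!r}")
        sl = _term_slice(di, term_expr)
        idx = np.arange(sl.start, sl.stop) + offset
        V = self.cov.to_numpy()
        return _wald_block_p(self.all_params[idx], V[np.ix_(idx, idx)])

    @property
    def _n_infl(self) -> int:
        return 0 if self.infl_params is None else len(self.infl_params)

    @property
    def all_params(self) -> np.ndarray:
        parts = [] if self.infl_params is None else [self.infl_params.to_numpy()]
        parts.append(self.count_params.to_numpy())
        return np.concatenate(parts)

    def with_params(self, vec: np.ndarray) -> "ZipFit":
        k = self._n_infl
        infl = (
            None
            if self.infl_params is None
            else pd.Series(vec[:k], index=self.infl_params.index)
        )
        count = pd.Series(vec[k:], index=self.count_params.index)
        return replace(self, infl_params=infl, count_params=count)

    def mean_response(self, data: pd.DataFrame) -> np.ndarray:
        return self.expected_count(data)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "zip",
                "design": self.design.to_dict(),
                "infl_design": (
                    None if self.infl_design is None else self.infl_design.to_dict()
                ),
                "count_params": self.count_params.to_dict(),
                "infl_params": (
                    None if self.infl_params is None else self.infl_params.to_dict()
                ),
                "cov": self.cov.to_numpy().tolist(),
                "param_names": list(self.cov.index),
                "llf": self.llf,
                "nobs": self.nobs,
                "robust": self.robust,
                "stats": self.stats,
            },
            indent=2,
        )


def _check_cov_psd(cov: np.ndarray, label: str) -> None:
    if not np.isfinite(cov).all():
        warnings.warn(f"{label} covariance has non-finite entries "
                      "(likely quasi-separation)")
        return
    eigmin = float(np.linalg.eigvalsh((cov + cov.T) / 2).min())
    if eigmin < -1e-6 * max(1.0, float(np.abs(cov).max())):
        warnings.warn(f"{label} covariance is not positive semidefinite")


def fit_poisson(data: pd.DataFrame, design: ModelDesign, robust: bool = True):
    """Plain Poisson fit wrapped as a degenerate :class:`ZipFit` (pi = 0)."""
    y = data[design.response].to_numpy(dtype=float)
    _check_counts(y, design.response)
    X = design.matrix(data)
    res = Poisson(y, X).fit(
        disp=0, cov_type="HC1" if robust else "nonrobust", maxiter=200
    )
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("Poisson fit did not converge")
    cov = pd.DataFrame(
        res.cov_params(), index=X.columns, columns=X.columns
    )
    return ZipFit(
        design=design,
        infl_design=None,
        count_params=pd.Series(np.asarray(res.params), index=X.columns),
        infl_params=None,
        cov=cov,
        llf=float(res.llf),
        nobs=len(y),
        robust=robust,
        stats={"df_model": int(res.df_model)},
        _count_di=X.design_info,
    )


def _check_counts(y: np.ndarray, name: str) -> None:
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError(f"response {name!r} must be nonnegative integers")


def fit_zip(
    data: pd.DataFrame,
    design: ModelDesign,
    infl_design: ModelDesign | str | None = None,
    robust: bool = True,
    maxiter: int = 500,
) -> ZipFit:
    """Fit a zero-inflated Poisson model by maximum likelihood.

    ``infl_design`` defaults to the count-stage design (both stages see the
    same candidate covariates and are selected independently); pass the
    string ``"none"`` for the degenerate plain-Poisson fit.  Robust
    (sandwich) covariances are used by default.
    """
    if infl_design == "none":
        return fit_poisson(data, design, robust=robust)
    if infl_design is None:
        infl_design = ModelDesign(design.response, design.terms)
    y = data[design.response].to_numpy(dtype=float)
    _check_counts(y, design.response)
    if (y == 0).all():
        raise ValueError("response is identically zero; model is degenerate")
    X = design.matrix(data)
    Xi = infl_design.matrix(data)
    # Column scaling keeps the optimization well conditioned (quadratic age
    # terms otherwise dominate the gradient); estimates are mapped back to
    # the original units afterwards.
    scale_c = np.maximum(np.abs(np.asarray(X)).max(axis=0), 1e-12)
    scale_i = np.maximum(np.abs(np.asarray(Xi)).max(axis=0), 1e-12)
    Xs = np.asarray(X) / scale_c
    Xis = np.asarray(Xi) / scale_i
    start = _zip_start(y, Xs, Xis, list(Xi.columns))
    model = ZeroInflatedPoisson(y, Xs, exog_infl=Xis, inflation="logit")
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs"):
            res = model.fit(
                start_params=start, method=method, maxiter=maxiter, disp=0,
            )
            grad = np.linalg.norm(model.score(np.asarray(res.params)))
            if grad <= 1e-2 * max(1.0, abs(float(res.llf))):
                break
        else:
            raise ConvergenceError(
                f"ZIP fit did not converge (gradient norm {grad:.3g})"
            )
    params = np.asarray(res.params)
    k_infl = Xi.shape[1]
    infl_params = pd.Series(params[:k_infl] / scale_i, index=Xi.columns)
    count_params = pd.Series(params[k_infl:] / scale_c, index=X.columns)
    _warn_separation(infl_params, "inflation")
    names = [f"infl::{c}" for c in Xi.columns] + [f"count::{c}" for c in X.columns]
    d = 1.0 / np.concatenate([scale_i, scale_c])
    cov_np = _zip_covariance(model, params, robust) * np.outer(d, d)
    cov = pd.DataFrame(cov_np, index=names, columns=names)
    _check_cov_psd(cov.to_numpy(), "ZIP")
    fit = ZipFit(
        design=design,
        infl_design=infl_design,
        count_params=count_params,
        infl_params=infl_params,
        cov=cov,
        llf=float(res.llf),
        nobs=len(y),
        robust=robust,
        _count_di=X.design_info,
        _infl_di=Xi.design_info,
    )
    fit.stats = _zip_fit_stats(fit, res)
    return fit


def _zip_covariance(model, params: np.ndarray, robust: bool) -> np.ndarray:
    """Coefficient covariance from a finite-difference Hessian.

    The Hessian is differentiated from the analytic score; with
    ``robust`` the outer product of per-observation scores forms the
    sandwich filling.  (The packaged analytic ZIP Hessian omits
    inflation/count cross terms and understates the variance, which this
    computation was validated against by simulation.)
    """
    k = len(params)
    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(params[j]))
        up, dn = params.copy(), params.copy()
        up[j] += h
        dn[j] -= h
        H[:, j] = (model.score(up) - model.score(dn)) / (2 * h)
    H = (H + H.T) / 2.0
    A = np.linalg.pinv(-H)
    if not robust:
        return A
    s = model.score_obs(params)
    return A @ (s.T @ s) @ A


def _zip_start(y, X, Xi, infl_columns) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = Poisson(y, X).fit(disp=0, maxiter=200)
    p0_obs = float(np.mean(y == 0))
    p0_pois = float(np.mean(np.exp(-pois.predict())))
    excess = np.clip((p0_obs - p0_pois) / max(1e-6, 1 - p0_pois), 0.02, 0.95)
    infl0 = np.zeros(Xi.shape[1])
    icpt = [i for i, c in enumerate(infl_columns) if c == "Intercept"]
    if icpt:
        infl0[icpt[0]] = float(np.log(excess / (1 - excess)))
    return np.concatenate([infl0, np.asarray(pois.params)])


def _warn_separation(params: pd.Series, stage: str, limit: float = 12.0) -> None:
    big = params[params.abs() > limit]
    for name in big.index:
        warnings.warn(
            f"possible quasi-separation in {stage} stage: |coef| > {limit} "
            f"for {name!r}"
        )


def _zip_fit_stats(fit: ZipFit, res) -> dict:
    names = list(fit.cov.index)
    free = [i for i, n in enumerate(names) if not n.endswith("::Intercept")]
    stats = {"df_model": len(free)}
    if free:
        V = fit.cov.to_numpy()[np.ix_(free, free)]
        b = fit.all_params[free]
        try:
            wald = float(b @ np.linalg.solve(V, b))
            stats["wald_chi2"] = wald
            stats["wald_p"] = float(sps.chi2.sf(wald, df=len(free)))
        except np.linalg.LinAlgError:
            pass
    try:
        stats["llnull"] = float(res.llnull)
        k = len(names)
        stats["pseudo_r2_adj"] = 1.0 - (fit.llf - k) / stats["llnull"]
    except Exception:
        pass
    return stats


def zip_expected_count(fit: ZipFit, x: pd.DataFrame) -> np.ndarray:
    """Expected daily trips ``(1 - pi(x)) * lambda(x)`` under a ZIP fit."""
    return fit.expected_count(x)


# ---------------------------------------------------------------------------
# Specification tests
# ---------------------------------------------------------------------------

def vuong_test(zip_fit: ZipFit, poisson_fit: ZipFit, data: pd.DataFrame) -> SpecTestResult:
    """Vuong non-nested test of ZIP against plain Poisson.

    The statistic is the mean per-observation log-likelihood ratio divided
    by its standard error, scaled by sqrt(n); positive values favor the
    zero-inflated model.  Uncorrected (no AIC/BIC adjustment).
    """
    m = zip_fit.loglike_obs(data) - poisson_fit.loglike_obs(data)
    sd = float(np.std(m, ddof=1))
    if sd < 1e-12:
        if np.abs(m).max() < 1e-10:
            # a model compared with itself: the ratio is identically zero
            return SpecTestResult("vuong", 0.0, 1.0, "poisson")
        raise ValueError(
            "per-observation likelihood ratios have zero variance; "
            "the models are identical on these data"
        )
    stat = float(np.sqrt(len(m)) * np.mean(m) / sd)
    p = float(2.0 * sps.norm.sf(abs(stat)))
    return SpecTestResult(
        name="vuong",
        statistic=stat,
        pvalue=p,
        preferred="zip" if stat > 0 else "poisson",
    )


def lm_zero_inflation_test(poisson_fit: ZipFit, data: pd.DataFrame) -> SpecTestResult:
    """Score (Lagrange multiplier) test for excess zeros against Poisson.

    Uses the classical score statistic for a zero-inflated alternative:
    with ``p0 = exp(-mu_hat)``, the statistic
    ``[sum((1{y=0} - p0)/p0)]^2 / [sum((1-p0)/p0) - n*ybar]``
    is compared to a chi-square with 1 df.
    """
    y = data[poisson_fit.design.response].to_numpy(dtype=float)
    if (y == 0).all():
        raise ValueError("all counts are zero; no information on inflation")
    mu = poisson_fit.lam(data)
    p0 = np.exp(-mu)
    num = float(np.sum((np.where(y == 0, 1.0, 0.0) - p0) / p0)) ** 2
    den = float(np.sum((1 - p0) / p0) - len(y) * np.mean(y))
    if den <= 0:
        raise ValueError("degenerate score-test denominator")
    stat = num / den
    p = float(sps.chi2.sf(stat, df=1))
    return SpecTestResult(
        name="lm_zero_inflation",
        statistic=stat,
        pvalue=p,
        preferred="zip" if p < 0.05 else "poisson",
    )


# ---------------------------------------------------------------------------
# Multinomial-logit trip-purpose models
# ---------------------------------------------------------------------------

@dataclass
class MnlFit:
    """Fitted multinomial logit over trip purposes.

    ``outcomes`` lists the categories with the declared base outcome first;
    its coefficients are identically zero.  ``params`` has one column per
    non-base outcome, indexed by design columns.
    """

    design: ModelDesign
    outcomes: tuple[str, ...]
    params: pd.DataFrame
    cov: pd.DataFrame
    llf: float
    nobs: int
    _di: object = None

    @property
    def base(self) -> str:
        return self.outcomes[0]

    def linear_index(self, data: pd.DataFrame) -> pd.DataFrame:
        X = predict_matrix(self._di, data).to_numpy()
        eta = X @ self.params.to_numpy()
        out = np.column_stack([np.zeros(len(data)), eta])
        return pd.DataFrame(out, columns=list(self.outcomes), index=data.index)

    def probabilities(self, data: pd.DataFrame) -> pd.DataFrame:
        eta = self.linear_index(data).to_numpy()
        eta -= eta.max(axis=1, keepdims=True)
        w = np.exp(eta)
        probs = w / w.sum(axis=1, keepdims=True)
        return pd.DataFrame(probs, columns=list(self.outcomes), index=data.index)

    def term_pvalue(self, term_expr: str) -> float:
        sl = _term_slice(self._di, term_expr)
        k = self.params.shape[0]
        idx = np.concatenate(
            [np.arange(sl.start, sl.stop) + j * k for j in range(self.params.shape[1])]
        )
        V = self.cov.to_numpy()
        return _wald_block_p(self.all_params[idx], V[np.ix_(idx, idx)])

    @property
    def all_params(self) -> np.ndarray:
        # equation-major (outcome by outcome), matching statsmodels cov order
        return self.params.to_numpy().ravel(order="F")

    def with_params(self, vec: np.ndarray) -> "MnlFit":
        mat = vec.reshape(self.params.shape, order="F")
        return replace(
            self,
            params=pd.DataFrame(
                mat, index=self.params.index, columns=self.params.columns
            ),
        )

    def mean_response(self, data: pd.DataFrame) -> pd.DataFrame:
        return self.probabilities(data)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "mnl",
                "design": self.design.to_dict(),
                "outcomes": list(self.outcomes),
                "params": {c: self.params[c].to_dict() for c in self.params},
                "cov": self.cov.to_numpy().tolist(),
                "param_names": list(self.cov.index),
                "llf": self.llf,
                "nobs": self.nobs,
            },
            indent=2,
        )


def fit_purpose_mnl(
    trips: pd.DataFrame,
    design: ModelDesign,
    base: str,
    outcomes: Sequence[str] | None = None,
) -> MnlFit:
    """Fit a multinomial logit for trip purpose with a declared base outcome."""
    observed = list(pd.unique(trips[design.response]))
    if outcomes is not None:
        missing = [o for o in outcomes if o not in observed]
        if missing:
            raise ValueError(f"outcome categories with no observations: {missing}")
        cats = list(outcomes)
        if base in cats:
            cats.remove(base)
        cats = [base] + cats
    else:
        if base not in observed:
            raise ValueError(f"base outcome {base!r} not observed")
        cats = [base] + sorted(o for o in observed if o != base)
    if len(cats) < 2:
        raise ValueError("need at least 2 observed outcome categories")
    codes = pd.Categorical(trips[design.response], categories=cats).codes
    if (codes < 0).any():
        bad = sorted(set(trips[design.response]) - set(cats))
        raise ValueError(f"outcomes outside the declared category set: {bad}")
    X = design.matrix(trips)
    scale = np.maximum(np.abs(np.asarray(X)).max(axis=0), 1e-12)
    Xs = np.asarray(X) / scale
    model = MNLogit(codes, Xs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method, it in (("newton", 200), ("bfgs", 1000)):
            try:
                res = model.fit(disp=0, maxiter=it, method=method)
            except np.linalg.LinAlgError:
                grad = np.inf
                continue
            grad = np.linalg.norm(model.score(np.asarray(res.params)))
            if np.isfinite(res.llf) and grad <= 1e-2 * max(1.0, abs(float(res.llf))):
                break
        else:
            raise ConvergenceError(
                f"multinomial logit did not converge (gradient norm {grad:.3g})"
            )
    params = pd.DataFrame(
        np.asarray(res.params) / scale[:, None], index=X.columns,
        columns=cats[1:],
    )
    _warn_separation(params.abs().max(axis=1), "multinomial")
    d = 1.0 / np.tile(scale, len(cats) - 1)
    names = [f"{o}::{c}" for o in cats[1:] for c in X.columns]
    cov = pd.DataFrame(np.asarray(res.cov_params()) * np.outer(d, d),
                       index=names, columns=names)
    _check_cov_psd(cov.to_numpy(), "MNL")
    return MnlFit(
        design=design,
        outcomes=tuple(cats),
        params=params,
        cov=cov,
        llf=float(res.llf),
        nobs=len(trips),
        _di=X.design_info,
    )


def purpose_probabilities(fit: MnlFit, x: pd.DataFrame) -> pd.DataFrame:
    """Simplex probability vector over purposes for each covariate row."""
    return fit.probabilities(x)


# ---------------------------------------------------------------------------
# Log-link clustered duration models
# ---------------------------------------------------------------------------

@dataclass
class DurationFit:
    """Estimating-equation fit for log-mean trip duration.

    Predictions are ``exp(x'beta)``; the covariance is cluster-robust with
    trips clustered within persons.
    """

    design: ModelDesign
    params: pd.Series
    cov: pd.DataFrame
    working_corr: str
    cluster: str
    nobs: int
    n_clusters: int
    _di: object = None

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = predict_matrix(self._di, data).to_numpy()
        return np.exp(np.clip(X @ self.params.to_numpy(), -700.0, 30.0))

    def term_pvalue(self, term_expr: str) -> float:
        sl = _term_slice(self._di, term_expr)
        idx = np.arange(sl.start, sl.stop)
        V = self.cov.to_numpy()
        return _wald_block_p(
            self.params.to_numpy()[idx], V[np.ix_(idx, idx)]
        )

    @property
    def all_params(self) -> np.ndarray:
        return self.params.to_numpy()

    def with_params(self, vec: np.ndarray) -> "DurationFit":
        return replace(self, params=pd.Series(vec, index=self.params.index))

    def mean_response(self, data: pd.DataFrame) -> np.ndarray:
        return self.predict(data)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "duration_gee",
                "design": self.design.to_dict(),
                "params": self.params.to_dict(),
                "cov": self.cov.to_numpy().tolist(),
                "param_names": list(self.cov.index),
                "working_corr": self.working_corr,
                "cluster": self.cluster,
                "nobs": self.nobs,
                "n_clusters": self.n_clusters,
            },
            indent=2,
        )


def fit_duration_gee(
    trips: pd.DataFrame,
    design: ModelDesign,
    cluster: str = "person_id",
    working_corr: str = "exchangeable",
) -> DurationFit:
    """Fit a log-link GEE for trip duration clustered within persons.

    The variance is taken proportional to the mean on the natural scale
    (Poisson-type quasi-likelihood), with an exchangeable working
    correlation by default.  If every cluster is a singleton the working
    structure falls back to independence with a warning.
    """
    y = trips[design.response].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("durations must be strictly positive")
    groups = trips[cluster]
    sizes = groups.value_counts()
    corr = working_corr
    if working_corr == "exchangeable" and (sizes.max() if len(sizes) else 0) <= 1:
        warnings.warn(
            "all clusters are singletons; falling back to an independence "
            "working correlation"
        )
        corr = "independence"
    cov_struct = Exchangeable() if corr == "exchangeable" else Independence()
    X = design.matrix(trips)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = GEE(
            y, X, groups=groups.to_numpy(), family=PoissonFamily(), cov_struct=cov_struct
        ).fit(maxiter=120)
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)
    _check_cov_psd(cov.to_numpy(), "GEE")
    return DurationFit(
        design=design,
        params=pd.Series(np.asarray(res.params), index=X.columns),
        cov=cov,
        working_corr=corr,
        cluster=cluster,
        nobs=len(trips),
        n_clusters=int(groups.nunique()),
        _di=X.design_info,
    )


def fit_from_json(payload: str | dict, data: pd.DataFrame):
    """Rehydrate a serialized fit, re-anchoring its design on ``data``.

    ``data`` must contain the covariates (and categorical levels) the
    original fit was estimated on — e.g. the cleaned analysis table the
    fit was produced from — so patsy reproduces the same model matrix
    columns.
    """
    d = json.loads(payload) if isinstance(payload, str) else payload
    kind = d["kind"]
    if kind == "zip":
        design = ModelDesign.from_dict(d["design"])
        X = design.matrix(data)
        count_params = pd.Series(d["count_params"]).reindex(X.columns)
        cov = pd.DataFrame(np.asarray(d["cov"]), index=d["param_names"],
                           columns=d["param_names"])
        if d["infl_design"] is None:
            return ZipFit(
                design=design, infl_design=None, count_params=count_params,
                infl_params=None, cov=cov, llf=d["llf"], nobs=d["nobs"],
                robust=d["robust"], stats=d.get("stats", {}),
                _count_di=X.design_info,
            )
        infl_design = ModelDesign.from_dict(d["infl_design"])
        Xi = infl_design.matrix(data)
        infl_params = pd.Series(d["infl_params"]).reindex(Xi.columns)
        return ZipFit(
            design=design, infl_design=infl_design, count_params=count_params,
            infl_params=infl_params, cov=cov, llf=d["llf"], nobs=d["nobs"],
            robust=d["robust"], stats=d.get("stats", {}),
            _count_di=X.design_info, _infl_di=Xi.design_info,
        )
    if kind == "mnl":
        design = ModelDesign.from_dict(d["design"])
        X = design.matrix(data)
        outcomes = tuple(d["outcomes"])
        params = pd.DataFrame(
            {o: pd.Series(d["params"][o]).reindex(X.columns)
             for o in outcomes[1:]}
        )
        cov = pd.DataFrame(np.asarray(d["cov"]), index=d["param_names"],
                           columns=d["param_names"])
        return MnlFit(
            design=design, outcomes=outcomes, params=params, cov=cov,
            llf=d["llf"], nobs=d["nobs"], _di=X.design_info,
        )
    if kind == "duration_gee":
        design = ModelDesign.from_dict(d["design"])
        X = design.matrix(data)
        params = pd.Series(d["params"]).reindex(X.columns)
        cov = pd.DataFrame(np.asarray(d["cov"]), index=d["param_names"],
                           columns=d["param_names"])
        return DurationFit(
            design=design, params=params, cov=cov,
            working_corr=d["working_corr"], cluster=d["cluster"],
            nobs=d["nobs"], n_clusters=d["n_clusters"], _di=X.design_info,
        )
    raise ValueError(f"unknown serialized fit kind {kind!r}")


# ---------------------------------------------------------------------------
# Backward elimination at the 10% level
# ---------------------------------------------------------------------------

def backward_select(
    data: pd.DataFrame,
    design: ModelDesign,
    fitter: Callable[[pd.DataFrame, ModelDesign], object],
    alpha: float = 0.10,
    pvalue: Callable[[object, str], float] | None = None,
) -> ModelDesign:
    """Iteratively remove the least significant candidate term.

    Each iteration refits, computes a joint Wald p-value per candidate term
    (categorical variables are tested and removed as whole dummy blocks),
    and drops the term with the largest p-value if it is >= ``alpha``.
    Control and fixed-effect terms are never removed.  Ties break toward the
    lexicographically larger term name.
    """
    if pvalue is None:
        pvalue = lambda fit, term: fit.term_pvalue(term)  # noqa: E731
    while True:
        cands = design.candidates()
        if not cands:
            return design
        fit = fitter(data, design)
        pvals = {t: pvalue(fit, t) for t in cands}
        worst, worst_p = max(pvals.items(), key=lambda kv: (kv[1], kv[0]))
        if worst_p < alpha:
            return design
        design = design.drop(worst)


# ---------------------------------------------------------------------------
# Average marginal effects
# ---------------------------------------------------------------------------

@dataclass
class MarginalEffect:
    """Average marginal effect with a delta-method standard error."""

    variable: str
    level: str | None
    effect: float | pd.Series
    se: float | pd.Series


def _ame_value(fit, data: pd.DataFrame, variable: str, level, reference, h):
    """AME as a function of the fit's parameters (returns scalar or Series)."""
    if level is not None:
        hi = data.assign(**{variable: level})
        lo = data.assign(**{variable: reference})
        diff = np.asarray(fit.mean_response(hi)) - np.asarray(fit.mean_response(lo))
    else:
        x = data[variable].to_numpy(dtype=float)
        up = data.assign(**{variable: x + h})
        dn = data.assign(**{variable: x - h})
        diff = (
            np.asarray(fit.mean_response(up)) - np.asarray(fit.mean_response(dn))
        ) / (2 * h)
    mean = diff.mean(axis=0)
    return mean


def marginal_effects(
    fit,
    data: pd.DataFrame,
    variable: str,
    level: str | None = None,
    reference: str | None = None,
) -> MarginalEffect:
    """Average marginal effect of ``variable`` on the fit's mean response.

    For categorical variables the effect is the sample-averaged difference
    between predictions at ``level`` and at ``reference``; for continuous
    variables it is the sample-averaged derivative.  Standard errors come
    from the delta method with a numerical gradient in the coefficients.
    For multinomial fits the effect is a vector over outcomes.
    """
    is_cat = (
        data[variable].dtype == object
        or isinstance(data[variable].dtype, pd.CategoricalDtype)
        or data[variable].dtype == bool
    )
    if is_cat:
        if reference is None:
            raise ValueError("categorical variables need an explicit reference level")
        if level is None:
            raise ValueError("categorical variables need the level to contrast")
        if level == reference:
            raise ValueError(
                f"effect of the reference level {reference!r} is 0 by construction"
            )
        h = None
    else:
        x = data[variable].to_numpy(dtype=float)
        h = 1e-4 * max(1.0, float(np.std(x)))
        level = reference = None

    theta0 = fit.all_params.copy()
    g0 = _ame_value(fit, data, variable, level, reference, h)
    grad_cols = []
    for k in range(len(theta0)):
        step = 1e-6 * (1.0 + abs(theta0[k]))
        up, dn = theta0.copy(), theta0.copy()
        up[k] += step
        dn[k] -= step
        gu = _ame_value(fit.with_params(up), data, variable, level, reference, h)
        gd = _ame_value(fit.with_params(dn), data, variable, level, reference, h)
        grad_cols.append((np.asarray(gu) - np.asarray(gd)) / (2 * step))
    G = np.column_stack(grad_cols) if np.ndim(g0) else np.array(grad_cols)[None, :]
    G = np.atleast_2d(G)
    V = fit.cov.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", G, V, G))
    if np.ndim(g0):
        outcomes = list(getattr(fit, "outcomes", range(len(np.atleast_1d(g0)))))
        return MarginalEffect(
            variable,
            level,
            pd.Series(np.atleast_1d(g0), index=outcomes),
            pd.Series(se, index=outcomes),
        )
    return MarginalEffect(variable, level, float(g0), float(se[0]))
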