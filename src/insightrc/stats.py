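"""Mixed-model inference scaffold.

Linear and binomial-logistic mixed models with *crossed* random
intercepts (subject and item), fitted by maximum likelihood so that
nested models can be compared with likelihood-ratio tests. The gaussian
family uses the profiled ML deviance (the random-effect scale is
optimized on the relative-standard-deviation scale with the residual
variance profiled out); the binomial family uses the Laplace
approximation with penalized iteratively reweighted least squares for
the joint (fixed, random) mode — the same strategy the reference mixed
model software in this field uses.

On top of the fitter: likelihood-ratio tests, permutation LRTs (tested
predictor shuffled within subject), subject-level case-resampling
bootstrap odds ratios, post hoc simple slopes with Bonferroni
correction, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, sparse
from scipy.linalg import cholesky, solve_triangular
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "fit_mixed_model",
    "likelihood_ratio_test",
    "permutation_lrt",
    "bootstrap_odds_ratio",
    "BootstrapORResult",
    "posthoc_slopes",
    "fdr_correct",
]

_SINGULAR_TOL = 1e-4
_THETA_RESTARTS = ((1.0, 1.0), (0.1, 0.1), (2.0, 0.5), (0.5, 2.0))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model specification.

    Parameters
    ----------
    response:
        Name of the response column (binary 0/1 for binomial).
    fixed:
        Right-hand-side fixed-effects formula (patsy syntax), e.g.
        ``"run + insight * memory"``. An intercept is implied.
    groups:
        Random-intercept grouping columns; crossed, typically
        ``("subject_id", "item_id")``.
    family:
        ``"gaussian"`` or ``"binomial"``.
    """

    response: str
    fixed: str
    groups: tuple = ("subject_id", "item_id")
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")
        if not self.groups:
            raise ValueError("at least one random-intercept grouping factor")
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"


@dataclass
class FitResult:
    """A fitted mixed model (ML)."""

    spec: ModelSpec
    params: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    deviance: float
    theta: dict            # group -> relative (binomial: absolute) RE sd
    random_effect_sd: dict # group -> random intercept SD on response scale
    sigma: float | None    # residual SD (gaussian only)
    n_obs: int
    converged: bool
    singular: bool
    term_names: tuple
    row_index: pd.Index = field(repr=False, default=None)
    model_data: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())),
            index=self.params.index,
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        se = self.bse()
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se}
        )


@dataclass
class LRTResult:
    """Nested-model likelihood-ratio comparison."""

    chi2: float
    df: int
    p: float
    effect_name: str | None = None
    estimate: float | None = None       # beta (gaussian) or OR (binomial)
    ci: tuple | None = None
    converged: bool = True


def _binomial_deviance_resid_sum(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(
        2.0 * np.sum(y * np.log(np.where(y > 0, y / mu, 1.0))
                     + (1 - y) * np.log(np.where(y < 1, (1 - y) / (1 - mu), 1.0)))
    )


class _CrossedMixedModel:
    """Internal solver for crossed-random-intercept (G)LMMs.

    Holds the design (dense X, sparse indicator Z for the grouping
    factors) and evaluates the profiled ML deviance (gaussian) or the
    Laplace deviance (binomial) at a given vector of relative random
    effect standard deviations theta.
    """

    def __init__(self, y, X, group_codes, group_sizes, family):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.family = family
        self.sizes = list(group_sizes)
        self.q = int(sum(self.sizes))
        rows = np.tile(np.arange(self.n), len(self.sizes))
        cols = []
        offset = 0
        for codes, size in zip(group_codes, self.sizes):
            cols.append(np.asarray(codes) + offset)
            offset += size
        cols = np.concatenate(cols)
        data = np.ones(len(rows))
        self.Z = sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n, self.q)
        )
        self.block = np.concatenate(
            [np.full(s, k) for k, s in enumerate(self.sizes)]
        )
        if family == "gaussian":
            # cross-products are weight-free: compute once
            self._ZtZ = (self.Z.T @ self.Z).toarray()
            self._ZtX = self.Z.T @ self.X
            self._Zty = self.Z.T @ self.y
            self._XtX = self.X.T @ self.X
            self._Xty = self.X.T @ self.y
            self._yty = float(self.y @ self.y)
        self._warm = None  # (u, beta) PIRLS warm start across theta evals

    def _lambda_vec(self, theta) -> np.ndarray:
        theta = np.abs(np.asarray(theta, dtype=float))
        return theta[self.block]

    # -- shared penalized weighted LS step ---------------------------------
    def _solve_blocks(self, lam, w, z_work):
        """Solve the penalized weighted LS system for (u, beta).

        Returns (u, beta, L, S) where L is the Cholesky factor of
        Lam Z'WZ Lam + I and S = X'WX - RZX'RZX (the information matrix
        of beta after eliminating u).
        """
        Zw = self.Z.multiply(w[:, None])
        ZtWZ = (self.Z.T @ Zw).toarray()
        ZtWX = self.Z.T @ (w[:, None] * self.X)
        ZtWy = self.Z.T @ (w * z_work)
        XtWX = self.X.T @ (w[:, None] * self.X)
        XtWy = self.X.T @ (w * z_work)

        A = lam[:, None] * ZtWZ * lam[None, :]
        A[np.diag_indices_from(A)] += 1.0
        L = cholesky(A, lower=True)
        RZX = solve_triangular(L, lam[:, None] * ZtWX, lower=True)
        cu = solve_triangular(L, lam * ZtWy, lower=True)
        S = XtWX - RZX.T @ RZX
        beta = np.linalg.solve(S, XtWy - RZX.T @ cu)
        u = solve_triangular(L.T, cu - RZX @ beta, lower=False)
        return u, beta, L, S

    # -- gaussian: profiled ML deviance ------------------------------------
    def gaussian_profile(self, theta):
        lam = self._lambda_vec(theta)
        A = lam[:, None] * self._ZtZ * lam[None, :]
        A[np.diag_indices_from(A)] += 1.0
        L = cholesky(A, lower=True)
        RZX = solve_triangular(L, lam[:, None] * self._ZtX, lower=True)
        cu = solve_triangular(L, lam * self._Zty, lower=True)
        S = self._XtX - RZX.T @ RZX
        beta = np.linalg.solve(S, self._Xty - RZX.T @ cu)
        u = solve_triangular(L.T, cu - RZX @ beta, lower=False)
        b = lam * u
        pwrss = float(
            self._yty
            - 2.0 * beta @ self._Xty
            - 2.0 * b @ self._Zty
            + beta @ self._XtX @ beta
            + 2.0 * b @ (self._ZtX @ beta)
            + b @ self._ZtZ @ b
            + u @ u
        )
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        dev = logdet + self.n * (1.0 + np.log(2.0 * np.pi * pwrss / self.n))
        sigma2 = pwrss / self.n
        return {
            "deviance": dev, "beta": beta, "u": u, "sigma2": sigma2,
            "S": S, "lam": lam,
        }

    # -- binomial: Laplace deviance via PIRLS ------------------------------
    def laplace_binomial(self, theta, max_iter=80, tol=1e-9):
        lam = self._lambda_vec(theta)
        if self._warm is not None:
            u, beta = self._warm
            u, beta = u.copy(), beta.copy()
        else:
            beta = np.zeros(self.p)
            u = np.zeros(self.q)
        eta = self.X @ beta + self.Z @ (lam * u)
        pdev_old = np.inf
        L = S = None
        converged = False
        for _ in range(max_iter):
            mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
            w = mu * (1 - mu)
            z_work = eta + (self.y - mu) / w
            u_new, beta_new, L, S = self._solve_blocks(lam, w, z_work)
            # step-halving on the penalized deviance
            step = 1.0
            for _ in range(12):
                u_try = u + step * (u_new - u)
                beta_try = beta + step * (beta_new - beta)
                eta_try = self.X @ beta_try + self.Z @ (lam * u_try)
                mu_try = expit(eta_try)
                pdev = _binomial_deviance_resid_sum(self.y, mu_try) + float(
                    u_try @ u_try
                )
                if pdev <= pdev_old + 1e-10:
                    break
                step /= 2.0
            u, beta, eta = u_try, beta_try, eta_try
            if abs(pdev_old - pdev) < tol * (abs(pdev) + 1.0):
                converged = True
                pdev_old = pdev
                break
            pdev_old = pdev
        # logdet at the mode with final weights
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        Zw = self.Z.multiply(w[:, None])
        ZtWZ = (self.Z.T @ Zw).toarray()
        A = lam[:, None] * ZtWZ * lam[None, :]
        A[np.diag_indices_from(A)] += 1.0
        Lfin = cholesky(A, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(Lfin))))
        dev = pdev_old + logdet
        self._warm = (u.copy(), beta.copy())
        return {
            "deviance": dev, "beta": beta, "u": u, "S": S, "lam": lam,
            "pirls_converged": converged,
        }


def _build_design(spec: ModelSpec, data: pd.DataFrame):
    frame = data.reset_index(drop=True)
    y_df, X_df = patsy.dmatrices(
        spec.formula, frame, return_type="dataframe", NA_action="drop"
    )
    idx = X_df.index
    y = y_df.to_numpy().ravel()
    if spec.family == "binomial":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("binomial response must be coded 0/1")
    codes, sizes = [], []
    for g in spec.groups:
        if g not in frame.columns:
            raise ValueError(f"grouping factor {g!r} absent from data")
        cat = pd.Categorical(frame.loc[idx, g])
        codes.append(cat.codes.astype(int))
        sizes.append(len(cat.categories))
    term_names = tuple(X_df.design_info.term_names)
    return y, X_df, codes, sizes, term_names, idx, frame


def _standardize(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """z-score the (gaussian) response and continuous predictors.

    Binary/categorical columns and the grouping factors are left alone;
    a column is treated as continuous when it is numeric with more than
    two distinct values.
    """
    out = data.copy()
    skip = set(spec.groups)
    for col in out.columns:
        if col in skip:
            continue
        if col != spec.response and col not in spec.fixed:
            continue
        if col == spec.response and spec.family == "binomial":
            continue
        s = out[col]
        if not pd.api.types.is_numeric_dtype(s):
            continue
        vals = s.dropna()
        if vals.nunique() <= 2:
            continue
        sd = vals.std(ddof=0)
        if sd > 0:
            out[col] = (s - vals.mean()) / sd
    return out


def fit_mixed_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    standardize: bool = False,
    theta_start=None,
    restarts: bool = False,
) -> FitResult:
    """Fit a crossed-random-intercept mixed model by maximum likelihood.

    Parameters
    ----------
    standardize:
        z-score the response (gaussian) and continuous predictors before
        fitting, so coefficients are standardized effect sizes.
    theta_start:
        Starting relative random-effect SDs; useful to warm-start
        repeated refits (permutations, bootstrap).
    restarts:
        Try several theta starting points and keep the best likelihood
        (used when an LRT comes out negative).

    Notes
    -----
    ML (never REML) is used throughout so log-likelihoods are comparable
    across fixed-effect structures. A random-effect SD estimated at
    (numerically) zero is reported with ``singular=True``.
    """
    if standardize:
        data = _standardize(data, spec)
    y, X_df, codes, sizes, term_names, idx, frame = _build_design(spec, data)
    X = X_df.to_numpy()
    model = _CrossedMixedModel(y, X, codes, sizes, spec.family)

    k = len(sizes)
    if theta_start is None:
        theta_start = np.ones(k)
    starts = [np.asarray(theta_start, dtype=float)]
    if restarts:
        starts += [np.resize(np.asarray(s, dtype=float), k)
                   for s in _THETA_RESTARTS]

    def objective(theta):
        try:
            if spec.family == "gaussian":
                return model.gaussian_profile(theta)["deviance"]
            return model.laplace_binomial(theta)["deviance"]
        except np.linalg.LinAlgError:
            return np.inf

    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta_hat = np.abs(best.x)

    if spec.family == "gaussian":
        sol = model.gaussian_profile(theta_hat)
        sigma = float(np.sqrt(sol["sigma2"]))
        cov = np.linalg.inv(sol["S"]) * sol["sigma2"]
        re_sd = {g: float(t * sigma) for g, t in zip(spec.groups, theta_hat)}
        loglik = -0.5 * sol["deviance"]
        converged = bool(best.success)
    else:
        sol = model.laplace_binomial(theta_hat)
        sigma = None
        cov = np.linalg.inv(sol["S"])
        re_sd = {g: float(t) for g, t in zip(spec.groups, theta_hat)}
        loglik = -0.5 * sol["deviance"]
        converged = bool(best.success and sol["pirls_converged"])

    singular = bool(np.any(theta_hat < _SINGULAR_TOL))
    if singular:
        logger.warning(
            "random-effect variance estimated at (near) zero for %s",
            [g for g, t in zip(spec.groups, theta_hat) if t < _SINGULAR_TOL],
        )
    names = list(X_df.columns)
    return FitResult(
        spec=spec,
        params=pd.Series(sol["beta"], index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        loglik=float(loglik),
        deviance=float(sol["deviance"]),
        theta={g: float(t) for g, t in zip(spec.groups, theta_hat)},
        random_effect_sd=re_sd,
        sigma=sigma,
        n_obs=model.n,
        converged=converged,
        singular=singular,
        term_names=term_names,
        row_index=idx,
        model_data=frame.loc[idx],
    )


def _added_effect(base: FitResult, full: FitResult):
    added_cols = [c for c in full.params.index if c not in base.params.index]
    if len(added_cols) != 1:
        return None, None, None
    name = added_cols[0]
    est = float(full.params[name])
    se = float(np.sqrt(full.cov_params.loc[name, name]))
    lo, hi = est - 1.96 * se, est + 1.96 * se
    if full.spec.family == "binomial":
        return name, float(np.exp(est)), (float(np.exp(lo)), float(np.exp(hi)))
    return name, est, (lo, hi)


def likelihood_ratio_test(base: FitResult, full: FitResult) -> LRTResult:
    """Chi-square LRT of two nested ML fits on the same rows.

    If the full model's likelihood falls below the base model's beyond
    numerical tolerance, both are refitted from several starting points;
    a persistent inversion raises.
    """
    if not set(base.term_names) <= set(full.term_names):
        raise ValueError("models are not nested (base terms not a subset)")
    if base.n_obs != full.n_obs or not base.row_index.equals(full.row_index):
        raise ValueError("LRT requires identical rows in both fits")
    df = full.n_params - base.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than the base model")
    if df == 0:
        # identical fixed-effect structure: the comparison is vacuous
        return LRTResult(chi2=0.0, df=0, p=1.0,
                         converged=base.converged and full.converged)
    chi2 = 2.0 * (full.loglik - base.loglik)
    if chi2 < -1e-6 * max(1.0, abs(full.loglik)):
        base = fit_mixed_model(base.spec, base.model_data, restarts=True)
        full = fit_mixed_model(full.spec, full.model_data, restarts=True)
        chi2 = 2.0 * (full.loglik - base.loglik)
        if chi2 < -1e-4 * max(1.0, abs(full.loglik)):
            raise RuntimeError(
                "full-model likelihood below base-model likelihood after restarts"
            )
    chi2 = max(chi2, 0.0)
    p = float(chi2_dist.sf(chi2, df)) if chi2 > 0 else 1.0
    name, est, ci = _added_effect(base, full)
    return LRTResult(
        chi2=float(chi2), df=df, p=p, effect_name=name, estimate=est, ci=ci,
        converged=base.converged and full.converged,
    )


def permutation_lrt(
    base_spec: ModelSpec,
    full_spec: ModelSpec,
    data: pd.DataFrame,
    term: str,
    n_perm: int = 999,
    seed: int = 0,
    within: str | None = None,
) -> dict:
    """Permutation p value for the LRT of one added predictor.

    The tested predictor's values are shuffled within subject (the first
    grouping factor unless ``within`` is given), keeping covariates and
    the grouping structure intact, and both models are refitted for each
    permutation. ``p = (1 + #{chi2_perm >= chi2_obs}) / (1 + n_valid)``.
    Non-convergent permutation fits are redrawn up to 10 times, then
    dropped (count reported).
    """
    if term not in data.columns:
        raise ValueError(f"tested term {term!r} not a data column")
    within = within or full_spec.groups[0]
    base = fit_mixed_model(base_spec, data)
    full = fit_mixed_model(full_spec, data, theta_start=list(base.theta.values()))
    obs = likelihood_ratio_test(base, full)

    rng = np.random.default_rng(seed)
    group_indices = {
        g: np.asarray(ix) for g, ix in data.groupby(within).indices.items()
    }
    values = data[term].to_numpy()
    # the base fit is permutation-invariant when the shuffled term does not
    # enter the base model; skip its refit in that (common) case
    base_uses_term = any(
        term in t.split(":") or term == t for t in base.term_names
    ) or term in base_spec.fixed
    chi2_null = []
    dropped = 0
    theta_b = list(base.theta.values())
    theta_f = list(full.theta.values())
    for _ in range(n_perm):
        ok = False
        for _retry in range(10):
            perm = values.copy()
            for ix in group_indices.values():
                perm[ix] = values[ix][rng.permutation(len(ix))]
            shuffled = data.copy()
            shuffled[term] = perm
            try:
                if base_uses_term:
                    b_ll = fit_mixed_model(
                        base_spec, shuffled, theta_start=theta_b
                    ).loglik
                else:
                    b_ll = base.loglik
                f = fit_mixed_model(full_spec, shuffled, theta_start=theta_f)
                chi2_null.append(max(2.0 * (f.loglik - b_ll), 0.0))
                ok = True
                break
            except (np.linalg.LinAlgError, RuntimeError):
                continue
        if not ok:
            dropped += 1
    chi2_null = np.asarray(chi2_null)
    n_valid = len(chi2_null)
    p = (1.0 + np.sum(chi2_null >= obs.chi2)) / (1.0 + n_valid)
    if dropped:
        logger.warning("permutation LRT: %d draws dropped (non-convergence)",
                       dropped)
    return {
        "p": float(p),
        "chi2_obs": obs.chi2,
        "df": obs.df,
        "n_valid": n_valid,
        "n_dropped": dropped,
        "null": chi2_null,
        "observed_lrt": obs,
    }


@dataclass
class BootstrapORResult:
    odds_ratio: float
    ci: tuple
    n_boot: int
    samples: np.ndarray = field(repr=False, default=None)


def bootstrap_odds_ratio(
    spec: ModelSpec,
    data: pd.DataFrame,
    term: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapORResult:
    """Subject-level case-resampling bootstrap odds ratio with 95% CI.

    Subjects are resampled with replacement (respecting the clustering
    in the data); each resampled subject receives a fresh id so the
    subject random intercept treats duplicates as distinct clusters. The
    point estimate is the full-data fit; the CI is the percentile
    interval of the refitted coefficients. Resamples whose response is
    single-class are redrawn.
    """
    if spec.family != "binomial":
        raise ValueError("bootstrap odds ratios require a binomial model")
    full = fit_mixed_model(spec, data)
    if term not in full.params.index:
        raise ValueError(f"term {term!r} not among fitted coefficients")
    point = float(np.exp(full.params[term]))

    subject_col = spec.groups[0]
    subjects = data[subject_col].unique()
    by_subject = {s: df for s, df in data.groupby(subject_col)}
    rng = np.random.default_rng(seed)
    theta0 = list(full.theta.values())
    draws = []
    for _ in range(n_boot):
        for _retry in range(20):
            chosen = rng.choice(subjects, size=len(subjects), replace=True)
            parts = []
            for new_id, s in enumerate(chosen):
                part = by_subject[s].copy()
                part[subject_col] = f"bs_{new_id}"
                parts.append(part)
            sample = pd.concat(parts, ignore_index=True)
            yvals = patsy.dmatrices(
                spec.formula, sample, NA_action="drop"
            )[0].ravel()
            if len(np.unique(yvals)) < 2:
                continue
            try:
                fit = fit_mixed_model(spec, sample, theta_start=theta0)
            except np.linalg.LinAlgError:
                continue
            if term in fit.params.index:
                draws.append(float(np.exp(fit.params[term])))
                break
    draws = np.asarray(draws)
    ci = tuple(np.percentile(draws, [2.5, 97.5])) if len(draws) else (np.nan, np.nan)
    return BootstrapORResult(odds_ratio=point, ci=ci, n_boot=len(draws),
                             samples=draws)


def posthoc_slopes(
    fit: FitResult,
    by: str,
    term: str,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Per-level simple slopes of ``term`` across the levels of ``by``.

    The fit must contain the ``by`` x ``term`` interaction. Each level's
    slope is the linear combination of the main-effect coefficient and
    the level's interaction coefficient; Wald z tests, with p values
    multiplied by the number of levels under Bonferroni correction
    (capped at 1).
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    cols = list(fit.params.index)
    if term not in cols:
        raise ValueError(f"main effect {term!r} absent from the fit")
    inter = {}
    for c in cols:
        parts = c.split(":")
        if len(parts) == 2 and term in parts:
            other = parts[0] if parts[1] == term else parts[1]
            if other.startswith(f"{by}[") or other.startswith(f"C({by})["):
                level = other.split("[", 1)[1].rstrip("]").removeprefix("T.")
                inter[level] = c
    if not inter and by not in fit.model_data.columns:
        raise ValueError(f"factor {by!r} not found in the fit")
    levels = sorted(pd.unique(fit.model_data[by]).tolist()) if (
        fit.model_data is not None and by in fit.model_data.columns
    ) else sorted(inter)
    if not levels:
        raise ValueError(f"factor {by!r} has no levels")

    beta = fit.params
    cov = fit.cov_params
    rows = []
    for level in levels:
        c = pd.Series(0.0, index=beta.index)
        c[term] = 1.0
        name = inter.get(str(level))
        if name is not None:
            c[name] = 1.0
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov.to_numpy() @ c))
        z = est / se if se > 0 else np.nan
        p = float(2 * norm.sf(abs(z)))
        p_corr = min(1.0, p * len(levels)) if correction == "bonferroni" else p
        rows.append({"level": level, "slope": est, "se": se, "z": z,
                     "p": p, "p_corrected": p_corr})
    return pd.DataFrame(rows)


def fdr_correct(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
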