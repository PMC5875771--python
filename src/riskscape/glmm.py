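"""Logit-link Bernoulli mixed models with Gaussian random intercepts.

Estimation follows the standard Laplace route for binomial GLMMs: given the
fixed effects beta and random-intercept SDs sigma, the random-effect values
u are set to the mode of the joint penalised log-likelihood by Newton
iterations, and the Laplace-approximate marginal log-likelihood

    l(beta, sigma) = l(y | beta, u_hat) - u_hat' D^-1 u_hat / 2
                     - log|D| / 2 - log|Z' W Z + D^-1| / 2

is maximised over (beta, log sigma) with a quasi-Newton search (the
log-determinant depends on beta through the working weights W, so beta
belongs in the outer problem).  The supported grouping structures are a
single site intercept, or box nested in site (each box belongs to exactly
one site); nesting makes every inner linear solve and the log-determinant
closed-form diagonal work, so fits are fast enough to be repeated hundreds
of times inside AIC grid searches.

With no random structure the fit reduces exactly to ordinary logistic
regression (damped Newton / IRLS).  AIC counts fixed effects plus variance
parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.special import expit, ndtr

logger = logging.getLogger(__name__)

__all__ = ["BinomialMixedLogit", "FitResult", "fit_glmm", "wald_table"]

_SEPARATION_BOUND = 15.0
_LOG_SIGMA_MIN = -8.0  # sigma ~ 3e-4: numerically the no-variance boundary
_LOG_SIGMA_MAX = 3.0


@dataclass
class FitResult:
    """Coefficients, uncertainty, likelihood and random-effect summaries."""

    terms: list[str]
    estimate: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    sigma_site: float | None
    sigma_box: float | None
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    fitted: np.ndarray = field(repr=False)
    ranef_site: np.ndarray | None = field(default=None, repr=False)
    ranef_box: np.ndarray | None = field(default=None, repr=False)
    site_levels: np.ndarray | None = field(default=None, repr=False)
    box_levels: np.ndarray | None = field(default=None, repr=False)
    scalers: dict = field(default_factory=dict, repr=False)

    @property
    def z(self) -> np.ndarray:
        return self.estimate / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * ndtr(-np.abs(self.z))

    def params_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimate,
                "se": self.se,
                "z": self.z,
                "p": self.p,
            }
        )

    def coef(self, term: str) -> float:
        return float(self.estimate[self.terms.index(term)])

    def term_se(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def summary_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "sigma_site": self.sigma_site,
            "sigma_box": self.sigma_box,
            "converged": self.converged,
        }


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(-np.logaddexp(0.0, (1.0 - 2.0 * y) * eta).sum())


class BinomialMixedLogit:
    """Estimator-style interface to the Laplace binomial mixed logit.

    Parameters
    ----------
    random : {"site_box", "site", "none"}
        Random-intercept structure: box nested in site, site only, or pure
        logistic regression.
    var_start : float
        Starting random-intercept variance for the outer search.
    tol_loglik, tol_grad, max_inner : inner Newton convergence controls for
        the random-effect mode (relative penalised log-likelihood change,
        gradient infinity norm, iteration cap).
    max_outer : iteration cap for the outer quasi-Newton search.
    se_method : {"hessian", "profile"}
        "hessian" (default) derives the fixed-effect covariance from a
        central-difference Hessian of the Laplace objective over all outer
        parameters (matches glmmTMB-style uncertainty, accounting for the
        variance-parameter estimation); "profile" uses the cheaper
        penalised-likelihood Schur complement at fixed variances, which is
        adequate when only AIC is needed (e.g. inside grid searches).
    """

    def __init__(
        self,
        random: str = "site_box",
        var_start: float = 0.1,
        tol_loglik: float = 1e-11,
        tol_grad: float = 1e-7,
        max_inner: int = 200,
        max_outer: int = 200,
        se_method: str = "hessian",
    ):
        if random not in {"site_box", "site", "none"}:
            raise ValueError("random must be 'site_box', 'site' or 'none'")
        if se_method not in {"hessian", "profile"}:
            raise ValueError("se_method must be 'hessian' or 'profile'")
        self.random = random
        self.var_start = var_start
        self.tol_loglik = tol_loglik
        self.tol_grad = tol_grad
        self.max_inner = max_inner
        self.max_outer = max_outer
        self.se_method = se_method

    # -- sklearn-style plumbing -------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "random", "var_start", "tol_loglik", "tol_grad",
                "max_inner", "max_outer", "se_method",
            )
        }

    def set_params(self, **params) -> "BinomialMixedLogit":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- core --------------------------------------------------------------
    def fit(self, X, y, site=None, box=None, feature_names=None) -> "BinomialMixedLogit":
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")

        site_idx = box_idx = box_site = None
        n_sites = n_boxes = 0
        site_levels = box_levels = None
        if self.random in {"site_box", "site"}:
            if site is None:
                raise ValueError("site grouping required for this random structure")
            site_idx, site_levels = pd.factorize(pd.Series(site), sort=True)
            n_sites = len(site_levels)
        if self.random == "site_box":
            if box is None:
                raise ValueError("box grouping required for nested random structure")
            box_idx, box_levels = pd.factorize(pd.Series(box), sort=True)
            n_boxes = len(box_levels)
            box_site = np.full(n_boxes, -1, dtype=np.int64)
            for b, s in zip(box_idx, site_idx):
                if box_site[b] == -1:
                    box_site[b] = s
                elif box_site[b] != s:
                    raise ValueError("box grouping is not nested within site")

        self._data = (X, y, site_idx, box_idx, box_site, n_sites, n_boxes)

        # Fixed deterministic start: plain-logistic estimates, variance 0.1.
        beta_glm, glm_info = self._glm_newton(X, y)
        n_sigma = {"none": 0, "site": 1, "site_box": 2}[self.random]

        if n_sigma == 0:
            beta = beta_glm
            sigmas: tuple[float, ...] = ()
            loglik = glm_info["loglik"]
            u = v = np.zeros(0)
            converged = glm_info["converged"]
            logdet = 0.0
        else:
            warm = {"uv": (np.zeros(n_sites), np.zeros(n_boxes))}

            def objective(psi):
                res = self._laplace(psi, warm["uv"])
                warm["uv"] = (res["u"], res["v"])
                return -res["loglik"]

            psi0 = np.concatenate(
                [beta_glm, np.full(n_sigma, 0.5 * np.log(self.var_start))]
            )
            bounds = [(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)] * n_sigma
            opt = optimize.minimize(
                objective,
                psi0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.max_outer, "ftol": 1e-11, "gtol": 1e-6},
            )
            final = self._laplace(opt.x, warm["uv"])
            beta = opt.x[:p]
            sigmas = tuple(float(np.exp(s)) for s in opt.x[p:])
            loglik = final["loglik"]
            u, v = final["u"], final["v"]
            logdet = final["logdet_c"]
            converged = bool(opt.success) and final["converged"]

        vcov = None
        if n_sigma > 0 and self.se_method == "hessian":
            vcov = self._numeric_vcov(opt.x, p, warm["uv"])
        if vcov is None:
            vcov = self._beta_vcov(beta, u, v, sigmas)
        se = np.sqrt(np.diag(vcov))
        if np.any(np.abs(beta) > _SEPARATION_BOUND):
            warnings.warn(
                "possible separation: |coefficient| exceeds "
                f"{_SEPARATION_BOUND} on the log-odds scale",
                RuntimeWarning,
                stacklevel=2,
            )
        k = p + n_sigma
        eta = X @ beta
        if site_idx is not None:
            eta = eta + u[site_idx]
        if box_idx is not None:
            eta = eta + v[box_idx]

        self.result_ = FitResult(
            terms=feature_names,
            estimate=beta,
            se=se,
            vcov=vcov,
            sigma_site=sigmas[0] if n_sigma >= 1 else None,
            sigma_box=sigmas[1] if n_sigma >= 2 else None,
            loglik=float(loglik),
            aic=float(-2.0 * loglik + 2.0 * k),
            n_obs=n,
            n_params=k,
            converged=bool(converged),
            fitted=expit(eta),
            ranef_site=u if site_idx is not None else None,
            ranef_box=v if box_idx is not None else None,
            site_levels=np.asarray(site_levels) if site_levels is not None else None,
            box_levels=np.asarray(box_levels) if box_levels is not None else None,
        )
        self.coef_ = beta
        self.n_features_in_ = p
        return self

    def predict_proba(self, X, site=None, box=None) -> np.ndarray:
        """Fitted probabilities including random-effect modes (0 for unseen groups)."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the model first")
        res = self.result_
        if isinstance(X, pd.DataFrame):
            X = X[res.terms].to_numpy(dtype=float)
        eta = np.asarray(X, dtype=float) @ res.estimate
        if res.ranef_site is not None and site is not None:
            lookup = {lv: i for i, lv in enumerate(res.site_levels)}
            eta = eta + np.array([res.ranef_site[lookup[s]] if s in lookup else 0.0 for s in site])
        if res.ranef_box is not None and box is not None:
            lookup = {lv: i for i, lv in enumerate(res.box_levels)}
            eta = eta + np.array([res.ranef_box[lookup[b]] if b in lookup else 0.0 for b in box])
        return expit(eta)

    # -- internals ---------------------------------------------------------
    def _glm_newton(self, X, y):
        """Damped-Newton (IRLS) logistic regression; exact log-likelihood."""
        n, p = X.shape
        beta = np.zeros(p)
        eta = X @ beta
        ll = _bernoulli_loglik(eta, y)
        converged = False
        for _ in range(self.max_inner):
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            g = X.T @ (y - mu)
            A = X.T @ (X * w[:, None])
            try:
                cf = linalg.cho_factor(A)
            except linalg.LinAlgError as exc:
                raise ValueError(
                    "design matrix is rank deficient (singular Hessian)"
                ) from exc
            step = linalg.cho_solve(cf, g)
            t = 1.0
            for _half in range(30):
                beta_n = beta + t * step
                eta_n = X @ beta_n
                ll_n = _bernoulli_loglik(eta_n, y)
                if ll_n >= ll - 1e-12:
                    break
                t *= 0.5
            rel = abs(ll_n - ll) / (abs(ll) + 1.0)
            beta, eta, ll = beta_n, eta_n, ll_n
            if rel < 1e-12 and np.abs(g).max() < 1e-8:
                converged = True
                break
        return beta, {"loglik": ll, "converged": converged}

    def _ranef_mode(self, eta_fixed, prec_s, prec_b, start_uv):
        """Newton solve for the random-effect modes at fixed beta.

        Under nesting the (u, v) Hessian inverts by two diagonal Schur steps,
        so each iteration is O(n + S + B).
        """
        X, y, site_idx, box_idx, box_site, n_sites, n_boxes = self._data
        use_b = box_idx is not None
        u = start_uv[0].copy()
        v = start_uv[1].copy() if use_b else np.zeros(0)

        def eta_of(u, v):
            eta = eta_fixed + u[site_idx]
            if use_b:
                eta = eta + v[box_idx]
            return eta

        def pen(u, v, eta):
            ll = _bernoulli_loglik(eta, y)
            ll -= 0.5 * prec_s * float(u @ u)
            if use_b:
                ll -= 0.5 * prec_b * float(v @ v)
            return ll

        eta = eta_of(u, v)
        ll = pen(u, v, eta)
        converged = False
        Css1 = Cbb = None
        for _ in range(self.max_inner):
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            r = y - mu
            g_u = np.bincount(site_idx, weights=r, minlength=n_sites) - prec_s * u
            bs = np.bincount(site_idx, weights=w, minlength=n_sites)
            Css = bs + prec_s
            if use_b:
                g_v = np.bincount(box_idx, weights=r, minlength=n_boxes) - prec_b * v
                bb = np.bincount(box_idx, weights=w, minlength=n_boxes)
                Cbb = bb + prec_b
                coupl = bb / Cbb
                Css1 = Css - np.bincount(box_site, weights=bb * coupl,
                                         minlength=n_sites)
                g_u1 = g_u - np.bincount(box_site, weights=coupl * g_v,
                                         minlength=n_sites)
                d_u = g_u1 / Css1
                d_v = (g_v - bb * d_u[box_site]) / Cbb
            else:
                Css1 = Css
                d_u = g_u / Css
                d_v = None

            grad_norm = np.abs(g_u).max(initial=0.0)
            if use_b:
                grad_norm = max(grad_norm, np.abs(g_v).max(initial=0.0))

            t = 1.0
            for _half in range(30):
                u_n = u + t * d_u
                v_n = v + t * d_v if use_b else v
                eta_n = eta_of(u_n, v_n)
                ll_n = pen(u_n, v_n, eta_n)
                if ll_n >= ll - 1e-12:
                    break
                t *= 0.5
            rel = abs(ll_n - ll) / (abs(ll) + 1.0)
            u, v, eta, ll = u_n, v_n, eta_n, ll_n
            if rel < self.tol_loglik and grad_norm < self.tol_grad:
                converged = True
                break

        # log|Z' W Z + D^-1| at the mode (recompute weights there)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        bs = np.bincount(site_idx, weights=w, minlength=n_sites)
        Css = bs + prec_s
        if use_b:
            bb = np.bincount(box_idx, weights=w, minlength=n_boxes)
            Cbb = bb + prec_b
            Css1 = Css - np.bincount(box_site, weights=bb * bb / Cbb,
                                     minlength=n_sites)
            logdet = float(np.log(Cbb).sum() + np.log(Css1).sum())
        else:
            logdet = float(np.log(Css).sum())
        return {
            "u": u, "v": v, "eta": eta, "pen_loglik": ll,
            "logdet_c": logdet, "converged": converged,
        }

    def _laplace(self, psi, start_uv):
        """Laplace marginal log-likelihood at (beta, log sigma)."""
        X, y, site_idx, box_idx, box_site, n_sites, n_boxes = self._data
        p = X.shape[1]
        beta = psi[:p]
        log_sig = psi[p:]
        prec_s = float(np.exp(-2.0 * log_sig[0]))
        prec_b = float(np.exp(-2.0 * log_sig[1])) if self.random == "site_box" else None
        mode = self._ranef_mode(X @ beta, prec_s, prec_b, start_uv)
        ll = mode["pen_loglik"] - 0.5 * mode["logdet_c"]
        ll -= n_sites * float(log_sig[0])
        if self.random == "site_box":
            ll -= n_boxes * float(log_sig[1])
        mode["loglik"] = ll
        return mode

    def _numeric_vcov(self, psi_hat, p, uv):
        """Fixed-effect covariance from the observed information of the
        Laplace objective over (beta, log sigma), by central differences.

        Variance parameters stuck at the lower boundary (effectively zero
        variance) are held fixed.  Returns None when the information matrix
        is not positive definite, in which case the caller falls back to the
        profile covariance.
        """
        warm = {"uv": uv}

        def f(psi):
            res = self._laplace(psi, warm["uv"])
            warm["uv"] = (res["u"], res["v"])
            return -res["loglik"]

        free = list(range(p)) + [
            p + i for i in range(len(psi_hat) - p)
            if psi_hat[p + i] > _LOG_SIGMA_MIN + 0.5
        ]
        k = len(free)
        h = 1e-4
        H = np.zeros((k, k))
        for a in range(k):
            for b in range(a, k):
                ea = np.zeros_like(psi_hat)
                eb = np.zeros_like(psi_hat)
                ea[free[a]] = h
                eb[free[b]] = h
                H[a, b] = H[b, a] = (
                    f(psi_hat + ea + eb) - f(psi_hat + ea - eb)
                    - f(psi_hat - ea + eb) + f(psi_hat - ea - eb)
                ) / (4.0 * h * h)
        try:
            cov = linalg.inv(H)
        except linalg.LinAlgError:
            return None
        bcov = cov[:p, :p]
        if np.any(np.diag(bcov) <= 0):
            return None
        return bcov

    def _beta_vcov(self, beta, u, v, sigmas):
        """Fixed-effect covariance: beta block of the inverse joint Hessian.

        Computed by eliminating the (diagonal-solvable) random-effect blocks
        from the penalised-likelihood Hessian at the fitted values, matching
        the usual mixed-model vcov.
        """
        X, y, site_idx, box_idx, box_site, n_sites, n_boxes = self._data
        p = X.shape[1]
        eta = X @ beta
        if site_idx is not None:
            eta = eta + u[site_idx]
        if box_idx is not None:
            eta = eta + v[box_idx]
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        Xw = X * w[:, None]
        A = X.T @ Xw
        if site_idx is not None:
            prec_s = 1.0 / max(sigmas[0], 1e-8) ** 2
            bs = np.bincount(site_idx, weights=w, minlength=n_sites)
            Bs = np.column_stack(
                [np.bincount(site_idx, weights=Xw[:, j], minlength=n_sites)
                 for j in range(p)]
            )
            Css = bs + prec_s
            if box_idx is not None:
                prec_b = 1.0 / max(sigmas[1], 1e-8) ** 2
                bb = np.bincount(box_idx, weights=w, minlength=n_boxes)
                Bb = np.column_stack(
                    [np.bincount(box_idx, weights=Xw[:, j], minlength=n_boxes)
                     for j in range(p)]
                )
                Cbb = bb + prec_b
                inv_cbb = 1.0 / Cbb
                A = A - Bb.T @ (Bb * inv_cbb[:, None])
                coupl = bb * inv_cbb
                np.add.at(Bs, box_site, -(coupl[:, None] * Bb))
                Css = Css - np.bincount(box_site, weights=bb * coupl,
                                        minlength=n_sites)
            A = A - Bs.T @ (Bs / Css[:, None])
        try:
            return linalg.inv(A)
        except linalg.LinAlgError as exc:
            raise ValueError("design matrix is rank deficient") from exc


def fit_glmm(design, warn_nonconverged: bool = True, **estimator_kwargs) -> FitResult:
    """Fit the mixed occupancy model for a built :class:`DesignMatrix`."""
    est = BinomialMixedLogit(random=design.spec.random, **estimator_kwargs)
    est.fit(
        design.X,
        design.y,
        site=design.site if design.spec.random != "none" else None,
        box=design.box if design.spec.random == "site_box" else None,
    )
    res = est.result_
    res.scalers = dict(design.scalers)
    if warn_nonconverged and not res.converged:
        logger.warning("GLMM fit flagged non-converged")
    return res


def wald_table(fit: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Coefficient table with Wald z, two-sided p, and significance marks."""
    if not fit.converged:
        raise ValueError("refusing to tabulate a non-converged fit")
    if np.any(fit.se <= 0) or np.any(~np.isfinite(fit.se)):
        raise ValueError("degenerate standard error in fit")
    tab = fit.params_table()
    tab["significant"] = tab["p"] < alpha
    return tab
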