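"""REML fitting of the random-slopes linear mixed model on balanced data.

The model (trial form) is

    y_ij = beta0 + beta1 * t_j + gamma * z_i * t_j + u0_i + u1_i * t_j + e_ij

with Gaussian random intercepts/slopes and residual error; the observational
form drops the ``gamma`` term.  Because every dataset here is balanced and
complete, the marginal likelihood factorises over subjects with at most two
distinct (design, covariance) patterns — one per arm — so the restricted
log-likelihood is evaluated from per-arm sufficient statistics (sum and
outer-product of the per-subject outcome vectors) with a single visit-level
covariance inverse per evaluation.  Fitting at trial scale therefore costs
microseconds per likelihood call regardless of the number of subjects.

Variance components are optimised on an unconstrained scale: log variances
plus a tanh-transformed intercept-slope correlation clamped to |rho| <= 0.999,
which turns the correlation boundary into an interior (finite) parameter
value.  A fit whose back-transformed correlation has magnitude > 0.99 is
flagged as a boundary fit.  A fixed ladder of optimisers is worked through
until one converges:

1. quasi-Newton (L-BFGS-B) from method-of-moments starting values;
2. Nelder-Mead restarted from the rung-1 endpoint;
3. quasi-Newton from a diagonal-G start (``sigma_u01 = 0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .params import VarianceComponents
from .simulate import LongitudinalDataset

__all__ = ["RandomSlopesFit", "reml_loglik_rs", "fit_random_slopes", "fit_with_ladder"]

_LOG2PI = np.log(2.0 * np.pi)
_RHO_MAX = 0.999
# exp(+/-15) spans ~3e-7 to ~3e6 on an outcome-squared scale: far beyond any
# plausible component, while keeping the covariance numerically sane.
_LOGV_BOUNDS = (-15.0, 15.0)
_X3_BOUND = 20.0  # tanh is fully saturated far before this

_DESIGNS = ("trial", "observational")


@dataclass
class RandomSlopesFit:
    """Result of a random-slopes REML fit.

    ``gamma``/``se_gamma``/``df_gamma`` are None for the observational model,
    which has no treatment term.  ``boundary`` flags an intercept-slope
    correlation estimate of magnitude > 0.99.
    """

    beta0: float
    beta1: float
    gamma: Optional[float]
    vc_hat: VarianceComponents
    se_gamma: Optional[float]
    converged: bool
    boundary: bool
    algorithm_used: Optional[str]
    loglik_reml: float
    df_gamma: Optional[float] = None
    n_subjects: int = 0
    design: str = "trial"

    @property
    def model_kind(self) -> str:
        return "rs"

    def to_dict(self) -> dict:
        d = {
            "model": "rs",
            "design": self.design,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "gamma": self.gamma,
            "se_gamma": self.se_gamma,
            "df_gamma": self.df_gamma,
            "vc_hat": dict(zip(("sigma2_u0", "sigma2_u1", "sigma_u01", "sigma2_e"),
                               self.vc_hat.astuple())),
            "converged": self.converged,
            "boundary": self.boundary,
            "algorithm_used": self.algorithm_used,
            "loglik_reml": self.loglik_reml,
            "n_subjects": self.n_subjects,
        }
        return d


class _Suffstats:
    """Per-arm sufficient statistics of a balanced dataset."""

    def __init__(self, dataset: LongitudinalDataset, design: str):
        if design not in _DESIGNS:
            raise ValueError(f"design must be one of {_DESIGNS}")
        times = dataset.schedule.asarray()
        self.times = times
        self.design = design
        self.p = 3 if design == "trial" else 2
        base = np.column_stack([np.ones_like(times), times])
        self.groups = []  # (N_a, X_a, S_a, Q_a)
        if design == "trial":
            arms = dataset.arms
            if not (0 in arms and 1 in arms):
                raise ValueError("trial design requires both arms present")
            for arm in (0, 1):
                Y = dataset.arm_outcome_matrix(arm)
                X = np.column_stack([base, arm * times])
                self.groups.append((Y.shape[0], X, Y.sum(axis=0), Y.T @ Y))
        else:
            # Observational model ignores arm: one shared design pattern.
            mats = [dataset.arm_outcome_matrix(a) for a in dataset.arms]
            Y = np.vstack(mats)
            self.groups.append((Y.shape[0], base, Y.sum(axis=0), Y.T @ Y))
        self.n_total = sum(g[0] for g in self.groups)
        self.m_total = self.n_total * len(times)


def _reml_pieces(Sigma: np.ndarray, stats: _Suffstats):
    """Return (restricted loglik, information A, X'V^-1 y) at covariance Sigma."""
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return None
    dl = np.diag(L)
    # An extremely ill-conditioned covariance yields garbage solves that can
    # masquerade as a huge likelihood; treat it as an evaluation failure.
    if dl.max() / dl.min() > 1e8:
        return None
    logdet = 2.0 * np.sum(np.log(dl))
    Sinv = np.linalg.inv(Sigma)
    p = stats.p
    A = np.zeros((p, p))
    b = np.zeros(p)
    quad = 0.0
    for N_a, X, S, Q in stats.groups:
        SiX = Sinv @ X
        A += N_a * (X.T @ SiX)
        b += SiX.T @ S
        quad += float(np.sum(Sinv * Q))
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return None
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None
    ypy = quad - float(b @ beta)
    ll = -0.5 * (
        (stats.m_total - p) * _LOG2PI
        + stats.n_total * logdet
        + logdetA
        + ypy
    )
    return ll, A, beta


def reml_loglik_rs(
    dataset: LongitudinalDataset,
    vc: VarianceComponents,
    design: str = "trial",
) -> float:
    """Restricted log-likelihood of the random-slopes model at `vc`.

    Fixed effects are profiled out by GLS; the REML criterion includes the
    ``log|X' V^-1 X|`` adjustment and full Gaussian constants.

    Raises
    ------
    np.linalg.LinAlgError
        If the implied covariance is singular at this parameter point.
    """
    stats = _Suffstats(dataset, design)
    Sigma = vc.marginal_covariance(stats.times)
    pieces = _reml_pieces(Sigma, stats)
    if pieces is None:
        raise np.linalg.LinAlgError("singular covariance at this parameter point")
    return pieces[0]


# ---------------------------------------------------------------------------
# unconstrained parameterisation


def _x_to_vc(x: np.ndarray) -> tuple[float, float, float, float]:
    s2u0 = np.exp(np.clip(x[0], *_LOGV_BOUNDS))
    s2u1 = np.exp(np.clip(x[1], *_LOGV_BOUNDS))
    rho = _RHO_MAX * np.tanh(x[2])
    s2e = np.exp(np.clip(x[3], *_LOGV_BOUNDS))
    return s2u0, s2u1, rho * np.sqrt(s2u0 * s2u1), s2e


def _vc_to_x(s2u0: float, s2u1: float, s_u01: float, s2e: float) -> np.ndarray:
    s2u0 = max(s2u0, 1e-10)
    s2u1 = max(s2u1, 1e-10)
    s2e = max(s2e, 1e-10)
    rho = np.clip(s_u01 / np.sqrt(s2u0 * s2u1), -0.99, 0.99)
    return np.array([np.log(s2u0), np.log(s2u1), np.arctanh(rho / _RHO_MAX), np.log(s2e)])


def _sigma_from_x(x: np.ndarray, times: np.ndarray) -> np.ndarray:
    s2u0, s2u1, s_u01, s2e = _x_to_vc(x)
    Z = np.column_stack([np.ones_like(times), times])
    G = np.array([[s2u0, s_u01], [s_u01, s2u1]])
    return Z @ G @ Z.T + s2e * np.eye(len(times))


def _neg_reml(x: np.ndarray, stats: _Suffstats) -> float:
    Sigma = _sigma_from_x(x, stats.times)
    pieces = _reml_pieces(Sigma, stats)
    if pieces is None:
        return 1e12
    return -pieces[0]


def _mom_start(dataset: LongitudinalDataset, stats: _Suffstats) -> np.ndarray:
    """Method-of-moments starting values from per-subject OLS lines.

    Outcomes are first centred on arm-by-visit sample means, then each
    subject's residual profile is regressed on time; the covariance of the
    per-subject coefficients minus the OLS noise contribution starts G, and
    pooled within-subject residual variance starts sigma2_e.
    """
    times = stats.times
    n_v = len(times)
    A = np.column_stack([np.ones_like(times), times])
    pinvA = np.linalg.pinv(A)
    resid_mats = []
    for arm in dataset.arms:
        Y = dataset.arm_outcome_matrix(arm)
        resid_mats.append(Y - Y.mean(axis=0, keepdims=True))
    R = np.vstack(resid_mats)  # (N, n_v), centred profiles
    B = R @ pinvA.T  # per-subject (intercept, slope)
    fitted = B @ A.T
    rss = float(np.sum((R - fitted) ** 2))
    if n_v > 2:
        s2e = rss / (R.shape[0] * (n_v - 2))
    else:
        s2e = np.var(R) * 0.5
    s2e = max(s2e, 1e-6)
    covB = np.cov(B, rowvar=False)
    noise = s2e * np.linalg.pinv(A.T @ A)
    G0 = covB - noise
    # Floors keep the log-scale start away from the edge of the box when the
    # moment estimate of a variance is (near-)negative.
    s2u0 = max(G0[0, 0], 1e-4)
    s2u1 = max(G0[1, 1], 1e-5)
    return _vc_to_x(s2u0, s2u1, G0[0, 1], s2e)


def _run_rung(name: str, x0: np.ndarray, stats: _Suffstats):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if name.startswith("nelder"):
            res = optimize.minimize(
                _neg_reml, x0, args=(stats,), method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000, "maxfev": 4000},
            )
            ok = bool(res.success) and np.isfinite(res.fun)
        else:
            bounds = [(-30, 30), (-30, 30), (-_X3_BOUND, _X3_BOUND), (-30, 30)]
            res = optimize.minimize(
                _neg_reml, x0, args=(stats,), method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-6, "maxiter": 500},
            )
            grad_ok = np.max(np.abs(res.jac)) < 1e-2 * max(1.0, abs(res.fun)) ** 0.5
            ok = np.isfinite(res.fun) and (bool(res.success) or grad_ok)
    return res, ok


def fit_random_slopes(
    dataset: LongitudinalDataset,
    design: str = "trial",
    compute_df: bool = True,
) -> RandomSlopesFit:
    """Fit the random-slopes model by REML, working through the optimiser ladder.

    Parameters
    ----------
    dataset
        Balanced complete data; both arms required when ``design="trial"``.
    design
        ``"trial"`` fits the treatment-slope term; ``"observational"`` omits
        it (the variance-component model used at the design stage).
    compute_df
        Whether to compute Satterthwaite-style degrees of freedom for the
        treatment slope (trial design only); skipping it saves a numerical
        Hessian when only the variance components are needed.

    Non-convergence is reported via ``converged=False`` on the returned fit,
    never raised.
    """
    stats = _Suffstats(dataset, design)
    x_mom = _mom_start(dataset, stats)
    rungs = [("lbfgs-mom", x_mom)]
    best = None
    algorithm = None
    for i, (name, x0) in enumerate(rungs):
        res, ok = _run_rung(name, x0, stats)
        if best is None or res.fun < best.fun:
            best = res
        if ok:
            algorithm = name
            best = res
            break
        if i == 0:
            # rung 2: simplex restart from the rung-1 endpoint
            rungs.append(("nelder-mead", np.asarray(res.x, dtype=float)))
        elif i == 1:
            # rung 3: quasi-Newton from a diagonal-G start
            x_diag = x_mom.copy()
            x_diag[2] = 0.0
            rungs.append(("lbfgs-diag", x_diag))
    converged = algorithm is not None
    if converged:
        # Derivative-free polish: the quasi-Newton rungs rely on noisy
        # finite-difference gradients, which caps their final precision; a
        # short simplex descent from the accepted point recovers the last
        # few decimals of the restricted likelihood.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            polish = optimize.minimize(
                _neg_reml, np.asarray(best.x, dtype=float), args=(stats,),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 800, "maxfev": 800},
            )
        if np.isfinite(polish.fun) and polish.fun <= best.fun:
            best = polish
    x_hat = np.asarray(best.x, dtype=float)
    s2u0, s2u1, s_u01, s2e = _x_to_vc(x_hat)
    vc_hat = VarianceComponents(s2u0, s2u1, s_u01, s2e)
    pieces = _reml_pieces(vc_hat.marginal_covariance(stats.times), stats)
    if pieces is None:  # pragma: no cover - valid vc always has PD covariance
        ll, A, beta = -np.inf, np.eye(stats.p), np.zeros(stats.p)
        converged = False
    else:
        ll, A, beta = pieces
    cov_beta = np.linalg.inv(A)
    boundary = converged and abs(vc_hat.correlation) > 0.99
    gamma = se_gamma = df_gamma = None
    if design == "trial":
        gamma = float(beta[2])
        se_gamma = float(np.sqrt(cov_beta[2, 2]))
        if compute_df and converged:
            df_gamma = _satterthwaite_df(x_hat, stats)
        else:
            df_gamma = float(stats.n_total - 2)
    return RandomSlopesFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        gamma=gamma,
        vc_hat=vc_hat,
        se_gamma=se_gamma,
        converged=converged,
        boundary=boundary,
        algorithm_used=algorithm,
        loglik_reml=float(ll),
        df_gamma=df_gamma,
        n_subjects=stats.n_total,
        design=design,
    )


def fit_with_ladder(dataset: LongitudinalDataset, design: str = "trial") -> RandomSlopesFit:
    """Alias for :func:`fit_random_slopes`: the ladder is the default path."""
    return fit_random_slopes(dataset, design)


def _v_gamma(x: np.ndarray, stats: _Suffstats) -> float:
    Sigma = _sigma_from_x(x, stats.times)
    pieces = _reml_pieces(Sigma, stats)
    if pieces is None:
        return np.nan
    return float(np.linalg.inv(pieces[1])[2, 2])


def _satterthwaite_df(x_hat: np.ndarray, stats: _Suffstats) -> float:
    """Satterthwaite-style df for the treatment slope.

    df = 2 V^2 / Var(V-hat) with V = Var(gamma-hat) as a function of the
    variance components; the gradient of V and the observed REML information
    are both obtained by central finite differences on the transformed scale
    (the df is invariant to the parameterisation).  Falls back to the
    between-subject residual df when the information matrix is not usable.
    """
    fallback = float(max(stats.n_total - 2, 3))
    try:
        n = len(x_hat)
        h = 1e-4
        V0 = _v_gamma(x_hat, stats)
        grad = np.zeros(n)
        for i in range(n):
            e = np.zeros(n)
            e[i] = h
            grad[i] = (_v_gamma(x_hat + e, stats) - _v_gamma(x_hat - e, stats)) / (2 * h)
        hh = 1e-3
        H = np.zeros((n, n))
        f0 = _neg_reml(x_hat, stats)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = hh
                ej = np.zeros(n); ej[j] = hh
                if i == j:
                    fpp = _neg_reml(x_hat + ei, stats)
                    fmm = _neg_reml(x_hat - ei, stats)
                    H[i, i] = (fpp - 2 * f0 + fmm) / hh**2
                else:
                    fpp = _neg_reml(x_hat + ei + ej, stats)
                    fpm = _neg_reml(x_hat + ei - ej, stats)
                    fmp = _neg_reml(x_hat - ei + ej, stats)
                    fmm = _neg_reml(x_hat - ei - ej, stats)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hh**2)
        if not np.all(np.isfinite(H)) or not np.isfinite(V0) or V0 <= 0:
            return fallback
    except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
        return fallback
    # Use the pseudo-inverse: near the correlation boundary the information
    # in the saturated tanh direction is ~0 and contributes ~0 variance.
    C = np.linalg.pinv(H, rcond=1e-10, hermitian=True)
    denom = float(grad @ C @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return fallback
    df = 2.0 * V0**2 / denom
    if not np.isfinite(df) or df < 3:
        return fallback if df < 1 else max(df, 3.0)
    return float(min(df, 1e7))
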