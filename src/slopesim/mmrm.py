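"""Marginal repeated-measures models with unstructured covariance.

Three relaxations of the random-slopes model, all Gaussian with a free
(n_visits x n_visits) covariance shared by the two arms:

* ``ltfc``  — linear trajectories, free covariance:
  ``y_ij = beta0 + beta1 t_j + gamma z_i t_j + eps_ij``
* ``fctfc`` — free control-group trajectory, free covariance:
  ``y_ij = beta_j + gamma z_i t_j + eps_ij``
* ``ftfc``  — free trajectories, free covariance:
  ``y_ij = beta_j + gamma_j z_i + eps_ij`` with ``gamma_0 = 0`` (randomisation
  guarantees equal means at baseline, so no baseline effect is estimated).

Fitting is Gaussian maximum likelihood by iterated GLS: alternate the GLS
fixed-effect solve (with the covariance held block-diagonal at the current
visit-level estimate) and the covariance update (average of residual outer
products across subjects, divisor N) until the log-likelihood is stationary.
Balanced data again reduce everything to per-arm sufficient statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import LongitudinalDataset

__all__ = ["MarginalFit", "fit_marginal", "MARGINAL_KINDS"]

_LOG2PI = np.log(2.0 * np.pi)

MARGINAL_KINDS = ("ltfc", "fctfc", "ftfc")


@dataclass
class MarginalFit:
    """Result of an iterated-GLS marginal-model fit.

    ``fixed_effects`` is ordered so its *last* entry is the treatment
    parameter relevant to the final-visit estimand: ``gamma`` for
    ``ltfc``/``fctfc``; the final-visit ``gamma_j`` for ``ftfc`` (preceded by
    the earlier post-baseline effects).
    """

    model_kind: str
    fixed_effects: np.ndarray
    coef_names: tuple[str, ...]
    sigma_hat: np.ndarray
    cov_fixed: np.ndarray
    converged: bool
    loglik: float
    n_subjects: int
    n_iter: int = 0

    @property
    def gamma(self) -> float:
        """Treatment parameter for the final-visit estimand (see class docs)."""
        return float(self.fixed_effects[-1])

    @property
    def se_gamma(self) -> float:
        return float(np.sqrt(self.cov_fixed[-1, -1]))

    @property
    def df_resid(self) -> float:
        # Between-subject residual df: subjects minus the rank of the
        # between-subject (arm) design, i.e. N - 2 for a two-arm trial.
        return float(self.n_subjects - 2)

    def to_dict(self) -> dict:
        return {
            "model": self.model_kind,
            "coef": dict(zip(self.coef_names, map(float, self.fixed_effects))),
            "se": dict(
                zip(self.coef_names, map(float, np.sqrt(np.diag(self.cov_fixed))))
            ),
            "sigma_hat": self.sigma_hat.tolist(),
            "converged": self.converged,
            "loglik": self.loglik,
            "n_subjects": self.n_subjects,
        }


def _design_matrices(kind: str, times: np.ndarray):
    """Per-arm fixed-effect design matrices (control, treated) and names."""
    n_v = len(times)
    ones = np.ones_like(times)
    eye = np.eye(n_v)
    if kind == "ltfc":
        names = ("beta0", "beta1", "gamma")
        Xc = np.column_stack([ones, times, 0.0 * times])
        Xt = np.column_stack([ones, times, times])
    elif kind == "fctfc":
        names = tuple(f"beta_{j}" for j in range(n_v)) + ("gamma",)
        Xc = np.column_stack([eye, 0.0 * times])
        Xt = np.column_stack([eye, times])
    elif kind == "ftfc":
        if n_v < 2:
            raise ValueError("ftfc needs at least 2 visits")
        names = tuple(f"beta_{j}" for j in range(n_v)) + tuple(
            f"gamma_{j}" for j in range(1, n_v)
        )
        # gamma_0 is identically zero, not estimated.
        E = eye[:, 1:]
        Xc = np.column_stack([eye, 0.0 * E])
        Xt = np.column_stack([eye, E])
    else:
        raise ValueError(f"unknown marginal model kind {kind!r}")
    return (Xc, Xt), names


def fit_marginal(
    dataset: LongitudinalDataset,
    model_kind: str,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> "MarginalFit":
    """Fit one of the unstructured-covariance models by iterated GLS (ML).

    Parameters
    ----------
    dataset
        Balanced, complete, two-arm trial data.
    model_kind
        ``"ltfc"``, ``"fctfc"`` or ``"ftfc"``.
    tol
        Relative log-likelihood change declaring the fixed point reached.
    max_iter
        Iteration budget; exceeding it sets ``converged=False``.
    """
    kind = model_kind.lower()
    times = dataset.schedule.asarray()
    (Xc, Xt), names = _design_matrices(kind, times)
    arms = dataset.arms
    if not (0 in arms and 1 in arms):
        raise ValueError("marginal models require a two-arm trial dataset")
    groups = []
    for arm, X in ((0, Xc), (1, Xt)):
        Y = dataset.arm_outcome_matrix(arm)
        groups.append((Y.shape[0], X, Y.sum(axis=0), Y.T @ Y))
    N = sum(g[0] for g in groups)
    n_v = len(times)
    p = Xc.shape[1]

    # Start from the pooled within-arm scatter (divisor N).
    Sigma = sum(Q - np.outer(S, S) / N_a for N_a, _, S, Q in groups) / N
    Sigma += 1e-8 * np.mean(np.diag(Sigma)) * np.eye(n_v)

    def gls_beta(Sigma):
        Sinv = np.linalg.inv(Sigma)
        A = np.zeros((p, p))
        b = np.zeros(p)
        for N_a, X, S, Q in groups:
            SiX = Sinv @ X
            A += N_a * (X.T @ SiX)
            b += SiX.T @ S
        return np.linalg.solve(A, b), A, Sinv

    def resid_scatter(beta):
        out = np.zeros((n_v, n_v))
        for N_a, X, S, Q in groups:
            m = X @ beta
            out += Q - np.outer(S, m) - np.outer(m, S) + N_a * np.outer(m, m)
        return out / N

    def loglik(Sigma, beta, Sinv):
        C = resid_scatter(beta)
        sign, logdet = np.linalg.slogdet(Sigma)
        return -0.5 * (
            N * n_v * _LOG2PI + N * logdet + N * float(np.sum(Sinv * C))
        )

    converged = False
    ll_old = -np.inf
    beta = np.zeros(p)
    A = np.eye(p)
    it = 0
    for it in range(1, max_iter + 1):
        try:
            beta, A, Sinv = gls_beta(Sigma)
        except np.linalg.LinAlgError:
            break
        ll = loglik(Sigma, beta, Sinv)
        Sigma = resid_scatter(beta)
        if np.isfinite(ll) and abs(ll - ll_old) <= tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll
    # Final evaluation at the fixed point.
    try:
        beta, A, Sinv = gls_beta(Sigma)
        ll = loglik(Sigma, beta, Sinv)
        cov_fixed = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        converged = False
        ll = -np.inf
        cov_fixed = np.full((p, p), np.nan)
    return MarginalFit(
        model_kind=kind,
        fixed_effects=np.asarray(beta, dtype=float),
        coef_names=names,
        sigma_hat=Sigma,
        cov_fixed=cov_fixed,
        converged=converged,
        loglik=float(ll),
        n_subjects=N,
        n_iter=it,
    )
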