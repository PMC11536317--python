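"""Dense REML for linear mixed models with independent variance components.

Fits y = X b + sum_k Z_k u_k + e with u_k ~ N(0, s2_k I) and
e ~ N(0, s2_e I) by average-information (AI) REML with an EM fallback
whenever an AI step would leave the parameter space or decrease the
restricted likelihood.  Everything is dense; intended for field-trial
sized problems (n up to a few thousand plots, a handful of components).

Standard errors of the components come from the inverse AI matrix at the
optimum, which approximates the Fisher information.  Components are kept
non-negative throughout (boundary estimates are reported as 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class RemlError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message + f" (log-likelihood trace: {trace})")
        self.trace = trace


@dataclass
class RemlFit:
    """Converged REML solution."""

    names: list[str]  # component names, residual last
    sigma2: np.ndarray  # variance components, residual last
    sigma2_se: np.ndarray
    sigma2_cov: np.ndarray  # inverse AI matrix
    loglik: float
    beta: np.ndarray
    beta_cov: np.ndarray
    n_iter: int
    trace: list[float] = field(default_factory=list)

    def component(self, name: str) -> float:
        return float(self.sigma2[self.names.index(name)])

    def component_se(self, name: str) -> float:
        return float(self.sigma2_se[self.names.index(name)])


def _reml_pieces(y, X, Gs, theta):
    """V, P, Py and the restricted log-likelihood at theta."""
    n = y.shape[0]
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], Gs):
        V += t * G
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    XtVinvX = XtVinv @ X
    XtVinvX_inv = np.linalg.inv(XtVinvX)
    P = Vinv - XtVinv.T @ XtVinvX_inv @ XtVinv
    Py = P @ y
    sign, logdetV = np.linalg.slogdet(V)
    sign2, logdetXVX = np.linalg.slogdet(XtVinvX)
    ll = -0.5 * (logdetV + logdetXVX + float(y @ Py))
    return V, Vinv, P, Py, ll, XtVinvX_inv, XtVinv


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z_list: list[np.ndarray],
    names: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    init: np.ndarray | None = None,
) -> RemlFit:
    """AI-REML with EM fallback for a multi-component mixed model.

    Parameters
    ----------
    y : response vector (n,)
    X : fixed-effect design (n, p), full column rank
    Z_list : incidence matrices for each random factor, (n, q_k)
    names : labels for the components; 'residual' is appended
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed-effect columns than observations")
    K = len(Z_list)
    if names is None:
        names = [f"vc{k}" for k in range(K)]
    names = list(names) + ["residual"]
    Gs = [np.asarray(Z, dtype=float) @ np.asarray(Z, dtype=float).T for Z in Z_list]
    qs = [Z.shape[1] for Z in Z_list] + [len(y)]  # EM denominators

    vary = float(np.var(y))
    if vary == 0.0:
        raise ValueError("response has zero variance; REML is degenerate")
    floor = 1e-10 * vary
    theta = np.full(K + 1, vary / (K + 1)) if init is None else np.asarray(init, float).copy()
    theta = np.maximum(theta, floor)

    trace: list[float] = []
    _, _, P, Py, ll, XtVinvX_inv, XtVinv = _reml_pieces(y, X, Gs, theta)
    trace.append(ll)
    AI = np.eye(K + 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        all_G = Gs + [np.eye(n)]
        GPy = [G @ Py for G in all_G]
        score = np.empty(K + 1)
        for k, (G, gpy) in enumerate(zip(all_G, GPy)):
            trPG = float(np.sum(P * G))  # G symmetric
            score[k] = -0.5 * (trPG - float(Py @ gpy))
        AI = np.empty((K + 1, K + 1))
        PGPy = [P @ gpy for gpy in GPy]
        for k in range(K + 1):
            for l in range(k, K + 1):
                AI[k, l] = AI[l, k] = 0.5 * float(GPy[k] @ PGPy[l])

        # active set: components pinned at the zero boundary with a
        # negative gradient stay pinned and leave the Newton step
        pinned = (theta <= 2 * floor) & (score < 0)
        free = ~pinned
        step_ok = False
        delta = None
        if free.any():
            try:
                delta_free = np.linalg.solve(AI[np.ix_(free, free)], score[free])
                delta = np.zeros(K + 1)
                delta[free] = delta_free
            except np.linalg.LinAlgError:
                delta = None
        if delta is not None:
            # clamp at the boundary and halve until the likelihood improves
            for halving in range(6):
                cand = np.maximum(theta + delta / (2**halving), floor)
                _, _, P2, Py2, ll2, Xi2, XtVinv2 = _reml_pieces(y, X, Gs, cand)
                if np.isfinite(ll2) and ll2 >= ll - 1e-10:
                    step_ok = True
                    break

        if not step_ok:
            # EM update: always in-bounds, monotone in the likelihood
            cand = theta.copy()
            for k, (G, gpy) in enumerate(zip(all_G, GPy)):
                trPG = float(np.sum(P * G))
                cand[k] = theta[k] + (theta[k] ** 2 / qs[k]) * (float(Py @ gpy) - trPG)
            cand = np.maximum(cand, floor)
            _, _, P2, Py2, ll2, Xi2, XtVinv2 = _reml_pieces(y, X, Gs, cand)

        d_ll = ll2 - ll
        theta, P, Py, ll, XtVinvX_inv, XtVinv = cand, P2, Py2, ll2, Xi2, XtVinv2
        trace.append(ll)
        if abs(d_ll) < tol:
            converged = True
            break

    if not converged:
        raise RemlError(f"REML did not converge in {max_iter} iterations", trace)

    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    beta = XtVinvX_inv @ (XtVinv @ y)
    out_theta = np.where(theta <= 2 * floor, 0.0, theta)
    return RemlFit(
        names=names,
        sigma2=out_theta,
        sigma2_se=se,
        sigma2_cov=cov,
        loglik=ll,
        beta=beta,
        beta_cov=XtVinvX_inv,
        n_iter=it,
        trace=trace,
    )


def indicator_matrix(labels) -> tuple[np.ndarray, list]:
    """0/1 incidence matrix for a categorical vector, columns in sorted order."""
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    Z = np.zeros((labels.shape[0], len(levels)))
    index = {lv: j for j, lv in enumerate(levels)}
    for i, lab in enumerate(labels):
        Z[i, index[lab]] = 1.0
    return Z, levels
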