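"""Generic numerical REML oracle for the four-component mixed model.

Independent cross-check for the closed-form balanced estimators: builds the
full marginal covariance V = s2_G Z_G Z_G' + s2_A Z_A Z_A' + s2_GP Z_GP Z_GP'
+ s2_e I explicitly and maximises the restricted log-likelihood over the four
variance parameters with a gradient-based optimiser (analytic REML gradient,
log-parameterised).  No expected-mean-square algebra is used anywhere, so
agreement with the closed-form path is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

STRATA = ("sigma2_group", "sigma2_animal", "sigma2_group_phase", "sigma2_residual")


def design_matrices(n_g: int, n_n: int, n_p: int):
    """Fixed-effects X (intercept + phase dummies) and random-effects Z blocks.

    Row order matches ``y.ravel()`` of a (n_g, n_n, n_p) response array.
    """
    n = n_g * n_n * n_p
    g_idx, a_idx, p_idx = np.unravel_index(np.arange(n), (n_g, n_n, n_p))
    X = np.zeros((n, n_p))
    X[:, 0] = 1.0
    for p in range(1, n_p):
        X[:, p] = (p_idx == p).astype(float)
    Z_G = np.eye(n_g)[g_idx]
    Z_A = np.eye(n_g * n_n)[g_idx * n_n + a_idx]
    Z_GP = np.eye(n_g * n_p)[g_idx * n_p + p_idx]
    return X, (Z_G, Z_A, Z_GP)


def _m2reml_and_grad(s2, y_flat, X, Zs):
    """-2 restricted log-likelihood (constant dropped) and its gradient in s2."""
    n = len(y_flat)
    eye = np.eye(n)
    blocks = [Z @ Z.T for Z in Zs] + [eye]
    V = sum(s * B for s, B in zip(s2, blocks))
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(4)
    Vi = np.linalg.inv(V)
    logdetV = 2.0 * float(np.log(np.diag(c)).sum())
    XtViX = X.T @ Vi @ X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, np.zeros(4)
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y_flat)
    r = y_flat - X @ beta
    Py = Vi @ r
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    value = float(logdetV + logdetX + r @ Py)
    grad = np.array([float(np.sum(P * B) - Py @ B @ Py) for B in blocks])
    return value, grad


def reml_fit(y: np.ndarray, x0=None) -> dict[str, float]:
    """Maximise the restricted likelihood numerically; returns the four components.

    Starts from an equal split of the total variance (not from the
    closed-form estimates); log-parameterised L-BFGS-B with analytic
    gradients, then a tight polishing pass.  Only meaningful for interior
    optima (all components > 0).
    """
    n_g, n_n, n_p = y.shape
    X, Zs = design_matrices(n_g, n_n, n_p)
    y_flat = y.ravel()
    total = float(y_flat.var())
    start = np.full(4, max(total, 1e-6) / 4.0) if x0 is None else np.asarray(x0, float)

    def obj(log_s2):
        s2 = np.exp(log_s2)
        value, grad = _m2reml_and_grad(s2, y_flat, X, Zs)
        return value, grad * s2  # chain rule onto the log scale

    res = optimize.minimize(obj, np.log(start), jac=True, method="L-BFGS-B",
                            options={"ftol": 1e-17, "gtol": 1e-12, "maxiter": 5000})
    res = optimize.minimize(obj, res.x, jac=True, method="L-BFGS-B",
                            options={"ftol": 1e-18, "gtol": 1e-13, "maxiter": 5000})
    return dict(zip(STRATA, map(float, np.exp(res.x))))
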