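"""Hot numerical kernels for the forward-Euler transcription.

The discretized optimal-control problem is solved in reduced form: the Euler
equality constraints are eliminated by running the recursion
``x[k+1] = x[k] + h f(x[k], u[k])`` forward, and the exact gradient of the
discrete objective with respect to the control vector is obtained by a
reverse (adjoint) sweep through the same recursion.  Both sweeps are plain
scalar loops so that numba can compile them; if numba is unavailable the
pure-Python versions are used unchanged.

Parameter vector layout ``p`` (see ``ModelParams.as_vector``):
    [lambda1, lambda2, tau1, tau2, mu, b, d, beta1, beta, gamma]
Weight vector layout ``w`` (see ``ObjectiveWeights.as_vector``):
    [omega1, omega2, eta1, eta2, xi, epsilon, theta]
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["euler_states", "euler_objective_gradient", "HAVE_NUMBA"]

# Euler states are clamped to this floor before taking logarithms; for the
# dose and parameter ranges the package targets it is never active, but it
# keeps exploratory line-search iterates well defined.
_FLOOR = 1e-9


def _rhs_scalar(n1, n2, k, u, v, p):
    n = n1 + n2
    log_ratio = math.log(n / k)
    dn1 = -p[0] * n1 * log_ratio - p[2] * n1 + p[3] * n2 - p[7] * n1 * u
    dn2 = -p[1] * n2 * log_ratio + p[2] * n1 - p[3] * n2
    dk = -p[4] * k + p[5] * n - p[6] * n ** (2.0 / 3.0) * k - p[8] * k * u - p[9] * k * v
    return dn1, dn2, dk


def euler_states(u, v, x0, h, p):
    """Forward-Euler state sequence, shape (M+1, 3), for control vector ``u``."""
    m = u.shape[0]
    xs = np.empty((m + 1, 3))
    xs[0, 0] = x0[0]
    xs[0, 1] = x0[1]
    xs[0, 2] = x0[2]
    for kk in range(m):
        n1 = max(xs[kk, 0], _FLOOR)
        n2 = max(xs[kk, 1], _FLOOR)
        k = max(xs[kk, 2], _FLOOR)
        dn1, dn2, dk = _rhs_scalar(n1, n2, k, u[kk], v, p)
        xs[kk + 1, 0] = n1 + h * dn1
        xs[kk + 1, 1] = n2 + h * dn2
        xs[kk + 1, 2] = k + h * dk
    return xs


def euler_objective_gradient(u, v, x0, h, p, w):
    """Discrete objective (left-rectangle quadrature) and its exact gradient.

    Returns ``(J, grad)`` where ``grad[k] = dJ/du[k]`` from the adjoint
    recursion through the forward-Euler dynamics.
    """
    m = u.shape[0]
    omega1, omega2, eta1, eta2, xi, eps, theta = w[0], w[1], w[2], w[3], w[4], w[5], w[6]
    xs = euler_states(u, v, x0, h, p)

    j = 0.0
    for kk in range(m):
        n1 = xs[kk, 0]
        n2 = xs[kk, 1]
        pen = 0.5 * xi * (1.0 + math.tanh((n2 - n1) / eps))
        j += h * (eta1 * n1 + eta2 * n2 + pen + theta * u[kk])
    j += omega1 * xs[m, 0] + omega2 * xs[m, 1]

    # adjoint sweep
    lam1 = omega1
    lam2 = omega2
    lam3 = 0.0
    grad = np.empty(m)
    for kk in range(m - 1, -1, -1):
        n1 = max(xs[kk, 0], _FLOOR)
        n2 = max(xs[kk, 1], _FLOOR)
        k = max(xs[kk, 2], _FLOOR)
        n = n1 + n2
        log_ratio = math.log(n / k)

        # dJ/du_k = theta*h + h * lam^T df/du
        grad[kk] = theta * h + h * (lam1 * (-p[7] * n1) + lam3 * (-p[8] * k))

        # running-cost state gradient
        th = math.tanh((n2 - n1) / eps)
        sech2 = 1.0 - th * th
        l1 = h * (eta1 - 0.5 * xi * sech2 / eps)
        l2 = h * (eta2 + 0.5 * xi * sech2 / eps)
        l3 = 0.0

        # analytic Jacobian of the rhs
        a11 = -p[0] * log_ratio - p[0] * n1 / n - p[2] - p[7] * u[kk]
        a12 = -p[0] * n1 / n + p[3]
        a13 = p[0] * n1 / k
        a21 = -p[1] * n2 / n + p[2]
        a22 = -p[1] * log_ratio - p[1] * n2 / n - p[3]
        a23 = p[1] * n2 / k
        dvdn = (2.0 / 3.0) * p[6] * n ** (-1.0 / 3.0) * k
        a31 = p[5] - dvdn
        a32 = p[5] - dvdn
        a33 = -p[4] - p[6] * n ** (2.0 / 3.0) - p[8] * u[kk] - p[9] * v

        # lam_k = L_x + lam_{k+1}^T (I + h A)
        nl1 = l1 + lam1 * (1.0 + h * a11) + lam2 * h * a21 + lam3 * h * a31
        nl2 = l2 + lam1 * h * a12 + lam2 * (1.0 + h * a22) + lam3 * h * a32
        nl3 = l3 + lam1 * h * a13 + lam2 * h * a23 + lam3 * (1.0 + h * a33)
        lam1, lam2, lam3 = nl1, nl2, nl3
    return j, grad


try:  # compile the sweeps when numba is present; fall back silently otherwise
    from numba import njit

    _rhs_scalar = njit(cache=False)(_rhs_scalar)
    euler_states = njit(cache=False)(euler_states)
    euler_objective_gradient = njit(cache=False)(euler_objective_gradient)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False
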