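"""Sequential numerical kernels (MVAR recursion, dual Kalman filtering).

These loops are inherently sample-by-sample; they are JIT-compiled with numba
when available and fall back to identical pure-Python implementations
otherwise.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def mvar_recurse(Astack: np.ndarray, u: np.ndarray, p: int) -> np.ndarray:
    """x_t = sum_r A_r x_{t-r} + u_t with A_r stacked as (n, n*p)."""
    n, T = u.shape
    x = np.zeros((n, T))
    for t in range(T):
        if t < p:
            for i in range(n):
                x[i, t] = u[i, t]
        else:
            for i in range(n):
                acc = u[i, t]
                for r in range(p):
                    base = r * n
                    for j in range(n):
                        acc += Astack[i, base + j] * x[j, t - r - 1]
                x[i, t] = acc
    return x


@njit(cache=False)
def dual_ekf_core(y: np.ndarray, p: int, q: float, sigma_e: np.ndarray,
                  r_obs: np.ndarray, p0: float, theta0: np.ndarray):
    """Dual (state + parameter) Kalman filtering of a vector AR process.

    y : (n, T) standardized signals
    sigma_e : per-channel innovation variance of the AR process (state
        process noise; also the parameter filter's measurement noise)
    r_obs : per-channel observation noise variance (how far the recorded
        samples may sit from the true AR state)
    theta0 : (n, n*p) initial coefficients (row i stacks channel i's lag
        coefficients, lag-major: [lag1 ch0..chn, lag2 ch0..chn, ...])

    Two filters run in tandem each sample.  The state filter propagates the
    companion-form AR model with the current coefficients and innovation
    covariance, treating ``y`` as an observation with noise ``r_obs``, and
    emits filtered signal values.  The parameter filter models each channel's
    coefficient row as a random walk (process noise ``q``) observed through
    the shared regressor of filtered past values; its covariance is block
    diagonal with one (n*p, n*p) block per channel.

    Returns (coeffs (T, n, n*p), residuals (n, T), parameter-covariance trace
    per step).
    """
    n, T = y.shape
    d = n * p
    P_th = np.empty((n, d, d))
    for i in range(n):
        P_th[i] = np.eye(d) * p0
    theta = theta0.copy()

    # companion state s = [x_t, x_{t-1}, ..., x_{t-p+1}]
    s = np.zeros(d)
    for k in range(p):
        for i in range(n):
            s[k * n + i] = y[i, max(p - 1 - k, 0)]
    P_s = np.eye(d)
    xf = y.copy()  # filtered signal estimates (first p samples kept raw)

    coeffs = np.zeros((T, n, d))
    resid = np.zeros((n, T))
    tr = np.zeros(T)

    F = np.zeros((d, d))
    for k in range(n, d):
        F[k, k - n] = 1.0
    Q_s = np.zeros((d, d))
    for i in range(n):
        Q_s[i, i] = sigma_e[i]

    for t in range(p, T):
        # ----- state filter (predict with current parameters, update on y_t)
        for i in range(n):
            for j in range(d):
                F[i, j] = theta[i, j]
        s_pred = F @ s
        P_pred = F @ P_s @ F.T + Q_s
        v = np.empty(n)
        for i in range(n):
            v[i] = y[i, t] - s_pred[i]
        S_in = P_pred[:n, :n].copy()
        for i in range(n):
            S_in[i, i] += r_obs[i]
        S_inv = np.linalg.inv(S_in)
        K = np.ascontiguousarray(P_pred[:, :n]) @ S_inv
        s = s_pred + K @ v
        P_s = P_pred - K @ np.ascontiguousarray(P_pred[:n, :])
        for i in range(n):
            xf[i, t] = s[i]

        # ----- parameter filter (regressor = filtered past values)
        phi = np.empty(d)
        for k in range(p):
            for i in range(n):
                phi[k * n + i] = xf[i, t - 1 - k]
        for i in range(n):
            Pi = P_th[i]
            for a in range(d):
                Pi[a, a] += q
            Pphi = Pi @ phi
            denom = phi @ Pphi + sigma_e[i]
            e = y[i, t] - theta[i] @ phi
            gain = Pphi / denom
            theta[i] = theta[i] + gain * e
            Pi -= np.outer(gain, Pphi)
            resid[i, t] = e
            tr[t] += np.trace(Pi)
        coeffs[t] = theta
    return coeffs, resid, tr
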