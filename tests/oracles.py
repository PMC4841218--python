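"""Independent oracles used to validate the fitting code.

Each oracle deliberately takes a different computational route from the
implementation it checks: explicit normal equations instead of lstsq, a
hand-coded Newton-Raphson logit instead of the packaged MLE, and a dense
grid search over acrophase instead of the sine/cosine linearization.
"""

import numpy as np

TWO_PI = 2.0 * np.pi


def normal_equations_residuals(X, y):
    """OLS residuals by explicitly solving X'X b = X'y."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


def irls_logit_probs(X, y, tol=1e-12, max_iter=100):
    """Logit fitted probabilities via hand-coded Newton-Raphson."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * W[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return 1.0 / (1.0 + np.exp(-(X @ beta)))


def grid_search_cosinor(y, t, phi_step=0.01):
    """Best-fitting cosine by brute-force search over the acrophase grid.

    For each candidate acrophase the mesor and (signed) amplitude are the
    exact 2-parameter OLS solution; the grid minimizer with non-negative
    amplitude is returned as (mesor, amplitude, acrophase, r2_pct).
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    phis = np.arange(0.0, 24.0, phi_step)
    X = np.cos(TWO_PI * (t[:, None] - phis[None, :]) / 24.0)
    xbar = X.mean(axis=0)
    ybar = y.mean()
    Xc = X - xbar
    yc = y - ybar
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    sxy = yc @ Xc
    syy = float(yc @ yc)
    slope = sxy / sxx
    sse = syy - sxy**2 / sxx
    valid = slope >= 0.0
    sse_masked = np.where(valid, sse, np.inf)
    j = int(np.argmin(sse_masked))
    amp = float(slope[j])
    mesor = float(ybar - amp * xbar[j])
    r2_pct = 100.0 * (1.0 - sse[j] / syy)
    return mesor, amp, float(phis[j]), r2_pct


def cosinor_normal_equations(y, t):
    """Cosinor parameters by explicitly solving the normal equations.

    Returns (mesor, amplitude, r2_pct) from the sine/cosine linearization,
    with the sums of squares accumulated in a separate two-pass sweep.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    X = np.column_stack(
        [np.ones_like(t), np.sin(TWO_PI * t / 24.0), np.cos(TWO_PI * t / 24.0)]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    amp = float(np.hypot(beta[1], beta[2]))
    return float(beta[0]), amp, 100.0 * (1.0 - sse / sst)


def ols_slope_intercept(x, y):
    """Closed-form simple linear regression."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    a = y.mean() - b * x.mean()
    return a, b


def circular_gap_hours(a, b):
    """Absolute circular distance between two clock times in hours."""
    d = abs(a - b) % 24.0
    return min(d, 24.0 - d)
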