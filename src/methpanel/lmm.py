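"""Random-intercept linear mixed model with a Satterthwaite F-test.

A single-variance-component model tailored to paired tumor/normal designs:

    y = X b + Z u + e,   u_g ~ N(0, sigma_u^2) per group,  e ~ N(0, sigma_e^2)

Groups are patients; a patient contributes one or two samples, so the
marginal covariance is block diagonal with blocks sigma_e^2 I + sigma_u^2 J,
which this module exploits for closed-form block inverses. Estimation is
restricted maximum likelihood, profiled over the variance ratio
lambda = sigma_u^2 / sigma_e^2. The fixed-effect F-test uses a Satterthwaite
approximation for the denominator degrees of freedom: for a single contrast
l, with v(theta) = l' (X'V^-1 X)^-1 l,

    ddf = 2 v^2 / Var(v),   Var(v) ~= g' A g,

where g is the gradient of v in the variance components theta and A the
inverse observed REML information, both obtained by finite differences.

When the random-intercept variance is estimated at (or indistinguishable
from) zero — including the fully unpaired design, where it is not
identifiable — the test reduces exactly to the ordinary least-squares F-test
with n - p denominator df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_BOUNDARY_TOL = 1e-7  # lambda below this is treated as sigma_u^2 = 0


@dataclass
class MixedFit:
    """REML fit of ``y ~ X`` with a random intercept per group."""

    coef: np.ndarray
    se: np.ndarray
    sigma_u2: float
    sigma_e2: float
    fstat: float
    ddf: float
    pvalue: float
    converged: bool
    boundary: bool  # variance component at zero -> OLS test used


class _Profile:
    """Pre-aggregated sufficient statistics for the profiled REML criterion."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        codes, counts = np.unique(groups, return_counts=True)
        code_map = {c: i for i, c in enumerate(codes)}
        idx = np.array([code_map[g] for g in groups])
        G = len(codes)
        self.k = counts.astype(float)
        S = np.zeros((G, self.p))
        np.add.at(S, idx, X)
        sy = np.zeros(G)
        np.add.at(sy, idx, y)
        self.S, self.sy = S, sy
        self.xtx = X.T @ X
        self.xty = X.T @ y
        self.yty = float(y @ y)
        self.all_singletons = bool(np.all(counts == 1))

    def gls_parts(self, lam: float):
        """X'W^-1 X, X'W^-1 y, y'W^-1 y and log|W| for W = I + lam*J (blockwise)."""
        c = lam / (1.0 + self.k * lam)
        xtwx = self.xtx - (self.S * c[:, None]).T @ self.S
        xtwy = self.xty - self.S.T @ (c * self.sy)
        ytwy = self.yty - float(c @ (self.sy**2))
        logdet_w = float(np.sum(np.log1p(self.k * lam)))
        return xtwx, xtwy, ytwy, logdet_w

    def neg2_reml(self, lam: float) -> float:
        xtwx, xtwy, ytwy, logdet_w = self.gls_parts(lam)
        sign, logdet_x = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        b = np.linalg.solve(xtwx, xtwy)
        rss = ytwy - float(b @ xtwy)
        if rss <= 0:
            return np.inf
        df = self.n - self.p
        return logdet_w + logdet_x + df * np.log(rss / df)

    def reml_loglik(self, sigma_u2: float, sigma_e2: float) -> float:
        """Unprofiled restricted log-likelihood (constants dropped)."""
        lam = sigma_u2 / sigma_e2
        xtwx, xtwy, ytwy, logdet_w = self.gls_parts(lam)
        sign, logdet_x = np.linalg.slogdet(xtwx / sigma_e2)
        b = np.linalg.solve(xtwx, xtwy)
        rss = ytwy - float(b @ xtwy)
        return -0.5 * (
            self.n * np.log(sigma_e2) + logdet_w + logdet_x + rss / sigma_e2
        )

    def contrast_var(self, sigma_u2: float, sigma_e2: float, j: int) -> float:
        lam = sigma_u2 / sigma_e2
        xtwx, _, _, _ = self.gls_parts(lam)
        cov = np.linalg.inv(xtwx) * sigma_e2
        return float(cov[j, j])


def _satterthwaite_ddf(prof: _Profile, sigma_u2: float, sigma_e2: float, j: int) -> float:
    theta = np.array([sigma_u2, sigma_e2])
    steps = np.maximum(theta, sigma_e2) * 1e-5

    def v_of(th):
        return prof.contrast_var(max(th[0], 0.0), max(th[1], 1e-12), j)

    def ll_of(th):
        return prof.reml_loglik(max(th[0], 0.0), max(th[1], 1e-12))

    # gradient of the contrast variance (forward difference at the zero boundary)
    g = np.zeros(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = steps[i]
        if theta[i] - steps[i] <= 0:
            g[i] = (v_of(theta + e) - v_of(theta)) / steps[i]
        else:
            g[i] = (v_of(theta + e) - v_of(theta - e)) / (2 * steps[i])

    # observed REML information by central second differences
    H = np.zeros((2, 2))
    f0 = ll_of(theta)
    for a in range(2):
        ea = np.zeros(2)
        ea[a] = steps[a]
        H[a, a] = (ll_of(theta + ea) - 2 * f0 + ll_of(theta - ea)) / steps[a] ** 2
        for b in range(a + 1, 2):
            eb = np.zeros(2)
            eb[b] = steps[b]
            H[a, b] = H[b, a] = (
                ll_of(theta + ea + eb)
                - ll_of(theta + ea - eb)
                - ll_of(theta - ea + eb)
                + ll_of(theta - ea - eb)
            ) / (4 * steps[a] * steps[b])
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(-H)
    var_v = float(g @ A @ g)
    v = v_of(theta)
    if var_v <= 0 or not np.isfinite(var_v):
        return float(prof.n - prof.p)
    ddf = 2 * v**2 / var_v
    if not np.isfinite(ddf) or ddf <= 0:
        return float(prof.n - prof.p)
    return ddf


def fit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, test_index: int = 1
) -> MixedFit:
    """REML fit plus Satterthwaite F-test on the coefficient ``test_index``.

    ``groups`` is any array of hashable group labels (one per sample).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y must be 1-D and aligned with rows of X")
    prof = _Profile(y, X, groups)

    if prof.all_singletons:
        lam_hat = 0.0
        converged = True
    else:
        log_lams = np.linspace(-12, 8, 41)
        vals = [prof.neg2_reml(0.0)] + [prof.neg2_reml(np.exp(t)) for t in log_lams]
        best = int(np.argmin(vals))
        if best == 0:
            lam_hat = 0.0
            converged = True
        else:
            t0 = log_lams[best - 1]
            res = optimize.minimize_scalar(
                lambda t: prof.neg2_reml(np.exp(t)),
                bounds=(t0 - 1.0, t0 + 1.0),
                method="bounded",
                options={"xatol": 1e-8},
            )
            converged = bool(res.success)
            lam_hat = float(np.exp(res.x))
            if prof.neg2_reml(0.0) <= res.fun:
                lam_hat = 0.0

    xtwx, xtwy, ytwy, _ = prof.gls_parts(lam_hat)
    b = np.linalg.solve(xtwx, xtwy)
    rss = ytwy - float(b @ xtwy)
    sigma_e2 = rss / (prof.n - prof.p)
    sigma_u2 = lam_hat * sigma_e2
    cov = np.linalg.inv(xtwx) * sigma_e2
    se = np.sqrt(np.diag(cov))

    boundary = lam_hat < _BOUNDARY_TOL
    if boundary:
        ddf = float(prof.n - prof.p)
    else:
        ddf = _satterthwaite_ddf(prof, sigma_u2, sigma_e2, test_index)

    fstat = float((b[test_index] / se[test_index]) ** 2)
    pvalue = float(stats.f.sf(fstat, 1, ddf))
    return MixedFit(
        coef=b,
        se=se,
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        fstat=fstat,
        ddf=float(ddf),
        pvalue=pvalue,
        converged=converged,
        boundary=boundary,
    )
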