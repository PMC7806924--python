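"""Bivariate polygenic model: partitioning a phenotypic correlation.

For a pair of prepared traits the covariance is Omega = G (x) 2*Phi +
E (x) I with per-trait genetic/environmental variances and the additive
genetic (rho_G) and environmental (rho_E) correlations. The fitted phenotypic
correlation follows the decomposition

    rho_P = sqrt(h1^2 * h2^2) * rho_G + sqrt(e1^2 * e2^2) * rho_E,

so a nonzero rho_G is evidence of pleiotropy (shared genetic influences).

After rotating each family block onto the eigenbasis of 2*Phi, the pair
(y1_i, y2_i) at eigenvalue lam_i has 2x2 covariance lam_i * G + E, and the
log-likelihood is a fully vectorized sum of closed-form 2x2 terms. Variances
are optimized on the log scale and correlations on the Fisher-z scale so the
search is smooth and unconstrained; correlation tests use a chi2_1 reference
(interior parameters), and 95% intervals are Wald on the z scale,
back-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from .pedigree import KinshipMatrix
from .polygenic import ModelError, _align, _check_identifiable, _rotate, fit_polygenic

_LOG2PI = np.log(2.0 * np.pi)
_ZMAX = 7.0  # |rho| <= tanh(7) ~ 0.9999983


def decompose_rho_p(h2_1: float, h2_2: float, rho_g: float, rho_e: float) -> float:
    """Phenotypic correlation implied by the bivariate decomposition.

    rho_p = sqrt(h2_1 * h2_2) * rho_g + sqrt((1-h2_1) * (1-h2_2)) * rho_e.
    """
    for h in (h2_1, h2_2):
        if not 0.0 <= h <= 1.0:
            raise ValueError(f"heritability out of [0, 1]: {h}")
    for r in (rho_g, rho_e):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation out of [-1, 1]: {r}")
    return float(
        np.sqrt(h2_1 * h2_2) * rho_g + np.sqrt((1 - h2_1) * (1 - h2_2)) * rho_e
    )


@dataclass
class BivariateFit:
    """Result of a bivariate polygenic fit for one trait pair."""

    trait1: str
    trait2: str
    h2_1: float
    h2_2: float
    rho_g: float
    rho_e: float
    rho_p: float
    loglik: float
    n: int
    p_rho_g: float = np.nan
    p_rho_e: float = np.nan
    p_rho_p: float = np.nan
    ci_rho_g: tuple = (np.nan, np.nan)
    ci_rho_e: tuple = (np.nan, np.nan)
    ci_rho_p: tuple = (np.nan, np.nan)
    boundary_flags: list = field(default_factory=list)

    @property
    def e2_1(self) -> float:
        return 1.0 - self.h2_1

    @property
    def e2_2(self) -> float:
        return 1.0 - self.h2_2

    def as_row(self) -> dict:
        return {
            "trait1": self.trait1, "trait2": self.trait2,
            "rho_p": self.rho_p, "rho_p_lo": self.ci_rho_p[0],
            "rho_p_hi": self.ci_rho_p[1], "p_rho_p": self.p_rho_p,
            "rho_g": self.rho_g, "rho_g_lo": self.ci_rho_g[0],
            "rho_g_hi": self.ci_rho_g[1], "p_rho_g": self.p_rho_g,
            "rho_e": self.rho_e, "rho_e_lo": self.ci_rho_e[0],
            "rho_e_hi": self.ci_rho_e[1], "p_rho_e": self.p_rho_e,
            "h2_1": self.h2_1, "h2_2": self.h2_2, "n": self.n,
            "boundary": ";".join(self.boundary_flags),
        }


def _pair_rotate(y1, y2, kinship: KinshipMatrix):
    """Complete-case intersection of two traits, rotated per family block."""
    if isinstance(y1, pd.Series) and isinstance(y2, pd.Series):
        ids = [
            i for i in kinship.ids
            if np.isfinite(y1.get(i, np.nan)) and np.isfinite(y2.get(i, np.nan))
        ]
        kin = kinship.subset(ids)
        v1 = y1.loc[ids].to_numpy(dtype=float)
        v2 = y2.loc[ids].to_numpy(dtype=float)
    else:
        v1 = np.asarray(y1, dtype=float)
        v2 = np.asarray(y2, dtype=float)
        if v1.shape[0] != len(kinship.ids) or v2.shape[0] != len(kinship.ids):
            raise ValueError("array traits must align with kinship ids")
        mask = np.isfinite(v1) & np.isfinite(v2)
        ids = [i for i, m in zip(kinship.ids, mask) if m]
        kin = kinship.subset(ids)
        v1, v2 = v1[mask], v2[mask]
    _check_identifiable(kin)
    lam, y1t, rotations = _rotate(v1, kin)
    y2t = np.concatenate([U.T @ v2[block] for block, U in rotations])
    return lam, y1t, y2t, v1, v2


def _nll(params: np.ndarray, lam, y1t, y2t) -> float:
    """Negative log-likelihood; params = (log s2g1, log s2e1, log s2g2,
    log s2e2, atanh rho_g, atanh rho_e)."""
    s2g1, s2e1, s2g2, s2e2 = np.exp(np.clip(params[:4], -16.0, 16.0))
    rg = np.tanh(params[4])
    re = np.tanh(params[5])
    a = lam * s2g1 + s2e1
    c = lam * s2g2 + s2e2
    b = lam * rg * np.sqrt(s2g1 * s2g2) + re * np.sqrt(s2e1 * s2e2)
    det = a * c - b * b
    if det.min() <= 0 or a.min() <= 0:
        return np.inf
    quad = (c * y1t * y1t - 2.0 * b * y1t * y2t + a * y2t * y2t) / det
    return 0.5 * float(np.sum(np.log(det) + quad)) + lam.size * _LOG2PI


def _minimize(fun, x0, bounds):
    best = None
    res = minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    best = res
    return best


def _fit_full(lam, y1t, y2t, starts):
    bounds = [(-16, 16)] * 4 + [(-_ZMAX, _ZMAX)] * 2
    best = None
    for x0 in starts:
        res = _minimize(lambda p: _nll(p, lam, y1t, y2t), x0, bounds)
        if best is None or res.fun < best.fun:
            best = res
    return best


def _starts(lam, y1t, y2t, v1, v2, kinship_ids_n):
    """Data-driven optimizer starts from moment estimates."""
    var1 = max(np.var(v1), 1e-6)
    var2 = max(np.var(v2), 1e-6)
    r = float(np.clip(np.corrcoef(v1, v2)[0, 1], -0.95, 0.95)) if v1.size > 2 else 0.0
    z = np.arctanh(r)
    starts = []
    for h2 in (0.4, 0.8):
        s = [np.log(h2 * var1), np.log((1 - h2) * var1),
             np.log(h2 * var2), np.log((1 - h2) * var2), z, z]
        starts.append(np.array(s))
    starts.append(np.array([np.log(0.4 * var1), np.log(0.6 * var1),
                            np.log(0.4 * var2), np.log(0.6 * var2), 0.0, z]))
    return starts


def _params_to_estimates(p):
    s2g1, s2e1, s2g2, s2e2 = np.exp(p[:4])
    h2_1 = s2g1 / (s2g1 + s2e1)
    h2_2 = s2g2 / (s2g2 + s2e2)
    rg, re = np.tanh(p[4]), np.tanh(p[5])
    return h2_1, h2_2, float(rg), float(re)


def _hessian(fun, x, step=1e-4):
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step * step)
    return H


def lrt_correlation(loglik_full: float, loglik_constrained: float) -> float:
    """chi2_1 likelihood-ratio p-value for an interior correlation parameter."""
    lam = 2.0 * (loglik_full - loglik_constrained)
    if lam < 0:
        if lam < -1e-6:
            warnings.warn("constrained optimum exceeded full; clamping LRT to 0")
        lam = 0.0
    return float(stats.chi2.sf(lam, df=1))


def fit_bivariate(
    y1,
    y2,
    kinship: KinshipMatrix,
    names: tuple[str, str] = ("trait1", "trait2"),
    tests=True,
    ci: bool = True,
) -> BivariateFit:
    """ML bivariate polygenic fit on the complete-case trait intersection.

    ``tests`` may be True (all three LRTs), False (none) or an iterable from
    {"rho_g", "rho_e", "rho_p"}; ``ci=False`` skips the Hessian. Both options
    are useful inside simulation loops.
    """
    lam, y1t, y2t, v1, v2 = _pair_rotate(y1, y2, kinship)
    n = lam.size
    starts = _starts(lam, y1t, y2t, v1, v2, n)
    best = _fit_full(lam, y1t, y2t, starts)
    if not np.isfinite(best.fun):
        raise ModelError("bivariate likelihood not finite at the optimum")
    p_hat = best.x
    h2_1, h2_2, rg, re = _params_to_estimates(p_hat)
    rho_p = decompose_rho_p(h2_1, h2_2, rg, re)
    ll_full = -best.fun

    flags = []
    if abs(rg) > 0.999:
        flags.append("rho_g at boundary")
    if abs(re) > 0.999:
        flags.append("rho_e at boundary")
    for label, h in (("h2_1", h2_1), ("h2_2", h2_2)):
        if h < 1e-4 or h > 1 - 1e-4:
            flags.append(f"{label} at boundary")

    fit = BivariateFit(
        trait1=names[0], trait2=names[1],
        h2_1=h2_1, h2_2=h2_2, rho_g=rg, rho_e=re, rho_p=rho_p,
        loglik=ll_full, n=n, boundary_flags=flags,
    )

    wanted = ("rho_g", "rho_e", "rho_p") if tests is True else (tests or ())
    for which in wanted:
        p_val = lrt_correlation(
            ll_full, _constrained_ll(lam, y1t, y2t, p_hat, f"{which}=0")
        )
        setattr(fit, f"p_{which}", p_val)

    if ci:
        fit.ci_rho_g, fit.ci_rho_e, fit.ci_rho_p = _wald_cis(lam, y1t, y2t, p_hat, rho_p)
    return fit


def _constrained_ll(lam, y1t, y2t, p_hat, constraint: str) -> float:
    """Maximized log-likelihood under rho_g=0, rho_e=0 or rho_p=0."""
    bounds5 = [(-16, 16)] * 4 + [(-_ZMAX, _ZMAX)]

    if constraint in ("rho_g=0", "rho_e=0"):
        fixed = 4 if constraint == "rho_g=0" else 5
        free = 5 if constraint == "rho_g=0" else 4

        def nll5(q):
            p = np.empty(6)
            p[:4] = q[:4]
            p[fixed] = 0.0
            p[free] = q[4]
            return _nll(p, lam, y1t, y2t)

        x0s = [np.concatenate([p_hat[:4], [p_hat[free]]]),
               np.concatenate([p_hat[:4], [0.0]])]
    elif constraint == "rho_p=0":
        # rho_e is determined by rho_g through the decomposition identity
        def nll5(q):
            p = np.empty(6)
            p[:4] = q[:4]
            p[4] = q[4]
            s2g1, s2e1, s2g2, s2e2 = np.exp(np.clip(q[:4], -16.0, 16.0))
            h1 = s2g1 / (s2g1 + s2e1)
            h2 = s2g2 / (s2g2 + s2e2)
            denom = np.sqrt(max((1 - h1) * (1 - h2), 1e-12))
            re_req = -np.sqrt(h1 * h2) / denom * np.tanh(q[4])
            pen = 0.0
            if abs(re_req) > 0.999:
                pen = 1e4 * (abs(re_req) - 0.999) ** 2
                re_req = np.clip(re_req, -0.999, 0.999)
            p[5] = np.arctanh(re_req)
            return _nll(p, lam, y1t, y2t) + pen

        x0s = [np.concatenate([p_hat[:4], [0.0]]),
               np.concatenate([p_hat[:4], [p_hat[4] * 0.25]])]
    else:  # pragma: no cover
        raise ValueError(f"unknown constraint {constraint!r}")

    best = np.inf
    for x0 in x0s:
        res = _minimize(nll5, x0, bounds5)
        best = min(best, res.fun)
    return -best


def _wald_cis(lam, y1t, y2t, p_hat, rho_p):
    """Wald 95% intervals on the Fisher-z scale via the observed information."""
    fun = lambda p: _nll(p, lam, y1t, y2t)
    x = np.clip(p_hat, [-15.9] * 4 + [-_ZMAX + 0.01] * 2,
                [15.9] * 4 + [_ZMAX - 0.01] * 2)
    H = _hessian(fun, x)
    try:
        cov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        return ((np.nan, np.nan),) * 3
    var = np.clip(np.diag(cov), 0.0, None)
    z = 1.959963984540054

    def ci_tanh(idx):
        se = np.sqrt(var[idx])
        if not np.isfinite(se) or se == 0:
            return (np.nan, np.nan)
        return (float(np.tanh(x[idx] - z * se)), float(np.tanh(x[idx] + z * se)))

    # rho_p: delta-method variance, then a Fisher-z interval
    grad = np.empty(6)
    step = 1e-5
    for i in range(6):
        e = np.zeros(6); e[i] = step
        grad[i] = (_rho_p_of(x + e) - _rho_p_of(x - e)) / (2 * step)
    var_p = float(grad @ cov @ grad)
    if var_p > 0 and abs(rho_p) < 1:
        se_z = np.sqrt(var_p) / (1 - rho_p**2)
        zp = np.arctanh(np.clip(rho_p, -0.999999, 0.999999))
        ci_p = (float(np.tanh(zp - z * se_z)), float(np.tanh(zp + z * se_z)))
    else:
        ci_p = (np.nan, np.nan)
    return ci_tanh(4), ci_tanh(5), ci_p


def _rho_p_of(p):
    h1, h2, rg, re = _params_to_estimates(p)
    return decompose_rho_p(h1, h2, rg, re)


def univariate_marginals(y1, y2, kinship: KinshipMatrix):
    """Convenience: univariate fits of both traits (consistency checks)."""
    return fit_polygenic(y1, kinship), fit_polygenic(y2, kinship)
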