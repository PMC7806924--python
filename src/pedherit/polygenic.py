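"""Univariate polygenic (variance-components) model: heritability estimation.

The trait vector y over a pedigree is modelled as multivariate normal with
covariance Omega = 2 * Phi * sigma2_g + I * sigma2_e, where Phi is the kinship
matrix, sigma2_g the additive genetic variance and sigma2_e the residual
(environmental) variance. Heritability is h2 = sigma2_g / (sigma2_g +
sigma2_e). Because founders are mutually unrelated, Phi is block diagonal by
(extended) family and the likelihood factorizes over families.

Fitting strategy: within each family block, 2*Phi is eigendecomposed once;
rotating the data onto the eigenbasis diagonalizes Omega, so for a fixed h2
the total variance sigma2_p has a closed-form maximizer and the profile
log-likelihood is a smooth one-dimensional function of h2 on [0, 1]. A global
grid over h2 followed by bounded local refinement then finds the ML estimate
without multi-start heuristics. The fit is maximum likelihood by default (the
trait mean is absorbed by prior covariate residualization); REML with respect
to an intercept is available via ``reml=True``.

The test of H0: sigma2_g = 0 is a likelihood-ratio test at a boundary of the
parameter space, so the null distribution is the 1/2 chi2_0 : 1/2 chi2_1
mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .pedigree import KinshipMatrix

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class UnivariateFit:
    """Result of a univariate polygenic fit."""

    sigma2_g: float
    sigma2_e: float
    h2: float
    h2_se: float
    loglik: float
    loglik_null: float
    lrt_p: float
    n: int

    def as_row(self) -> dict:
        return {
            "h2": self.h2, "h2_se": self.h2_se, "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e, "loglik": self.loglik,
            "p": self.lrt_p, "n": self.n,
        }


class ModelError(RuntimeError):
    """Polygenic model cannot be fitted (unidentifiable or numerically broken)."""


def _align(y, kinship: KinshipMatrix):
    """Complete-case alignment of a trait to the kinship matrix."""
    if isinstance(y, pd.Series):
        ids = [i for i in kinship.ids if i in y.index and np.isfinite(y.get(i, np.nan))]
        return y.loc[ids].to_numpy(dtype=float), kinship.subset(ids)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(kinship.ids):
        raise ValueError("array trait must align with kinship ids")
    mask = np.isfinite(y)
    ids = [i for i, m in zip(kinship.ids, mask) if m]
    return y[mask], kinship.subset(ids)


def _rotate(y: np.ndarray, kinship: KinshipMatrix):
    """Per-family eigendecomposition of 2*Phi; returns (eigenvalues, rotated y).

    Omega = sigma2_p * diag(h2 * lam + (1 - h2)) in the rotated basis.
    """
    K = 2.0 * kinship.values
    lam_parts, yt_parts, rotations = [], [], []
    for block in kinship.family_blocks():
        w, U = np.linalg.eigh(K[np.ix_(block, block)])
        w = np.clip(w, 0.0, None)
        lam_parts.append(w)
        yt_parts.append(U.T @ y[block])
        rotations.append((block, U))
    return np.concatenate(lam_parts), np.concatenate(yt_parts), rotations


def _profile_ml(h2: float, lam: np.ndarray, yt: np.ndarray):
    """Profile log-likelihood over sigma2_p for fixed h2; returns (ll, s2p)."""
    d = h2 * lam + (1.0 - h2)
    if d.min() < 1e-12:
        return -np.inf, np.nan
    n = lam.size
    s2p = float(np.mean(yt * yt / d))
    if s2p <= 0:
        return -np.inf, np.nan
    ll = -0.5 * (n * (_LOG2PI + np.log(s2p) + 1.0) + np.sum(np.log(d)))
    return ll, s2p


def _profile_reml(h2: float, lam: np.ndarray, yt: np.ndarray, xt: np.ndarray):
    """REML profile with a single (rotated intercept) fixed effect."""
    d = h2 * lam + (1.0 - h2)
    if d.min() < 1e-12:
        return -np.inf, np.nan
    n = lam.size
    xtx = float(np.sum(xt * xt / d))
    beta = float(np.sum(xt * yt / d)) / xtx
    r = yt - beta * xt
    s2p = float(np.sum(r * r / d)) / (n - 1)
    if s2p <= 0:
        return -np.inf, np.nan
    ll = -0.5 * (
        (n - 1) * (_LOG2PI + np.log(s2p) + 1.0)
        + np.sum(np.log(d))
        + np.log(xtx)
    )
    return ll, s2p


def _check_identifiable(kinship: KinshipMatrix) -> None:
    sizes = [len(b) for b in kinship.family_blocks()]
    if sum(1 for s in sizes if s >= 2) < 2:
        raise ModelError(
            "polygenic model unidentifiable: need at least 2 families "
            "with 2+ phenotyped relatives"
        )


def fit_polygenic(y, kinship: KinshipMatrix, reml: bool = False) -> UnivariateFit:
    """Maximum-likelihood polygenic fit of one prepared (residualized) trait.

    ``y`` is a pandas Series indexed by individual id (complete cases taken
    against the kinship ids) or an array aligned to ``kinship.ids``.
    """
    yv, kin = _align(y, kinship)
    _check_identifiable(kin)
    lam, yt, rotations = _rotate(yv, kin)
    if reml:
        ones = np.ones_like(yv)
        xt = np.concatenate([U.T @ ones[block] for block, U in rotations])
        profile = lambda h: _profile_reml(h, lam, yt, xt)[0]
        full = lambda h: _profile_reml(h, lam, yt, xt)
    else:
        profile = lambda h: _profile_ml(h, lam, yt)[0]
        full = lambda h: _profile_ml(h, lam, yt)

    grid = np.linspace(0.0, 1.0, 101)
    ll_grid = np.array([profile(h) for h in grid])
    k = int(np.argmax(ll_grid))
    lo, hi = max(0.0, grid[k] - 0.015), min(1.0, grid[k] + 0.015)
    res = minimize_scalar(
        lambda h: -profile(h), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    h2_hat = float(res.x) if -res.fun >= ll_grid[k] else float(grid[k])
    ll_full, s2p = full(h2_hat)
    if not np.isfinite(ll_full):
        raise ModelError("polygenic likelihood not finite at the optimum")
    ll_null = profile(0.0)
    lrt_p = lrt_h2(ll_full, ll_null)
    h2_se = _profile_se(profile, h2_hat)
    return UnivariateFit(
        sigma2_g=h2_hat * s2p,
        sigma2_e=(1.0 - h2_hat) * s2p,
        h2=h2_hat,
        h2_se=h2_se,
        loglik=ll_full,
        loglik_null=ll_null,
        lrt_p=lrt_p,
        n=lam.size,
    )


def _profile_se(profile, h2_hat: float, step: float = 0.01) -> float:
    """SE of h2 from the curvature of the profile log-likelihood.

    The profile curvature equals the observed-information (delta-method)
    variance for h2 with the nuisance variance profiled out. Near the [0, 1]
    boundary the quadratic is fitted on a one-sided interior stencil.
    """
    lo = max(1e-9, h2_hat - 2 * step)
    hi = min(1.0 - 1e-9, h2_hat + 2 * step)
    if hi - lo < 2 * step:  # squeezed against a boundary
        if h2_hat < 0.5:
            lo, hi = 1e-9, 4 * step
        else:
            lo, hi = 1.0 - 4 * step, 1.0 - 1e-9
    hs = np.linspace(lo, hi, 7)
    lls = np.array([profile(h) for h in hs])
    mask = np.isfinite(lls)
    if mask.sum() < 3:
        return np.nan
    a = np.polyfit(hs[mask], lls[mask], 2)[0]
    curv = 2.0 * a
    if curv >= 0:
        return np.nan
    return float(np.sqrt(-1.0 / curv))


def lrt_h2(loglik_full: float | UnivariateFit, loglik_null: float) -> float:
    """Boundary likelihood-ratio p-value for H0: sigma2_g = 0.

    Lambda = 2 * (l_full - l_null), clamped at 0; p = 0.5 * P(chi2_1 >= Lambda)
    under the 1/2 chi2_0 : 1/2 chi2_1 boundary mixture.
    """
    if isinstance(loglik_full, UnivariateFit):
        loglik_full = loglik_full.loglik
    lam = max(0.0, 2.0 * (loglik_full - loglik_null))
    return float(0.5 * stats.chi2.sf(lam, df=1))


def profile_loglik_curve(y, kinship: KinshipMatrix, grid=None) -> pd.DataFrame:
    """Profile log-likelihood of h2 on a grid (for plotting/diagnostics)."""
    yv, kin = _align(y, kinship)
    lam, yt, _ = _rotate(yv, kin)
    grid = np.linspace(0, 1, 101) if grid is None else np.asarray(grid, dtype=float)
    lls = [_profile_ml(h, lam, yt)[0] for h in grid]
    return pd.DataFrame({"h2": grid, "loglik": lls})
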