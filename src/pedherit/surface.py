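"""Distance-weighted quadratic response surfaces (two predictors, one response).

Used to map the joint association of a serum carotenoid concentration and the
Pediatric Metabolic Index with the Matsuda insulin sensitivity index. At each
node of a regular grid a quadratic polynomial (terms 1, x, y, x^2, x*y, y^2)
is fitted by weighted least squares with Gaussian kernel weights on
standardized distances, optionally multiplied by per-point precision
(inverse-variance) weights; the node prediction is the local intercept. With
bandwidth -> infinity the surface converges to the global quadratic fit.

Nodes whose Kish effective sample size falls below a threshold are flagged as
unsupported rather than silently extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: minimum Kish effective local sample for a supported node
MIN_EFFECTIVE_N = 6.0


@dataclass
class SurfaceFit:
    """Fitted surface: grid axes, node predictions and support flags."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    z_hat: np.ndarray       # shape (len(grid_y), len(grid_x))
    supported: np.ndarray   # same shape, bool
    effective_n: np.ndarray
    bandwidth: float
    degree: int = 2

    def to_long(self) -> pd.DataFrame:
        """Long-format grid (x, y, z_hat, supported) for export."""
        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {
                "x": gx.ravel(),
                "y": gy.ravel(),
                "z_hat": self.z_hat.ravel(),
                "supported": self.supported.ravel(),
            }
        )


def _quad_design(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(dx), dx, dy, dx * dx, dx * dy, dy * dy])


def fit_surface(
    x,
    y,
    z,
    bandwidth: float = 0.5,
    grid_size: int = 50,
    precision_weights=None,
    min_effective_n: float = MIN_EFFECTIVE_N,
) -> SurfaceFit:
    """Distance-weighted quadratic least-squares surface of z over (x, y).

    ``bandwidth`` is the Gaussian kernel scale in SD units of the z-scored
    predictor coordinates. ``precision_weights`` (optional, positive) multiply
    the kernel weights point-wise. Rows with any missing value are dropped;
    at least 10 complete triples are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    w0 = (np.ones_like(z) if precision_weights is None
          else np.asarray(precision_weights, dtype=float))
    if np.any(w0 < 0):
        raise ValueError("precision weights must be nonnegative")
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z) & np.isfinite(w0)
    x, y, z, w0 = x[mask], y[mask], z[mask], w0[mask]
    if x.size < 10:
        raise ValueError("need at least 10 complete (x, y, z) triples")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    sx = np.std(x) or 1.0
    sy = np.std(y) or 1.0
    xs, ys = x / sx, y / sy

    grid_x = np.linspace(x.min(), x.max(), grid_size)
    grid_y = np.linspace(y.min(), y.max(), grid_size)
    z_hat = np.empty((grid_size, grid_size))
    eff_n = np.empty((grid_size, grid_size))

    for j, gy in enumerate(grid_y):
        dys = ys - gy / sy
        for i, gx in enumerate(grid_x):
            dxs = xs - gx / sx
            d2 = dxs * dxs + dys * dys
            w = w0 * np.exp(-d2 / (2.0 * bandwidth * bandwidth))
            sw = w.sum()
            eff_n[j, i] = sw * sw / np.sum(w * w) if sw > 0 else 0.0
            X = _quad_design(x - gx, y - gy)
            Xw = X * w[:, None]
            beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ z, rcond=None)
            z_hat[j, i] = beta[0]

    supported = eff_n >= min_effective_n
    return SurfaceFit(
        grid_x=grid_x, grid_y=grid_y, z_hat=z_hat,
        supported=supported, effective_n=eff_n, bandwidth=bandwidth,
    )


def summarize_surface(fit: SurfaceFit, pmi_band: tuple[float, float],
                      flat_tol: float = 0.15) -> dict:
    """Monotonicity/extremum report along the x (carotenoid) axis in a y band.

    Averages the fitted surface over the grid rows inside ``pmi_band``, then
    reports the sign pattern of the finite-difference slope along x, the
    location of an interior maximum (if any), and the response range across x
    (the "variability" of the response within the band). ``flat_tol`` is the
    fraction of the overall response range below which the band profile is
    called flat.
    """
    lo, hi = pmi_band
    rows = (fit.grid_y >= lo) & (fit.grid_y <= hi)
    if not rows.any():
        raise ValueError(f"PMI band {pmi_band} lies outside the fitted grid")
    # unsupported nodes are extrapolations; keep them out of the summary, and
    # drop ragged edge columns where less than half the band rows are supported
    sup = fit.supported[rows]
    counts = sup.sum(axis=0)
    keep = counts >= max(1, sup.shape[0] // 2)
    if keep.sum() < 3:
        raise ValueError("too few supported nodes in the requested band")
    z_band = np.where(sup, fit.z_hat[rows], 0.0)
    profile = (z_band.sum(axis=0)[keep] / counts[keep])
    grid_x = fit.grid_x[keep]
    d = np.diff(profile)
    z_ok = fit.z_hat[fit.supported]
    zrange = float(z_ok.max() - z_ok.min()) or 1.0
    prange = float(profile.max() - profile.min())

    if prange < flat_tol * zrange:
        trend = "no trend"
    else:
        frac_up = float((d > 0).mean())
        k = int(np.argmax(profile))
        if 0 < k < profile.size - 1 and frac_up > 0.2 and frac_up < 0.8:
            trend = "interior maximum"
        elif frac_up >= 0.8:
            trend = "increasing"
        elif frac_up <= 0.2:
            trend = "decreasing"
        else:
            trend = "nonmonotone"

    k = int(np.argmax(profile))
    return {
        "band": (float(lo), float(hi)),
        "trend": trend,
        "argmax_x": float(grid_x[k]),
        "argmax_interior": bool(0 < k < profile.size - 1),
        "range": prange,
        "frac_slope_positive": float((d > 0).mean()),
        "profile": profile,
    }
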