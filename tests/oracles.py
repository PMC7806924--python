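"""Independent oracles used by the unit and acceptance tests.

Each function recomputes a quantity by a route disjoint from the package's
implementation: Monte-Carlo gene dropping for kinship, a dense grid search
over the raw multivariate-normal likelihood for the polygenic fit, the
textbook step-up recursion for BH, and explicit normal equations for the
locally weighted surface.
"""

import numpy as np
from scipy.stats import multivariate_normal


def gene_drop_kinship(ped, n_drops: int, rng) -> np.ndarray:
    """Estimate kinship by dropping founder alleles through the pedigree.

    Founders get unique allele labels; each nonfounder inherits one random
    allele from each parent per drop. phi_ij is the probability that one
    allele drawn at random from i matches one drawn from j.
    """
    n = len(ped)
    alleles = np.empty((n, 2, n_drops), dtype=np.int32)
    for pos, ind in enumerate(ped.individuals):
        if ind.is_founder:
            alleles[pos, 0] = 2 * pos
            alleles[pos, 1] = 2 * pos + 1
        else:
            fa = ped.index[ind.father_id]
            mo = ped.index[ind.mother_id]
            for slot, parent in ((0, fa), (1, mo)):
                pick = rng.integers(0, 2, n_drops)
                alleles[pos, slot] = np.take_along_axis(
                    alleles[parent], pick[None, :], axis=0
                )[0]
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            m = sum(
                (alleles[i, a] == alleles[j, b]).mean()
                for a in (0, 1) for b in (0, 1)
            )
            phi[i, j] = phi[j, i] = m / 4.0
    return phi


def grid_search_polygenic_loglik(y: np.ndarray, K: np.ndarray) -> float:
    """Best log-likelihood over a dense (h2, total variance) grid.

    Evaluates the raw zero-mean MVN density with covariance
    s2p * (h2 * K + (1 - h2) * I) via scipy; coarse pass then refinement.
    """
    n = y.size
    eye = np.eye(n)

    def ll(h2, s2p):
        cov = s2p * (h2 * K + (1 - h2) * eye)
        return multivariate_normal.logpdf(
            y, mean=np.zeros(n), cov=cov, allow_singular=True
        )

    s2_center = np.var(y)
    h_grid = np.linspace(0.0, 1.0, 51)
    s_grid = s2_center * np.exp(np.linspace(-1.5, 1.5, 41))
    best, bh, bs = -np.inf, 0.0, s2_center
    for h in h_grid:
        for s in s_grid:
            v = ll(h, s)
            if v > best:
                best, bh, bs = v, h, s
    h_grid = np.clip(np.linspace(bh - 0.025, bh + 0.025, 51), 0.0, 1.0)
    s_grid = bs * np.exp(np.linspace(-0.08, 0.08, 41))
    for h in h_grid:
        for s in s_grid:
            v = ll(h, s)
            best = max(best, v)
    return float(best)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Textbook BH: sort, scale by n/rank, cumulative min from the largest."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def weighted_quadratic_node(x, y, z, gx, gy, bandwidth, sx, sy, w0=None):
    """One surface node by explicit Gaussian-weighted normal equations."""
    dxs = (x - gx) / sx
    dys = (y - gy) / sy
    w = np.exp(-(dxs**2 + dys**2) / (2 * bandwidth**2))
    if w0 is not None:
        w = w * w0
    X = np.column_stack([
        np.ones_like(x), x - gx, y - gy,
        (x - gx) ** 2, (x - gx) * (y - gy), (y - gy) ** 2,
    ])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * z)
    return float(np.linalg.solve(A, b)[0])
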