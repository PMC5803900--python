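"""Independent oracles used to check the package's computations.

Everything here is deliberately written from first principles (plain loops,
textbook formulas, normal equations) and independent of the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def mde_expected_richness(
    range_sizes,
    domain_min: float,
    domain_max: float,
    band_width: float,
    n_midpoints: int = 20001,
) -> np.ndarray:
    """Brute-force expected richness per band under the mid-domain null.

    For every range size, enumerate a dense uniform grid of feasible
    midpoints, bin each placed interval (floor the lower limit, ceil the
    upper limit to band edges, occupancy = bands strictly above the lower
    edge and at most the upper edge), and average the per-band indicator.
    Expected richness is the sum over species of these occupancy
    probabilities.
    """
    n_bands = int(round((domain_max - domain_min) / band_width))
    labels = [domain_min + band_width * (j + 1) for j in range(n_bands)]
    expected = np.zeros(n_bands)
    for R in range_sizes:
        lo_f = domain_min + R / 2.0
        hi_f = domain_max - R / 2.0
        if hi_f < lo_f:
            raise ValueError("range size exceeds domain length")
        if hi_f == lo_f:
            mids = [lo_f]
        else:
            mids = [lo_f + (hi_f - lo_f) * k / (n_midpoints - 1) for k in range(n_midpoints)]
        prob = np.zeros(n_bands)
        for m in mids:
            lower = m - R / 2.0
            upper = m + R / 2.0
            lo_edge = domain_min + math.floor((lower - domain_min) / band_width) * band_width
            up_edge = domain_min + math.ceil((upper - domain_min) / band_width) * band_width
            for j, b in enumerate(labels):
                if lo_edge < b <= up_edge:
                    prob[j] += 1.0
        expected += prob / len(mids)
    return expected


def pearson_r_textbook(x, y) -> float:
    """Pearson correlation via the raw sum formula."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def normal_equations_fit(X, y):
    """Least-squares coefficients via explicit normal equations (X'X)b = X'y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX = X.T @ X
    Xty = X.T @ y
    return np.linalg.solve(XtX, Xty)


def r_squared_of_regression(X, y) -> float:
    """R^2 of y on X (X includes the intercept column)."""
    b = normal_equations_fit(X, y)
    resid = y - X @ b
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def poisson_deviance(y, mu) -> float:
    """Poisson deviance 2 * sum(y log(y/mu) - (y - mu)), with 0 log 0 = 0."""
    total = 0.0
    for yi, mi in zip(y, mu):
        if yi > 0:
            total += yi * math.log(yi / mi)
        total -= yi - mi
    return 2.0 * total
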