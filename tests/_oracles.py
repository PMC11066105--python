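"""Independent reference computations the implementation is checked against.

These deliberately avoid the code paths they validate: the autocorrelation
oracle works lag-by-lag in the spatial domain via circular shifts (no FFT),
and the regression oracle evaluates the ordinary-least-squares normal
equations and the t distribution by hand.
"""

import numpy as np
from scipy.special import stdtr


def circular_acf_oracle(img: np.ndarray) -> np.ndarray:
    """Spatial-domain circular autocorrelation, zero lag at the grid centre:
    r(dy, dx) = <i(x) i(x + d)> / <i>^2 - 1 computed with explicit shifts."""
    img = np.asarray(img, dtype=np.float64)
    mean = img.mean()
    rows, cols = img.shape
    out = np.empty((rows, cols))
    for dy in range(rows):
        for dx in range(cols):
            out[dy, dx] = np.mean(img * np.roll(img, (-dy, -dx), axis=(0, 1)))
    out = out / mean**2 - 1.0
    return np.fft.fftshift(out)


def masked_acf_oracle(img: np.ndarray, mask: np.ndarray,
                      min_overlap: int = 16) -> np.ndarray:
    """Spatial-domain mask-overlap-normalized fluctuation autocorrelation."""
    img = np.asarray(img, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    mu = img[m].mean()
    delta = np.where(m, img - mu, 0.0)
    rows, cols = img.shape
    out = np.full((rows, cols), np.nan)
    mf = m.astype(np.float64)
    for dy in range(rows):
        for dx in range(cols):
            shifted = np.roll(delta, (-dy, -dx), axis=(0, 1))
            overlap = np.sum(mf * np.roll(mf, (-dy, -dx), axis=(0, 1)))
            if overlap >= min_overlap:
                out[dy, dx] = np.sum(delta * shifted) / (overlap * mu**2)
    return np.fft.fftshift(out)


def ols_slope_oracle(x, y):
    """Closed-form simple OLS: slope, intercept, slope SE, t, two-sided p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    df = n - 2
    s2 = np.sum(resid**2) / df
    se = np.sqrt(s2 / sxx)
    if se == 0:
        t = np.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = 2.0 * (1.0 - stdtr(df, abs(t)))
    return slope, intercept, se, t, p


def bh_adjust_oracle(p):
    """Benjamini-Hochberg by its textbook definition:
    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1."""
    p = np.asarray(p, dtype=np.float64)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, m * p[idx] / rank_from_top)
        q[idx] = running_min
    return np.minimum(q, 1.0)
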