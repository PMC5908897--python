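"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: dense convolution by
explicit loops over the kernel support, and lagged Pearson statistics via
per-lag calls to numpy's corrcoef.
"""

import math

import numpy as np


def mirror_indices(idx: np.ndarray, n: int) -> np.ndarray:
    """Reflect out-of-range indices about the edges without duplicating
    the edge sample (..., 2, 1, 0, 1, 2, ..., n-2, n-1, n-2, ...)."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n - 2
    idx = np.abs(idx) % period
    return np.where(idx < n, idx, period - idx)


def truncated_gaussian(sigma: float) -> np.ndarray:
    radius = math.ceil(4.0 * sigma)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def dense_gauss4d(data5: np.ndarray, sigmas_tzyx) -> np.ndarray:
    """Dense 4D Gaussian convolution of a (C,T,Z,Y,X) array, channel-wise.

    The full separable kernel is materialized as an outer product and the
    convolution runs as explicit nested loops over every kernel offset,
    with mirror boundary handling.
    """
    kernels = [
        truncated_gaussian(s) if s > 0 else np.ones(1) for s in sigmas_tzyx
    ]
    radii = [(k.size - 1) // 2 for k in kernels]
    out = np.zeros(data5.shape, dtype=np.float64)
    arr = data5.astype(np.float64)
    dims = data5.shape[1:]
    axis_idx = [np.arange(n) for n in dims]
    for it, wt in enumerate(kernels[0]):
        sh_t = mirror_indices(axis_idx[0] + (it - radii[0]), dims[0])
        for iz, wz in enumerate(kernels[1]):
            sh_z = mirror_indices(axis_idx[1] + (iz - radii[1]), dims[1])
            for iy, wy in enumerate(kernels[2]):
                sh_y = mirror_indices(axis_idx[2] + (iy - radii[2]), dims[2])
                for ix, wx in enumerate(kernels[3]):
                    sh_x = mirror_indices(axis_idx[3] + (ix - radii[3]), dims[3])
                    w = wt * wz * wy * wx
                    out += w * arr[
                        :,
                        sh_t[:, None, None, None],
                        sh_z[None, :, None, None],
                        sh_y[None, None, :, None],
                        sh_x[None, None, None, :],
                    ]
    return out


def pearson_lag_oracle(f: np.ndarray, s: np.ndarray, k: int) -> float:
    """Pearson r of (s[t], f[t+k]) pairs via numpy corrcoef; degenerate -> 0."""
    T = f.size
    x = s[: T - k]
    y = f[k:]
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def cumulative_oracle(f: np.ndarray, s: np.ndarray, K: int) -> float:
    return sum(pearson_lag_oracle(f, s, k) for k in range(K + 1))


def peak_oracle(f: np.ndarray, s: np.ndarray, K: int) -> tuple[float, int]:
    rs = [pearson_lag_oracle(f, s, k) for k in range(K + 1)]
    best = max(rs)
    return best, rs.index(best)


def running_mean_oracle(v: np.ndarray, window: int) -> np.ndarray:
    h = window // 2
    return np.array(
        [v[max(0, i - h): i + h + 1].mean() for i in range(v.size)]
    )


def running_percentile_oracle(v: np.ndarray, halfwidth: int, q: float) -> np.ndarray:
    return np.array(
        [
            np.percentile(v[max(0, i - halfwidth): i + halfwidth + 1], q)
            for i in range(v.size)
        ]
    )
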