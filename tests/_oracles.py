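"""Independent slow-but-simple oracles used to check the implementation.

These deliberately avoid the code paths they validate: the truncated power
series below never calls scipy's expm, and the brute-force Hessian never
touches the analytic gradient.
"""

import numpy as np


def series_expm(Q: np.ndarray, t: float, k_max: int = 60) -> np.ndarray:
    """Truncated Taylor/uniformization series sum_{k<=k_max} (Qt)^k / k!.

    Accurate for moderate ||Qt||; used only on generators kept small enough
    for the series to converge well before k_max terms.
    """
    A = np.asarray(Q, dtype=float) * t
    term = np.eye(A.shape[0])
    out = term.copy()
    for k in range(1, k_max + 1):
        term = term @ A / k
        out = out + term
    return out


def random_generator(rng: np.random.Generator, structure, low=0.05, high=2.0):
    """Random valid generator matrix over an allowed-transition structure."""
    n = structure.n_states
    Q = np.zeros((n, n))
    for r, s in structure.allowed:
        Q[r - 1, s - 1] = rng.uniform(low, high)
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return Q


def brute_force_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central second differences of a scalar function; O(h^2) accurate."""
    p = len(x)
    H = np.empty((p, p))
    fx = f(x)
    for i in range(p):
        for j in range(i, p):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return H
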