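"""Matrix-exponential evaluation and directional derivatives for generator matrices.

The transition probability matrix of a time-homogeneous continuous-time Markov
chain is P(t) = expm(Q t).  Likelihood evaluation needs P(t) at many interval
lengths t for the same Q, and its gradient needs the Frechet derivative of the
matrix exponential in a handful of structured directions (one per allowed
transition).  Both are computed here from a single eigendecomposition of Q,
with the divided-difference (Loewner) formula for the derivative; when the
eigendecomposition is ill-conditioned (near-defective Q) we fall back to
scipy's Pade-based ``expm``/``expm_frechet``, which are slower but
unconditionally stable.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm, expm_frechet

__all__ = ["expm_stack", "expm_and_frechet_stack"]

# Relative eigenvalue-gap threshold below which the divided-difference formula
# loses accuracy and the Pade fallback is used instead.
_EIG_GAP_RTOL = 1e-6
_COND_MAX = 1e10


def _try_eig(Q: np.ndarray):
    """Eigendecomposition of Q if well-conditioned, else None."""
    n = Q.shape[0]
    w, V = np.linalg.eig(Q)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return None
    if np.linalg.cond(V) > _COND_MAX:
        return None
    scale = max(np.max(np.abs(w)), 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if 0 < abs(w[i] - w[j]) < _EIG_GAP_RTOL * scale:
                return None
    return w, V, Vinv


def expm_stack(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """expm(Q t) for each t in ``ts``; shape (len(ts), n, n)."""
    ts = np.asarray(ts, dtype=float)
    dec = _try_eig(Q)
    if dec is not None:
        w, V, Vinv = dec
        E = np.exp(np.multiply.outer(ts, w))  # (T, n)
        P = np.matmul(V[None, :, :] * E[:, None, :], Vinv)
        P = np.ascontiguousarray(P.real)
    else:
        P = np.stack([expm(Q * t) for t in ts])
    # clip roundoff outside [0, 1]; structural zeros may come out ~ -1e-17
    np.clip(P, 0.0, 1.0, out=P)
    return P


def _loewner(w: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Divided-difference matrices Phi[t]_ij = (e^{w_i t}-e^{w_j t})/(w_i-w_j).

    Diagonal (and coincident-eigenvalue) entries take the limit t e^{w_i t}.
    Shape (len(ts), n, n); complex.
    """
    dw = w[:, None] - w[None, :]
    ew = np.exp(np.multiply.outer(ts, w))  # (T, n)
    num = ew[:, :, None] - ew[:, None, :]
    same = np.abs(dw) < 1e-300
    dw_safe = np.where(same, 1.0, dw)
    phi = num / dw_safe[None, :, :]
    lim = ts[:, None] * ew  # t e^{w t}
    phi = np.where(same[None, :, :], lim[:, :, None] * np.ones_like(phi), phi)
    return phi


def expm_and_frechet_stack(
    Q: np.ndarray, dirs: np.ndarray, ts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """P(t)=expm(Qt) and Frechet derivatives L(Qt, D_a t) for every direction.

    Parameters
    ----------
    Q : (n, n) generator matrix.
    dirs : (n_dir, n, n) stack of derivative directions dQ/dtheta_a.
    ts : (T,) interval lengths.

    Returns
    -------
    P : (T, n, n) transition matrices.
    dP : (n_dir, T, n, n) where dP[a, t] = d expm(Q t) / d theta_a.
    """
    ts = np.asarray(ts, dtype=float)
    dirs = np.asarray(dirs, dtype=float)
    dec = _try_eig(Q)
    if dec is not None:
        w, V, Vinv = dec
        E = np.exp(np.multiply.outer(ts, w))
        P = np.matmul(V[None, :, :] * E[:, None, :], Vinv).real
        G = np.matmul(np.matmul(Vinv, dirs.astype(complex)), V)  # (A,n,n)
        phi = _loewner(w, ts)  # (T,n,n)
        inner = G[:, None, :, :] * phi[None, :, :, :]  # (A,T,n,n)
        dP = np.matmul(np.matmul(V[None, None, :, :], inner), Vinv).real
    else:
        T, n = len(ts), Q.shape[0]
        A = dirs.shape[0]
        P = np.empty((T, n, n))
        dP = np.empty((A, T, n, n))
        for t_idx, t in enumerate(ts):
            for a in range(A):
                Pt, Lt = expm_frechet(Q * t, dirs[a] * t)
                P[t_idx] = Pt
                dP[a, t_idx] = Lt
    P = np.clip(np.ascontiguousarray(P), 0.0, 1.0)
    return P, np.ascontiguousarray(dP)
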