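"""Model structure and generator-matrix algebra for multi-state Markov models.

Everything downstream of a parameter vector lives here, independent of any
dataset: the allowed-transition structure, covariate-dependent transition
intensity (generator) matrices, transition probability matrices at arbitrary
horizons, mean sojourn times, and hazard ratios with Wald confidence
intervals.

States are numbered 1..n at every interface (matching clinical reporting
conventions); the 0-based shift is internal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import expm

__all__ = [
    "TransitionStructure",
    "CovariateVector",
    "ModelParameters",
    "GeneratorMatrix",
    "TransitionProbabilityMatrix",
    "breast_cancer_structure",
    "build_generator",
    "transition_probability",
    "matrix_power_horizon",
    "mean_sojourn",
    "hazard_ratios",
    "write_matrix_csv",
    "read_matrix_csv",
]


@dataclass(frozen=True)
class TransitionStructure:
    """Directed graph of allowed instantaneous transitions.

    Parameters
    ----------
    n_states : number of states.
    allowed : iterable of 1-based ordered pairs (r, s), r != s, for which the
        transition intensity q_rs may be nonzero.
    state_labels : display name per state; defaults to "state 1", ...

    Absorbing states are those with no outgoing allowed pair.  Every
    non-absorbing state must have at least one outgoing pair (states that can
    never be left nor entered would make the chain ill-defined).
    """

    n_states: int
    allowed: tuple[tuple[int, int], ...]
    state_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        pairs = tuple(sorted(set(map(tuple, self.allowed))))
        object.__setattr__(self, "allowed", pairs)
        for r, s in pairs:
            if not (1 <= r <= self.n_states and 1 <= s <= self.n_states):
                raise ValueError(f"transition ({r},{s}) outside 1..{self.n_states}")
            if r == s:
                raise ValueError(f"self-transition ({r},{s}) not allowed")
        labels = self.state_labels or tuple(
            f"state {i}" for i in range(1, self.n_states + 1)
        )
        if len(labels) != self.n_states:
            raise ValueError("state_labels length must equal n_states")
        object.__setattr__(self, "state_labels", tuple(labels))
        out = {r for r, _ in pairs}
        incoming = {s for _, s in pairs}
        for k in range(1, self.n_states + 1):
            if k not in out and k not in incoming:
                raise ValueError(f"state {k} is disconnected from the structure")

    @property
    def absorbing(self) -> frozenset[int]:
        out = {r for r, _ in self.allowed}
        return frozenset(k for k in range(1, self.n_states + 1) if k not in out)

    @property
    def n_transitions(self) -> int:
        return len(self.allowed)

    def transition_index(self, r: int, s: int) -> int:
        """Position of (r, s) in the fixed enumeration order of `allowed`."""
        return self.allowed.index((r, s))

    def reachability(self) -> np.ndarray:
        """Boolean matrix: can state s be occupied at some t > 0 given start r."""
        A = np.zeros((self.n_states, self.n_states), dtype=bool)
        for r, s in self.allowed:
            A[r - 1, s - 1] = True
        R = np.eye(self.n_states, dtype=bool) | A
        for _ in range(self.n_states):
            R = R | (R @ R)
        return R


def breast_cancer_structure() -> TransitionStructure:
    """The four-state breast-cancer progression structure.

    State 1 (initial treatment) can move to any other state; recovery (2) and
    metastasis (3) are mutually accessible and each can end in death (4),
    which is absorbing.
    """
    return TransitionStructure(
        n_states=4,
        allowed=((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 2), (3, 4)),
        state_labels=("initial treatment", "recovery", "metastasis", "death"),
    )


@dataclass(frozen=True)
class CovariateVector:
    """Per-subject covariate values with aligned names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", tuple(self.names))
        if v.ndim != 1 or len(v) != len(self.names):
            raise ValueError("values and names must be 1-d and equal length")


@dataclass(frozen=True)
class ModelParameters:
    """Baseline log-intensities and covariate coefficients.

    ``log_baseline[a]`` is log q_rs^(0) for the a-th pair in the structure's
    enumeration order; ``beta[a, c]`` is the log-linear effect of covariate c
    on that intensity, so the hazard ratio per unit covariate increase is
    exp(beta[a, c]).  ``beta`` may have zero columns (no-covariate model).
    """

    log_baseline: np.ndarray
    beta: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self):
        lb = np.asarray(self.log_baseline, dtype=float)
        b = np.asarray(self.beta, dtype=float)
        if b.size == 0:
            b = np.zeros((len(lb), 0))
        object.__setattr__(self, "log_baseline", lb)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        if b.shape[0] != len(lb):
            raise ValueError("beta rows must match log_baseline length")
        if b.shape[1] != len(self.covariate_names):
            raise ValueError("beta columns must match covariate_names")

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[1]

    def stacked(self) -> np.ndarray:
        """Stacked parameter vector: log_baseline then beta, row-major."""
        return np.concatenate([self.log_baseline, self.beta.ravel()])

    @classmethod
    def from_stacked(
        cls, theta: np.ndarray, n_transitions: int, covariate_names=()
    ) -> "ModelParameters":
        theta = np.asarray(theta, dtype=float)
        k = len(covariate_names)
        if len(theta) != n_transitions * (1 + k):
            raise ValueError("stacked vector length mismatch")
        return cls(
            log_baseline=theta[:n_transitions],
            beta=theta[n_transitions:].reshape(n_transitions, k),
            covariate_names=tuple(covariate_names),
        )


@dataclass(frozen=True)
class GeneratorMatrix:
    """Transition intensity matrix Q (units 1/year); rows sum to zero."""

    Q: np.ndarray
    structure: TransitionStructure

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "Q", Q)
        n = self.structure.n_states
        if Q.shape != (n, n):
            raise ValueError("Q shape does not match structure")
        allowed = set(self.structure.allowed)
        for r in range(1, n + 1):
            for s in range(1, n + 1):
                if r == s:
                    continue
                v = Q[r - 1, s - 1]
                if (r, s) in allowed:
                    if v < 0:
                        raise ValueError(f"negative intensity q_{r}{s}")
                elif v != 0.0:
                    raise ValueError(f"nonzero intensity on disallowed ({r},{s})")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-12 * max(1.0, np.max(np.abs(Q))):
            raise ValueError("generator rows must sum to zero")


@dataclass(frozen=True)
class TransitionProbabilityMatrix:
    """Stochastic matrix P(t) with its horizon t in years."""

    P: np.ndarray
    horizon: float
    state_labels: tuple[str, ...] = ()

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        if self.horizon < 0:
            raise ValueError("horizon must be nonnegative")
        if np.any(P < -1e-10) or np.any(P > 1 + 1e-10):
            raise ValueError("entries must lie in [0, 1]")
        # tolerance admits matrices printed to 3 decimals; computed matrices
        # are held to ~1e-10 by the test suite and the report pipeline
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 5e-3:
            raise ValueError("rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        labels = self.state_labels or tuple(
            f"state {i}" for i in range(1, self.P.shape[0] + 1)
        )
        return pd.DataFrame(self.P, index=labels, columns=labels)


def build_generator(
    params: ModelParameters,
    structure: TransitionStructure,
    z: CovariateVector | np.ndarray | None = None,
) -> GeneratorMatrix:
    """Assemble Q for one covariate vector: q_rs(z) = exp(log q_rs0 + beta_rs . z).

    With an empty ``beta`` the covariates are ignored and the baseline
    intensities are returned.
    """
    if len(params.log_baseline) != structure.n_transitions:
        raise ValueError("parameter count does not match structure")
    if not np.all(np.isfinite(params.log_baseline)) or not np.all(
        np.isfinite(params.beta)
    ):
        raise ValueError("non-finite model parameters")
    eta = params.log_baseline.copy()
    if params.n_covariates > 0:
        zv = z.values if isinstance(z, CovariateVector) else np.asarray(z, float)
        if zv is None or zv.shape != (params.n_covariates,):
            raise ValueError(
                f"covariate vector of length {params.n_covariates} required"
            )
        if not np.all(np.isfinite(zv)):
            raise ValueError("non-finite covariate values")
        eta = eta + params.beta @ zv
    q = np.exp(eta)
    n = structure.n_states
    Q = np.zeros((n, n))
    for a, (r, s) in enumerate(structure.allowed):
        Q[r - 1, s - 1] = q[a]
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return GeneratorMatrix(Q=Q, structure=structure)


def transition_probability(
    Q: GeneratorMatrix | np.ndarray, t: float
) -> TransitionProbabilityMatrix:
    """P(t) = expm(Q t): probability of occupying state s at horizon t from r."""
    if t < 0:
        raise ValueError("horizon t must be nonnegative")
    Qm = Q.Q if isinstance(Q, GeneratorMatrix) else np.asarray(Q, float)
    labels = Q.structure.state_labels if isinstance(Q, GeneratorMatrix) else ()
    with np.errstate(over="raise", invalid="raise"):
        try:
            P = expm(Qm * t)
        except FloatingPointError as exc:  # pragma: no cover - extreme Qt
            raise OverflowError(
                f"matrix exponential overflow for |Q|t ~ {np.max(np.abs(Qm)) * t:g}"
            ) from exc
    if not np.all(np.isfinite(P)):
        raise OverflowError("matrix exponential produced non-finite entries")
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    return TransitionProbabilityMatrix(P=P, horizon=float(t), state_labels=labels)


def matrix_power_horizon(
    P1: TransitionProbabilityMatrix, k: int
) -> TransitionProbabilityMatrix:
    """P(k t) = P(t)^k under time homogeneity (Chapman-Kolmogorov)."""
    if k < 1 or int(k) != k:
        raise ValueError("k must be a positive integer")
    Pk = np.linalg.matrix_power(P1.P, int(k))
    return TransitionProbabilityMatrix(
        P=Pk, horizon=P1.horizon * int(k), state_labels=P1.state_labels
    )


def mean_sojourn(Q: GeneratorMatrix) -> np.ndarray:
    """Mean sojourn time per state: -1/q_rr, in years.

    Absorbing states are reported as ``inf`` (once entered, never left).  A
    zero diagonal on a non-absorbing state is degenerate and raises.
    """
    diag = np.diag(Q.Q)
    absorbing = Q.structure.absorbing
    out = np.empty(Q.structure.n_states)
    for i in range(Q.structure.n_states):
        if (i + 1) in absorbing:
            out[i] = np.inf
        elif diag[i] >= 0:
            raise ValueError(
                f"state {i + 1} is non-absorbing but has exit rate {-diag[i]:g}"
            )
        else:
            out[i] = -1.0 / diag[i]
    return out


def hazard_ratios(
    params: ModelParameters,
    covariance: np.ndarray,
    level: float = 0.95,
    structure: TransitionStructure | None = None,
) -> pd.DataFrame:
    """Hazard ratios exp(beta) with Wald confidence intervals.

    ``covariance`` is over the stacked parameter vector (log-baselines first,
    then beta row-major, matching :meth:`ModelParameters.stacked`).  Returns
    one row per (allowed transition, covariate): columns transition, covariate,
    hr, ci_low, ci_high on the multiplicative scale.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    n_trans, n_cov = params.beta.shape
    p = n_trans * (1 + n_cov)
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (p, p):
        raise ValueError("covariance dimension does not match stacked parameters")
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ValueError("covariance is not positive semidefinite")
    zq = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for a in range(n_trans):
        pair = structure.allowed[a] if structure is not None else (a, a)
        label = (
            f"{structure.state_labels[pair[0] - 1]} -> {structure.state_labels[pair[1] - 1]}"
            if structure is not None
            else f"transition {a + 1}"
        )
        for c in range(n_cov):
            idx = n_trans + a * n_cov + c
            b = params.beta[a, c]
            se = np.sqrt(max(cov[idx, idx], 0.0))
            rows.append(
                {
                    "transition": label,
                    "from_state": pair[0],
                    "to_state": pair[1],
                    "covariate": params.covariate_names[c],
                    "hr": np.exp(b),
                    "ci_low": np.exp(b - zq * se),
                    "ci_high": np.exp(b + zq * se),
                }
            )
    return pd.DataFrame(rows)


def write_matrix_csv(
    path: str | Path,
    matrix: TransitionProbabilityMatrix | GeneratorMatrix,
    float_format: str = "%.6f",
) -> None:
    """Write a labeled matrix as CSV with a JSON sidecar carrying metadata."""
    path = Path(path)
    if isinstance(matrix, TransitionProbabilityMatrix):
        frame = matrix.to_frame()
        meta = {"kind": "transition_probability", "horizon_years": matrix.horizon}
    else:
        labels = matrix.structure.state_labels
        frame = pd.DataFrame(matrix.Q, index=labels, columns=labels)
        meta = {"kind": "generator", "units": "1/year"}
    frame.to_csv(path, float_format=float_format)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2) + "\n"
    )


def read_matrix_csv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a labeled matrix CSV and its sidecar metadata (empty if missing)."""
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return frame, meta
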