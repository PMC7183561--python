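"""Panel-data likelihood for interval-censored multi-state observations.

Living states are seen only at visit times (the exact transition moment
between visits is unobserved), while death times are recorded exactly.  Each
consecutive observation pair (state r at t_j, state s at t_{j+1}) therefore
contributes

    log P(dt)[r, s]                                      (panel pair)
    log sum_k  P(dt)[r, k] * q_{k, death}(z)             (exact death)

where dt = t_{j+1} - t_j, P(dt) = expm(Q(z) dt), and the exact-death sum runs
over the living states k the subject could occupy just before dying.  The
log-likelihood is additive over subjects and over within-subject intervals
(Markov property).

Intensities are log-linear in the covariates, q_rs(z) = exp(log q_rs0 +
beta_rs . z), so positivity is automatic and optimization is unconstrained.
The gradient is analytic: every partial derivative of Q is a scalar multiple
of one of the per-transition elementary directions q_a * (E_rs - E_rr), so
the Frechet derivatives of expm are needed in only n_transitions directions
per distinct covariate pattern regardless of how many covariates are in the
model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._linalg import expm_and_frechet_stack, expm_stack
from .core import (
    CovariateVector,
    ModelParameters,
    TransitionStructure,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PanelObservation",
    "PanelDataset",
    "StateTable",
    "FitConfig",
    "FitResult",
    "LRTResult",
    "read_panel_csv",
    "write_panel_csv",
    "state_table",
    "crude_initial_values",
    "log_likelihood",
    "fit_mle",
    "likelihood_ratio_test",
]

@dataclass(frozen=True)
class PanelObservation:
    """One visit record: subject, time (years since entry), observed state.

    ``exact_time`` marks records whose time is an exactly observed transition
    moment (used for death) rather than a scheduled visit.
    """

    subject_id: str
    time: float
    state: int
    exact_time: bool = False


class PanelDataset:
    """Visit-time/state sequences per subject plus time-fixed covariates.

    Subjects enter in state 1 at their first observation and have at least
    two observations; within a subject, times are strictly increasing and an
    absorbing-state record, if present, is last and unique.
    """

    def __init__(
        self,
        subject_ids: list,
        times: list[np.ndarray],
        states: list[np.ndarray],
        exact: list[np.ndarray],
        covariates: np.ndarray | None = None,
        covariate_names: tuple[str, ...] = (),
        n_states: int = 4,
    ):
        self.subject_ids = list(subject_ids)
        self.times = [np.asarray(t, dtype=float) for t in times]
        self.states = [np.asarray(s, dtype=int) for s in states]
        self.exact = [np.asarray(e, dtype=bool) for e in exact]
        self.covariate_names = tuple(covariate_names)
        self.n_states = n_states
        if covariates is None:
            covariates = np.zeros((len(self.subject_ids), 0))
        self.covariates = np.asarray(covariates, dtype=float)
        self._validate()

    def _validate(self):
        n = len(self.subject_ids)
        if not (len(self.times) == len(self.states) == len(self.exact) == n):
            raise ValueError("per-subject arrays must align with subject_ids")
        if self.covariates.shape != (n, len(self.covariate_names)):
            raise ValueError("covariate matrix shape mismatch")
        for sid, t, s in zip(self.subject_ids, self.times, self.states):
            if len(t) < 2:
                raise ValueError(f"subject {sid}: fewer than 2 observations")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"subject {sid}: times not strictly increasing")
            if t[0] < 0:
                raise ValueError(f"subject {sid}: negative observation time")
            if s[0] != 1:
                raise ValueError(f"subject {sid}: first observed state must be 1")
            if np.any((s < 1) | (s > self.n_states)):
                raise ValueError(f"subject {sid}: state outside 1..{self.n_states}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_transition_pairs(self) -> int:
        return sum(len(t) - 1 for t in self.times)

    def covariate_vector(self, i: int) -> CovariateVector:
        return CovariateVector(values=self.covariates[i], names=self.covariate_names)

    def subset_covariates(self, names: list[str]) -> "PanelDataset":
        idx = [self.covariate_names.index(n) for n in names]
        return PanelDataset(
            self.subject_ids,
            self.times,
            self.states,
            self.exact,
            self.covariates[:, idx],
            tuple(names),
            self.n_states,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.subject_ids):
            for t, s, e in zip(self.times[i], self.states[i], self.exact[i]):
                row = {
                    "subject_id": sid,
                    "time_years": t,
                    "state": int(s),
                    "exact_time": int(e),
                }
                for c, name in enumerate(self.covariate_names):
                    row[name] = self.covariates[i, c]
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, covariate_names: list[str] | None = None, n_states: int = 4
    ) -> "PanelDataset":
        required = {"subject_id", "time_years", "state"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if covariate_names is None:
            covariate_names = [
                c
                for c in df.columns
                if c not in {"subject_id", "time_years", "state", "exact_time"}
            ]
        has_exact = "exact_time" in df.columns
        ids, times, states, exact, covs = [], [], [], [], []
        n_dropped = 0
        for sid, g in df.groupby("subject_id", sort=False):
            g = g.sort_values("time_years")
            zrow = g.iloc[0][covariate_names].to_numpy(dtype=float) if covariate_names else np.zeros(0)
            if covariate_names and not np.all(np.isfinite(zrow)):
                n_dropped += 1
                continue
            ids.append(sid)
            times.append(g["time_years"].to_numpy(dtype=float))
            states.append(g["state"].to_numpy(dtype=int))
            exact.append(
                g["exact_time"].to_numpy(dtype=bool)
                if has_exact
                else np.zeros(len(g), dtype=bool)
            )
            covs.append(zrow)
        if n_dropped:
            logger.info("excluded %d subjects with missing covariates", n_dropped)
        return cls(
            ids,
            times,
            states,
            exact,
            np.array(covs) if covariate_names else None,
            tuple(covariate_names),
            n_states,
        )


def read_panel_csv(
    path, covariate_names: list[str] | None = None, n_states: int = 4
) -> PanelDataset:
    """Read long-format panel data (subject_id, time_years, state, exact_time,
    covariate columns).  Subjects with missing covariates are excluded and the
    count logged."""
    return PanelDataset.from_dataframe(
        pd.read_csv(path), covariate_names=covariate_names, n_states=n_states
    )


def write_panel_csv(path, data: PanelDataset, float_format: str = "%.6f") -> None:
    data.to_dataframe().to_csv(path, index=False, float_format=float_format)


@dataclass(frozen=True)
class StateTable:
    """Counts of consecutive observed state pairs (a descriptive summary)."""

    counts: np.ndarray
    state_labels: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        labels = self.state_labels or tuple(
            f"state {i}" for i in range(1, self.counts.shape[0] + 1)
        )
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def state_table(
    data: PanelDataset, structure: TransitionStructure | None = None
) -> StateTable:
    """Tabulate successive observation pairs, diagonal (same-state) included."""
    n = data.n_states
    counts = np.zeros((n, n), dtype=int)
    for s in data.states:
        for r, c in zip(s[:-1], s[1:]):
            counts[r - 1, c - 1] += 1
    labels = structure.state_labels if structure is not None else ()
    return StateTable(counts=counts, state_labels=labels)


def crude_initial_values(
    data: PanelDataset,
    structure: TransitionStructure,
    floor: float = 1e-3,
) -> ModelParameters:
    """Rough intensity estimates q_rs ~ n_rs / T_r from the observed pairs.

    n_rs counts consecutive r -> s observation pairs and T_r is the total
    interval time whose left endpoint was observed in state r.  Allowed
    transitions never observed get the ``floor`` intensity (1e-3/yr by
    default) so the optimizer starts in the interior of the parameter space.
    Covariate coefficients start at zero.
    """
    n = data.n_states
    counts = state_table(data).counts
    time_at = np.zeros(n)
    for t, s in zip(data.times, data.states):
        dt = np.diff(t)
        for r, d in zip(s[:-1], dt):
            time_at[r - 1] += d
    lb = np.empty(structure.n_transitions)
    for a, (r, s) in enumerate(structure.allowed):
        # states with no exposure time (never observed, or seen only as a
        # final endpoint) carry no rate information and get the floor
        rate = counts[r - 1, s - 1] / time_at[r - 1] if time_at[r - 1] > 0 else 0.0
        if rate <= 0 and floor <= 0:
            raise ValueError(
                f"transition ({r},{s}) never observed and flooring disabled"
            )
        lb[a] = np.log(max(rate, floor))
    return ModelParameters(log_baseline=lb)


# --------------------------------------------------------------------------
# Likelihood internals
# --------------------------------------------------------------------------


@dataclass
class _CompiledData:
    """Dataset reorganized for fast likelihood evaluation.

    Subjects sharing a covariate pattern share a generator matrix, so their
    intervals are pooled; within a pool, intervals sharing a length share one
    matrix exponential.
    """

    structure: TransitionStructure
    groups: list[dict]  # per distinct covariate pattern
    covariate_names: tuple[str, ...]
    n_intervals: int


def _compile(
    data: PanelDataset,
    structure: TransitionStructure,
    use_covariates: bool,
    exact_death: bool,
) -> _CompiledData:
    reach = structure.reachability()
    death_states = structure.absorbing
    if use_covariates and data.covariates.shape[1] > 0:
        keys = [tuple(row) for row in np.round(data.covariates, 12)]
    else:
        keys = [()] * data.n_subjects
    pools: dict[tuple, dict] = {}
    n_int = 0
    for i in range(data.n_subjects):
        key = keys[i]
        pool = pools.setdefault(
            key,
            {
                "z": np.asarray(key, dtype=float),
                "dt": [],
                "r": [],
                "s": [],
                "exact": [],
            },
        )
        t, s, e = data.times[i], data.states[i], data.exact[i]
        for j in range(len(t) - 1):
            r0, s0 = int(s[j]), int(s[j + 1])
            dt = float(t[j + 1] - t[j])
            if r0 - 1 != s0 - 1 and not reach[r0 - 1, s0 - 1]:
                warnings.warn(
                    f"subject {data.subject_ids[i]}: observed {r0}->{s0} over "
                    f"({t[j]:g}, {t[j + 1]:g}) is impossible under the structure",
                    stacklevel=2,
                )
                pool["impossible"] = True
            is_exact = bool(e[j + 1]) and s0 in death_states and exact_death
            pool["dt"].append(dt)
            pool["r"].append(r0 - 1)
            pool["s"].append(s0 - 1)
            pool["exact"].append(is_exact)
            n_int += 1
    groups = []
    for pool in pools.values():
        dts = np.asarray(pool["dt"])
        uq, inv = np.unique(dts, return_inverse=True)
        groups.append(
            {
                "z": pool["z"],
                "uq_dt": uq,
                "inv": inv,
                "r": np.asarray(pool["r"], dtype=int),
                "s": np.asarray(pool["s"], dtype=int),
                "exact": np.asarray(pool["exact"], dtype=bool),
                "impossible": pool.get("impossible", False),
            }
        )
    return _CompiledData(
        structure=structure,
        groups=groups,
        covariate_names=data.covariate_names if use_covariates else (),
        n_intervals=n_int,
    )


def _group_generator(theta, comp: _CompiledData, z):
    """Q, per-transition intensities q_a, for one covariate pattern."""
    st = comp.structure
    nt = st.n_transitions
    k = len(comp.covariate_names)
    lb = theta[:nt]
    eta = lb.copy()
    if k:
        beta = theta[nt:].reshape(nt, k)
        eta = eta + beta @ z
    q = np.exp(eta)
    n = st.n_states
    Q = np.zeros((n, n))
    for a, (r, s) in enumerate(st.allowed):
        Q[r - 1, s - 1] = q[a]
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return Q, q


def _loglik_core(theta, comp: _CompiledData, want_grad: bool):
    st = comp.structure
    nt = st.n_transitions
    k = len(comp.covariate_names)
    n = st.n_states
    death0 = [d - 1 for d in sorted(st.absorbing)]
    ll = 0.0
    grad = np.zeros(nt * (1 + k)) if want_grad else None
    for g in comp.groups:
        if g["impossible"]:
            return -np.inf, grad
        Q, q = _group_generator(theta, comp, g["z"])
        if want_grad:
            dirs = np.zeros((nt, n, n))
            for a, (r, s) in enumerate(st.allowed):
                dirs[a, r - 1, s - 1] = q[a]
                dirs[a, r - 1, r - 1] = -q[a]
            P_u, dP_u = expm_and_frechet_stack(Q, dirs, g["uq_dt"])
        else:
            P_u = expm_stack(Q, g["uq_dt"])
            dP_u = None
        inv, r_idx, s_idx, ex = g["inv"], g["r"], g["s"], g["exact"]
        P = P_u[inv]  # (m, n, n)
        m = len(r_idx)
        contrib = np.empty(m)
        panel = ~ex
        p_panel = P[panel, r_idx[panel], s_idx[panel]]
        if np.any(p_panel <= 0):
            return -np.inf, grad
        contrib[panel] = np.log(p_panel)
        # per-direction elementary gradients, assembled per interval
        if want_grad:
            dcontrib = np.zeros((nt, m))
            dP = dP_u[:, inv]  # (nt, m, n, n)
            dcontrib[:, panel] = (
                dP[:, panel, r_idx[panel], s_idx[panel]] / p_panel[None, :]
            )
        if np.any(ex):
            # exact death: sum over living k of P[r,k] q_{k,death}
            qd = Q[:, death0].sum(axis=1)  # exit-to-death intensity per state
            living = np.array(
                [i for i in range(n) if (i + 1) not in st.absorbing], dtype=int
            )
            e_pos = np.where(ex)[0]
            Pe = P[e_pos, r_idx[e_pos], :]  # (me, n): row r per exact-death interval
            L = Pe[:, living] @ qd[living]
            if np.any(L <= 0):
                return -np.inf, grad
            contrib[ex] = np.log(L)
            if want_grad:
                dPe = dP[:, e_pos, r_idx[e_pos], :]  # (nt, me, n)
                term1 = dPe[:, :, living] @ qd[living]  # (nt, me)
                # dq_{k,death}/d a = q_a when transition a is (k+1 -> death)
                term2 = np.zeros_like(term1)
                for a, (r, s) in enumerate(st.allowed):
                    if s in st.absorbing:
                        term2[a] += Pe[:, r - 1] * q[a]
                dcontrib[:, ex] = (term1 + term2) / L[None, :]
        ll += float(contrib.sum())
        if want_grad:
            elem = dcontrib.sum(axis=1)  # (nt,) sums of d/d(elementary a)
            grad[:nt] += elem
            if k:
                grad[nt:] += np.outer(elem, g["z"]).ravel()
    return ll, grad


def log_likelihood(
    params: ModelParameters,
    data: PanelDataset,
    structure: TransitionStructure,
    exact_death: bool = True,
) -> float:
    """Panel log-likelihood of the dataset under the given parameters."""
    if not np.all(np.isfinite(params.stacked())):
        raise ValueError("non-finite parameters")
    use_cov = params.n_covariates > 0
    if use_cov and tuple(params.covariate_names) != tuple(data.covariate_names):
        data = data.subset_covariates(list(params.covariate_names))
    comp = _compile(data, structure, use_cov, exact_death)
    ll, _ = _loglik_core(params.stacked(), comp, want_grad=False)
    return ll


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and likelihood settings for :func:`fit_mle`.

    ``exact_death`` switches the exactly-observed-death contribution on or
    off (off treats death records as ordinary panel observations, for
    sensitivity analysis).  ``standardize`` centers and scales covariates for
    optimizer conditioning; coefficients are reported on the original scale.
    """

    exact_death: bool = True
    standardize: bool = False
    gtol: float = 1e-8
    maxiter: int = 500
    init_floor: float = 1e-3
    compute_covariance: bool = True


@dataclass
class FitResult:
    """MLE output: parameters, covariance, log-likelihood, convergence."""

    params: ModelParameters
    covariance: np.ndarray | None
    log_likelihood: float
    converged: bool
    n_iterations: int
    n_subjects: int
    n_transition_pairs: int
    structure: TransitionStructure
    config: FitConfig = field(default_factory=FitConfig)

    @property
    def n_parameters(self) -> int:
        return len(self.params.stacked())

    def to_dict(self) -> dict:
        return {
            "log_baseline": self.params.log_baseline.tolist(),
            "beta": self.params.beta.tolist(),
            "covariate_names": list(self.params.covariate_names),
            "allowed_transitions": [list(p) for p in self.structure.allowed],
            "covariance": None
            if self.covariance is None
            else self.covariance.tolist(),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n_subjects": self.n_subjects,
            "n_transition_pairs": self.n_transition_pairs,
        }


def _numerical_hessian(fun_grad, theta, rel_step=1e-5):
    """Hessian of -loglik via central differences of the analytic gradient."""
    p = len(theta)
    H = np.empty((p, p))
    for i in range(p):
        h = rel_step * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        _, gp = fun_grad(tp)
        tm = theta.copy()
        tm[i] -= h
        _, gm = fun_grad(tm)
        H[i] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def fit_mle(
    data: PanelDataset,
    structure: TransitionStructure,
    with_covariates: bool = False,
    config: FitConfig | None = None,
    init: ModelParameters | None = None,
) -> FitResult:
    """Maximize the panel likelihood by quasi-Newton ascent on the
    unconstrained (log-intensity, beta) scale.

    Starts from crude initial values (beta = 0) unless ``init`` is given.
    The covariance is the inverse of the observed information (numerical
    Hessian of the negative log-likelihood at the optimum); if that Hessian
    is singular the covariance is ``None`` with a warning, and the point
    estimates are still returned.
    """
    config = config or FitConfig()
    use_cov = with_covariates and len(data.covariate_names) > 0
    cov_names = data.covariate_names if use_cov else ()
    k = len(cov_names)
    nt = structure.n_transitions

    work = data
    z_mean = np.zeros(k)
    z_sd = np.ones(k)
    if use_cov and config.standardize:
        z_mean = data.covariates.mean(axis=0)
        z_sd = data.covariates.std(axis=0)
        z_sd[z_sd == 0] = 1.0
        work = PanelDataset(
            data.subject_ids,
            data.times,
            data.states,
            data.exact,
            (data.covariates - z_mean) / z_sd,
            data.covariate_names,
            data.n_states,
        )

    comp = _compile(work, structure, use_cov, config.exact_death)

    if init is not None:
        theta0 = np.concatenate(
            [init.log_baseline, init.beta.ravel() if init.beta.size else np.zeros(nt * k)]
        )
        if len(theta0) != nt * (1 + k):
            raise ValueError("init dimensions do not match model")
    else:
        crude = crude_initial_values(data, structure, floor=config.init_floor)
        theta0 = np.concatenate([crude.log_baseline, np.zeros(nt * k)])

    def negloglik(theta):
        ll, g = _loglik_core(theta, comp, want_grad=True)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(theta)
        return -ll, -g

    res = optimize.minimize(
        negloglik,
        theta0,
        jac=True,
        method="BFGS",
        options={"gtol": config.gtol, "maxiter": config.maxiter},
    )
    theta_hat = res.x
    ll_hat, g_hat = _loglik_core(theta_hat, comp, want_grad=True)
    gnorm = float(np.max(np.abs(g_hat)))
    # BFGS frequently stops on "precision loss" once the gradient is already
    # tiny relative to the likelihood scale; accept those as converged.
    converged = bool(res.success) or gnorm <= 1e-4 * max(1.0, abs(ll_hat))
    if not converged:
        warnings.warn(
            f"optimizer did not converge after {res.nit} iterations "
            f"(|grad|_inf = {gnorm:.3g})",
            stacklevel=2,
        )

    covariance = None
    if config.compute_covariance:
        H = _numerical_hessian(
            lambda t: (lambda v, g: (-v, -g))(*_loglik_core(t, comp, True)), theta_hat
        )
        try:
            covariance = np.linalg.inv(H)
            if not np.all(np.isfinite(covariance)) or np.any(np.diag(covariance) < 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            covariance = None
            warnings.warn(
                "observed information is singular; covariance unavailable",
                stacklevel=2,
            )

    # map back to the original covariate scale
    lb_hat = theta_hat[:nt].copy()
    beta_hat = theta_hat[nt:].reshape(nt, k) if k else np.zeros((nt, 0))
    if use_cov and config.standardize:
        beta_orig = beta_hat / z_sd[None, :]
        lb_orig = lb_hat - beta_orig @ z_mean
        if covariance is not None:
            # theta_orig = J theta_std with constant Jacobian
            p = nt * (1 + k)
            J = np.eye(p)
            for a in range(nt):
                for c in range(k):
                    col = nt + a * k + c
                    J[a, col] = -z_mean[c] / z_sd[c]
                    J[col, col] = 1.0 / z_sd[c]
            covariance = J @ covariance @ J.T
        lb_hat, beta_hat = lb_orig, beta_orig

    params = ModelParameters(
        log_baseline=lb_hat, beta=beta_hat, covariate_names=cov_names
    )
    logger.info(
        "fit: %d subjects, %d pairs, %d params, loglik %.4f, converged=%s",
        data.n_subjects,
        data.n_transition_pairs,
        nt * (1 + k),
        ll_hat,
        converged,
    )
    return FitResult(
        params=params,
        covariance=covariance,
        log_likelihood=float(ll_hat),
        converged=converged,
        n_iterations=int(res.nit),
        n_subjects=data.n_subjects,
        n_transition_pairs=data.n_transition_pairs,
        structure=structure,
        config=config,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(fit_null: FitResult, fit_full: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2 (ll_full - ll_null) ~ chi2(df).

    The null model's parameters must be a subset of the full model's (same
    transition structure, fewer covariates), both fitted to the same data.
    """
    if fit_null.structure.allowed != fit_full.structure.allowed:
        raise ValueError("fits use different transition structures")
    if not set(fit_null.params.covariate_names) <= set(fit_full.params.covariate_names):
        raise ValueError("null model covariates are not a subset of the full model's")
    df = fit_full.n_parameters - fit_null.n_parameters
    if df < 0:
        raise ValueError("full model has fewer parameters than null")
    if fit_null.n_subjects != fit_full.n_subjects:
        raise ValueError("fits appear to use different datasets")
    stat = 2.0 * (fit_full.log_likelihood - fit_null.log_likelihood)
    if stat < -1e-6 * max(1.0, abs(fit_full.log_likelihood)):
        warnings.warn(
            f"LRT statistic {stat:.4g} < 0: the full fit is worse than the null; "
            "check convergence",
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LRTResult(statistic=float(stat), df=int(df), p_value=p)
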