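"""End-to-end analysis pipeline: cohort in, report tables out.

Runs the full analysis shape in one call: load (or simulate) a panel cohort,
fit the multi-state model with and without covariates, compare them by
likelihood-ratio test, and emit the standard report tables — observed state
table, transition probability matrices with bootstrap confidence intervals
at each horizon, per-transition hazard ratios, and mean sojourn times.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ModelParameters,
    TransitionStructure,
    breast_cancer_structure,
    build_generator,
    hazard_ratios,
    mean_sojourn,
    transition_probability,
    write_matrix_csv,
)
from .likelihood import (
    FitConfig,
    FitResult,
    PanelDataset,
    fit_mle,
    likelihood_ratio_test,
    read_panel_csv,
    state_table,
    write_panel_csv,
)
from .simulate import default_schedule, default_true_model, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "AnalysisConfig",
    "ReportBundle",
    "probability_matrix_cis",
    "sojourn_table",
    "run_paper_analysis",
]

_FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class SimulationSpec:
    """Cohort-simulation request used when no input CSV is given."""

    n_subjects: int = 573
    covariate_effects: str = "none"
    interval_years: float = 1.0
    jitter_sd: float = 1.0 / 12.0
    max_followup_years: float = 11.0
    scheme: str = "jittered-interval"


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything one pipeline run needs; fully determines the outputs."""

    input_csv: str | None = None
    simulation: SimulationSpec | None = None
    horizons: tuple[float, ...] = (1.0, 5.0)
    level: float = 0.95
    covariates: tuple[str, ...] | None = None  # None = all columns present
    fit_config: FitConfig = field(default_factory=FitConfig)
    output_dir: str = "panelmsm_report"
    seed: int = 0
    n_boot: int = 1000
    fit_covariate_model: bool = True

    def __post_init__(self):
        if any(h <= 0 for h in self.horizons):
            raise ValueError("horizons must be positive")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.input_csv is None and self.simulation is None:
            raise ValueError("either input_csv or simulation must be given")


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run (also written to output_dir)."""

    config: AnalysisConfig
    data: PanelDataset
    fit_null: FitResult
    fit_full: FitResult | None
    lrt: object | None
    state_counts: pd.DataFrame
    probability_tables: dict[float, pd.DataFrame]
    hazard_table: pd.DataFrame | None
    sojourn: pd.DataFrame
    output_dir: Path

    @property
    def converged(self) -> bool:
        ok = self.fit_null.converged
        if self.fit_full is not None:
            ok = ok and self.fit_full.converged
        return ok


def probability_matrix_cis(
    fit: FitResult,
    t: float,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    z: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric-bootstrap confidence envelope for P(t), entrywise.

    Draws ``n_boot`` parameter vectors from the normal approximation at the
    MLE, maps each through the matrix exponential, and takes the
    level-quantile envelope per entry.  Intervals are clipped to [0, 1].
    """
    if fit.covariance is None:
        raise ValueError(
            "fit covariance unavailable; bootstrap-by-refit would be required"
        )
    theta = fit.params.stacked()
    cov = np.asarray(fit.covariance)
    rng = np.random.default_rng(seed)
    if np.allclose(cov, 0):
        P = _point_matrix(fit, t, z)
        return P.copy(), P.copy()
    # eigenvalue-clipped square root: covariance may be singular PSD
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    w = np.clip(w, 0, None)
    root = V * np.sqrt(w)
    draws = theta[None, :] + rng.standard_normal((n_boot, len(theta))) @ root.T
    # near-flat likelihood directions (rarely observed transitions) can put
    # draws at log-intensities whose exp overflows; cap them at rates far
    # outside any biological range so the envelope is unaffected
    nt = fit.structure.n_transitions
    draws[:, :nt] = np.clip(draws[:, :nt], -20.0, 10.0)
    n = fit.structure.n_states
    sims = np.empty((n_boot, n, n))
    k = len(fit.params.covariate_names)
    for b in range(n_boot):
        p = ModelParameters.from_stacked(
            draws[b], fit.structure.n_transitions, fit.params.covariate_names
        )
        Q = build_generator(p, fit.structure, z if k else None)
        sims[b] = transition_probability(Q, t).P
    alpha = 1 - level
    lo = np.quantile(sims, alpha / 2, axis=0)
    hi = np.quantile(sims, 1 - alpha / 2, axis=0)
    return np.clip(lo, 0, 1), np.clip(hi, 0, 1)


def _point_matrix(fit: FitResult, t: float, z=None) -> np.ndarray:
    k = len(fit.params.covariate_names)
    Q = build_generator(fit.params, fit.structure, z if k else None)
    return transition_probability(Q, t).P


def sojourn_table(
    fit_null: FitResult,
    fit_full: FitResult | None = None,
    z_reference: np.ndarray | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Mean sojourn times per non-absorbing state, in years.

    The no-covariate column carries delta-method confidence intervals on the
    log scale.  When a covariate fit is supplied, its column reports sojourn
    times at the reference covariate values without intervals (the sampling
    distribution at an arbitrary reference point is not reduced to a simple
    Wald form here).
    """
    st = fit_null.structure
    Q0 = build_generator(fit_null.params, st)
    soj0 = mean_sojourn(Q0)
    zq = stats.norm.ppf(0.5 + level / 2)
    nt = st.n_transitions
    rows = []
    for i in range(st.n_states):
        state = i + 1
        if state in st.absorbing:
            continue
        row = {"state": st.state_labels[i], "sojourn_years": soj0[i]}
        if fit_null.covariance is not None:
            # log sojourn_r = -log(sum_a q_a over transitions out of r);
            # gradient wrt log-baseline a is -q_a / exit rate.
            out_idx = [a for a, (r, _) in enumerate(st.allowed) if r == state]
            q = np.exp(fit_null.params.log_baseline)
            exit_rate = q[out_idx].sum()
            grad = np.zeros(nt)
            grad[out_idx] = -q[out_idx] / exit_rate
            var = grad @ fit_null.covariance[:nt, :nt] @ grad
            se = np.sqrt(max(var, 0))
            row["ci_low"] = soj0[i] * np.exp(-zq * se)
            row["ci_high"] = soj0[i] * np.exp(zq * se)
        else:
            row["ci_low"] = np.nan
            row["ci_high"] = np.nan
        if fit_full is not None:
            zref = (
                z_reference
                if z_reference is not None
                else np.zeros(len(fit_full.params.covariate_names))
            )
            Q1 = build_generator(fit_full.params, st, zref)
            row["sojourn_years_with_covariates"] = mean_sojourn(Q1)[i]
        rows.append(row)
    return pd.DataFrame(rows)


def _load_or_simulate(config: AnalysisConfig) -> PanelDataset:
    if config.input_csv is not None:
        data = read_panel_csv(config.input_csv)
        logger.info("loaded %d subjects from %s", data.n_subjects, config.input_csv)
        return data
    spec = config.simulation
    model = default_true_model(covariate_effects=spec.covariate_effects)
    schedule = default_schedule()
    schedule = type(schedule)(
        scheme=spec.scheme,
        interval_years=spec.interval_years,
        jitter_sd=spec.jitter_sd,
        max_followup_years=spec.max_followup_years,
    )
    return generate_cohort(model, spec.n_subjects, schedule, seed=config.seed)


def _prob_table(P, lo, hi, labels) -> pd.DataFrame:
    rows = []
    n = P.shape[0]
    for i in range(n):
        for j in range(n):
            rows.append(
                {
                    "from_state": labels[i],
                    "to_state": labels[j],
                    "estimate": P[i, j],
                    "ci_low": lo[i, j],
                    "ci_high": hi[i, j],
                }
            )
    return pd.DataFrame(rows)


def run_paper_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the complete analysis and write every report table to disk.

    Outputs (CSV + a human-readable report.txt) land in ``config.output_dir``:
    state_table.csv, transition_probability_{t}yr.csv per horizon,
    hazard_ratios.csv, sojourn_times.csv, lrt.json, fit_*.json, and the
    cohort itself when simulated.  Identical config and seed give
    byte-identical outputs.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure = breast_cancer_structure()
    data = _load_or_simulate(config)
    if config.covariates is not None:
        data = data.subset_covariates(list(config.covariates))
    if config.input_csv is None:
        write_panel_csv(outdir / "cohort.csv", data)

    counts = state_table(data, structure).to_frame()
    counts.to_csv(outdir / "state_table.csv")
    logger.info("stage state_table done (%.2fs)", time.time() - t0)

    fit_null = fit_mle(data, structure, with_covariates=False, config=config.fit_config)
    logger.info(
        "stage fit_null done: loglik=%.3f params=%d (%.2fs)",
        fit_null.log_likelihood,
        fit_null.n_parameters,
        time.time() - t0,
    )
    fit_full = None
    lrt = None
    if config.fit_covariate_model and len(data.covariate_names) > 0:
        fit_full = fit_mle(
            data, structure, with_covariates=True, config=config.fit_config
        )
        lrt = likelihood_ratio_test(fit_null, fit_full)
        logger.info(
            "stage fit_full done: loglik=%.3f params=%d (%.2fs)",
            fit_full.log_likelihood,
            fit_full.n_parameters,
            time.time() - t0,
        )

    prob_tables: dict[float, pd.DataFrame] = {}
    for h in config.horizons:
        P = _point_matrix(fit_null, h)
        if fit_null.covariance is not None:
            lo, hi = probability_matrix_cis(
                fit_null, h, config.level, config.n_boot, seed=config.seed + 1
            )
        else:
            lo = hi = np.full_like(P, np.nan)
        tbl = _prob_table(P, lo, hi, structure.state_labels)
        _check_matrix(P, structure)
        prob_tables[h] = tbl
        tbl.to_csv(
            outdir / f"transition_probability_{_fmt_h(h)}yr.csv",
            index=False,
            float_format=_FLOAT_FMT,
        )
        write_matrix_csv(
            outdir / f"transition_matrix_{_fmt_h(h)}yr.csv",
            transition_probability(build_generator(fit_null.params, structure), h),
        )

    hr_table = None
    if fit_full is not None and fit_full.covariance is not None:
        hr_table = hazard_ratios(
            fit_full.params, fit_full.covariance, config.level, structure
        )
        hr_table.to_csv(outdir / "hazard_ratios.csv", index=False, float_format=_FLOAT_FMT)

    z_ref = (
        data.covariates.mean(axis=0) if fit_full is not None and data.covariates.size else None
    )
    soj = sojourn_table(fit_null, fit_full, z_reference=z_ref, level=config.level)
    soj.to_csv(outdir / "sojourn_times.csv", index=False, float_format=_FLOAT_FMT)

    (outdir / "fit_null.json").write_text(json.dumps(fit_null.to_dict(), indent=2))
    if fit_full is not None:
        (outdir / "fit_full.json").write_text(json.dumps(fit_full.to_dict(), indent=2))
    if lrt is not None:
        (outdir / "lrt.json").write_text(
            json.dumps(
                {"statistic": lrt.statistic, "df": lrt.df, "p_value": lrt.p_value},
                indent=2,
            )
        )
    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "seed": config.seed,
                "n_subjects": data.n_subjects,
                "horizons": list(config.horizons),
                "level": config.level,
                "n_boot": config.n_boot,
            },
            indent=2,
        )
    )

    bundle = ReportBundle(
        config=config,
        data=data,
        fit_null=fit_null,
        fit_full=fit_full,
        lrt=lrt,
        state_counts=counts,
        probability_tables=prob_tables,
        hazard_table=hr_table,
        sojourn=soj,
        output_dir=outdir,
    )
    _write_text_report(bundle)
    if not bundle.converged:
        warnings.warn("UNCONVERGED fit in report bundle", stacklevel=2)
    logger.info("pipeline complete (%.2fs)", time.time() - t0)
    return bundle


def _fmt_h(h: float) -> str:
    return f"{h:g}".replace(".", "p")


def _check_matrix(P: np.ndarray, structure: TransitionStructure) -> None:
    if np.max(np.abs(P.sum(axis=1) - 1)) > 1e-8:
        raise AssertionError("probability table rows do not sum to 1; aborting write")
    for a in structure.absorbing:
        row = np.zeros(structure.n_states)
        row[a - 1] = 1.0
        if not np.allclose(P[a - 1], row, atol=1e-10):
            raise AssertionError("absorbing row is not a unit vector; aborting write")


def _write_text_report(bundle: ReportBundle) -> None:
    lines = []
    if not bundle.converged:
        lines += ["#" * 60, "###  UNCONVERGED FIT — interpret nothing below  ###", "#" * 60, ""]
    lines.append("Multi-state model analysis report")
    lines.append("=" * 40)
    lines.append(f"subjects: {bundle.data.n_subjects}; "
                 f"observation pairs: {bundle.data.n_transition_pairs}")
    lines.append("")
    lines.append("Observed state table (consecutive observation pairs):")
    lines.append(bundle.state_counts.to_string())
    lines.append("")
    lines.append(
        f"No-covariate fit: loglik = {bundle.fit_null.log_likelihood:.3f}, "
        f"{bundle.fit_null.n_parameters} parameters, "
        f"converged = {bundle.fit_null.converged}"
    )
    if bundle.fit_full is not None:
        lines.append(
            f"Covariate fit:    loglik = {bundle.fit_full.log_likelihood:.3f}, "
            f"{bundle.fit_full.n_parameters} parameters, "
            f"converged = {bundle.fit_full.converged}"
        )
    if bundle.lrt is not None:
        lines.append(
            f"Likelihood-ratio test: statistic = {bundle.lrt.statistic:.3f}, "
            f"df = {bundle.lrt.df}, p = {bundle.lrt.p_value:.3g}"
        )
    lines.append("")
    for h, tbl in bundle.probability_tables.items():
        lines.append(f"Transition probabilities at {h:g} year(s):")
        wide = tbl.pivot(index="from_state", columns="to_state", values="estimate")
        order = list(bundle.fit_null.structure.state_labels)
        lines.append(wide.loc[order, order].round(3).to_string())
        lines.append("")
    lines.append("Mean sojourn times (years):")
    lines.append(bundle.sojourn.round(3).to_string(index=False))
    lines.append("")
    (bundle.output_dir / "report.txt").write_text("\n".join(lines) + "\n")
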