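"""Sequential calibration stages and the study driver.

The study calibrates the model hierarchy in four stages, each isolating a
parameter with data acquired to interrogate it specifically:

1. **apoptosis** -- proliferation-inhibited wells in rich nutrient; the
   exponential-death model calibrates ``lambda_apop``, ``phi_V0`` and the
   noise sd ``sigma`` from uniform priors;
2. **proliferation** -- untreated wells at optimal nutrient (phi_sigma = 1);
   the logistic model calibrates ``lambda_prol`` and ``K`` while *updating*
   ``lambda_apop`` and ``phi_V0`` under priors fitted to the stage-1
   posterior;
3. **necrosis** -- nutrient-deprived wells (one stage per FBS level and
   seeding density); the two-compartment model calibrates ``lambda_VN``
   under stage-2 posteriors as priors for the shared parameters;
4. **mobility** -- 12-hour spatial field series; the mobility-only
   Cahn--Hilliard model calibrates ``M_T``, ``E_bar_T`` and ``epsilon_T``
   with the Pearson-correlation likelihood.

Each stage reports its posterior, a posterior-predictive band, and per-day /
day-averaged L1-CDF calibration errors. Posteriors propagate downstream as
fitted parametric priors truncated to the original supports, with full
provenance recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from tumorcal.bayes import (
    MCMCConfig,
    PosteriorSample,
    PredictiveBand,
    Prior,
    PriorSpec,
    log_likelihood_pcc,
    log_prior,
    pearson_cc,
    posterior_predictive,
    posterior_to_prior,
    run_mcmc,
)
from tumorcal.data_model import FieldSeries, TimeCourseDataset
from tumorcal.forward_models import (
    Grid,
    PhaseFieldParams,
    PhaseFieldState,
    simulate_mobility_ch,
)
from tumorcal.metrics import timecourse_calibration_error

__all__ = [
    "StageSpec",
    "CalibrationResult",
    "StudyResult",
    "default_priors",
    "run_stage",
    "run_sequential_study",
    "cross_validate",
    "MODEL_PARAMS",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: Full parameter list of each stage's model variant (sigma included:
#: the noise sd is calibrated alongside the physical parameters).
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "apoptosis": ("lambda_apop", "phi_V0", "sigma"),
    "proliferation": ("lambda_prol", "K", "lambda_apop", "phi_V0", "sigma"),
    "necrosis": ("lambda_VN", "lambda_apop", "lambda_prol", "K", "phi_V0", "sigma"),
    "mobility": ("M_T", "E_bar_T", "epsilon_T", "sigma"),
}


def default_priors(stage: str) -> PriorSpec:
    """Stage-1 (non-propagated) uniform priors for each scenario.

    Time-course stages use wide uniforms: rates U(0, 10) per day, phi_V0
    U(1e-5, 1), K U(0, 1), noise sd U(1e-5, 20). The mobility stage uses
    M_T U(0, 1000) um/day, E_bar_T U(0.15, 1.15), epsilon_T U(1, 1000) um
    and sigma U(1e-5, 0.2).
    """
    u = lambda name, a, b: Prior(name, "uniform", (a, b))  # noqa: E731
    if stage == "apoptosis":
        return PriorSpec([u("lambda_apop", 0, 10), u("phi_V0", 1e-5, 1),
                          u("sigma", 1e-5, 20)])
    if stage == "proliferation":
        return PriorSpec([u("lambda_prol", 0, 10), u("K", 0, 1),
                          u("lambda_apop", 0, 10), u("phi_V0", 1e-5, 1),
                          u("sigma", 1e-5, 20)])
    if stage == "necrosis":
        return PriorSpec([u("lambda_VN", 0, 10), u("lambda_apop", 0, 10),
                          u("lambda_prol", 0, 10), u("K", 0, 1),
                          u("phi_V0", 1e-5, 1), u("sigma", 1e-5, 20)])
    if stage == "mobility":
        return PriorSpec([u("M_T", 0, 1000), u("E_bar_T", 0.15, 1.15),
                          u("epsilon_T", 1, 1000), u("sigma", 1e-5, 0.2)])
    raise ValueError(f"unknown stage {stage!r}")


@dataclass
class StageSpec:
    """Configuration of one calibration stage.

    ``priors`` covers the calibrated parameters (including ``sigma``);
    ``fixed`` pins the remaining model parameters (e.g. ``phi_sigma``).
    Together they must cover the model's parameter list exactly once.
    """

    name: str
    scenario_id: str
    priors: PriorSpec
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    fixed: dict[str, float] = field(default_factory=dict)
    phi_sigma: float = 1.0
    predictive_draws: int = 2_000
    predictive_seed: int = 0
    ode_dt: float = 0.05  # days, RK4 step inside the necrosis likelihood
    # (RK4 error ~(rate*dt)^4 ~ 1e-8 relative here, far below the noise)
    ch_dt: float | None = None  # days, CH step for mobility (default: frame gap)
    prior_source: str | None = None  # provenance: upstream stage id

    def __post_init__(self) -> None:
        if self.name not in MODEL_PARAMS:
            raise ValueError(f"unknown stage {self.name!r}")
        want = set(MODEL_PARAMS[self.name])
        have = set(self.priors.names) | set(self.fixed)
        overlap = set(self.priors.names) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both calibrated and fixed: {sorted(overlap)}")
        if have != want:
            raise ValueError(
                f"stage {self.name}: calibrated+fixed must cover {sorted(want)}, "
                f"got {sorted(have)}"
            )


@dataclass
class CalibrationResult:
    """Posterior, predictive band, and calibration errors of one stage."""

    spec: StageSpec
    posterior: PosteriorSample
    band: PredictiveBand | None
    per_day_errors: np.ndarray | None
    average_error: float | None

    @property
    def stage(self) -> str:
        return self.spec.name


@dataclass
class StudyResult:
    """All stage results of a sequential study with prior provenance.

    ``provenance[stage_id]`` names the upstream stage whose posterior
    supplied the priors (None for stages with configured priors);
    ``failed[stage_id]`` records the error message of an aborted stage.
    """

    results: dict[str, CalibrationResult]
    provenance: dict[str, str | None]
    failed: dict[str, str]
    master_seed: int


# ---------------------------------------------------------------------------
# Forward predictors (closed forms / fast integrators, vectorized over draws)
# ---------------------------------------------------------------------------

def _predict_exponential(lam, phi0, t: np.ndarray) -> np.ndarray:
    """phi_V for exponential death; broadcasts (n,1) params over (t,)."""
    return phi0 * np.exp(-np.clip(lam * t, -500.0, 500.0))


def _predict_logistic(lam_p, K, lam_a, phi0, phi_sigma: float, t: np.ndarray):
    """Closed-form logistic-with-death phi_V, vectorized over parameter draws."""
    a = lam_p * phi_sigma
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        r = a - lam_a
        safe_a = np.where(a == 0.0, 1.0, a)
        k_eff = K * (1.0 - lam_a / safe_a)
        e = np.exp(np.clip(-r * t, -500.0, 500.0))
        k_safe = np.where(k_eff == 0.0, 1.0, k_eff)
        logistic = k_safe / (1.0 + (k_safe / phi0 - 1.0) * e)
        logistic = np.where(k_eff == 0.0, phi0 / (1.0 + (safe_a / K) * phi0 * t), logistic)
        decay = phi0 * np.exp(np.clip(-lam_a * t, -500.0, 500.0))
        out = np.where(a == 0.0, decay, logistic)
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


def _necrosis_phi_v_scalar(lam_vn, lam_a, lam_p, K, phi0, phi_sigma, times, dt):
    """Scalar RK4 for the two-compartment system; returns phi_V at `times`.

    Plain-float inner loop: this sits inside the MCMC likelihood, where it
    is called tens of thousands of times.
    """
    a = lam_p * phi_sigma
    phi_t, phi_n = phi0, 0.0
    out = [phi0]
    t = times[0]
    for t_next in times[1:]:
        span = t_next - t
        n = max(1, int(math.ceil(span / dt - 1e-12)))
        h = span / n
        for _ in range(n):
            def f(pt, pn):
                pv = pt - pn
                return (a * pv * (1.0 - pt / K) - lam_a * pv, lam_vn * pv)
            k1t, k1n = f(phi_t, phi_n)
            k2t, k2n = f(phi_t + 0.5 * h * k1t, phi_n + 0.5 * h * k1n)
            k3t, k3n = f(phi_t + 0.5 * h * k2t, phi_n + 0.5 * h * k2n)
            k4t, k4n = f(phi_t + h * k3t, phi_n + h * k3n)
            phi_t += (h / 6.0) * (k1t + 2 * k2t + 2 * k3t + k4t)
            phi_n += (h / 6.0) * (k1n + 2 * k2n + 2 * k3n + k4n)
        t = t_next
        out.append(phi_t - phi_n)
    return out


def _predict_necrosis_batch(lam_vn, lam_a, lam_p, K, phi0, phi_sigma, times, dt):
    """Vectorized RK4 over parameter draws; returns (n_draws, n_times) phi_V."""
    a = lam_p * phi_sigma
    phi_t = phi0.copy()
    phi_n = np.zeros_like(phi0)
    cols = [phi_t - phi_n]
    t = times[0]
    for t_next in times[1:]:
        span = t_next - t
        n = max(1, int(math.ceil(span / dt - 1e-12)))
        h = span / n
        for _ in range(n):
            def f(pt, pn):
                pv = pt - pn
                return (a * pv * (1.0 - pt / K) - lam_a * pv, lam_vn * pv)
            k1t, k1n = f(phi_t, phi_n)
            k2t, k2n = f(phi_t + 0.5 * h * k1t, phi_n + 0.5 * h * k1n)
            k3t, k3n = f(phi_t + 0.5 * h * k2t, phi_n + 0.5 * h * k2n)
            k4t, k4n = f(phi_t + h * k3t, phi_n + h * k3n)
            phi_t = phi_t + (h / 6.0) * (k1t + 2 * k2t + 2 * k3t + k4t)
            phi_n = phi_n + (h / 6.0) * (k1n + 2 * k2n + 2 * k3n + k4n)
        t = t_next
        cols.append(phi_t - phi_n)
    return np.column_stack(cols)


def _gauss_loglik(y: np.ndarray, pred: np.ndarray, sigma: float) -> float:
    """Gaussian i.i.d. log-likelihood of (N_t, N_r) data given day means."""
    resid = y - pred[:, None]
    n = resid.size
    return -0.5 * n * (_LOG_2PI + 2.0 * math.log(sigma)) - float(
        np.sum(resid * resid)
    ) / (2.0 * sigma * sigma)


# ---------------------------------------------------------------------------
# Stage log-posteriors
# ---------------------------------------------------------------------------

def _make_timecourse_log_posterior(spec: StageSpec, data: TimeCourseDataset):
    names = spec.priors.names
    idx = {n: i for i, n in enumerate(names)}
    fixed = spec.fixed
    t = data.times
    y = data.values
    phi_sigma = spec.phi_sigma
    stage = spec.name
    priors = spec.priors
    dt = spec.ode_dt

    def get(theta, name):
        return fixed[name] if name in fixed else theta[idx[name]]

    def logpost(theta: np.ndarray) -> float:
        lp = log_prior(theta, priors)
        if lp == -math.inf:
            return -math.inf
        sigma = get(theta, "sigma")
        if stage == "apoptosis":
            pred = _predict_exponential(get(theta, "lambda_apop"),
                                        get(theta, "phi_V0"), t)
        elif stage == "proliferation":
            pred = _predict_logistic(get(theta, "lambda_prol"), get(theta, "K"),
                                     get(theta, "lambda_apop"), get(theta, "phi_V0"),
                                     phi_sigma, t)
        else:  # necrosis
            pred = np.array(_necrosis_phi_v_scalar(
                get(theta, "lambda_VN"), get(theta, "lambda_apop"),
                get(theta, "lambda_prol"), get(theta, "K"), get(theta, "phi_V0"),
                phi_sigma, t, dt,
            ))
        return lp + _gauss_loglik(y, pred, sigma)

    return logpost


def _make_mobility_log_posterior(spec: StageSpec, data: FieldSeries):
    priors = spec.priors
    idx = {n: i for i, n in enumerate(priors.names)}
    fixed = spec.fixed
    times_days = data.times / 24.0
    grid = Grid(nx=data.shape[1], ny=data.shape[0], spacing=data.pixel_size)
    initial = PhaseFieldState(
        phi_T=data.grids[0].copy(), phi_N=np.zeros(data.shape), time=times_days[0]
    )
    ch_dt = spec.ch_dt if spec.ch_dt is not None else float(np.diff(times_days).min())
    obs = [g.ravel() for g in data.grids[1:]]

    def get(theta, name):
        return fixed[name] if name in fixed else theta[idx[name]]

    def logpost(theta: np.ndarray) -> float:
        lp = log_prior(theta, priors)
        if lp == -math.inf:
            return -math.inf
        sigma = get(theta, "sigma")
        params = PhaseFieldParams(
            M_T=get(theta, "M_T"), E_bar_T=get(theta, "E_bar_T"),
            epsilon_T=get(theta, "epsilon_T"),
        )
        try:
            traj = simulate_mobility_ch(params, initial, times_days, grid,
                                        dt=ch_dt, bound_tol=0.1)
        except Exception:  # noqa: BLE001 - solver failure => zero likelihood
            return -math.inf
        total = lp
        # frame 0 is the shared initial condition; score the evolved frames
        for g_obs, state in zip(obs, traj.states[1:]):
            r = 1.0 - pearson_cc(g_obs, state.phi_V.ravel())
            total += -0.5 * (_LOG_2PI + 2.0 * math.log(sigma)) - r * r / (
                2.0 * sigma * sigma
            )
        return total

    return logpost


# ---------------------------------------------------------------------------
# Stage execution
# ---------------------------------------------------------------------------

def _predictive_simulator(spec: StageSpec, times: np.ndarray):
    """Vectorized map from posterior draw matrix to phi_V at `times`."""
    names = spec.priors.names
    idx = {n: i for i, n in enumerate(names)}
    fixed = spec.fixed

    def col(thetas, name):
        if name in fixed:
            return np.full((thetas.shape[0], 1), fixed[name])
        return thetas[:, idx[name]][:, None]

    def simulate(thetas: np.ndarray) -> np.ndarray:
        if spec.name == "apoptosis":
            return _predict_exponential(col(thetas, "lambda_apop"),
                                        col(thetas, "phi_V0"), times)
        if spec.name == "proliferation":
            return _predict_logistic(col(thetas, "lambda_prol"), col(thetas, "K"),
                                     col(thetas, "lambda_apop"), col(thetas, "phi_V0"),
                                     spec.phi_sigma, times)
        if spec.name == "necrosis":
            return _predict_necrosis_batch(
                col(thetas, "lambda_VN")[:, 0], col(thetas, "lambda_apop")[:, 0],
                col(thetas, "lambda_prol")[:, 0], col(thetas, "K")[:, 0],
                col(thetas, "phi_V0")[:, 0], spec.phi_sigma, times, spec.ode_dt,
            )
        raise ValueError(f"no scalar predictive for stage {spec.name}")

    return simulate


def run_stage(
    spec: StageSpec, data: TimeCourseDataset | FieldSeries
) -> CalibrationResult:
    """Calibrate one stage: MCMC, predictive band, L1-CDF errors.

    Time-course stages get a posterior-predictive band over the data days
    and per-day / day-averaged calibration errors; the mobility stage
    (spatial data) reports the posterior only.
    """
    if spec.name == "mobility":
        if not isinstance(data, FieldSeries):
            raise TypeError("mobility stage needs a FieldSeries")
        logpost = _make_mobility_log_posterior(spec, data)
        posterior = run_mcmc(logpost, spec.priors, spec.mcmc)
        return CalibrationResult(spec, posterior, None, None, None)

    if not isinstance(data, TimeCourseDataset):
        raise TypeError(f"{spec.name} stage needs a TimeCourseDataset")
    logpost = _make_timecourse_log_posterior(spec, data)
    posterior = run_mcmc(logpost, spec.priors, spec.mcmc)
    simulate = _predictive_simulator(spec, data.times)
    band = posterior_predictive(
        posterior, simulate, data.times, n_draws=spec.predictive_draws,
        seed=spec.predictive_seed, vectorized=True,
    )
    per_day, avg = timecourse_calibration_error(
        [band.samples[:, j] for j in range(data.n_times)], data
    )
    return CalibrationResult(spec, posterior, band, per_day, avg)


# ---------------------------------------------------------------------------
# Sequential study
# ---------------------------------------------------------------------------

def _stage_mcmc(base: MCMCConfig, seed: int) -> MCMCConfig:
    return replace(base, seed=seed)


def run_sequential_study(
    bundle: dict[str, TimeCourseDataset | FieldSeries],
    densities: tuple[float, ...] = (5e3, 1e4, 2.5e4, 5e4, 1e5),
    necrosis_densities: tuple[float, ...] = (2.5e4, 5e4, 1e5),
    necrosis_fbs: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5),
    mobility_fbs: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0),
    mcmc: MCMCConfig | None = None,
    predictive_draws: int = 2_000,
    master_seed: int = 0,
) -> StudyResult:
    """Run the four-stage study, threading posteriors into priors.

    ``bundle`` maps scenario ids (as produced by the synthetic study
    fixture: ``apoptosis_d5000``, ``proliferation_d5000``,
    ``necrosis_f0p0_d25000``, ``mobility_f0p0``, ...) to datasets. Stages
    run per seeding density: each density's apoptosis posterior seeds its
    proliferation priors, whose posterior seeds that density's necrosis
    stages across FBS levels. Mobility stages are independent per FBS
    level. A failed stage aborts its dependents but not the rest.
    """
    mcmc = mcmc or MCMCConfig(n_steps=6_000, burn_in=3_000)
    results: dict[str, CalibrationResult] = {}
    provenance: dict[str, str | None] = {}
    failed: dict[str, str] = {}
    seed_counter = master_seed

    def next_seed() -> int:
        nonlocal seed_counter
        seed_counter += 1
        return seed_counter % (2**31 - 1)

    def fbs_tag(fbs: float) -> str:
        return f"f{str(fbs).replace('.', 'p')}"

    for d in densities:
        apo_id = f"apoptosis_d{int(d)}"
        prol_id = f"proliferation_d{int(d)}"
        try:
            spec = StageSpec(
                name="apoptosis", scenario_id=apo_id,
                priors=default_priors("apoptosis"),
                mcmc=_stage_mcmc(mcmc, next_seed()),
                predictive_draws=predictive_draws,
            )
            results[apo_id] = run_stage(spec, bundle[apo_id])
            provenance[apo_id] = None
        except Exception as exc:  # noqa: BLE001 - record and continue study
            failed[apo_id] = str(exc)
            continue

        try:
            prol_priors = default_priors("proliferation").replace(
                **{
                    name: _chained_prior(results[apo_id], name,
                                         default_priors("proliferation")[name],
                                         apo_id)
                    for name in ("lambda_apop", "phi_V0")
                }
            )
            spec = StageSpec(
                name="proliferation", scenario_id=prol_id, priors=prol_priors,
                mcmc=_stage_mcmc(mcmc, next_seed()), phi_sigma=1.0,
                predictive_draws=predictive_draws, prior_source=apo_id,
            )
            results[prol_id] = run_stage(spec, bundle[prol_id])
            provenance[prol_id] = apo_id
        except Exception as exc:  # noqa: BLE001
            failed[prol_id] = str(exc)
            continue

        if d in necrosis_densities:
            for fbs in necrosis_fbs:
                nec_id = f"necrosis_{fbs_tag(fbs)}_d{int(d)}"
                try:
                    nec_priors = default_priors("necrosis").replace(
                        **{
                            name: _chained_prior(results[prol_id], name,
                                                 default_priors("necrosis")[name],
                                                 prol_id)
                            for name in ("lambda_apop", "lambda_prol", "K", "phi_V0")
                        }
                    )
                    spec = StageSpec(
                        name="necrosis", scenario_id=nec_id, priors=nec_priors,
                        mcmc=_stage_mcmc(mcmc, next_seed()), phi_sigma=fbs / 10.0,
                        predictive_draws=predictive_draws, prior_source=prol_id,
                    )
                    results[nec_id] = run_stage(spec, bundle[nec_id])
                    provenance[nec_id] = prol_id
                except Exception as exc:  # noqa: BLE001
                    failed[nec_id] = str(exc)

    for fbs in mobility_fbs:
        mob_id = f"mobility_{fbs_tag(fbs)}"
        if mob_id not in bundle:
            continue
        try:
            spec = StageSpec(
                name="mobility", scenario_id=mob_id,
                priors=default_priors("mobility"),
                mcmc=_stage_mcmc(mcmc, next_seed()),
            )
            results[mob_id] = run_stage(spec, bundle[mob_id])
            provenance[mob_id] = None
        except Exception as exc:  # noqa: BLE001
            failed[mob_id] = str(exc)

    return StudyResult(results=results, provenance=provenance, failed=failed,
                       master_seed=master_seed)


def _chained_prior(upstream: CalibrationResult, name: str, original: Prior,
                   source_id: str) -> Prior:
    """Fitted marginal of an upstream posterior, truncated to the original support."""
    from tumorcal.bayes import fit_posterior_distribution

    fit = fit_posterior_distribution(upstream.posterior.marginal(name), name=name)
    p = fit.prior
    return Prior(name, p.family, p.params, bounds=original.bounds, source=source_id)


def require_dependency(results: dict[str, CalibrationResult], stage_id: str) -> None:
    """Raise if a prior-source stage is absent (provenance completeness check)."""
    if stage_id not in results:
        raise KeyError(f"dependency {stage_id!r} has no completed result")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(data: TimeCourseDataset, spec: StageSpec) -> dict:
    """Leave-one-replicate-out prediction error for a time-course stage.

    For each replicate: calibrate on the other replicates, push the
    posterior-predictive ensemble forward with the held-out replicate's
    day-0 measurement as the initial condition, and score the prediction
    against the held-out time course with the per-day L1-CDF metric.
    Returns per-fold per-day errors, per-fold averages, and the overall
    average, all in percent.
    """
    if spec.name == "mobility":
        raise ValueError("cross-validation applies to time-course stages")
    if data.n_replicates < 2:
        raise ValueError("need at least 2 replicates to cross-validate")
    folds = []
    for i in range(data.n_replicates):
        train = data.drop_replicate(i)
        held = data.replicate(i)
        fold_spec = replace(
            spec, mcmc=replace(spec.mcmc, seed=spec.mcmc.seed + 1000 * (i + 1))
        )
        fit = run_stage(fold_spec, train)
        # predictive ensemble re-initialized at the held-out day-0 reading
        draws = fit.posterior.draws.copy()
        if "phi_V0" in fit.posterior.names:
            draws[:, fit.posterior.names.index("phi_V0")] = held[0]
        refit_posterior = replace_draws(fit.posterior, draws)
        simulate = _predictive_simulator(fold_spec, data.times)
        band = posterior_predictive(
            refit_posterior, simulate, data.times,
            n_draws=fold_spec.predictive_draws, seed=fold_spec.predictive_seed,
            vectorized=True,
        )
        per_day = np.empty(data.n_times)
        for j in range(data.n_times):
            from tumorcal.metrics import l1_cdf_distance

            ybar = float(held[j]) if held[j] > 0 else float(data.values[j].mean())
            per_day[j] = 100.0 * l1_cdf_distance(band.samples[:, j],
                                                 np.array([held[j]]), ybar)
        folds.append({"replicate": i, "per_day": per_day,
                      "average": float(per_day.mean())})
    overall = float(np.mean([f["average"] for f in folds]))
    return {"folds": folds, "average": overall}


def replace_draws(posterior: PosteriorSample, draws: np.ndarray) -> PosteriorSample:
    """Posterior with a substituted draw matrix (diagnostics carried over)."""
    return PosteriorSample(
        names=list(posterior.names), draws=draws,
        log_posterior=posterior.log_posterior,
        acceptance_rate=posterior.acceptance_rate,
        ess=posterior.ess, seed=posterior.seed,
    )
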