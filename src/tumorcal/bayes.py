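"""Bayesian calibration machinery: priors, likelihoods, MCMC, propagation.

The calibration treats parameters, data and model outputs as random
variables. Measurement noise and model inadequacy are folded into one
zero-mean Gaussian whose standard deviation ``sigma`` is itself calibrated
as a hyperparameter. Two likelihoods are used:

* a Gaussian i.i.d. likelihood over replicate-by-day viability residuals
  for the time-course stages, and
* a Gaussian likelihood on ``1 - PCC`` per frame for the spatial mobility
  stage, where PCC is the Pearson correlation between the model field and
  the measured field at matched pixels.

Sampling uses an adaptive random-walk Metropolis chain: a diagonal Gaussian
proposal whose global scale is tuned during burn-in toward a 20--40%
acceptance rate and whose per-parameter widths follow the running posterior
spread. Stage chaining fits each posterior marginal with a Normal or
LogNormal (whichever is closer to the empirical CDF in L1) and uses the fit,
truncated to the original support, as the downstream prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtr

from tumorcal.data_model import FieldSeries, TimeCourseDataset
from tumorcal.forward_models import Trajectory

__all__ = [
    "Prior",
    "PriorSpec",
    "NoiseModel",
    "PosteriorSample",
    "PredictiveBand",
    "MCMCConfig",
    "FitResult",
    "log_prior",
    "log_likelihood_timecourse",
    "pearson_cc",
    "log_likelihood_pcc",
    "run_mcmc",
    "fit_posterior_distribution",
    "posterior_to_prior",
    "posterior_predictive",
]

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class Prior:
    """One parameter's prior: a family, its parameters, and support bounds.

    Families: ``uniform(a, b)`` (params = bounds); ``normal(mu, sd)`` and
    ``lognormal(mu_log, sd_log)``, both optionally truncated to ``bounds``;
    ``empirical`` (Gaussian KDE over a retained sample set). ``source``
    records provenance when the prior is a fitted upstream posterior.
    """

    name: str
    family: str
    params: tuple[float, ...] = ()
    bounds: tuple[float, float] = (-math.inf, math.inf)
    samples: np.ndarray | None = None  # empirical family only
    source: str | None = None

    def __post_init__(self) -> None:
        a, b = self.bounds
        if self.family == "uniform":
            if not self.params:
                self.params = (a, b)
            a, b = self.params
            self.bounds = (a, b)
            if not (math.isfinite(a) and math.isfinite(b) and b > a):
                raise ValueError(f"uniform prior {self.name}: need finite a < b")
        elif self.family in ("normal", "lognormal"):
            if len(self.params) != 2 or self.params[1] <= 0:
                raise ValueError(f"{self.family} prior {self.name}: need (loc, scale>0)")
            if self.family == "lognormal":
                self.bounds = (max(a, 0.0), b)
        elif self.family == "empirical":
            if self.samples is None or len(self.samples) < 2:
                raise ValueError(f"empirical prior {self.name}: need retained samples")
            self.samples = np.asarray(self.samples, dtype=float)
            self._kde = stats.gaussian_kde(self.samples)
        else:
            raise ValueError(f"unknown prior family {self.family!r}")
        self._init_norm()

    def _init_norm(self) -> None:
        """Precompute the log of the truncated-density normalizing constant."""
        a, b = self.bounds
        if self.family == "normal":
            mu, sd = self.params
            za = (a - mu) / sd if math.isfinite(a) else -math.inf
            zb = (b - mu) / sd if math.isfinite(b) else math.inf
            mass = (ndtr(zb) if math.isfinite(zb) else 1.0) - (
                ndtr(za) if math.isfinite(za) else 0.0
            )
            self._log_trunc = math.log(mass) if mass > 0 else -math.inf
        elif self.family == "lognormal":
            mu, sd = self.params
            za = (math.log(a) - mu) / sd if a > 0 else -math.inf
            zb = (math.log(b) - mu) / sd if math.isfinite(b) else math.inf
            mass = (ndtr(zb) if math.isfinite(zb) else 1.0) - (
                ndtr(za) if math.isfinite(za) else 0.0
            )
            self._log_trunc = math.log(mass) if mass > 0 else -math.inf
        else:
            self._log_trunc = 0.0

    def logpdf(self, x: float) -> float:
        a, b = self.bounds
        if x < a or x > b:
            return -math.inf
        if self.family == "uniform":
            return -math.log(b - a)
        if self.family == "normal":
            mu, sd = self.params
            z = (x - mu) / sd
            return -0.5 * (_LOG_2PI + z * z) - math.log(sd) - self._log_trunc
        if self.family == "lognormal":
            if x <= 0:
                return -math.inf
            mu, sd = self.params
            lx = math.log(x)
            z = (lx - mu) / sd
            return (
                -0.5 * (_LOG_2PI + z * z) - math.log(sd) - lx - self._log_trunc
            )
        # empirical
        val = float(self._kde.logpdf(x)[0])
        return val

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        a, b = self.bounds
        if self.family == "uniform":
            return rng.uniform(a, b, size)
        if self.family == "empirical":
            return self._kde.resample(size, seed=rng).ravel()
        # truncated normal / lognormal by inverse-CDF on the retained mass
        mu, sd = self.params
        if self.family == "normal":
            za = (a - mu) / sd if math.isfinite(a) else -math.inf
            zb = (b - mu) / sd if math.isfinite(b) else math.inf
            lo = ndtr(za) if math.isfinite(za) else 0.0
            hi = ndtr(zb) if math.isfinite(zb) else 1.0
            u = rng.uniform(lo, hi, size)
            return mu + sd * stats.norm.ppf(u)
        za = (math.log(a) - mu) / sd if a > 0 else -math.inf
        zb = (math.log(b) - mu) / sd if math.isfinite(b) else math.inf
        lo = ndtr(za) if math.isfinite(za) else 0.0
        hi = ndtr(zb) if math.isfinite(zb) else 1.0
        u = rng.uniform(lo, hi, size)
        return np.exp(mu + sd * stats.norm.ppf(u))

    def std(self) -> float:
        """A scale estimate used to seed proposal widths."""
        if self.family == "uniform":
            a, b = self.params
            return (b - a) / math.sqrt(12.0)
        if self.family == "normal":
            return self.params[1]
        if self.family == "lognormal":
            mu, sd = self.params
            return math.sqrt((math.exp(sd**2) - 1.0)) * math.exp(mu + 0.5 * sd**2)
        return float(np.std(self.samples))


@dataclass
class PriorSpec:
    """Ordered collection of per-parameter priors."""

    priors: list[Prior]

    def __post_init__(self) -> None:
        names = [p.name for p in self.priors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate prior names in {names}")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.priors]

    def __getitem__(self, name: str) -> Prior:
        for p in self.priors:
            if p.name == name:
                return p
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.priors)

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw a (size, n_params) matrix of independent prior samples."""
        return np.column_stack([p.sample(rng, size) for p in self.priors])

    def replace(self, **updates: Prior) -> "PriorSpec":
        """New spec with the named priors swapped out, order preserved."""
        unknown = set(updates) - set(self.names)
        if unknown:
            raise KeyError(f"not in spec: {sorted(unknown)}")
        return PriorSpec([updates.get(p.name, p) for p in self.priors])


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean Gaussian noise/inadequacy model with calibrated sigma."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def log_prior(theta: np.ndarray, priors: PriorSpec, names: list[str] | None = None) -> float:
    """Sum of per-parameter log prior densities; -inf outside any support."""
    theta = np.asarray(theta, dtype=float)
    if names is not None and names != priors.names:
        raise ValueError(f"parameter names {names} do not match priors {priors.names}")
    if theta.size != len(priors):
        raise ValueError(f"theta has {theta.size} entries for {len(priors)} priors")
    total = 0.0
    for x, p in zip(theta, priors.priors):
        lp = p.logpdf(float(x))
        if lp == -math.inf:
            return -math.inf
        total += lp
    return total


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def log_likelihood_timecourse(
    data: TimeCourseDataset, model_traj: Trajectory, sigma: float
) -> float:
    """Gaussian log-likelihood of replicate viability data given a trajectory.

    ``sum_j sum_i [ -1/2 log(2 pi sigma^2) - (y_ij - d_j)^2 / (2 sigma^2) ]``
    over ``N_t`` measurement days and ``N_r`` replicates per day; the model
    must be evaluated at exactly the data days.
    """
    if sigma <= 0:
        return -math.inf
    if model_traj.times.size != data.times.size or not np.allclose(
        model_traj.times, data.times, atol=1e-9
    ):
        raise ValueError("model trajectory times do not match data days")
    d = model_traj.phi_V
    resid = data.values - d[:, None]
    n_obs = resid.size
    return float(
        -0.5 * n_obs * (_LOG_2PI + 2.0 * math.log(sigma))
        - float(np.sum(resid**2)) / (2.0 * sigma**2)
    )


def pearson_cc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two fields, matched pixel by pixel.

    1 is total positive linear correlation, -1 total negative, 0 none.
    Raises on shape mismatch or zero variance in either field.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"field shapes differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 elements")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        raise ValueError("zero-variance field: correlation undefined")
    return float(np.clip((da @ db) / math.sqrt(va * vb), -1.0, 1.0))


def log_likelihood_pcc(data: FieldSeries, model: Trajectory, sigma: float) -> float:
    """Spatial likelihood: Gaussian in ``1 - PCC`` per frame.

    Each measured frame is correlated with the model field at the same time;
    perfect agreement gives residual 0, anti-correlation residual 2. Model
    states must already live on the data grid and times.
    """
    if sigma <= 0:
        return -math.inf
    if model.states is None:
        raise ValueError("model trajectory must carry field states")
    if len(model.states) != data.n_frames or not np.allclose(
        model.times, data.times / 24.0, atol=1e-9
    ) and not np.allclose(model.times, data.times, atol=1e-9):
        raise ValueError("model state times do not match data frames")
    total = 0.0
    for grid_obs, state in zip(data.grids, model.states):
        if grid_obs.shape != state.phi_V.shape:
            raise ValueError("model state shape does not match data grid")
        r = 1.0 - pearson_cc(grid_obs, state.phi_V)
        total += -0.5 * (_LOG_2PI + 2.0 * math.log(sigma)) - r * r / (2.0 * sigma**2)
    return float(total)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Adaptive random-walk Metropolis settings.

    ``n_steps`` kept post-burn-in iterations (before thinning); proposal
    scale is adapted only during burn-in so the kept chain is Markovian.
    """

    n_steps: int = 20_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.3
    init_scale: float = 0.2  # initial proposal sd as a fraction of prior sd
    adapt_window: int = 100
    n_init: int = 256  # prior draws scanned for the chain's starting point
    optimize_start: bool = True  # refine the start by a bounded simplex search
    n_opt_starts: int = 3  # simplex refinements from the top prior draws


@dataclass
class PosteriorSample:
    """MCMC draws with diagnostics.

    ``draws`` is (n_draws, n_params) in the order of ``names``; every draw
    lies inside the prior support by construction of the accept rule.
    """

    names: list[str]
    draws: np.ndarray
    log_posterior: np.ndarray
    acceptance_rate: float
    ess: np.ndarray
    seed: int

    def marginal(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Equal-tail credible interval for one parameter."""
        tail = 100.0 * (1.0 - level) / 2.0
        x = self.marginal(name)
        return (float(np.percentile(x, tail)), float(np.percentile(x, 100.0 - tail)))


def _crude_ess(x: np.ndarray) -> float:
    """Effective sample size from the initial positive autocorrelation sum."""
    n = x.size
    if n < 10 or np.std(x) == 0:
        return float(n)
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    acf /= acf[0]
    s = 0.0
    for k in range(1, min(n, 1000)):
        if acf[k] <= 0.0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def run_mcmc(log_posterior, priors: PriorSpec, config: MCMCConfig) -> PosteriorSample:
    """Sample a posterior with adaptive random-walk Metropolis.

    The chain starts from a prior draw with finite posterior density
    (an unidentifiable-setup error is raised if 1,000 prior draws all have
    density zero). During burn-in the global proposal scale follows a
    Robbins--Monro update toward the target acceptance rate and the
    per-parameter widths track the running chain spread; both are frozen
    afterwards. Fixed ``config.seed`` gives a bit-identical draw matrix.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    ndim = len(priors)

    # Start from the best of a batch of prior draws: still a prior-drawn
    # initial state, but it skips the flat tails of very wide hyperpriors.
    scanned: list[tuple[float, np.ndarray]] = []
    for k in range(max(1000, config.n_init)):
        cand = priors.sample(rng, 1)[0]
        lp = log_posterior(cand)
        if math.isfinite(lp):
            scanned.append((lp, cand))
        if scanned and k + 1 >= config.n_init:
            break
    if not scanned:
        raise RuntimeError(
            "unidentifiable setup: log-posterior is -inf at 1,000 prior draws"
        )
    scanned.sort(key=lambda t: -t[0])
    logp, theta = scanned[0]

    if config.optimize_start:
        # Deterministic simplex refinement toward the posterior mode from
        # the top prior draws (multi-start: a single local search can land
        # in a spurious mode of the hyperparameter surface), so burn-in
        # spends its budget on adaptation rather than on locating a
        # sharply peaked region.
        from scipy.optimize import minimize

        for _, start in scanned[: max(1, config.n_opt_starts)]:
            res = minimize(
                lambda th: -log_posterior(th), start, method="Nelder-Mead",
                options={"maxfev": 400 * ndim, "xatol": 1e-10, "fatol": 1e-10},
            )
            if math.isfinite(res.fun) and -res.fun > logp:
                lp_check = log_posterior(res.x)
                if math.isfinite(lp_check) and lp_check > logp:
                    theta, logp = np.asarray(res.x, dtype=float), lp_check

    # Proposal: scaled Cholesky factor of the running burn-in covariance
    # (cumulative Welford update), seeded from the prior scales. The full
    # covariance matters: chained stages leave strongly correlated
    # posteriors (e.g. necrosis and apoptosis rates trade off through the
    # observed combined decay), where a diagonal proposal mixes poorly.
    # Proposal scales seeded from the start point (the posterior typically
    # lives at a much smaller scale than wide uniform hyperpriors suggest),
    # then adapted: first half of burn-in diagonally, second half with the
    # full running covariance -- chained stages leave strongly correlated
    # posteriors (e.g. necrosis and apoptosis rates trade off through the
    # observed combined decay), where a diagonal proposal mixes poorly.
    # The running statistics restart at the phase switch so the covariance
    # reflects the equilibrated chain, not the initial transient.
    prior_widths = np.array([max(p.std(), 1e-12) for p in priors.priors])
    init_widths = np.maximum(np.abs(theta) * 0.25, 1e-4 * prior_widths)
    chol = np.diag(init_widths)
    scale = config.init_scale
    opt = 2.38 / math.sqrt(ndim)  # classical optimal-scaling factor
    phase_switch = config.burn_in // 2
    n_total = config.burn_in + config.n_steps
    kept = np.empty(((config.n_steps + config.thin - 1) // config.thin, ndim))
    kept_lp = np.empty(kept.shape[0])
    n_accept = 0
    n_accept_window = 0
    run_mean = np.zeros(ndim)
    run_m2 = np.zeros((ndim, ndim))
    n_stat = 0
    k_out = 0

    for it in range(n_total):
        prop = theta + scale * (chol @ rng.standard_normal(ndim))
        lp_prop = log_posterior(prop)
        if math.log(rng.uniform()) < lp_prop - logp:
            theta, logp = prop, lp_prop
            n_accept_window += 1
            if it >= config.burn_in:
                n_accept += 1
        if it < config.burn_in:
            if it == phase_switch:
                run_mean[:] = 0.0
                run_m2[:] = 0.0
                n_stat = 0
            n_stat += 1
            delta = theta - run_mean
            run_mean += delta / n_stat
            run_m2 += np.outer(delta, theta - run_mean)
            if (it + 1) % config.adapt_window == 0:
                rate = n_accept_window / config.adapt_window
                scale *= math.exp(1.0 * (rate - config.target_accept))
                n_accept_window = 0
                if n_stat < 10 * ndim:
                    continue
                cov = run_m2 / n_stat
                diag = np.sqrt(np.maximum(np.diag(cov), 0.0))
                if it < phase_switch:
                    chol = np.diag(np.where(diag > 0, diag, init_widths))
                else:
                    jitter = np.maximum(1e-12 * np.diag(cov), 1e-20)
                    try:
                        cand = np.linalg.cholesky(cov + np.diag(jitter))
                        if np.all(np.diag(cand) > 0):
                            chol = opt * cand
                    except np.linalg.LinAlgError:
                        pass  # keep the previous factor
        else:
            j = it - config.burn_in
            if j % config.thin == 0:
                kept[k_out] = theta
                kept_lp[k_out] = logp
                k_out += 1

    acc = n_accept / config.n_steps
    ess = np.array([_crude_ess(kept[:, d]) for d in range(ndim)])
    return PosteriorSample(
        names=list(priors.names),
        draws=kept,
        log_posterior=kept_lp,
        acceptance_rate=acc,
        ess=ess,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Posterior -> prior propagation
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of fitting a parametric family to posterior draws."""

    prior: Prior
    candidates: dict[str, tuple[Prior, float]]  # family -> (fit, L1-CDF distance)


def _cdf_l1_to_empirical(dist, samples: np.ndarray) -> float:
    """L1 distance between a fitted CDF and the sample empirical CDF.

    Dense-grid trapezoid over the sample range (padded by 4 sd); adequate
    for family selection, where only the ordering of distances matters.
    """
    lo = samples.min() - 4.0 * samples.std()
    hi = samples.max() + 4.0 * samples.std()
    grid = np.linspace(lo, hi, 2001)
    f_fit = dist.cdf(grid)
    srt = np.sort(samples)
    f_emp = np.searchsorted(srt, grid, side="right") / srt.size
    return float(np.trapezoid(np.abs(f_fit - f_emp), grid))


def fit_posterior_distribution(samples: np.ndarray, name: str = "theta") -> FitResult:
    """Fit Normal and LogNormal candidates to draws; keep the closer one.

    The Normal is moment-matched; the LogNormal matches the moments of the
    log (skipped when any draw is nonpositive). Selection minimizes the L1
    distance between fitted and empirical CDFs. Raises on fewer than 100
    draws or near-degenerate spread.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 100:
        raise ValueError(f"need >= 100 samples to fit, got {samples.size}")
    mu, sd = float(samples.mean()), float(samples.std(ddof=1))
    if sd <= 1e-12 * max(abs(mu), 1.0):
        raise ValueError("degenerate (near-constant) sample set")
    candidates: dict[str, tuple[Prior, float]] = {}
    d_norm = _cdf_l1_to_empirical(stats.norm(mu, sd), samples)
    candidates["normal"] = (Prior(name, "normal", (mu, sd)), d_norm)
    if samples.min() > 0:
        lmu = float(np.log(samples).mean())
        lsd = float(np.log(samples).std(ddof=1))
        if lsd > 1e-12:
            d_ln = _cdf_l1_to_empirical(
                stats.lognorm(s=lsd, scale=math.exp(lmu)), samples
            )
            candidates["lognormal"] = (Prior(name, "lognormal", (lmu, lsd)), d_ln)
    best = min(candidates, key=lambda k: candidates[k][1])
    return FitResult(prior=candidates[best][0], candidates=candidates)


def posterior_to_prior(
    posterior: PosteriorSample,
    original: PriorSpec,
    kde: bool = False,
) -> PriorSpec:
    """Turn a stage posterior into the next stage's prior spec.

    Each calibrated parameter's marginal is replaced by its fitted
    parametric distribution truncated to the original support (or by a KDE
    empirical prior when ``kde=True``); parameters absent from the posterior
    keep their configured priors.
    """
    updates: dict[str, Prior] = {}
    for name in posterior.names:
        if name not in original.names:
            continue
        orig = original[name]
        draws = posterior.marginal(name)
        if kde:
            updates[name] = Prior(
                name, "empirical", samples=draws, bounds=orig.bounds,
                source=f"posterior(seed={posterior.seed})",
            )
            continue
        fit = fit_posterior_distribution(draws, name=name)
        p = fit.prior
        updates[name] = Prior(
            name, p.family, p.params, bounds=orig.bounds,
            source=f"posterior(seed={posterior.seed})",
        )
    return original.replace(**updates)


# ---------------------------------------------------------------------------
# Posterior predictive
# ---------------------------------------------------------------------------

@dataclass
class PredictiveBand:
    """Pointwise posterior-predictive mean and 95% equal-tail envelope."""

    times: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_draws: int
    samples: np.ndarray | None = None  # optional (n_draws, n_times) retained draws

    def __post_init__(self) -> None:
        if np.any(self.lower > self.mean + 1e-12) or np.any(self.mean > self.upper + 1e-12):
            raise ValueError("band ordering violated: need lower <= mean <= upper")


def posterior_predictive(
    posterior: PosteriorSample,
    simulator,
    times,
    n_draws: int = 200_000,
    seed: int = 0,
    vectorized: bool = False,
    keep_samples: bool = True,
    max_failure_frac: float = 0.001,
) -> PredictiveBand:
    """Push posterior draws through a simulator and summarize pointwise.

    ``simulator(theta) -> values at `times``` (or, with ``vectorized=True``,
    a (n, n_params) matrix to a (n, n_times) matrix). Parameter vectors are
    resampled from the posterior with replacement; the band is the pointwise
    mean with 2.5/97.5 percentile bounds. Aborts if more than
    ``max_failure_frac`` of the draws fail to simulate.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.Generator(np.random.PCG64(seed))
    idx = rng.integers(0, posterior.n_draws, size=n_draws)
    thetas = posterior.draws[idx]
    if vectorized:
        out = np.asarray(simulator(thetas), dtype=float)
        if out.shape != (n_draws, times.size):
            raise ValueError(f"vectorized simulator returned shape {out.shape}")
        ok = np.isfinite(out).all(axis=1)
        n_fail = int((~ok).sum())
        out = out[ok]
    else:
        rows = []
        n_fail = 0
        for th in thetas:
            try:
                rows.append(np.asarray(simulator(th), dtype=float))
            except Exception:  # noqa: BLE001 - count and bound failures
                n_fail += 1
        out = np.array(rows)
    if n_fail > max_failure_frac * n_draws:
        raise RuntimeError(
            f"simulator failed on {n_fail}/{n_draws} draws "
            f"(> {max_failure_frac:.1%} allowed)"
        )
    mean = out.mean(axis=0)
    lower = np.percentile(out, 2.5, axis=0)
    upper = np.percentile(out, 97.5, axis=0)
    return PredictiveBand(
        times=times, mean=mean, lower=lower, upper=upper,
        n_draws=n_draws, samples=out if keep_samples else None,
    )
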