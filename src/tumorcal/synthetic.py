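"""Synthetic study data with known ground truth.

Emulates the in-vitro study design so every calibration stage can be run
end to end without external downloads:

* apoptosis arm: 5 seeding densities (5e3--1e5 cells/ml), proliferation
  inhibited (MMC), 10% FBS, daily viability for 7 days, 4 replicates;
* proliferation arm: the same 5 densities untreated at 10% FBS, 21 days;
* necrosis arm: 3 densities x 4 sub-optimal FBS levels (0--7.5%), 7 days;
* mobility arm: one density, 5 FBS levels, 2D fields every 30 min for 12 h.

Viability observations are the deterministic reduced-model trajectory plus
i.i.d. zero-mean Gaussian noise per replicate, floored at zero (with the
flooring recorded per observation). Spatial series evolve a clustered
initial field under mobility-only Cahn--Hilliard transport with optional
pixel noise. Everything is reproducible from a single master seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from tumorcal.data_model import (
    DEFAULT_ANCHOR,
    FieldSeries,
    ScenarioMeta,
    TimeCourseDataset,
    seeding_density_to_volume_fraction,
    write_field_series,
    write_timecourse_csv,
)
from tumorcal.forward_models import (
    Grid,
    PhaseFieldParams,
    PhaseFieldState,
    ReducedParams,
    simulate_exponential_death,
    simulate_logistic_growth,
    simulate_mobility_ch,
    simulate_necrosis_system,
)

__all__ = [
    "SyntheticStudySpec",
    "synth_timecourses",
    "synth_initial_field",
    "synth_field_series",
    "full_study_fixture",
    "DENSITIES",
    "NECROSIS_DENSITIES",
    "FBS_LEVELS",
]

#: Seeding densities of the study design, cells/ml.
DENSITIES: tuple[float, ...] = (5e3, 1e4, 2.5e4, 5e4, 1e5)
#: Densities used in the necrosis (nutrient-deprivation) arm.
NECROSIS_DENSITIES: tuple[float, ...] = (2.5e4, 5e4, 1e5)
#: FBS percentages; phi_sigma = FBS% / 10.
FBS_LEVELS: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0)
#: Sub-optimal FBS levels that activate the necrosis gate.
NECROSIS_FBS: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5)


def _lambda_vn_default() -> dict[float, float]:
    # Necrosis rate per FBS level: strong at zero nutrient, weak near optimal.
    return {0.0: float(np.exp(-2.2)), 2.5: float(np.exp(-4.0)),
            5.0: float(np.exp(-5.0)), 7.5: float(np.exp(-5.5))}


@dataclass
class SyntheticStudySpec:
    """Ground-truth parameters and design of a synthetic study.

    Default truths sit centrally in the parameter ranges typical of liver
    carcinoma monolayers: apoptosis ~0.09/day, proliferation ~0.5/day,
    carrying capacity 0.14, necrosis rates spanning e^-5.5 to e^-2.2 per day
    across nutrient levels, interface length 30 um and mobility 200 um/day.
    Noise is scenario-level: each viability observation gets Gaussian noise
    with sd = ``noise_frac`` of that scenario's day-0 signal.
    """

    lambda_apop: float = 0.09
    lambda_prol: float = 0.5
    K: float = 0.14
    lambda_VN: dict[float, float] = field(default_factory=_lambda_vn_default)
    M_T: float = 200.0
    E_bar_T: float = 0.65
    epsilon_T: float = 30.0
    noise_frac: float = 0.05
    field_noise_sd: float = 0.01
    n_replicates: int = 4
    apoptosis_days: int = 7
    proliferation_days: int = 21
    necrosis_days: int = 7
    master_seed: int = 20180928

    def __post_init__(self) -> None:
        if self.noise_frac < 0 or self.field_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def synth_timecourses(
    model: str,
    params: ReducedParams,
    meta: ScenarioMeta,
    sigma_noise: float,
    n_replicates: int,
    seed: int,
    dt: float = 0.01,
) -> TimeCourseDataset:
    """Noisy replicate viability time courses from a reduced model.

    ``model`` is one of ``"exponential"``, ``"logistic"``, ``"necrosis"``.
    The deterministic trajectory is evaluated at the design days (0, 1, ...
    duration) and each replicate observation gets independent zero-mean
    Gaussian noise of sd ``sigma_noise``; negative draws are floored at 0
    and flagged in ``dataset.floored``.
    """
    times = np.arange(0.0, meta.duration + 0.5 * meta.sampling_interval,
                      meta.sampling_interval)
    if model == "exponential":
        traj = simulate_exponential_death(params, times, dt=dt)
    elif model == "logistic":
        traj = simulate_logistic_growth(params, times, dt=dt)
    elif model == "necrosis":
        traj = simulate_necrosis_system(params, times, dt=dt)
    else:
        raise ValueError(f"unknown model variant {model!r}")
    clean = traj.phi_V
    rng = np.random.Generator(np.random.PCG64(seed))
    noisy = clean[:, None] + sigma_noise * rng.standard_normal((times.size, n_replicates))
    floored = noisy < 0.0
    noisy = np.maximum(noisy, 0.0)
    return TimeCourseDataset(meta=meta, times=times, values=noisy, floored=floored)


def synth_initial_field(
    grid: Grid,
    n_clusters: int,
    cluster_radius: float,
    peak_fraction: float,
    interface_width: float,
    seed: int,
) -> PhaseFieldState:
    """Clustered initial tumor field: smoothed discs at random positions.

    Each cluster is a radially symmetric bump with a tanh interface profile
    of the given width (micrometers), height ``peak_fraction``; overlapping
    bumps are clipped at 1. ``phi_N`` starts at zero. Mirrors the mobility
    experiments, whose initial condition is clusters of viable tumor cells
    already segregated by adhesion.
    """
    if not (0.0 < peak_fraction <= 1.0):
        raise ValueError("peak_fraction must be in (0, 1]")
    if cluster_radius <= 0 or interface_width <= 0:
        raise ValueError("cluster_radius and interface_width must be > 0")
    rng = np.random.Generator(np.random.PCG64(seed))
    h = grid.spacing
    y = (np.arange(grid.ny) + 0.5) * h
    x = (np.arange(grid.nx) + 0.5) * h
    xx, yy = np.meshgrid(x, y)
    phi = np.zeros(grid.shape)
    width_x, width_y = grid.extent
    margin = cluster_radius + 2.0 * interface_width
    if n_clusters > 0 and (2 * margin >= width_x or 2 * margin >= width_y):
        raise ValueError("clusters do not fit in the domain")
    for _ in range(n_clusters):
        cx = rng.uniform(margin, width_x - margin)
        cy = rng.uniform(margin, width_y - margin)
        r = np.hypot(xx - cx, yy - cy)
        phi += 0.5 * peak_fraction * (1.0 - np.tanh((r - cluster_radius) / interface_width))
    np.clip(phi, 0.0, 1.0, out=phi)
    return PhaseFieldState(phi_T=phi, phi_N=np.zeros(grid.shape), time=0.0)


def synth_field_series(
    params: PhaseFieldParams,
    initial: PhaseFieldState,
    grid: Grid,
    seed: int,
    duration_hours: float = 12.0,
    interval_hours: float = 0.5,
    observation_noise_sd: float = 0.0,
    dt: float = 0.005,
) -> FieldSeries:
    """Evolve a field under mobility-only CH transport and observe it.

    Samples ``duration/interval + 1`` frames (25 for the default 12 h at 30
    min), optionally adds pixelwise Gaussian noise, and clamps to [0, 1].
    Frame times are reported in hours; the solver works in days.
    """
    times_days = np.arange(0.0, duration_hours + 0.5 * interval_hours, interval_hours) / 24.0
    # clipped overlapping clusters give flat-topped initial data; allow the
    # usual few-percent CH interface overshoot before the diagnostic trips
    traj = simulate_mobility_ch(params, initial, times_days, grid, dt=dt,
                                bound_tol=0.05)
    grids = np.stack([s.phi_T for s in traj.states])
    if observation_noise_sd > 0:
        rng = np.random.Generator(np.random.PCG64(seed))
        grids = grids + observation_noise_sd * rng.standard_normal(grids.shape)
    return FieldSeries(times=times_days * 24.0, grids=grids, pixel_size=grid.spacing)


# ---------------------------------------------------------------------------
# Full study fixture
# ---------------------------------------------------------------------------

def _scenario_seed(master: int, tag: str) -> int:
    """Stable per-scenario seed derived from the master seed (below 2^31)."""
    return (int(master) + zlib.crc32(tag.encode())) % (2**31 - 1)


def scenario_params(spec: SyntheticStudySpec, density: float, fbs: float,
                    treatment: str) -> ReducedParams:
    """Ground-truth reduced parameters for one scenario of the design."""
    phi_v0 = seeding_density_to_volume_fraction(density, DEFAULT_ANCHOR)
    return ReducedParams(
        lambda_prol=0.0 if treatment == "MMC" else spec.lambda_prol,
        lambda_apop=spec.lambda_apop,
        lambda_VN=spec.lambda_VN.get(fbs, 0.0) if fbs < 10.0 else 0.0,
        K=spec.K,
        phi_sigma=fbs / 10.0,
        phi_V0=phi_v0,
    )


def full_study_fixture(
    spec: SyntheticStudySpec,
    out_dir: str | Path,
    field_grid: Grid | None = None,
) -> dict:
    """Write every scenario of the synthetic study to disk; return a manifest.

    Produces 5 apoptosis + 5 proliferation + 12 necrosis time-course CSVs,
    5 mobility TIFF series, and ``manifest.yaml`` recording the ground truth
    and per-scenario seeds. Deterministic given the master seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if field_grid is None:
        # 1.16 mm square montage at reduced resolution for tractable solves
        field_grid = Grid(nx=32, ny=32, spacing=1160.0 / 32)
    manifest: dict = {
        "master_seed": spec.master_seed,
        "truth": {
            "lambda_apop": spec.lambda_apop,
            "lambda_prol": spec.lambda_prol,
            "K": spec.K,
            "lambda_VN": {str(k): v for k, v in spec.lambda_VN.items()},
            "M_T": spec.M_T,
            "E_bar_T": spec.E_bar_T,
            "epsilon_T": spec.epsilon_T,
        },
        "noise_frac": spec.noise_frac,
        "field_noise_sd": spec.field_noise_sd,
        "scenarios": [],
    }

    def emit_timecourse(tag: str, model: str, density: float, fbs: float,
                        treatment: str, duration: int) -> None:
        meta = ScenarioMeta(
            scenario_id=tag, seeding_density=density, fbs_percent=fbs,
            treatment=treatment, duration=float(duration), sampling_interval=1.0,
        )
        params = scenario_params(spec, density, fbs, treatment)
        sigma = spec.noise_frac * params.phi_V0
        seed = _scenario_seed(spec.master_seed, tag)
        ds = synth_timecourses(model, params, meta, sigma, spec.n_replicates, seed)
        path = out_dir / f"{tag}.csv"
        write_timecourse_csv(ds, path)
        manifest["scenarios"].append({
            "id": tag, "kind": model, "file": path.name, "seed": seed,
            "density": density, "fbs": fbs, "treatment": treatment,
            "sigma_noise": sigma, "phi_V0": params.phi_V0,
        })

    for d in DENSITIES:
        emit_timecourse(f"apoptosis_d{int(d)}", "exponential", d, 10.0, "MMC",
                        spec.apoptosis_days)
    for d in DENSITIES:
        emit_timecourse(f"proliferation_d{int(d)}", "logistic", d, 10.0, "none",
                        spec.proliferation_days)
    for fbs in NECROSIS_FBS:
        for d in NECROSIS_DENSITIES:
            emit_timecourse(
                f"necrosis_f{str(fbs).replace('.', 'p')}_d{int(d)}", "necrosis",
                d, fbs, "none", spec.necrosis_days,
            )
    for fbs in FBS_LEVELS:
        tag = f"mobility_f{str(fbs).replace('.', 'p')}"
        seed = _scenario_seed(spec.master_seed, tag)
        pf = PhaseFieldParams(M_T=spec.M_T, E_bar_T=spec.E_bar_T,
                              epsilon_T=spec.epsilon_T)
        initial = synth_initial_field(
            field_grid, n_clusters=4, cluster_radius=120.0, peak_fraction=0.9,
            interface_width=40.0, seed=seed,
        )
        series = synth_field_series(
            pf, initial, field_grid, seed=seed + 1,
            observation_noise_sd=spec.field_noise_sd,
        )
        path = out_dir / f"{tag}.tiff"
        write_field_series(series, path)
        manifest["scenarios"].append({
            "id": tag, "kind": "mobility", "file": path.name, "seed": seed,
            "density": 5e4, "fbs": fbs, "treatment": "none",
            "sigma_noise": spec.field_noise_sd,
        })

    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
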