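"""Forward simulators for the avascular tumor-growth model hierarchy.

The full model tracks tumor (``phi_T``) and necrotic (``phi_N``) volume
fractions on a 2D domain with zero-flux boundaries::

    d(phi_T)/dt = div( Mbar_T(phi) grad mu ) + S_V
    mu          = Psi'(phi_T) - eps_T^2 Lap phi_T
    d(phi_N)/dt = S_N

with a quartic double-well bulk energy ``Psi(phi) = E_T phi^2 (1-phi)^2``,
mobility degraded by the necrotic fraction, and source terms

    S_V = lambda_prol phi_sigma phi_V (1 - phi_T/K) - lambda_apop phi_V
          - lambda_VN H(sigma_VN - phi_sigma) phi_V
    S_N = lambda_VN H(sigma_VN - phi_sigma) phi_V,      phi_V = phi_T - phi_N.

Each calibration stage isolates part of this system:

* exponential death (proliferation chemically inhibited, rich nutrient),
* nutrient-modulated logistic growth (no necrosis),
* the viable/necrotic two-compartment ODE system (spatially homogeneous),
* mobility-only Cahn--Hilliard transport (sources switched off, 12 h scale).

ODEs are integrated with classical fixed-step RK4; every reduced model also
exposes its closed-form solution, which the solvers are tested against. The
PDE uses 2nd-order finite differences and a semi-implicit convex-splitting
scheme in time (contractive part and the ``-eps^2 Lap`` term implicit,
expansive part explicit, mobility lagged one step), which conserves mass
exactly and is unconditionally gradient-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "ReducedParams",
    "PhaseFieldParams",
    "Grid",
    "PhaseFieldState",
    "Trajectory",
    "double_well",
    "double_well_prime",
    "split_contractive_expansive",
    "split_contractive_expansive_prime",
    "degraded_mobility",
    "chemical_potential",
    "total_free_energy",
    "rk4_integrate",
    "simulate_exponential_death",
    "exponential_death_exact",
    "simulate_logistic_growth",
    "logistic_growth_exact",
    "simulate_necrosis_system",
    "necrosis_no_nutrient_exact",
    "simulate_mobility_ch",
    "simulate_full_phase_field",
    "ConvergenceError",
]

#: Nutrient threshold below which viable cells convert to necrotic, in
#: phi_sigma units (1.0 corresponds to the vendor-optimal 10% FBS): every
#: sub-optimal nutrient level activates the necrosis gate.
SIGMA_VN: float = 1.0


class ConvergenceError(RuntimeError):
    """The linear solve inside a PDE step failed its residual tolerance."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReducedParams:
    """Parameters of the reduced (spatially homogeneous) growth models.

    Rates are per day; ``K`` is the dimensionless carrying capacity of the
    well; ``phi_sigma`` the prescribed nutrient volume fraction (FBS%/10).
    """

    lambda_prol: float = 0.0
    lambda_apop: float = 0.0
    lambda_VN: float = 0.0
    K: float = 1.0
    phi_sigma: float = 1.0
    phi_V0: float = 1e-2
    phi_N0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda_prol", "lambda_apop", "lambda_VN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0.0 < self.K <= 1.0):
            raise ValueError(f"K must be in (0, 1], got {self.K}")
        if not (0.0 <= self.phi_sigma <= 1.0):
            raise ValueError(f"phi_sigma must be in [0, 1], got {self.phi_sigma}")
        if not (0.0 < self.phi_V0 < 1.0):
            raise ValueError(f"phi_V0 must be in (0, 1), got {self.phi_V0}")
        if self.phi_N0 < 0 or self.phi_V0 + self.phi_N0 > 1.0:
            raise ValueError("need phi_N0 >= 0 and phi_V0 + phi_N0 <= 1")


@dataclass(frozen=True)
class PhaseFieldParams:
    """Parameters of the phase-field (Cahn--Hilliard) model.

    ``M_T`` is the tumor mobility (nominally micrometers/day), ``E_bar_T``
    the dimensionless energy scale of the double well, ``epsilon_T`` the
    interface interaction length in micrometers. ``sigma_VN`` is the
    necrosis nutrient threshold in phi_sigma units. ``reduced`` supplies the
    source-term rates for the full model.
    """

    M_T: float = 200.0
    E_bar_T: float = 0.65
    epsilon_T: float = 30.0
    sigma_VN: float = SIGMA_VN
    reduced: ReducedParams = field(default_factory=ReducedParams)

    def __post_init__(self) -> None:
        if self.M_T < 0:
            raise ValueError(f"M_T must be >= 0, got {self.M_T}")
        if self.E_bar_T <= 0:
            raise ValueError(f"E_bar_T must be > 0, got {self.E_bar_T}")
        if self.epsilon_T <= 0:
            raise ValueError(f"epsilon_T must be > 0, got {self.epsilon_T}")


@dataclass(frozen=True)
class Grid:
    """Uniform 2D grid: ``nx`` columns, ``ny`` rows, ``spacing`` micrometers.

    Fields are stored row-major, origin top-left, x rightward, y downward;
    pixel centers at ``(i + 1/2) * spacing``.
    """

    nx: int
    ny: int
    spacing: float

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ValueError(f"grid must be at least 4x4, got {self.nx}x{self.ny}")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area(self) -> float:
        return self.spacing**2

    @property
    def extent(self) -> tuple[float, float]:
        return (self.nx * self.spacing, self.ny * self.spacing)


@dataclass
class PhaseFieldState:
    """Coupled fields of the phase-field model at one instant (time in days)."""

    phi_T: np.ndarray
    phi_N: np.ndarray
    time: float = 0.0
    mu: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phi_T = np.asarray(self.phi_T, dtype=float)
        self.phi_N = np.asarray(self.phi_N, dtype=float)
        if self.phi_T.shape != self.phi_N.shape or self.phi_T.ndim != 2:
            raise ValueError("phi_T and phi_N must be 2-D arrays of one shape")

    @property
    def phi_V(self) -> np.ndarray:
        return self.phi_T - self.phi_N

    def validate(self, tol: float = 1e-6) -> None:
        """Raise if fields leave [0, 1] or the ordering phi_N <= phi_T by > tol."""
        if self.phi_T.min() < -tol or self.phi_T.max() > 1.0 + tol:
            raise ValueError(
                f"phi_T out of [0,1] beyond tol={tol}: "
                f"range [{self.phi_T.min():.3e}, {self.phi_T.max():.3e}]"
            )
        if self.phi_N.min() < -tol:
            raise ValueError(f"phi_N < 0 beyond tol={tol}: min {self.phi_N.min():.3e}")
        excess = (self.phi_N - self.phi_T).max()
        if excess > tol:
            raise ValueError(f"phi_N > phi_T by {excess:.3e} (> tol={tol})")

    def copy(self) -> "PhaseFieldState":
        return PhaseFieldState(
            self.phi_T.copy(), self.phi_N.copy(), self.time,
            None if self.mu is None else self.mu.copy(),
        )


@dataclass
class Trajectory:
    """Time-indexed model output.

    For reduced models ``values`` is ``(n_times,)`` or ``(n_times, k)`` with
    ``columns`` naming the k components; for PDE models ``states`` holds one
    :class:`PhaseFieldState` snapshot per output time.
    """

    times: np.ndarray
    values: np.ndarray | None = None
    columns: tuple[str, ...] = ("phi_V",)
    states: list[PhaseFieldState] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)

    def column(self, name: str) -> np.ndarray:
        if self.values is None:
            raise ValueError("trajectory holds states, not scalar columns")
        if self.values.ndim == 1:
            if name != self.columns[0]:
                raise KeyError(name)
            return self.values
        return self.values[:, self.columns.index(name)]

    @property
    def phi_V(self) -> np.ndarray:
        if self.states is not None:
            return np.array([s.phi_V.mean() for s in self.states])
        return self.column("phi_V")


# ---------------------------------------------------------------------------
# Energy primitives
# ---------------------------------------------------------------------------

def double_well(phi, E_bar_T: float):
    """Quartic double-well bulk energy density ``E_T phi^2 (1 - phi)^2``.

    Zero at the pure phases phi = 0 and phi = 1; the energy scale ``E_bar_T``
    sets the barrier height (``E_bar_T / 16`` at phi = 1/2).
    """
    phi = np.asarray(phi, dtype=float)
    return E_bar_T * phi**2 * (1.0 - phi) ** 2


def double_well_prime(phi, E_bar_T: float):
    """Derivative of the double well: ``E_T (2 phi - 6 phi^2 + 4 phi^3)``."""
    phi = np.asarray(phi, dtype=float)
    return E_bar_T * (2.0 * phi - 6.0 * phi**2 + 4.0 * phi**3)


def split_contractive_expansive(phi, E_bar_T: float):
    """Convex (contractive/expansive) splitting ``Psi = Psi_c - Psi_e``.

    ``Psi_c = (3/2) E_T phi^2`` and ``Psi_e = -E_T (phi^4 - 2 phi^3 -
    phi^2/2)``; both are convex on [0, 1], which is what makes the
    semi-implicit scheme unconditionally gradient-stable.
    """
    phi = np.asarray(phi, dtype=float)
    psi_c = 1.5 * E_bar_T * phi**2
    psi_e = -E_bar_T * (phi**4 - 2.0 * phi**3 - 0.5 * phi**2)
    return psi_c, psi_e


def split_contractive_expansive_prime(phi, E_bar_T: float):
    """Derivatives of the splitting: ``Psi_c' = 3 E_T phi`` (linear) and
    ``Psi_e' = E_T (phi + 6 phi^2 - 4 phi^3)``."""
    phi = np.asarray(phi, dtype=float)
    return 3.0 * E_bar_T * phi, E_bar_T * (phi + 6.0 * phi**2 - 4.0 * phi**3)


def degraded_mobility(phi_T, phi_N, M_T: float):
    """Tumor mobility with the necrotic contribution removed.

    Necrotic cells are immotile, so the mobility is ``M_T (1 - phi_N/phi_T)``
    wherever tumor is present and ``M_T`` where ``phi_T = 0`` (the ratio is
    taken as zero there). Result lies in [0, M_T].
    """
    phi_T = np.asarray(phi_T, dtype=float)
    phi_N = np.asarray(phi_N, dtype=float)
    if np.any(phi_N > phi_T + 1e-9):
        raise ValueError("phi_N exceeds phi_T: mobility undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(phi_T == 0.0, 0.0, phi_N / np.where(phi_T == 0.0, 1.0, phi_T))
    return M_T * np.clip(1.0 - ratio, 0.0, 1.0)


def _laplacian_apply(phi: np.ndarray, spacing: float, bc: str = "neumann") -> np.ndarray:
    """5-point Laplacian with mirrored ghosts (zero-flux) or periodic wrap."""
    if bc == "neumann":
        p = np.pad(phi, 1, mode="edge")
    elif bc == "periodic":
        p = np.pad(phi, 1, mode="wrap")
    else:
        raise ValueError(f"unknown bc {bc!r}")
    return (
        p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * phi
    ) / spacing**2


def chemical_potential(
    phi_T: np.ndarray,
    E_bar_T: float,
    epsilon_T: float,
    grid: Grid,
    bc: str = "neumann",
) -> np.ndarray:
    """Chemical potential ``mu = Psi'(phi_T) - eps_T^2 Lap phi_T``."""
    phi_T = np.asarray(phi_T, dtype=float)
    if phi_T.shape != grid.shape:
        raise ValueError(f"field shape {phi_T.shape} != grid shape {grid.shape}")
    return double_well_prime(phi_T, E_bar_T) - epsilon_T**2 * _laplacian_apply(
        phi_T, grid.spacing, bc
    )


def total_free_energy(
    phi_T: np.ndarray, E_bar_T: float, epsilon_T: float, grid: Grid
) -> float:
    """Discrete Ginzburg--Landau free energy.

    ``E = sum[ Psi(phi) + (eps^2/2) |grad phi|^2 ] h^2`` with the gradient
    evaluated on interior faces (one-sided differences), so a uniform field
    contributes bulk energy only. Nonnegative by construction.
    """
    phi_T = np.asarray(phi_T, dtype=float)
    h = grid.spacing
    bulk = float(np.sum(double_well(phi_T, E_bar_T))) * h**2
    # (dphi/h)^2 * h^2 per face = (dphi)^2
    gx = np.diff(phi_T, axis=1)
    gy = np.diff(phi_T, axis=0)
    grad = 0.5 * epsilon_T**2 * (float(np.sum(gx**2)) + float(np.sum(gy**2)))
    return bulk + grad


# ---------------------------------------------------------------------------
# RK4 and the reduced ODE models
# ---------------------------------------------------------------------------

def rk4_integrate(rhs, y0, times, dt: float = 0.01):
    """Classical 4th-order Runge--Kutta at fixed step ``dt`` (days).

    Integrates from ``times[0]`` (the initial-condition time) and records the
    state at every requested time, sub-dividing each output interval into an
    integer number of steps no longer than ``dt``. ``y0`` may be a scalar or
    an array (the state is vectorized elementwise).
    """
    times = np.asarray(times, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    y = np.asarray(y0, dtype=float)
    out = [y.copy()]
    t = times[0]
    for t_next in times[1:]:
        span = t_next - t
        n = max(1, int(math.ceil(span / dt - 1e-12)))
        h = span / n
        for _ in range(n):
            k1 = rhs(t, y)
            k2 = rhs(t + 0.5 * h, y + 0.5 * h * k1)
            k3 = rhs(t + 0.5 * h, y + 0.5 * h * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        t = t_next
        out.append(y.copy())
    return np.array(out)


def exponential_death_exact(params: ReducedParams, times) -> np.ndarray:
    """Closed form of pure exponential death: ``phi_V0 exp(-lambda_apop t)``."""
    times = np.asarray(times, dtype=float)
    return params.phi_V0 * np.exp(-params.lambda_apop * (times - times[0]))


def simulate_exponential_death(
    params: ReducedParams, times, dt: float = 0.01, method: str = "rk4"
) -> Trajectory:
    """Apoptosis-only decay ``d(phi_V)/dt = -lambda_apop phi_V``.

    The model for chemically proliferation-inhibited cells in rich nutrient:
    no growth, no necrosis, only first-order programmed death. ``method``
    selects RK4 integration (default) or the exact exponential.
    """
    times = np.asarray(times, dtype=float)
    if method == "exact":
        vals = exponential_death_exact(params, times)
    elif method == "rk4":
        lam = params.lambda_apop
        vals = rk4_integrate(lambda t, y: -lam * y, params.phi_V0, times, dt)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Trajectory(times=times, values=vals, columns=("phi_V",))


def logistic_growth_exact(params: ReducedParams, times) -> np.ndarray:
    """Closed form of logistic growth with linear death.

    With ``a = lambda_prol * phi_sigma``, ``r = a - lambda_apop`` and
    effective capacity ``K_eff = K (1 - lambda_apop / a)``:

    * ``a = 0``: pure exponential decay at rate ``lambda_apop``;
    * ``r != 0``: ``phi_V(t) = K_eff / (1 + (K_eff/phi_V0 - 1) e^{-rt})``
      (valid for negative ``r`` and ``K_eff`` too);
    * ``r == 0``: the linear terms cancel, leaving algebraic decay
      ``phi_V(t) = phi_V0 / (1 + (a/K) phi_V0 t)``.
    """
    times = np.asarray(times, dtype=float)
    t = times - times[0]
    a = params.lambda_prol * params.phi_sigma
    b = params.lambda_apop
    phi0 = params.phi_V0
    if a == 0.0:
        return phi0 * np.exp(-b * t)
    r = a - b
    if r == 0.0:
        return phi0 / (1.0 + (a / params.K) * phi0 * t)
    k_eff = params.K * (1.0 - b / a)
    return k_eff / (1.0 + (k_eff / phi0 - 1.0) * np.exp(-r * t))


def simulate_logistic_growth(
    params: ReducedParams, times, dt: float = 0.01, method: str = "rk4"
) -> Trajectory:
    """Nutrient-modulated logistic growth with apoptosis.

    ``d(phi_V)/dt = lambda_prol phi_sigma phi_V (1 - phi_V/K)
    - lambda_apop phi_V``; growth is linear in the prescribed nutrient
    fraction and saturates at the carrying capacity ``K``.
    """
    times = np.asarray(times, dtype=float)
    if method == "exact":
        vals = logistic_growth_exact(params, times)
    elif method == "rk4":
        a = params.lambda_prol * params.phi_sigma
        b = params.lambda_apop
        K = params.K
        vals = rk4_integrate(
            lambda t, y: a * y * (1.0 - y / K) - b * y, params.phi_V0, times, dt
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return Trajectory(times=times, values=vals, columns=("phi_V",))


def necrosis_no_nutrient_exact(params: ReducedParams, times) -> np.ndarray:
    """Closed form of the two-compartment system at zero nutrient.

    With ``phi_sigma = 0`` the viable fraction decays linearly at the
    combined rate ``lambda_apop + lambda_VN`` and the necrotic compartment
    accumulates its transfer share. Returns columns (phi_T, phi_N, phi_V).
    """
    times = np.asarray(times, dtype=float)
    t = times - times[0]
    lam = params.lambda_apop + params.lambda_VN
    phi_v0 = params.phi_V0
    phi_v = phi_v0 * np.exp(-lam * t)
    if lam == 0.0:
        phi_n = np.full_like(t, params.phi_N0)
    else:
        phi_n = params.phi_N0 + params.lambda_VN * phi_v0 * (1.0 - np.exp(-lam * t)) / lam
    return np.column_stack([phi_v + phi_n, phi_n, phi_v])


def simulate_necrosis_system(
    params: ReducedParams, times, dt: float = 0.01
) -> Trajectory:
    """Viable/necrotic two-compartment dynamics under fixed nutrient.

    ``d(phi_T)/dt = lambda_prol phi_sigma (phi_T - phi_N)(1 - phi_T/K)
    - lambda_apop (phi_T - phi_N)``;  ``d(phi_N)/dt = lambda_VN (phi_T -
    phi_N)``. The necrosis gate is taken as open (the experiments this stage
    models all run below the 10%-FBS threshold), so the Heaviside factor is
    1 and the necrotic core is monotone non-decreasing. Returns a trajectory
    with columns (phi_T, phi_N, phi_V).
    """
    times = np.asarray(times, dtype=float)
    if params.phi_N0 > params.phi_V0 + params.phi_N0:  # pragma: no cover - impossible
        raise ValueError("phi_N0 exceeds phi_T0")
    a = params.lambda_prol * params.phi_sigma
    b = params.lambda_apop
    v = params.lambda_VN
    K = params.K
    y0 = np.array([params.phi_V0 + params.phi_N0, params.phi_N0])

    def rhs(t, y):
        phi_t, phi_n = y[..., 0], y[..., 1]
        phi_v = phi_t - phi_n
        d_t = a * phi_v * (1.0 - phi_t / K) - b * phi_v
        d_n = v * phi_v
        return np.stack([d_t, d_n], axis=-1)

    ys = rk4_integrate(rhs, y0, times, dt)
    phi_t, phi_n = ys[:, 0], ys[:, 1]
    vals = np.column_stack([phi_t, phi_n, phi_t - phi_n])
    return Trajectory(times=times, values=vals, columns=("phi_T", "phi_N", "phi_V"))


# ---------------------------------------------------------------------------
# Phase-field (Cahn--Hilliard) solver
# ---------------------------------------------------------------------------

def _neighbor_pairs(ny: int, nx: int, bc: str):
    """Index pairs (c, nb) for the faces of a structured grid, each face once."""
    idx = np.arange(ny * nx).reshape(ny, nx)
    pairs = [
        (idx[:, :-1].ravel(), idx[:, 1:].ravel()),  # horizontal faces
        (idx[:-1, :].ravel(), idx[1:, :].ravel()),  # vertical faces
    ]
    if bc == "periodic":
        pairs.append((idx[:, -1].ravel(), idx[:, 0].ravel()))
        pairs.append((idx[-1, :].ravel(), idx[0, :].ravel()))
    elif bc != "neumann":
        raise ValueError(f"unknown bc {bc!r}")
    left = np.concatenate([p[0] for p in pairs])
    right = np.concatenate([p[1] for p in pairs])
    return left, right


def _laplacian_matrix(grid: Grid, bc: str = "neumann") -> sp.csr_matrix:
    """Sparse 5-point Laplacian with zero-flux (or periodic) boundaries."""
    return _weighted_divergence_matrix(grid, np.ones(grid.n_cells), bc)


def _weighted_divergence_matrix(
    grid: Grid, cell_weights: np.ndarray, bc: str = "neumann"
) -> sp.csr_matrix:
    """Operator ``phi -> div(w grad phi)`` with face weights averaged from cells.

    Assembled face by face so the row sums vanish identically: the operator
    annihilates constants and its adjoint annihilates constants, which is
    what makes the CH update conserve mass to machine precision.
    """
    n = grid.n_cells
    w = np.asarray(cell_weights, dtype=float).ravel()
    left, right = _neighbor_pairs(grid.ny, grid.nx, bc)
    w_face = 0.5 * (w[left] + w[right]) / grid.spacing**2
    rows = np.concatenate([left, right, left, right])
    cols = np.concatenate([right, left, left, right])
    vals = np.concatenate([w_face, w_face, -w_face, -w_face])
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


class _CHStepper:
    """Semi-implicit convex-splitting stepper for CH transport of phi_T.

    Per step, with mobility lagged from the previous state:

        (I - dt D_M (3 E_T I - eps^2 L)) phi^{n+1}
            = phi^n - dt D_M Psi_e'(phi^n)

    where ``D_M = div(Mbar grad .)`` and ``L`` is the Laplacian, both with
    zero-flux boundaries. ``Psi_c' = 3 E_T phi`` is linear, so the implicit
    part is a single sparse solve. The factorization is cached and reused
    while the mobility field is unchanged (e.g. when no necrosis is present
    and the mobility is uniformly ``M_T``).
    """

    def __init__(
        self,
        params: PhaseFieldParams,
        grid: Grid,
        dt: float,
        bc: str = "neumann",
        residual_tol: float = 1e-8,
    ):
        self.params = params
        self.grid = grid
        self.dt = dt
        self.bc = bc
        self.residual_tol = residual_tol
        self._lap = _laplacian_matrix(grid, bc)
        self._identity = sp.identity(grid.n_cells, format="csr")
        self._cached_mob_key: bytes | None = None
        self._cached = None

    def _operator(self, mobility: np.ndarray):
        key = mobility.tobytes()
        if key != self._cached_mob_key:
            d_m = _weighted_divergence_matrix(self.grid, mobility, self.bc)
            inner = 3.0 * self.params.E_bar_T * self._identity - (
                self.params.epsilon_T**2
            ) * self._lap
            a_mat = (self._identity - self.dt * (d_m @ inner)).tocsc()
            self._cached = (spla.splu(a_mat), a_mat, d_m)
            self._cached_mob_key = key
        return self._cached

    def step(self, phi_T: np.ndarray, phi_N: np.ndarray) -> np.ndarray:
        # evaluate the mobility on clamped copies: the scheme has no maximum
        # principle, and interface undershoot (phi_T slightly < 0) must not
        # trip the strict phi_N <= phi_T contract of degraded_mobility
        phi_t_c = np.clip(phi_T, 0.0, 1.0)
        phi_n_c = np.minimum(np.clip(phi_N, 0.0, 1.0), phi_t_c)
        mobility = degraded_mobility(phi_t_c, phi_n_c, self.params.M_T).ravel()
        if self.params.M_T == 0.0 or not mobility.any():
            return phi_T
        lu, a_mat, d_m = self._operator(mobility)
        _, psi_e_prime = split_contractive_expansive_prime(
            phi_T.ravel(), self.params.E_bar_T
        )
        rhs = phi_T.ravel() - self.dt * (d_m @ psi_e_prime)
        sol = lu.solve(rhs)
        res = np.linalg.norm(a_mat @ sol - rhs)
        scale = max(np.linalg.norm(rhs), 1.0)
        if not np.isfinite(sol).all() or res > self.residual_tol * scale:
            raise ConvergenceError(
                f"CH linear solve residual {res:.3e} exceeds tolerance "
                f"{self.residual_tol:.1e} (dt={self.dt}, grid={self.grid.shape})"
            )
        return sol.reshape(self.grid.shape)


def _output_times_to_steps(times: np.ndarray, dt: float):
    """Split each output interval into an integer number of equal steps."""
    plan = []
    for t0, t1 in zip(times[:-1], times[1:]):
        span = t1 - t0
        n = max(1, int(math.ceil(span / dt - 1e-12)))
        plan.append((n, span / n))
    return plan


def simulate_mobility_ch(
    params: PhaseFieldParams,
    initial: PhaseFieldState,
    times,
    grid: Grid,
    dt: float = 0.005,
    bc: str = "neumann",
    bound_tol: float = 1e-2,
) -> Trajectory:
    """Mobility-only Cahn--Hilliard transport (all sources switched off).

    Models the 12-hour mobility experiments, during which proliferation,
    apoptosis and necrosis are negligible: ``d(phi_T)/dt = div(Mbar_T grad
    mu)`` with ``mu = Psi'(phi_T) - eps_T^2 Lap phi_T`` and zero-flux
    boundaries. ``phi_N`` is frozen. Mass is conserved to machine precision
    and the discrete free energy is non-increasing step to step.

    ``bound_tol`` is a diagnostic guard: the scheme does not enforce a
    maximum principle, so small interface under/overshoots are tolerated,
    but excursions beyond it abort the run.
    """
    times = np.asarray(times, dtype=float)
    if initial.phi_T.shape != grid.shape:
        raise ValueError("initial state does not match grid shape")
    stepper = _CHStepper(params, grid, dt=dt, bc=bc)
    phi_T = initial.phi_T.copy()
    phi_N = initial.phi_N.copy()
    states = [
        PhaseFieldState(
            phi_T.copy(), phi_N.copy(), times[0],
            chemical_potential(phi_T, params.E_bar_T, params.epsilon_T, grid, bc),
        )
    ]
    t = times[0]
    for (n, h), t_next in zip(_output_times_to_steps(times, dt), times[1:]):
        sub = _CHStepper(params, grid, dt=h, bc=bc) if abs(h - dt) > 1e-12 else stepper
        for _ in range(n):
            phi_T = sub.step(phi_T, phi_N)
        t = t_next
        state = PhaseFieldState(
            phi_T.copy(), phi_N.copy(), t,
            chemical_potential(phi_T, params.E_bar_T, params.epsilon_T, grid, bc),
        )
        state.validate(tol=bound_tol)
        states.append(state)
    return Trajectory(times=times, states=states)


def simulate_full_phase_field(
    params: PhaseFieldParams,
    initial: PhaseFieldState,
    phi_sigma: float,
    times,
    grid: Grid,
    dt: float = 0.005,
    bc: str = "neumann",
    bound_tol: float = 1e-2,
    ode_substeps: int = 1,
) -> Trajectory:
    """Full coupled phase-field model: CH transport plus growth/death sources.

    Operator (Lie) splitting per step: first the semi-implicit CH transport
    substep of :func:`simulate_mobility_ch`, then a pointwise RK4 reaction
    substep for the sources

        S_V = lambda_prol phi_sigma phi_V (1 - phi_T/K) - lambda_apop phi_V
              - lambda_VN H(sigma_VN - phi_sigma) phi_V
        S_N = lambda_VN H(sigma_VN - phi_sigma) phi_V.

    The Heaviside gate is exact; ``phi_sigma`` is constant per scenario, so
    it never switches mid-run. For a spatially uniform initial state the
    transport term vanishes and the trajectory matches the reduced
    two-compartment ODE system pointwise.
    """
    times = np.asarray(times, dtype=float)
    if initial.phi_T.shape != grid.shape:
        raise ValueError("initial state does not match grid shape")
    red = params.reduced
    # necrosis activates only on a strict nutrient deficit: at the optimal
    # level (phi_sigma = sigma_VN) no starvation transfer occurs
    gate = 1.0 if params.sigma_VN - phi_sigma > 0.0 else 0.0
    a = red.lambda_prol * phi_sigma
    b = red.lambda_apop
    v = red.lambda_VN * gate
    K = red.K

    def reaction_rhs(t, y):
        phi_t, phi_n = y[0], y[1]
        phi_v = phi_t - phi_n
        d_t = a * phi_v * (1.0 - phi_t / K) - b * phi_v
        d_n = v * phi_v
        return np.stack([d_t, d_n])

    stepper = _CHStepper(params, grid, dt=dt, bc=bc)
    phi_T = initial.phi_T.copy()
    phi_N = initial.phi_N.copy()
    states = [PhaseFieldState(phi_T.copy(), phi_N.copy(), times[0])]
    t = times[0]
    for (n, h), t_next in zip(_output_times_to_steps(times, dt), times[1:]):
        sub = _CHStepper(params, grid, dt=h, bc=bc) if abs(h - dt) > 1e-12 else stepper
        for _ in range(n):
            phi_T = sub.step(phi_T, phi_N)
            y = rk4_integrate(
                reaction_rhs,
                np.stack([phi_T, phi_N]),
                np.array([0.0, h]),
                dt=h / ode_substeps,
            )[-1]
            phi_T, phi_N = y[0], y[1]
        t = t_next
        state = PhaseFieldState(
            phi_T.copy(), phi_N.copy(), t,
            chemical_potential(phi_T, params.E_bar_T, params.epsilon_T, grid, bc),
        )
        state.validate(tol=bound_tol)
        states.append(state)
    return Trajectory(times=times, states=states)
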