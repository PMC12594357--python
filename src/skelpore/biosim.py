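"""Microbial mineralization of organic matter on the pore graph.

Five carbon pools live on every graph node: microbial biomass (MB, b1),
dissolved organic matter (DOM, b2), soil organic matter (SOM, b3), fresh
organic matter (FOM, b4) and respired CO2 (b5), all in micrograms of
carbon.  Each time step applies an operator splitting: first the local
transformation (Monod growth on DOM, mortality split between DOM and SOM,
respiration to CO2, first-order SOM/FOM hydrolysis), then diffusion of DOM
between adjacent pores, driven by the per-arc exchange volume

    theta_ij = alpha * Dc * s_ij * dt / d_ij

with s_ij the contact surface, d_ij the centroid distance and alpha the
diffusive overall conductance that corrects the Fick flow between regions
(a constant, calibrated in :mod:`skelpore.calibrate`).  Diffusion is solved
either backward Euler (conjugate gradient on the symmetric
positive-definite system ``(diag(v) + L) c' = v c``) or forward Euler with
an explicit stability guard.

Unit regime: biological rates in 1/day, the time step ``dt`` in seconds
(converted internally, 1 day = 86400 s), diffusion coefficient in
voxel^2/day, volumes in voxel^3, masses in micrograms C, concentrations in
micrograms C per voxel^3.  Both substeps conserve total carbon: the
transformation terms cancel pairwise and the diffusion operator has zero
column sums (implicit conservation holds to the linear-solver tolerance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import csr_matrix, diags
from scipy.sparse.linalg import cg

from skelpore.poregraph import PoreGraph

__all__ = [
    "BioParams",
    "BioState",
    "SimResult",
    "transform_step",
    "theta",
    "arc_thetas",
    "diffusion_step_implicit",
    "diffusion_step_explicit",
    "simulate",
    "ode0d",
    "place_initial_biomass",
    "uniform_dom",
    "dc_voxel2_per_day",
]

SECONDS_PER_DAY = 86400.0

POOLS = ("MB", "DOM", "SOM", "FOM", "CO2")


def dc_voxel2_per_day(dc_cm2_per_s: float, resolution_um: float) -> float:
    """Convert a molecular diffusion coefficient from cm^2/s to voxel^2/day.

    E.g. DOM in water, 6.73e-6 cm^2/s, at 24 um resolution gives about
    1.0e5 voxel^2/day.
    """
    um2_per_s = dc_cm2_per_s * 1e8
    return um2_per_s / resolution_um**2 * SECONDS_PER_DAY


@dataclass(frozen=True)
class BioParams:
    """Biological and transport constants.

    Defaults are the Arthrobacter sp. 9R DOM-degradation set commonly used
    in pore-scale mineralization studies: maximum growth rate 9.6/day,
    respiration 0.2/day, mortality 0.5/day, 55% of dead biomass recycled to
    DOM, SOM mineralization 0.001/day, no FOM hydrolysis.  ``k_dom`` (the
    Monod half-saturation constant) is a DOM *concentration* and must be
    supplied in the mass/volume units of the scenario (ugC per voxel^3
    internally).  ``dc`` is in voxel^2/day, ``dt`` in seconds, ``alpha`` in
    (0, 1].
    """

    rho: float = 0.2  # respiration rate, 1/day
    mu: float = 0.5  # mortality rate, 1/day
    v_dom: float = 9.6  # maximum growth rate, 1/day
    k_dom: float = 1e-3  # half-saturation DOM concentration, ugC/voxel^3
    beta: float = 0.55  # fraction of dead biomass returning to DOM
    v_som: float = 0.001  # SOM mineralization rate, 1/day
    v_fom: float = 0.0  # FOM hydrolysis rate, 1/day
    dc: float = 1e5  # DOM diffusion coefficient, voxel^2/day
    alpha: float = 0.35  # diffusive overall conductance
    dt: float = 30.0  # time step, seconds
    cg_rtol: float = 1e-12
    cg_maxiter_factor: int = 10

    def __post_init__(self) -> None:
        for name in ("rho", "mu", "v_dom", "k_dom", "v_som", "v_fom", "dc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def dt_days(self) -> float:
        return self.dt / SECONDS_PER_DAY


@dataclass
class BioState:
    """Per-node carbon masses (ugC): rows of ``b`` are MB, DOM, SOM, FOM, CO2."""

    b: np.ndarray  # (5, n)
    volumes: np.ndarray  # (n,) voxel^3

    def __post_init__(self) -> None:
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        self.volumes = np.asarray(self.volumes, dtype=float).reshape(-1)
        if self.b.shape != (5, self.volumes.size):
            raise ValueError(f"b must be (5, {self.volumes.size}), got {self.b.shape}")
        if (self.volumes <= 0).any():
            raise ValueError("all node volumes must be positive")

    @classmethod
    def zeros(cls, volumes: np.ndarray) -> "BioState":
        v = np.asarray(volumes, dtype=float).reshape(-1)
        return cls(b=np.zeros((5, v.size)), volumes=v)

    @property
    def n_nodes(self) -> int:
        return self.volumes.size

    @property
    def concentrations(self) -> np.ndarray:
        """DOM concentration c = b2 / v per node."""
        return self.b[1] / self.volumes

    def totals(self) -> np.ndarray:
        return self.b.sum(axis=1)

    @property
    def total_carbon(self) -> float:
        return float(self.b.sum())

    def copy(self) -> "BioState":
        return BioState(b=self.b.copy(), volumes=self.volumes)


@dataclass(frozen=True)
class SimResult:
    """Time series of pool totals; times in seconds from simulation start."""

    times: np.ndarray  # (T,)
    totals: np.ndarray  # (T, 5) in POOLS order
    snapshots: dict = field(default_factory=dict)  # time -> (5, n) masses

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.totals, columns=list(POOLS))
        df.insert(0, "time_s", self.times)
        df["total"] = self.totals.sum(axis=1)
        return df

    def percent_of_initial(self) -> pd.DataFrame:
        """Pool totals as percent of the total initial carbon mass."""
        df = self.to_dataframe()
        total0 = df["total"].iloc[0]
        out = df.copy()
        for col in POOLS + ("total",):
            out[col] = 100.0 * df[col] / total0
        return out


def _negative_pool_error(b_new: np.ndarray, b_old: np.ndarray, dt: float) -> None:
    bad = np.argwhere(b_new < 0)
    pool, node = bad[0]
    old = b_old[pool, node]
    new = b_new[pool, node]
    factor = old / (old - new) if old > new else 0.0
    raise ValueError(
        f"transformation step drove pool {POOLS[pool]} negative at node {node} "
        f"({new:.3e} ugC); time step too large, dt must be below {dt * factor:.6g} s"
    )


def transform_step(state: BioState, params: BioParams) -> BioState:
    """One explicit transformation (reaction) step on every node.

    Growth moves mass from DOM to MB at the Monod rate
    ``v_dom * c / (k_dom + c)``; mortality splits MB into DOM (fraction
    beta) and SOM; respiration moves MB to CO2; SOM and FOM hydrolyse to
    DOM.  All fluxes are evaluated at the start-of-step state, and the sum
    of the five pools is invariant to machine precision.
    """
    dt = params.dt_days
    if (params.rho + params.mu) * dt >= 1.0:
        raise ValueError(
            f"(rho + mu) * dt = {(params.rho + params.mu) * dt:.3g} >= 1; "
            f"dt must be below {SECONDS_PER_DAY / (params.rho + params.mu):.6g} s"
        )
    b = state.b
    c = state.concentrations
    growth = params.v_dom * c / (params.k_dom + c) * b[0] * dt
    mort = params.mu * b[0] * dt
    resp = params.rho * b[0] * dt
    hyd_som = params.v_som * b[2] * dt
    hyd_fom = params.v_fom * b[3] * dt
    new = np.empty_like(b)
    new[0] = b[0] - resp - mort + growth
    new[1] = b[1] + params.beta * mort - growth + hyd_som + hyd_fom
    new[2] = b[2] + (1.0 - params.beta) * mort - hyd_som
    new[3] = b[3] - hyd_fom
    new[4] = b[4] + resp
    if (new < 0).any():
        _negative_pool_error(new, b, params.dt)
    return BioState(b=new, volumes=state.volumes)


def theta(arc: tuple[float, float], params: BioParams) -> float:
    """Exchange volume theta_ij = alpha * Dc * s_ij * dt / d_ij of one arc.

    ``arc`` is the pair (contact faces s_ij, centroid distance d_ij).  The
    overall conductance alpha multiplies the Fick flow and is applied
    identically in the implicit and explicit schemes.
    """
    s, d = arc
    if s == 0:
        return 0.0
    if d <= 0:
        raise ValueError(f"arc distance must be positive, got {d}")
    return params.alpha * params.dc * s * params.dt_days / d


def arc_thetas(graph: PoreGraph, params: BioParams) -> np.ndarray:
    """Per-arc exchange volumes for every arc of the graph."""
    if graph.n_arcs == 0:
        return np.empty(0)
    if (graph.distances <= 0).any():
        raise ValueError("arc distances must be positive")
    return params.alpha * params.dc * graph.faces * params.dt_days / graph.distances


def _theta_matrix(graph: PoreGraph, params: BioParams) -> tuple[csr_matrix, np.ndarray]:
    """Symmetric sparse matrix W of exchange volumes and its row sums."""
    n = graph.n_nodes
    th = arc_thetas(graph, params)
    if graph.n_arcs:
        rows = np.concatenate([graph.arcs[:, 0] - 1, graph.arcs[:, 1] - 1])
        cols = np.concatenate([graph.arcs[:, 1] - 1, graph.arcs[:, 0] - 1])
        w = csr_matrix((np.concatenate([th, th]), (rows, cols)), shape=(n, n))
    else:
        w = csr_matrix((n, n))
    return w, np.asarray(w.sum(axis=1)).reshape(-1)


def _implicit_system(graph: PoreGraph, params: BioParams) -> csr_matrix:
    w, rowsum = _theta_matrix(graph, params)
    v = np.asarray(graph.volumes, dtype=float)
    a = diags(v + rowsum) - w
    a = a.tocsr()
    # the system must be symmetric positive definite for conjugate gradient
    assert abs(a - a.T).max() == 0.0
    assert (a.diagonal() > 0).all()
    return a


def _cg_solve(a: csr_matrix, rhs: np.ndarray, x0: np.ndarray, params: BioParams) -> np.ndarray:
    n = rhs.size
    maxiter = max(params.cg_maxiter_factor * n, 50)
    precond = diags(1.0 / a.diagonal())
    x, info = cg(a, rhs, x0=x0, rtol=params.cg_rtol, atol=0.0, maxiter=maxiter, M=precond)
    if info != 0:
        resid = np.linalg.norm(rhs - a @ x)
        raise RuntimeError(
            f"conjugate gradient failed to converge in {maxiter} iterations "
            f"(residual {resid:.3e})"
        )
    # one round of iterative refinement keeps per-step mass drift near
    # machine precision over long step schedules
    r = rhs - a @ x
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm > 0 and np.linalg.norm(r) > 1e-14 * rhs_norm:
        dx, info = cg(a, r, rtol=1e-2, atol=0.0, maxiter=maxiter, M=precond)
        if info == 0:
            x = x + dx
    return x


def diffusion_step_implicit(
    state: BioState,
    graph: PoreGraph,
    params: BioParams,
    _system: csr_matrix | None = None,
) -> BioState:
    """Backward-Euler DOM diffusion step, solved by conjugate gradient.

    Solves ``(diag(v) + L) c' = v c`` with L the theta-weighted graph
    Laplacian; unconditionally stable and obeys the maximum principle (the
    new concentrations stay within the range of the old ones).
    """
    a = _implicit_system(graph, params) if _system is None else _system
    c = state.concentrations
    rhs = state.b[1].copy()  # v * c
    c_new = _cg_solve(a, rhs, c, params)
    new = state.b.copy()
    new[1] = state.volumes * c_new
    return BioState(b=new, volumes=state.volumes)


def explicit_stability_factor(graph: PoreGraph, params: BioParams) -> float:
    """max_i (1/v_i) * sum_j theta_ij; must stay <= 1 for forward Euler."""
    _, rowsum = _theta_matrix(graph, params)
    v = np.asarray(graph.volumes, dtype=float)
    return float((rowsum / v).max()) if len(v) else 0.0


def diffusion_step_explicit(
    state: BioState,
    graph: PoreGraph,
    params: BioParams,
    _w: tuple[csr_matrix, np.ndarray] | None = None,
) -> BioState:
    """Forward-Euler DOM diffusion step.

    ``c_i' = (1 - sum_j theta_ij / v_i) c_i + sum_j theta_ij c_j / v_i``;
    rejected when the stability bound ``sum_j theta_ij <= v_i`` fails
    (negative concentrations would appear).
    """
    w, rowsum = _theta_matrix(graph, params) if _w is None else _w
    v = state.volumes
    factor = (rowsum / v).max() if v.size else 0.0
    if factor > 1.0 + 1e-12:
        raise ValueError(
            f"explicit diffusion unstable: max_i sum_j theta_ij / v_i = {factor:.3g} > 1; "
            f"dt must be below {params.dt / factor:.6g} s"
        )
    c = state.concentrations
    new = state.b.copy()
    new[1] = state.b[1] + (w @ c - rowsum * c)
    return BioState(b=new, volumes=state.volumes)


def simulate(
    graph: PoreGraph,
    init: BioState,
    params: BioParams,
    duration: float,
    scheme: str = "implicit",
    snapshot_times: list[float] | None = None,
) -> SimResult:
    """Alternate transformation and DOM diffusion for ``duration`` seconds.

    Each time step applies :func:`transform_step` then the requested
    diffusion scheme; only DOM diffuses.  Pool totals are recorded at every
    step (including t=0); per-node snapshots at the requested times (rounded
    to the nearest step).
    """
    if scheme not in ("implicit", "explicit"):
        raise ValueError(f"unknown scheme {scheme!r}")
    n_steps = int(np.floor(duration / params.dt + 1e-9))
    if abs(n_steps * params.dt - duration) > 1e-6 * params.dt:
        warnings.warn(
            f"duration {duration} s is not a multiple of dt={params.dt} s; "
            f"truncating to {n_steps} steps",
            stacklevel=2,
        )
    if init.n_nodes != graph.n_nodes:
        raise ValueError("state and graph node counts differ")

    system = _implicit_system(graph, params) if scheme == "implicit" else None
    w = _theta_matrix(graph, params) if scheme == "explicit" else None

    snap_steps = {}
    if snapshot_times:
        for t in snapshot_times:
            snap_steps[int(round(t / params.dt))] = float(t)

    state = init.copy()
    times = np.arange(n_steps + 1) * params.dt
    totals = np.empty((n_steps + 1, 5))
    totals[0] = state.totals()
    snapshots = {}
    if 0 in snap_steps:
        snapshots[snap_steps[0]] = state.b.copy()
    for step in range(1, n_steps + 1):
        state = transform_step(state, params)
        if scheme == "implicit":
            state = diffusion_step_implicit(state, graph, params, _system=system)
        else:
            state = diffusion_step_explicit(state, graph, params, _w=w)
        totals[step] = state.totals()
        if step in snap_steps:
            snapshots[snap_steps[step]] = state.b.copy()
    return SimResult(times=times, totals=totals, snapshots=snapshots)


@njit(cache=False)
def _ode_loop(b0, v, rho, mu, v_dom, k_dom, beta, v_som, v_fom, dt, n_steps, record_every):
    n_rec = n_steps // record_every + 1
    out = np.empty((n_rec, 5))
    b = b0.copy()
    for p in range(5):
        out[0, p] = b[p]
    r = 1
    for s in range(1, n_steps + 1):
        c = b[1] / v
        growth = v_dom * c / (k_dom + c) * b[0] * dt
        mort = mu * b[0] * dt
        resp = rho * b[0] * dt
        hyd_som = v_som * b[2] * dt
        hyd_fom = v_fom * b[3] * dt
        b[0] += growth - mort - resp
        b[1] += beta * mort - growth + hyd_som + hyd_fom
        b[2] += (1.0 - beta) * mort - hyd_som
        b[3] -= hyd_fom
        b[4] += resp
        for p in range(5):
            if b[p] < 0.0:
                return out[:r], s, p
        if s % record_every == 0:
            for p in range(5):
                out[r, p] = b[p]
            r += 1
    return out[:r], 0, -1


def ode0d(
    totals: tuple[float, float, float, float],
    params: BioParams,
    duration: float,
    volume: float = 1.0,
    record_every: int = 1,
) -> SimResult:
    """Non-spatialized (0D) baseline: the transformation update iterated on
    the aggregate masses, with the total pore volume as the single node's
    volume.  ``totals`` is (MB, DOM, SOM, FOM) in ugC; CO2 starts at zero.
    """
    if (params.rho + params.mu) * params.dt_days >= 1.0:
        raise ValueError("(rho + mu) * dt >= 1: time step too large")
    if volume <= 0:
        raise ValueError("volume must be positive")
    n_steps = int(np.floor(duration / params.dt + 1e-9))
    b0 = np.array([totals[0], totals[1], totals[2], totals[3], 0.0], dtype=float)
    out, fail_step, fail_pool = _ode_loop(
        b0,
        float(volume),
        params.rho,
        params.mu,
        params.v_dom,
        params.k_dom,
        params.beta,
        params.v_som,
        params.v_fom,
        params.dt_days,
        n_steps,
        record_every,
    )
    if fail_step:
        raise ValueError(
            f"transformation step drove pool {POOLS[fail_pool]} negative at step "
            f"{fail_step}; time step too large"
        )
    times = np.arange(out.shape[0]) * params.dt * record_every
    return SimResult(times=times, totals=out)


def place_initial_biomass(
    graph: PoreGraph,
    total_mass: float,
    n_spots: int | None = None,
    mode: str = "spots",
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Initial microbial biomass per node (ugC).

    ``spots``: ``n_spots`` distinct nodes sampled with probability
    proportional to node volume, equal mass per spot (per-spot ``weights``
    optional).  ``random``: each spot lands on a uniformly sampled node
    (with replacement).  ``uniform``: mass proportional to node volume,
    i.e. a spatially uniform biomass concentration.
    """
    n = graph.n_nodes
    v = graph.volumes
    rng = np.random.default_rng(seed)
    b1 = np.zeros(n)
    if mode == "uniform":
        return total_mass * v / v.sum()
    if n_spots is None:
        raise ValueError(f"mode {mode!r} requires n_spots")
    if weights is None:
        masses = np.full(n_spots, total_mass / n_spots)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.size != n_spots or (weights < 0).any() or weights.sum() == 0:
            raise ValueError("weights must be n_spots nonnegative values with positive sum")
        masses = total_mass * weights / weights.sum()
    if mode == "spots":
        if n_spots > n:
            raise ValueError(f"cannot place {n_spots} distinct spots on {n} nodes")
        nodes = rng.choice(n, size=n_spots, replace=False, p=v / v.sum())
        np.add.at(b1, nodes, masses)
    elif mode == "random":
        nodes = rng.integers(0, n, size=n_spots)
        np.add.at(b1, nodes, masses)
    else:
        raise ValueError(f"unknown placement mode {mode!r}")
    return b1


def uniform_dom(graph: PoreGraph, total_mass: float) -> np.ndarray:
    """DOM masses giving the same concentration in every pore:
    ``b2_i = total * v_i / V``."""
    v = graph.volumes
    return total_mass * v / v.sum()
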