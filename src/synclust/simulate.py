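"""Overdamped Brownian dynamics of interacting nuclei in the syncytium strip.

The model: ``n`` unit-diameter nuclei move in a corrugated 2D channel of
length L and mean thickness T (nuclear-diameter units) under

* a strong harmonic repulsion when nuclei or walls overlap,
* a weak adhesive well of depth S over the shell ``(1, 1+R)`` that keeps
  touching nuclei stuck together,
* isotropic diffusion with constant D,

integrated by Euler-Maruyama with unit mobility (first-order dynamics — the
nuclei are massively overdamped, so D is the only kinetic scale).

Nuclei enter either all at the start or staged over the first half of the
run, emulating continued cytotrophoblast fusion; entry x-positions are
uniform or, when a fusion-site spread sigma is given, drawn from
``Normal(L/2, sigma^2)`` truncated to the domain (preferential fusion
sites near the domain centre).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from . import _kernels
from .boundary import BoundaryParams, SyncytiumDomain, make_domain
from .clustering import ClusterAssignment, cluster_nuclei
from .potential import PotentialSpec

__all__ = [
    "SimParams",
    "SimState",
    "SimResult",
    "PlacementError",
    "IntegrationError",
    "target_nucleus_count",
    "place_initial_nuclei",
    "step",
    "run_simulation",
    "simulate_free_diffusion",
]

_MAX_DISC_PACKING = np.pi / np.sqrt(12)  # ~0.9069, hexagonal packing bound


class PlacementError(RuntimeError):
    """Rejection placement could not reach the target nucleus count."""


class IntegrationError(RuntimeError):
    """A nucleus position became non-finite during time stepping."""


@dataclass(frozen=True)
class SimParams:
    """Full parameter set of one simulation run (nuclear-diameter units).

    Defaults follow the modelled syncytiotrophoblast cross-section: a strip
    of L = 250 by T = 1.5 diameters holding 140 nuclei (29.4% areal nuclear
    density at term), interaction shell R = 0.05.
    """

    potential: PotentialSpec = field(default_factory=PotentialSpec)
    boundary: BoundaryParams = field(default_factory=BoundaryParams)
    length: float = 250.0
    thickness: float = 1.5
    diffusion: float = 0.2
    fusion_site_sd: Optional[float] = None  # None or 0 => uniform entry x
    n_nuclei: int = 140
    injection_mode: str = "all"  # "all" (at start) or "staged"
    dt: float = 1e-3
    t_end: float = 50.0
    snapshot_interval: float = 10.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.diffusion < 0:
            raise ValueError("diffusion must be non-negative")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.t_end < self.dt:
            raise ValueError("t_end must be at least one time step")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be at least 1")
        if self.fusion_site_sd is not None and self.fusion_site_sd < 0:
            raise ValueError("fusion_site_sd must be non-negative")
        if self.injection_mode not in ("all", "staged"):
            raise ValueError("injection_mode must be 'all' or 'staged'")

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass
class SimState:
    """Instantaneous state: clock, nucleus centres, geometry and RNG."""

    time: float
    positions: np.ndarray  # (n, 2), nuclear diameters
    domain: SyncytiumDomain
    rng: np.random.Generator

    @property
    def n_nuclei(self) -> int:
        return int(self.positions.shape[0])


@dataclass
class SimResult:
    """A finished run: final state plus periodic cluster snapshots."""

    final_state: SimState
    snapshot_times: np.ndarray
    snapshots: List[ClusterAssignment]
    params: SimParams

    def final_clusters(self) -> ClusterAssignment:
        return self.snapshots[-1]


def target_nucleus_count(length: float, thickness: float, packing_fraction: float) -> int:
    """Number of unit discs filling a given area fraction of the mean strip.

    ``round(packing_fraction * L * T / (pi/4))`` — with the strip of
    250 x 1.5 diameters and the 29.4% areal nuclear density measured at
    term this yields 140 nuclei.
    """
    if length <= 0 or thickness <= 0 or packing_fraction < 0:
        raise ValueError("length, thickness must be positive; packing_fraction >= 0")
    if packing_fraction >= _MAX_DISC_PACKING:
        raise ValueError(
            f"packing_fraction {packing_fraction} exceeds the disc packing bound "
            f"{_MAX_DISC_PACKING:.4f}"
        )
    return int(round(packing_fraction * length * thickness / (np.pi / 4.0)))


def _draw_entry_x(params: SimParams, rng: np.random.Generator) -> float:
    """Entry x: uniform, or Normal(L/2, sigma^2) truncated to the channel."""
    lo, hi = 0.5, params.length - 0.5
    sigma = params.fusion_site_sd
    if sigma is None or sigma == 0 or not np.isfinite(sigma):
        return rng.uniform(lo, hi)
    while True:  # truncated-normal resampling; acceptance >= 50% for sane sigma
        x = rng.normal(params.length / 2.0, sigma)
        if lo <= x <= hi:
            return x


def _draw_entry(
    params: SimParams,
    domain: SyncytiumDomain,
    rng: np.random.Generator,
    existing: np.ndarray,
    max_attempts: int = 200,
    require_clear: bool = True,
) -> np.ndarray:
    """One entry position by rejection against wall fit and overlaps.

    When ``require_clear`` is False the last candidate is accepted after
    ``max_attempts`` even if it overlaps (used for staged injection into a
    crowded region; the core repulsion resolves the overlap within a few
    steps)."""
    cand = None
    for _ in range(max_attempts):
        x = _draw_entry_x(params, rng)
        top = float(domain.height_at(x)) - 0.5
        if top <= 0.5:  # channel locally too thin for a nucleus
            continue
        y = rng.uniform(0.5, top)
        cand = np.array([x, y])
        if existing.shape[0] == 0:
            return cand
        d2 = np.sum((existing - cand) ** 2, axis=1)
        if np.min(d2) >= 1.0:
            return cand
    if cand is not None and not require_clear:
        return cand
    raise PlacementError(
        f"could not place a nucleus after {max_attempts} attempts "
        f"(already placed: {existing.shape[0]})"
    )


def place_initial_nuclei(
    params: SimParams,
    domain: SyncytiumDomain,
    rng: np.random.Generator,
    max_attempts_per_nucleus: int = 2000,
) -> SimState:
    """Sequential rejection placement of all nuclei at non-overlapping sites."""
    positions = np.empty((params.n_nuclei, 2))
    placed = 0
    try:
        for placed in range(params.n_nuclei):
            positions[placed] = _draw_entry(
                params, domain, rng, positions[:placed], max_attempts_per_nucleus
            )
    except PlacementError as exc:
        raise PlacementError(
            f"placed only {placed} of {params.n_nuclei} nuclei: {exc}"
        ) from exc
    return SimState(0.0, positions, domain, rng)


def _kernel_args(params: SimParams, domain: SyncytiumDomain):
    spec = params.potential
    if domain.upper_profile is None:
        has_profile = False
        bx0, bdx = 0.0, 1.0
        bc = np.zeros((4, 1))
    else:
        has_profile = True
        bx, bc = domain.upper_profile.spline_coefficients()
        bx0 = float(bx[0])
        bdx = float(bx[1] - bx[0])
        bc = np.ascontiguousarray(bc)
    return (
        params.dt,
        params.diffusion,
        spec.adhesion_strength,
        spec.repulsion_stiffness,
        spec.shell_width,
        params.length,
        params.thickness,
        has_profile,
        bx0,
        bdx,
        bc,
    )


def _advance(state: SimState, params: SimParams, n_steps: int) -> None:
    if n_steps <= 0 or state.n_nuclei == 0:
        state.time += n_steps * params.dt
        return
    args = _kernel_args(params, state.domain)
    bad_step, bad_i = _kernels.advance(state.positions, n_steps, *args, state.rng)
    if bad_step >= 0:
        raise IntegrationError(
            f"nucleus {bad_i} became non-finite at t="
            f"{state.time + (bad_step + 1) * params.dt:.4f} (dt={params.dt}); "
            "reduce dt or force magnitudes"
        )
    state.time += n_steps * params.dt


def step(state: SimState, params: SimParams) -> SimState:
    """Advance the state by a single Euler-Maruyama step (in place)."""
    _advance(state, params, 1)
    return state


def run_simulation(params: SimParams) -> SimResult:
    """Run a full trajectory and record periodic cluster snapshots.

    In ``staged`` mode the nuclei are injected at uniformly spaced arrival
    times over the first half of the run, each at a freshly drawn entry
    position; in ``all`` mode every nucleus is placed before t = 0.  The
    whole trajectory is reproducible bit-for-bit from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    domain = make_domain(params.boundary, params.length, params.thickness, seed=rng)
    n_steps_total = int(round(params.t_end / params.dt))
    snap_every = max(1, int(round(params.snapshot_interval / params.dt)))
    R = params.potential.shell_width

    if params.injection_mode == "all":
        state = place_initial_nuclei(params, domain, rng)
        arrivals: dict[int, int] = {}
    else:
        state = SimState(0.0, np.empty((0, 2)), domain, rng)
        # uniformly spaced arrival times over the first half of the run
        arrival_times = np.linspace(0.0, params.t_end / 2.0, params.n_nuclei, endpoint=False)
        arrivals = {}
        for t_arr in arrival_times:
            s = int(np.floor(t_arr / params.dt))
            arrivals[s] = arrivals.get(s, 0) + 1

    snapshot_times: list[float] = []
    snapshots: list[ClusterAssignment] = []
    event_steps = sorted(
        {0}
        | set(range(snap_every, n_steps_total + 1, snap_every))
        | {n_steps_total}
        | set(arrivals)
    )
    current = 0
    for s in event_steps:
        if s > current:
            _advance(state, params, s - current)
            current = s
        for _ in range(arrivals.get(s, 0)):
            entry = _draw_entry(params, domain, rng, state.positions, require_clear=False)
            state.positions = np.vstack([state.positions, entry])
        if s % snap_every == 0 or s == n_steps_total:
            snapshot_times.append(state.time)
            snapshots.append(cluster_nuclei(state.positions, R))
    return SimResult(state, np.array(snapshot_times), snapshots, params)


def simulate_free_diffusion(
    n_walkers: int, diffusion: float, dt: float, n_steps: int, seed=None
) -> np.ndarray:
    """Displacements of non-interacting walkers started at the origin.

    Runs the same JIT integrator with all forces and walls disabled — the
    calibration path for the free-diffusion limit (per-coordinate
    displacement ~ Normal(0, 2 D t))."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.zeros((n_walkers, 2))
    bad, _ = _kernels.advance(
        pos, n_steps, dt, diffusion, 0.0, 0.0, 0.05, np.inf, np.inf,
        False, 0.0, 1.0, np.zeros((4, 1)), rng,
    )
    assert bad == -1
    return pos
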