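"""Coupled-network integration with the two-phase protocol.

Phase 1 ([0, t_couple)): every neuron runs isolated from seeded
heterogeneous initial conditions.  Phase 2 ([t_couple, t_end]): the network
alternates between (a) integrating all 4N membrane equations with the
current topology snapshot frozen, and (b) updating the position vectors
from the end-of-window potentials and rebuilding the snapshot.  Integration
uses an adaptive Runge-Kutta scheme of Dormand-Prince type (scipy ``RK45``),
restarted at every window boundary because the vector field is
discontinuous there.

The diffusive coupling enters the voltage equation as a current:
``I_i = c_i * sum_j A_ij V_j = c_i * sum_{j ~ i} (V_j - V_i)`` with ``A``
the Laplacian and ``c_i = epsilon / N_eta_i`` -- a consensus controller
that vanishes identically once all potentials agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import stability
from .domains import StructuralNetwork, build_lattice, wrap
from .hh import HHParams, hh_derivative, steady_state
from .plasticity import PlasticityParams, TopologySnapshot, adjacency_from_positions, update_positions

__all__ = [
    "SimulationConfig",
    "SimulationTrace",
    "coupling_input",
    "coupling_currents",
    "run_simulation",
    "degree_series",
]


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run (defaults are the study setup)."""

    n: int = 64
    t_end: float = 3000.0
    t_couple: float = 400.0
    dt_output: float = 0.1
    hh: HHParams = field(default_factory=HHParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    structural: StructuralNetwork | None = None  # lattice built from n if None
    global_l: float = 100.0
    overlap_fraction: float = 0.25
    structural_mask: bool = True
    init_mode: str = "phase"  # "phase": random phases on the spiking orbit
    v_init_low: float = -70.0  # used by init_mode="uniform"
    v_init_high: float = -50.0
    i_ext_jitter: float = 0.1  # relative per-neuron jitter on the drive
    position_jitter: float = 0.1  # initial-position jitter, fraction of domain side
    rtol: float = 1e-6
    atol: float = 1e-8
    method: str = "RK45"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not 0 < self.t_couple <= self.t_end:
            raise ValueError("need 0 < t_couple <= t_end")
        if self.init_mode not in ("phase", "uniform"):
            raise ValueError("init_mode must be 'phase' or 'uniform'")
        if self.structural is not None and self.structural.n != self.n:
            raise ValueError("structural network size does not match n")
        if self.structural is None and self.n > 1:
            # fail fast on impossible lattice layouts
            import math

            if math.isqrt(self.n) ** 2 != self.n:
                raise ValueError(f"lattice layout needs a perfect-square n, got {self.n}")

    def build_structural(self) -> StructuralNetwork:
        if self.structural is not None:
            return self.structural
        if self.n == 1:
            from .domains import Domain

            return StructuralNetwork(
                domains=[Domain(0, (0.0, 0.0), (self.global_l, self.global_l))],
                global_l=self.global_l,
            )
        return build_lattice(self.n, self.global_l, self.overlap_fraction)


@dataclass
class SimulationTrace:
    """Recorded run: states on a uniform grid plus per-window topology."""

    times: np.ndarray  # (T,)
    states: np.ndarray  # (T, N, 4)
    degrees: np.ndarray  # (T, N) int
    snapshots: list[TopologySnapshot]
    lambda2: np.ndarray  # (W,) second-largest Laplacian eigenvalue per window
    positions: np.ndarray  # (W + 1, N, d) positions entering each window
    position_times: np.ndarray  # (W + 1,)
    config: SimulationConfig


def coupling_input(i: int, potentials: np.ndarray, snapshot: TopologySnapshot) -> float:
    """Coupling current into neuron i: c_i * sum_{j ~ i} (V_j - V_i) (uA/cm^2).

    Algebraically c_i * (Laplacian row i) . V, but computed from pairwise
    differences so that identical potentials give exactly zero.
    """
    v = np.asarray(potentials, dtype=float)
    row = snapshot.coupling[i].astype(bool)
    return float(snapshot.strengths[i] * (v[row] - v[i]).sum())


def coupling_currents(potentials: np.ndarray, snapshot: TopologySnapshot) -> np.ndarray:
    """Vector of coupling currents for all neurons at once (difference form)."""
    v = np.asarray(potentials, dtype=float)
    diff = snapshot.coupling * (v[None, :] - v[:, None])
    return snapshot.strengths * diff.sum(axis=1)


def _rhs_factory(n: int, params: HHParams, i_ext: np.ndarray, snapshot: TopologySnapshot | None):
    """Right-hand side of the 4N-dimensional system.

    ``snapshot`` carries the frozen topology, or None for the isolated
    phase.  The per-neuron drive replaces the scalar ``params.i_ext``.
    Coupling uses the pairwise-difference form so the consensus state has
    exactly zero input.
    """
    extra = i_ext - params.i_ext  # hh_derivative adds params.i_ext itself
    if snapshot is not None:
        adj = snapshot.coupling.astype(float)
        strengths = snapshot.strengths

    def rhs(t, y):
        state = y.reshape(n, 4)
        if snapshot is None:
            i_cpl = extra
        else:
            v = state[:, 0]
            i_cpl = extra + strengths * (adj * (v[None, :] - v[:, None])).sum(axis=1)
        return hh_derivative(state, i_cpl, params).ravel()

    return rhs


#: settle window (ms) on the isolated orbit from which random-phase initial
#: states are drawn; covers several spike periods, so uniform times give
#: approximately uniform phases.
_PHASE_WINDOW = (150.0, 200.0)


def _initial_states(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Seeded heterogeneous initial conditions, shape (N, 4).

    Default mode "phase" places every neuron on the isolated spiking orbit
    at an independent random phase: a reference neuron is integrated past
    its transient and sampled at random times.  This keeps the very first
    spikes inside the steady spike envelope (a cold hyperpolarized start
    with steady-state gates fires one anomalously tall spike) while still
    giving the neurons distinct behaviors.  Mode "uniform" instead draws
    V(0) ~ U(v_init_low, v_init_high) with gates at steady state.
    """
    if config.init_mode == "uniform":
        v0 = rng.uniform(config.v_init_low, config.v_init_high, size=config.n)
        n0, m0, h0 = steady_state(v0, config.hh)
        return np.stack([v0, n0, m0, h0], axis=-1)
    from .hh import resting_state

    y_ref = resting_state(config.hh)
    sol = solve_ivp(
        lambda t, y: hh_derivative(y, 0.0, config.hh),
        (0.0, _PHASE_WINDOW[1]),
        y_ref,
        dense_output=True,
        method=config.method,
        rtol=config.rtol,
        atol=config.atol,
    )
    t_samples = rng.uniform(*_PHASE_WINDOW, size=config.n)
    states = sol.sol(t_samples).T.copy()
    states[:, 1:] = np.clip(states[:, 1:], 0.0, 1.0)
    return states


def _clip_gates(y: np.ndarray) -> np.ndarray:
    state = y.reshape(-1, 4)
    state[:, 1:] = np.clip(state[:, 1:], 0.0, 1.0)
    return state.ravel()


def run_simulation(config: SimulationConfig) -> SimulationTrace:
    """Run the full two-phase protocol and return the trace.

    Deterministic for a fixed config and seed: all randomness (initial
    potentials, optional drive jitter, initial position jitter) comes from
    independent streams forked from the single run seed.
    """
    network = config.build_structural()
    n = config.n
    ss = np.random.SeedSequence(config.seed)
    rng_state, rng_pos, _rng_reserved = [np.random.default_rng(s) for s in ss.spawn(3)]

    y0 = _initial_states(config, rng_state).ravel()

    i_ext = np.full(n, config.hh.i_ext)
    if config.i_ext_jitter > 0:
        i_ext *= 1.0 + config.i_ext_jitter * rng_state.uniform(-1.0, 1.0, size=n)

    n_steps = int(round(config.t_end / config.dt_output))
    # rounded grid so samples compare exactly against window boundaries
    times = np.round(np.linspace(0.0, config.t_end, n_steps + 1), 9)
    states = np.empty((times.size, n, 4))
    degrees = np.zeros((times.size, n), dtype=np.int16)

    solver_opts = dict(method=config.method, rtol=config.rtol, atol=config.atol)

    # ---- phase 1: isolated neurons -------------------------------------
    rhs_iso = _rhs_factory(n, config.hh, i_ext, None)
    pre = times <= config.t_couple if config.t_couple == config.t_end else times < config.t_couple
    t_eval1 = times[pre]
    # always request the phase boundary so the handoff state is exact
    want_end = t_eval1.size == 0 or t_eval1[-1] < config.t_couple
    t_req = np.append(t_eval1, config.t_couple) if want_end else t_eval1
    sol = solve_ivp(rhs_iso, (0.0, config.t_couple), y0, t_eval=t_req, **solver_opts)
    if not sol.success:
        raise RuntimeError(f"isolated-phase integration failed: {sol.message}")
    states[: t_eval1.size] = sol.y[:, : t_eval1.size].T.reshape(-1, n, 4)
    y = _clip_gates(sol.y[:, -1].copy())

    # ---- phase 2: evolving coupled network -----------------------------
    centers = network.centers()
    sides = np.array([d.sides for d in network.domains])
    jitter = config.position_jitter * sides * rng_pos.uniform(-0.5, 0.5, size=centers.shape)
    positions = np.array(
        [wrap(centers[i] + jitter[i], network.domains[i]) for i in range(n)]
    )

    snapshots: list[TopologySnapshot] = []
    lambda2: list[float] = []
    pos_hist = [positions.copy()]
    pos_times = [config.t_couple]

    period = config.plasticity.update_period
    # boundaries rounded like the output grid so sample-to-window
    # assignment never loses a grid point to float drift
    if config.t_couple < config.t_end:
        n_windows = int(np.ceil((config.t_end - config.t_couple) / period - 1e-9))
        w_starts = np.round(config.t_couple + np.arange(n_windows) * period, 9)
    else:
        w_starts = np.array([])
    cursor = t_eval1.size
    for k, t_start in enumerate(w_starts):
        t_stop = min(np.round(config.t_couple + (k + 1) * period, 9), config.t_end)
        snap = adjacency_from_positions(
            positions, config.plasticity, network, t_start, t_stop, config.structural_mask
        )
        snapshots.append(snap)
        lam2 = stability.lambda2_max(snap.laplacian) if n >= 2 else 0.0
        lambda2.append(lam2)

        rhs = _rhs_factory(n, config.hh, i_ext, snap)
        sel = (times >= t_start) & (times <= t_stop) if t_start == config.t_couple else (
            (times > t_start) & (times <= t_stop)
        )
        t_eval = times[sel]
        want_end = t_eval.size == 0 or t_eval[-1] < t_stop
        t_req = np.append(t_eval, t_stop) if want_end else t_eval
        sol = solve_ivp(rhs, (t_start, t_stop), y, t_eval=t_req, **solver_opts)
        if not sol.success:
            raise RuntimeError(f"window [{t_start}, {t_stop}] integration failed: {sol.message}")
        if t_eval.size:
            states[cursor : cursor + t_eval.size] = sol.y[:, : t_eval.size].T.reshape(-1, n, 4)
            degrees[cursor : cursor + t_eval.size] = snap.degrees
            cursor += t_eval.size
        y = _clip_gates(sol.y[:, -1].copy())
        if not np.all(np.isfinite(y)):
            raise RuntimeError(f"non-finite state at t = {t_stop}")

        positions = update_positions(positions, y.reshape(n, 4)[:, 0], config.plasticity, network)
        pos_hist.append(positions.copy())
        pos_times.append(t_stop)

    if cursor != times.size:
        raise RuntimeError(
            f"output bookkeeping lost samples: filled {cursor} of {times.size}"
        )
    states[:, :, 1:] = np.clip(states[:, :, 1:], 0.0, 1.0)
    return SimulationTrace(
        times=times,
        states=states,
        degrees=degrees,
        snapshots=snapshots,
        lambda2=np.asarray(lambda2),
        positions=np.asarray(pos_hist),
        position_times=np.asarray(pos_times),
        config=config,
    )


def degree_series(trace: SimulationTrace) -> pd.DataFrame:
    """Node degree k_i(t) on the output grid (0 before coupling starts)."""
    return pd.DataFrame(
        trace.degrees,
        index=pd.Index(trace.times, name="t_ms"),
        columns=[f"neuron_{i}" for i in range(trace.degrees.shape[1])],
    )
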