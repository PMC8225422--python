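"""Per-window exponential-synchronization criterion.

On each window where the functional topology is fixed, synchronization of
the diffusively coupled network is certified by two ingredients:

* the second-largest eigenvalue ``lambda2_max`` of the (negative
  semidefinite) network Laplacian -- strictly negative exactly when the
  snapshot graph is connected;
* negative definiteness of the symmetrized variational matrix
  ``Psi(d) = (Df + d*Gamma)^T G + G (Df + d*Gamma)`` at a reference state
  of the isolated dynamics, where ``Df`` is the 4x4 membrane Jacobian,
  ``Gamma = diag(1, 0, 0, 0)`` selects the voltage as the coupled variable,
  and ``G`` is a positive-definite weight (identity by default).

Exponential synchronization on the window holds when
``lambda2_max <= d_bar < 0`` for some ``d_bar`` no larger than the critical
coupling parameter ``d`` at which Psi loses negative definiteness; the test
is Sylvester's criterion on the leading principal minors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hh import HHParams, NeuronState, hh_jacobian

__all__ = [
    "GAMMA_SELECTOR",
    "StabilityReport",
    "lambda2_max",
    "psi_from_jacobian",
    "psi_matrix",
    "is_negative_definite_sylvester",
    "critical_d",
    "critical_d_from_jacobian",
    "window_report",
]

#: Inner-coupling selector: neurons exchange current through V only.
GAMMA_SELECTOR = np.diag([1.0, 0.0, 0.0, 0.0])


def lambda2_max(laplacian, tol: float = 1e-9) -> float:
    """Second-largest eigenvalue of a graph Laplacian (convention A - D).

    The largest eigenvalue is always 0; the second-largest is 0 iff the
    graph is disconnected (no spanning tree) and strictly negative iff it
    is connected.
    """
    lap = np.asarray(laplacian, dtype=float)
    if lap.ndim != 2 or lap.shape[0] != lap.shape[1]:
        raise ValueError("Laplacian must be square")
    if lap.shape[0] < 2:
        raise ValueError("need at least two nodes for lambda2")
    if not np.allclose(lap, lap.T, atol=tol):
        raise ValueError("Laplacian must be symmetric")
    if not np.allclose(lap.sum(axis=1), 0.0, atol=tol):
        raise ValueError("Laplacian rows must sum to zero")
    eigs = np.linalg.eigvalsh(lap)
    return float(eigs[-2])


def _as_state_array(state) -> np.ndarray:
    if isinstance(state, NeuronState):
        return state.to_array()
    return np.asarray(state, dtype=float)


def psi_from_jacobian(jac: np.ndarray, d: float, g: np.ndarray | None = None) -> np.ndarray:
    """Psi = (J + d*Gamma)^T G + G (J + d*Gamma), symmetric by construction."""
    jac = np.asarray(jac, dtype=float)
    g = np.eye(jac.shape[0]) if g is None else np.asarray(g, dtype=float)
    gamma = np.zeros_like(jac)
    gamma[0, 0] = 1.0
    m = jac + d * gamma
    psi = m.T @ g + g @ m
    return 0.5 * (psi + psi.T)


def psi_matrix(state, d: float, g: np.ndarray | None = None, params: HHParams = HHParams()) -> np.ndarray:
    """Symmetrized variational matrix at a membrane state.

    Since the coupling selector only touches V, the parameter ``d`` enters
    the (1,1) entry alone (as 2d when G = I).
    """
    return psi_from_jacobian(hh_jacobian(_as_state_array(state), params), d, g)


def is_negative_definite_sylvester(matrix) -> bool:
    """Sylvester test: all leading principal minors alternate, (-1)^k det > 0."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10 * max(1.0, np.abs(m).max())):
        raise ValueError("matrix must be symmetric")
    for k in range(1, m.shape[0] + 1):
        minor = np.linalg.det(m[:k, :k])
        if not (-1.0) ** k * minor > 0.0:
            return False
    return True


def critical_d_from_jacobian(
    jac: np.ndarray,
    g: np.ndarray | None = None,
    rtol: float = 1e-6,
    d_limit: float = 1e12,
) -> float | None:
    """sup{d : Psi(jac, d, g) negative definite}, or None if none exists.

    Psi(d) = Psi(0) + 2 d G_11-weighted E11, so negative definiteness is
    monotone in d (lowering d only helps); bisection brackets the boundary.
    Returns None ("not certifiable at this state") when even arbitrarily
    negative d fails -- e.g. when a d-free diagonal block is not negative
    definite.
    """

    def nd(d: float) -> bool:
        return is_negative_definite_sylvester(psi_from_jacobian(jac, d, g))

    lo = -1.0
    hi = None
    while not nd(lo):
        hi = lo  # last failing probe brackets from above
        lo *= 10.0
        if lo < -d_limit:
            return None
    if hi is None:
        hi = 1.0
        while nd(hi):
            hi *= 10.0
            if hi > d_limit:
                return None
    while hi - lo > rtol * max(1.0, abs(lo)):
        mid = 0.5 * (lo + hi)
        if nd(mid):
            lo = mid
        else:
            hi = mid
    return float(lo)


def critical_d(
    state,
    g: np.ndarray | None = None,
    params: HHParams = HHParams(),
    rtol: float = 1e-6,
) -> float | None:
    """Critical coupling parameter at a membrane state (None if uncertifiable)."""
    return critical_d_from_jacobian(hh_jacobian(_as_state_array(state), params), g, rtol=rtol)


@dataclass
class StabilityReport:
    """Synchronization certificate for one fixed-topology window."""

    t_start: float
    t_end: float
    lambda2_max: float
    d_bar: float
    exponential_flag: bool
    critical_d: float | None = None


def window_report(trace, d_bar: float = -1e-3, critical_state=None, g=None) -> list[StabilityReport]:
    """One StabilityReport per topology snapshot of a simulation trace.

    ``exponential_flag`` is True when ``lambda2_max <= d_bar < 0`` (the
    graph is connected and the algebraic connectivity beats the margin).
    If ``critical_state`` is given, the critical d evaluated there is
    attached to every report (the topology does not enter Psi).
    """
    if not d_bar < 0:
        raise ValueError("d_bar must be negative")
    crit = None
    if critical_state is not None:
        crit = critical_d(critical_state, g=g, params=trace.config.hh)
    reports = []
    for snap, lam2 in zip(trace.snapshots, trace.lambda2):
        reports.append(
            StabilityReport(
                t_start=snap.t_start,
                t_end=snap.t_end,
                lambda2_max=float(lam2),
                d_bar=d_bar,
                exponential_flag=bool(lam2 <= d_bar),
                critical_d=crit,
            )
        )
    return reports
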