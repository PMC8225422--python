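"""Single-compartment Hodgkin-Huxley membrane dynamics.

The classic squid-axon model in an absolute-voltage convention: the reversal
potentials (55, -72, -49.4 mV) are the original dimensionless-formulation
values shifted by -60 mV, so the rate functions are evaluated on the shifted
variable ``u = V - v_rest`` with ``v_rest = -60 mV``.  State order throughout
the package is ``(V, n, m, h)``: membrane potential (mV), potassium
activation, sodium activation, sodium inactivation.

All functions are vectorized over a trailing state axis of length 4 (or a
voltage array), so a network of N neurons is just an ``(N, 4)`` array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HHParams",
    "NeuronState",
    "rate_constants",
    "steady_state",
    "resting_state",
    "hh_derivative",
    "hh_jacobian",
]

#: |w| below this, w/(e^w - 1) and its derivative use their limit values
#: (the removable singularities of the alpha_n / alpha_m rate functions).
_W_TOL = 1e-8


@dataclass(frozen=True)
class HHParams:
    """Membrane parameters.

    Conductances in mS/cm^2, potentials in mV, capacitance in uF/cm^2,
    currents in uA/cm^2.  Defaults are the simulation-table values; ``i_ext``
    is the constant external drive that makes an isolated neuron spike
    (the model leaves the injected current I(t) free).
    """

    g_na: float = 120.0
    g_k: float = 36.0
    g_l: float = 0.3
    e_na: float = 55.0
    e_k: float = -72.0
    e_l: float = -49.4
    c_m: float = 1.0
    i_ext: float = 10.0
    v_rest: float = -60.0

    def __post_init__(self) -> None:
        for name in ("g_na", "g_k", "g_l", "c_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass
class NeuronState:
    """One neuron's state; gating variables are open-channel probabilities."""

    v: float
    n: float
    m: float
    h: float

    def to_array(self) -> np.ndarray:
        return np.array([self.v, self.n, self.m, self.h], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "NeuronState":
        v, n, m, h = np.asarray(arr, dtype=float)
        return cls(v, n, m, h)


def _exprel_inv(w: np.ndarray) -> np.ndarray:
    """w / (e^w - 1) with the removable singularity at w = 0 filled in."""
    w = np.asarray(w, dtype=float)
    small = np.abs(w) < _W_TOL
    safe = np.where(small, 1.0, w)
    return np.where(small, 1.0 - w / 2.0, safe / np.expm1(safe))


def _dexprel_inv(w: np.ndarray) -> np.ndarray:
    """d/dw of w / (e^w - 1); limit -1/2 at w = 0."""
    w = np.asarray(w, dtype=float)
    small = np.abs(w) < _W_TOL
    safe = np.where(small, 1.0, w)
    em = np.expm1(safe)
    return np.where(small, -0.5 + w / 6.0, (em - safe * np.exp(safe)) / em**2)


def rate_constants(v, params: HHParams = HHParams()):
    """Voltage-dependent channel rates (1/ms).

    Returns ``(alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h)`` evaluated
    on ``u = v - v_rest`` with the classic forms; the removable singularities
    at u = 10 (alpha_n) and u = 25 (alpha_m) take their limit values 0.1
    and 1.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    u = v - params.v_rest
    alpha_n = 0.1 * _exprel_inv((10.0 - u) / 10.0)
    beta_n = 0.125 * np.exp(-u / 80.0)
    alpha_m = _exprel_inv((25.0 - u) / 10.0)
    beta_m = 4.0 * np.exp(-u / 18.0)
    alpha_h = 0.07 * np.exp(-u / 20.0)
    beta_h = 1.0 / (np.exp((30.0 - u) / 10.0) + 1.0)
    return alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h


def steady_state(v, params: HHParams = HHParams()):
    """Gating steady states ``x_inf = alpha / (alpha + beta)`` at voltage v."""
    an, bn, am, bm, ah, bh = rate_constants(v, params)
    return an / (an + bn), am / (am + bm), ah / (ah + bh)


def resting_state(params: HHParams = HHParams(), v: float | None = None) -> np.ndarray:
    """State vector (V, n, m, h) with gates at steady state for voltage v."""
    v = params.v_rest if v is None else v
    n, m, h = steady_state(v, params)
    return np.array([v, float(n), float(m), float(h)])


def hh_derivative(state, i_coupling=0.0, params: HHParams = HHParams()):
    """Time derivative of the state; ``state`` has shape (..., 4).

    ``i_coupling`` (uA/cm^2, broadcastable over the leading axes) is any
    current injected on top of the constant external drive -- in a network it
    carries the diffusive coupling term.
    """
    state = np.asarray(state, dtype=float)
    v = state[..., 0]
    n = state[..., 1]
    m = state[..., 2]
    h = state[..., 3]
    an, bn, am, bm, ah, bh = rate_constants(v, params)
    i_ion = (
        -params.g_na * m**3 * h * (v - params.e_na)
        - params.g_k * n**4 * (v - params.e_k)
        - params.g_l * (v - params.e_l)
    )
    dv = (i_ion + params.i_ext + np.asarray(i_coupling, dtype=float)) / params.c_m
    dn = an * (1.0 - n) - bn * n
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    return np.stack(np.broadcast_arrays(dv, dn, dm, dh), axis=-1)


def hh_jacobian(state, params: HHParams = HHParams()) -> np.ndarray:
    """Analytic 4x4 Jacobian d(dstate/dt)/d(state) at one state.

    The external and coupling currents are state-independent here, so they
    do not appear.  Used by the stability module to assemble the symmetrized
    variational matrix.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (4,):
        raise ValueError("expected a single state of shape (4,)")
    v, n, m, h = state
    u = v - params.v_rest
    an, bn, am, bm, ah, bh = rate_constants(v, params)

    # d(rate)/dV; alpha_n = 0.1*g(w), w = (10-u)/10, dw/dV = -1/10
    dan = -0.01 * _dexprel_inv((10.0 - u) / 10.0)
    dam = -0.1 * _dexprel_inv((25.0 - u) / 10.0)
    dbn = -0.125 / 80.0 * np.exp(-u / 80.0)
    dbm = -4.0 / 18.0 * np.exp(-u / 18.0)
    dah = -0.07 / 20.0 * np.exp(-u / 20.0)
    dbh = bh**2 * np.exp((30.0 - u) / 10.0) / 10.0

    jac = np.zeros((4, 4))
    jac[0, 0] = -(params.g_na * m**3 * h + params.g_k * n**4 + params.g_l) / params.c_m
    jac[0, 1] = -4.0 * params.g_k * n**3 * (v - params.e_k) / params.c_m
    jac[0, 2] = -3.0 * params.g_na * m**2 * h * (v - params.e_na) / params.c_m
    jac[0, 3] = -params.g_na * m**3 * (v - params.e_na) / params.c_m
    jac[1, 0] = dan * (1.0 - n) - dbn * n
    jac[1, 1] = -(an + bn)
    jac[2, 0] = dam * (1.0 - m) - dbm * m
    jac[2, 2] = -(am + bm)
    jac[3, 0] = dah * (1.0 - h) - dbh * h
    jac[3, 3] = -(ah + bh)
    return jac
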