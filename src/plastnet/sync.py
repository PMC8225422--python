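"""Synchronization diagnostics: mean potential, spread, and the index S(t).

S(t) = -ln sigma(t) with sigma the *population* (divisor N) standard
deviation of the membrane potentials over the network or any subset.
S > 0 exactly when sigma < 1 mV, i.e. when the potentials agree to within
a millivolt.  When sigma underflows (perfectly identical potentials) it is
floored at ``SIGMA_FLOOR`` and the sample is flagged, so tables stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SIGMA_FLOOR", "SyncSeries", "mean_potential", "sync_index", "sync_series", "subset_sync_series"]

SIGMA_FLOOR = 1e-12


@dataclass
class SyncSeries:
    """Per-time synchronization diagnostics for one set of neurons."""

    times: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    s: np.ndarray
    clamped: np.ndarray  # True where sigma underflowed the floor
    members: np.ndarray | None = None


def mean_potential(v) -> float:
    """Average membrane potential of a nonempty set of neurons (mV)."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("mean potential of an empty set is undefined")
    return float(v.mean())


def sync_index(v) -> tuple[float, float]:
    """Population standard deviation and synchronization index of one sample.

    Returns ``(sigma, S)`` with ``sigma = sqrt(mean((V - mu)^2))`` and
    ``S = -ln(max(sigma, SIGMA_FLOOR))``.
    """
    v = np.asarray(v, dtype=float)
    mu = mean_potential(v)
    sigma = float(np.sqrt(np.mean((v - mu) ** 2)))
    return sigma, float(-np.log(max(sigma, SIGMA_FLOOR)))


def sync_series(times, potentials, members=None) -> SyncSeries:
    """Diagnostics along a (T, N) potential array, optionally on a subset."""
    times = np.asarray(times, dtype=float)
    v = np.asarray(potentials, dtype=float)
    if members is not None:
        members = np.asarray(members, dtype=int)
        if members.size == 0:
            raise ValueError("member set must be nonempty")
        v = v[:, members]
    if v.shape[1] == 0:
        raise ValueError("member set must be nonempty")
    mu = v.mean(axis=1)
    sigma = np.sqrt(((v - mu[:, None]) ** 2).mean(axis=1))
    clamped = sigma < SIGMA_FLOOR
    s = -np.log(np.maximum(sigma, SIGMA_FLOOR))
    return SyncSeries(times=times, mu=mu, sigma=sigma, s=s, clamped=clamped, members=members)


def subset_sync_series(trace, members) -> SyncSeries:
    """Sync diagnostics of a simulation trace restricted to ``members``."""
    return sync_series(trace.times, trace.states[:, :, 0], members=members)
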