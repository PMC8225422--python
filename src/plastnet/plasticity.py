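"""The structural-plasticity rule: positions, neighborhoods, and topology.

Each neuron carries a position vector confined to its spatial domain.  The
functional network at any instant is the distance-thresholded graph of
those positions on the global torus (optionally masked by the structural
overlap graph), and the positions themselves move as a function of the
membrane potentials: same-sign potential pairs attract, opposite-sign pairs
repel, with gain ``gamma``.  Per-neuron coupling strength is
``epsilon / N_eta_i`` where ``N_eta_i`` counts neighbors within the
interaction radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domains import StructuralNetwork, wrap

__all__ = [
    "PlasticityParams",
    "TopologySnapshot",
    "periodic_distance",
    "min_image_delta",
    "pairwise_distances",
    "neighborhood",
    "update_positions",
    "adjacency_from_positions",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Parameters of the position-update / adjacency rule.

    gamma : gain of the potential-driven position update (lattice units per
        mV^2 per update); too large a gain scatters neighbors beyond the
        interaction radius and prevents group formation.
    radius : interaction radius R (lattice units) for both the neighborhood
        sets and the 0/1 functional adjacency.
    epsilon : coupling-force scale; neuron i couples with strength
        epsilon / N_eta_i.
    update_period : ms between position updates; the topology is frozen in
        between, which defines the fixed-topology windows used by the
        stability analysis.  The default (0.1 ms, the spike-resolving
        scale) makes the topology evolve continually; coarse cadences
        near-freeze it because each update moves positions by only
        ~gamma * V^2 * N_eta lattice units regardless of the period.
    pair_product : if True (default) the attraction weight of pair (i, j) is
        V_i * V_j inside the sum; if False the alternative global-prefactor
        reading V_i * (sum of neighbor V_j) multiplies every unit vector.
    """

    gamma: float = 6e-7
    radius: float = 25.0
    epsilon: float = 18.82
    update_period: float = 0.1
    pair_product: bool = True

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not self.update_period > 0:
            raise ValueError("update_period must be positive")


def min_image_delta(p, q, global_l: float) -> np.ndarray:
    """Shortest displacement vector from q to p on the global torus."""
    d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    return np.mod(d + global_l / 2.0, global_l) - global_l / 2.0


def periodic_distance(p, q, global_l: float) -> float:
    """Euclidean distance under the minimum-image convention."""
    return float(np.linalg.norm(min_image_delta(p, q, global_l)))


def pairwise_distances(positions: np.ndarray, global_l: float) -> np.ndarray:
    """(N, N) matrix of minimum-image distances."""
    r = np.asarray(positions, dtype=float)
    delta = np.mod(r[None, :, :] - r[:, None, :] + global_l / 2.0, global_l) - global_l / 2.0
    return np.sqrt((delta**2).sum(axis=-1))


def neighborhood(positions: np.ndarray, radius: float, global_l: float):
    """Interaction sets eta_i = {j != i : |r_j - r_i| <= R} (inclusive).

    Returns ``(mask, counts)`` where ``mask`` is the (N, N) boolean neighbor
    matrix with zero diagonal and ``counts[i] = N_eta_i``.  A neuron is not
    its own neighbor: the zero-distance self-pair has no direction and
    contributes nothing to the update.
    """
    dist = pairwise_distances(positions, global_l)
    mask = dist <= radius
    np.fill_diagonal(mask, False)
    return mask, mask.sum(axis=1)


def _displacements(
    positions: np.ndarray,
    potentials: np.ndarray,
    params: PlasticityParams,
    global_l: float,
) -> np.ndarray:
    """gamma-scaled displacement of every neuron for one update step."""
    r = np.asarray(positions, dtype=float)
    v = np.asarray(potentials, dtype=float)
    delta = np.mod(r[None, :, :] - r[:, None, :] + global_l / 2.0, global_l) - global_l / 2.0
    dist = np.sqrt((delta**2).sum(axis=-1))
    mask = dist <= params.radius
    np.fill_diagonal(mask, False)
    # unit vectors i -> j; coincident pairs get the zero vector
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dist[..., None] > 0.0, delta / dist[..., None], 0.0)
    if params.pair_product:
        weight = v[:, None] * v[None, :]
    else:
        weight = v[:, None] * (mask * v[None, :]).sum(axis=1)[:, None]
    return params.gamma * (mask[..., None] * unit * weight[..., None]).sum(axis=1)


def update_positions(
    positions: np.ndarray,
    potentials: np.ndarray,
    params: PlasticityParams,
    network: StructuralNetwork,
) -> np.ndarray:
    """One discrete position update driven by the membrane potentials.

    r_i <- wrap(r_i + gamma * sum_{j in eta_i} unit(r_j - r_i) * V_i * V_j),
    with the result wrapped back into neuron i's domain.  Neurons with an
    empty neighborhood do not move.
    """
    disp = _displacements(positions, potentials, params, network.global_l)
    new = np.asarray(positions, dtype=float) + disp
    return np.array([wrap(new[i], network.domains[i]) for i in range(len(new))])


@dataclass
class TopologySnapshot:
    """Frozen functional topology valid on the window [t_start, t_end).

    ``coupling`` is the symmetric 0/1 matrix; the Laplacian (coupling minus
    degree diagonal, negative semidefinite with zero row sums) and the
    degree vector are derived on demand.  ``strengths[i] = epsilon/N_eta_i``
    (0 for isolated neurons).
    """

    coupling: np.ndarray
    strengths: np.ndarray
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=np.int8)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if not np.array_equal(self.coupling, self.coupling.T):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling matrix must have zero diagonal")

    @property
    def degrees(self) -> np.ndarray:
        return self.coupling.sum(axis=1).astype(np.int64)

    @property
    def laplacian(self) -> np.ndarray:
        lap = self.coupling.astype(float)
        np.fill_diagonal(lap, -self.degrees.astype(float))
        return lap

    @property
    def n(self) -> int:
        return self.coupling.shape[0]


def adjacency_from_positions(
    positions: np.ndarray,
    params: PlasticityParams,
    network: StructuralNetwork,
    t_start: float = 0.0,
    t_end: float = 0.0,
    structural_mask: bool = True,
) -> TopologySnapshot:
    """Distance-thresholded 0/1 adjacency plus coupling strengths.

    An edge requires minimum-image distance <= R (boundary inclusive) and,
    when ``structural_mask`` is on, a structural overlap between the two
    neurons' domains -- the functional network then provably lives inside
    the fixed structural network.  Strengths use the unmasked neighbor
    counts N_eta_i.
    """
    mask, counts = neighborhood(positions, params.radius, network.global_l)
    adj = mask.copy()
    if structural_mask:
        adj &= network.overlap_graph.astype(bool)
    with np.errstate(divide="ignore"):
        strengths = np.where(counts > 0, params.epsilon / np.maximum(counts, 1), 0.0)
    return TopologySnapshot(
        coupling=adj.astype(np.int8),
        strengths=strengths,
        t_start=t_start,
        t_end=t_end,
    )
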