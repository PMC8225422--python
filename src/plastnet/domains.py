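"""The structural network: periodic spatial domains and their overlaps.

Physical wiring (axons/dendrites) is modeled geometrically: each neuron owns
a periodic axis-aligned box (its "domain") on a global periodic plane of
side ``global_l``, and two neurons are structurally connected iff their
domains intersect under periodic wrapping.  The position vector that drives
functional connectivity is confined to its neuron's domain.

``build_lattice`` produces the simulation scenario: a sqrt(N) x sqrt(N)
torus of domains whose overlap graph is the 4-regular lattice.  Equal
squares cannot do this (any square large enough to reach its edge neighbor
also clips the diagonal neighbor's corner), so the lattice uses a
checkerboard of rectangles -- long side ``s*(1+f)`` along alternating axes,
short side ``s*(1-f/2)`` -- which overlap edge neighbors only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Domain",
    "StructuralNetwork",
    "wrap",
    "overlaps",
    "build_lattice",
    "save_structural",
    "load_structural",
]


@dataclass(frozen=True)
class Domain:
    """Axis-aligned periodic box assigned to one neuron (lattice units)."""

    neuron_index: int
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower/upper must be equal-length vectors")
        if not np.all(lo < hi):
            raise ValueError("domain must satisfy lower < upper componentwise")
        object.__setattr__(self, "lower", tuple(float(x) for x in lo))
        object.__setattr__(self, "upper", tuple(float(x) for x in hi))

    @property
    def ndim(self) -> int:
        return len(self.lower)

    @property
    def sides(self) -> np.ndarray:
        return np.asarray(self.upper) - np.asarray(self.lower)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.upper) + np.asarray(self.lower))


def wrap(position, domain: Domain) -> np.ndarray:
    """Map a position into the domain's half-open box [lower, upper).

    The result is congruent to ``position`` modulo the domain's side lengths,
    which implements the periodic boundary condition of the per-neuron
    region.  Idempotent; ``position == upper`` maps to ``lower``.
    """
    lo = np.asarray(domain.lower)
    hi = np.asarray(domain.upper)
    out = lo + np.mod(np.asarray(position, dtype=float) - lo, domain.sides)
    # mod can round up to exactly `sides` for tiny negative offsets
    return np.where(out >= hi, lo, out)


def _circular_gap(c1: np.ndarray, c2: np.ndarray, global_l: float) -> np.ndarray:
    """Per-axis center distance under the minimum-image convention."""
    return np.abs(np.mod(c1 - c2 + global_l / 2.0, global_l) - global_l / 2.0)


def overlaps(domains: list[Domain], global_l: float) -> np.ndarray:
    """Symmetric 0/1 intersection matrix of the domains on the global torus.

    Two boxes intersect iff on every axis the minimum-image distance of the
    centers is at most the sum of the half-sides; boundary touching counts.
    """
    n = len(domains)
    centers = np.array([np.mod(d.center, global_l) for d in domains])
    halves = np.array([d.sides / 2.0 for d in domains])
    out = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            gap = _circular_gap(centers[i], centers[j], global_l)
            if np.all(gap <= halves[i] + halves[j] + 1e-12):
                out[i, j] = out[j, i] = 1
    return out


@dataclass
class StructuralNetwork:
    """Fixed physical wiring: domains plus the overlap graph they induce."""

    domains: list[Domain]
    global_l: float = 100.0
    overlap_graph: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.overlap_graph is None:
            self.overlap_graph = overlaps(self.domains, self.global_l)
        self.overlap_graph = np.asarray(self.overlap_graph, dtype=np.int8)

    @property
    def n(self) -> int:
        return len(self.domains)

    @property
    def ndim(self) -> int:
        return self.domains[0].ndim

    def centers(self) -> np.ndarray:
        return np.array([d.center for d in self.domains])


def build_lattice(
    n: int, global_l: float = 100.0, overlap_fraction: float = 0.25
) -> StructuralNetwork:
    """Torus lattice of N = k*k domains whose overlap graph is 4-regular.

    Grid step ``s = global_l / k``; each domain is a rectangle centered on
    its grid point, elongated along x or y in a checkerboard pattern so that
    only edge neighbors intersect.  For even k (the 8x8 and 4x4 scenarios)
    the overlap graph is exactly the 4-regular torus lattice (degree 2 on
    the degenerate 2x2 torus, where the two periodic neighbors coincide);
    odd k is connected but picks up extra seam edges where the checkerboard
    parity wraps inconsistently.
    """
    k = math.isqrt(n)
    if k * k != n:
        raise ValueError(f"lattice requires a perfect-square neuron count, got {n}")
    if not 0.0 < overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in (0, 1)")
    s = global_l / k
    long_half = s * (1.0 + overlap_fraction) / 2.0
    short_half = s * (1.0 - overlap_fraction / 2.0) / 2.0
    domains = []
    for row in range(k):
        for col in range(k):
            cx = (col + 0.5) * s
            cy = (row + 0.5) * s
            if (row + col) % 2 == 0:
                hx, hy = long_half, short_half
            else:
                hx, hy = short_half, long_half
            domains.append(
                Domain(
                    neuron_index=row * k + col,
                    lower=(cx - hx, cy - hy),
                    upper=(cx + hx, cy + hy),
                )
            )
    return StructuralNetwork(domains=domains, global_l=global_l)


def save_structural(network: StructuralNetwork, path) -> None:
    """Write a structural network: one JSON header line, then 'i j' edges."""
    header = {
        "global_l": network.global_l,
        "domains": [
            {"neuron_index": d.neuron_index, "lower": list(d.lower), "upper": list(d.upper)}
            for d in network.domains
        ],
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        rows, cols = np.nonzero(np.triu(network.overlap_graph))
        for i, j in zip(rows, cols):
            fh.write(f"{i} {j}\n")


def load_structural(path) -> StructuralNetwork:
    with open(path) as fh:
        header = json.loads(fh.readline())
        edges = [tuple(map(int, line.split())) for line in fh if line.strip()]
    domains = [
        Domain(d["neuron_index"], tuple(d["lower"]), tuple(d["upper"]))
        for d in header["domains"]
    ]
    n = len(domains)
    graph = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        graph[i, j] = graph[j, i] = 1
    return StructuralNetwork(domains=domains, global_l=header["global_l"], overlap_graph=graph)
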