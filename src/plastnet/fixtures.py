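"""Deterministic scenario generators: every test input is built in code.

Tags:

* ``pair``       -- two neurons with overlapping domains, 600 ms run.
* ``triangle``   -- three mutually overlapping neurons, 600 ms run.
* ``two-cliques``-- a static 8-node graph of two disjoint K4 cliques
                    (community-detection oracle; no dynamics).
* ``lattice16``  -- reduced 4x4 torus scenario, 1000 ms run.
* ``paper64``    -- the full 8x8, 3000 ms study scenario.
"""

from __future__ import annotations

import numpy as np

from .domains import Domain, StructuralNetwork
from .simulate import SimulationConfig

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("pair", "triangle", "two-cliques", "lattice16", "paper64")


def _square(index: int, center: tuple[float, float], side: float) -> Domain:
    cx, cy = center
    h = side / 2.0
    return Domain(index, (cx - h, cy - h), (cx + h, cy + h))


def make_fixture(name: str, seed: int = 0) -> dict:
    """Return a named deterministic scenario bundle.

    Simulation scenarios carry a ``config`` (with the seed baked in);
    the graph fixture carries an ``adjacency`` matrix instead.
    """
    if name == "pair":
        # centers 15*sqrt(2) ~ 21.2 apart: domains overlap and the jittered
        # positions start inside the interaction radius
        net = StructuralNetwork(
            domains=[_square(0, (20.0, 20.0), 40.0), _square(1, (35.0, 35.0), 40.0)],
            global_l=100.0,
        )
        cfg = SimulationConfig(n=2, t_end=600.0, t_couple=400.0, structural=net, seed=seed)
        return {"name": name, "seed": seed, "config": cfg, "network": net}
    if name == "triangle":
        net = StructuralNetwork(
            domains=[
                _square(0, (20.0, 20.0), 40.0),
                _square(1, (35.0, 20.0), 40.0),
                _square(2, (27.5, 33.0), 40.0),
            ],
            global_l=100.0,
        )
        cfg = SimulationConfig(n=3, t_end=600.0, t_couple=400.0, structural=net, seed=seed)
        return {"name": name, "seed": seed, "config": cfg, "network": net}
    if name == "two-cliques":
        adj = np.zeros((8, 8), dtype=np.int8)
        for block in (range(0, 4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        adj[i, j] = 1
        return {"name": name, "seed": seed, "adjacency": adj}
    if name == "lattice16":
        cfg = SimulationConfig(n=16, t_end=1000.0, t_couple=400.0, seed=seed)
        return {"name": name, "seed": seed, "config": cfg}
    if name == "paper64":
        cfg = SimulationConfig(seed=seed)
        return {"name": name, "seed": seed, "config": cfg}
    raise ValueError(f"unknown fixture tag {name!r}; known: {', '.join(FIXTURE_NAMES)}")
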