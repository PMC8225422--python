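"""Trace persistence (HDF5) and delimited-text exports.

The HDF5 container has one dataset per recorded quantity plus the config
(as YAML) and the structural geometry, so a saved trace round-trips into a
fully functional :class:`~plastnet.simulate.SimulationTrace`.  All text
exports use 9 significant digits so that cross-run diffs are meaningful.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .config import config_from_dict, config_to_dict
from .domains import Domain, StructuralNetwork
from .plasticity import TopologySnapshot
from .simulate import SimulationTrace

__all__ = [
    "save_trace",
    "load_trace",
    "export_degrees",
    "export_sync",
    "export_stability",
    "export_partitions",
    "export_snapshot_edgelists",
    "export_states",
    "RunManifest",
]

_FLOAT_FMT = "%.9g"


def save_trace(trace: SimulationTrace, path) -> None:
    cfg = trace.config
    network = cfg.build_structural()
    with h5py.File(path, "w") as f:
        f.attrs["config_yaml"] = yaml.safe_dump(config_to_dict(cfg))
        f.attrs["global_l"] = network.global_l
        f.create_dataset("times", data=trace.times)
        f.create_dataset("states", data=trace.states, compression="gzip", compression_opts=4)
        f.create_dataset("degrees", data=trace.degrees, compression="gzip", compression_opts=4)
        f.create_dataset("lambda2", data=trace.lambda2)
        f.create_dataset("positions", data=trace.positions)
        f.create_dataset("position_times", data=trace.position_times)
        f.create_dataset("domain_lower", data=np.array([d.lower for d in network.domains]))
        f.create_dataset("domain_upper", data=np.array([d.upper for d in network.domains]))
        f.create_dataset("overlap_graph", data=network.overlap_graph)
        if trace.snapshots:
            f.create_dataset(
                "snapshot_coupling",
                data=np.stack([s.coupling for s in trace.snapshots]),
                compression="gzip",
                compression_opts=4,
            )
            f.create_dataset(
                "snapshot_strengths", data=np.stack([s.strengths for s in trace.snapshots])
            )
            f.create_dataset(
                "snapshot_windows",
                data=np.array([[s.t_start, s.t_end] for s in trace.snapshots]),
            )


def load_trace(path) -> SimulationTrace:
    with h5py.File(path, "r") as f:
        cfg_dict = yaml.safe_load(f.attrs["config_yaml"])
        lower = f["domain_lower"][:]
        upper = f["domain_upper"][:]
        network = StructuralNetwork(
            domains=[
                Domain(i, tuple(lower[i]), tuple(upper[i])) for i in range(lower.shape[0])
            ],
            global_l=float(f.attrs["global_l"]),
            overlap_graph=f["overlap_graph"][:],
        )
        config = config_from_dict(cfg_dict, structural=network)
        snapshots = []
        if "snapshot_windows" in f:
            windows = f["snapshot_windows"][:]
            coupling = f["snapshot_coupling"][:]
            strengths = f["snapshot_strengths"][:]
            snapshots = [
                TopologySnapshot(coupling[k], strengths[k], windows[k, 0], windows[k, 1])
                for k in range(windows.shape[0])
            ]
        return SimulationTrace(
            times=f["times"][:],
            states=f["states"][:],
            degrees=f["degrees"][:],
            snapshots=snapshots,
            lambda2=f["lambda2"][:],
            positions=f["positions"][:],
            position_times=f["position_times"][:],
            config=config,
        )


def export_degrees(trace: SimulationTrace, path) -> None:
    from .simulate import degree_series

    degree_series(trace).to_csv(path, float_format=_FLOAT_FMT)


def export_states(trace: SimulationTrace, path) -> None:
    """Membrane potentials only (T x N table); gates are in the HDF5 trace."""
    pd.DataFrame(
        trace.states[:, :, 0],
        index=pd.Index(trace.times, name="t_ms"),
        columns=[f"neuron_{i}" for i in range(trace.states.shape[1])],
    ).to_csv(path, float_format=_FLOAT_FMT)


def export_sync(series, path) -> None:
    pd.DataFrame(
        {"t_ms": series.times, "mu": series.mu, "sigma": series.sigma, "S": series.s}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def export_stability(reports, path) -> None:
    pd.DataFrame(
        {
            "t_start": [r.t_start for r in reports],
            "t_end": [r.t_end for r in reports],
            "lambda2_max": [r.lambda2_max for r in reports],
            "d_bar": [r.d_bar for r in reports],
            "exponential_flag": [int(r.exponential_flag) for r in reports],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def export_partitions(partitions, path) -> None:
    rows = []
    for p in partitions:
        for neuron, label in enumerate(p.labels):
            rows.append((p.t_start, p.t_end, neuron, int(label)))
    pd.DataFrame(rows, columns=["t_start", "t_end", "neuron", "community"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def export_snapshot_edgelists(trace: SimulationTrace, path) -> None:
    """All snapshot edges as 't_start t_end i j' lines (header comment first)."""
    with open(path, "w") as fh:
        fh.write("# t_start t_end i j\n")
        for snap in trace.snapshots:
            rows, cols = np.nonzero(np.triu(snap.coupling))
            for i, j in zip(rows, cols):
                fh.write(f"{snap.t_start:.9g} {snap.t_end:.9g} {i} {j}\n")


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI run's outputs."""

    config: dict
    seed: int
    version: str
    outputs: dict = field(default_factory=dict)
    created: str = ""

    def write(self, path) -> None:
        if not self.created:
            self.created = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "version": self.version,
                    "outputs": self.outputs,
                    "created": self.created,
                },
                fh,
                indent=2,
            )
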