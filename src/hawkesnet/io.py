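"""Reading and writing networks, spike trains and reports.

Connectivity travels as a Matrix Market coordinate file (``.mtx``) or a
3-column TSV edge list (source, target, weight), in both cases with a
sidecar JSON (``<path>.json``) holding node types, ring positions and
generator metadata.  Spike trains are 2-column TSV (neuron_id, time_s).
Round trips are lossless for weights, types, positions and metadata;
explicit zeros in an .mtx are dropped on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .network import Network
from .simulate import SpikeTrains

__all__ = [
    "write_network",
    "read_network",
    "write_spikes",
    "read_spikes",
    "write_json_report",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_network(net: Network, path: str | Path) -> None:
    """Write a network as .mtx (or .tsv edge list) plus a sidecar JSON."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(net.G))
    elif path.suffix == ".tsv":
        rows, cols = np.nonzero(net.G)
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for i, j in zip(rows, cols):
                fh.write(f"{j}\t{i}\t{float(net.G[i, j])!r}\n")
    else:
        raise ValueError(f"unsupported network format: {path.suffix} (use .mtx or .tsv)")
    sidecar = {
        "n_nodes": net.n_nodes,
        "types": net.types.tolist(),
        "positions": None if net.positions is None else net.positions.tolist(),
        "meta": net.meta,
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))


def read_network(path: str | Path) -> Network:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    side = json.loads(_sidecar(path).read_text())
    n = int(side["n_nodes"])
    if path.suffix == ".mtx":
        M = scipy.io.mmread(str(path))
        G = np.asarray(M.todense() if scipy.sparse.issparse(M) else M, dtype=float)
        if G.shape != (n, n):
            raise ValueError(f"matrix shape {G.shape} does not match sidecar N = {n}")
    elif path.suffix == ".tsv":
        G = np.zeros((n, n))
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("source"):
                fh.seek(0)
            for line in fh:
                if not line.strip():
                    continue
                src_s, tgt_s, w_s = line.split("\t")
                src, tgt = int(src_s), int(tgt_s)
                if not (0 <= src < n and 0 <= tgt < n):
                    raise ValueError(f"edge ({src}, {tgt}) out of range for N = {n}")
                G[tgt, src] = float(w_s)
    else:
        raise ValueError(f"unsupported network format: {path.suffix}")
    positions = side.get("positions")
    return Network(
        G=G,
        types=np.asarray(side["types"], dtype="U1"),
        positions=None if positions is None else np.asarray(positions, dtype=int),
        meta=side.get("meta", {}),
    )


def write_spikes(spikes: SpikeTrains, path: str | Path) -> None:
    """Write spike trains as TSV (neuron_id, time_s), sorted by time."""
    path = Path(path)
    ids = np.concatenate([np.full(t.size, i) for i, t in enumerate(spikes.times)]) if spikes.n else np.empty(0)
    ts = np.concatenate(spikes.times) if spikes.n else np.empty(0)
    order = np.argsort(ts, kind="stable")
    with open(path, "w") as fh:
        fh.write(f"# n_neurons={spikes.n} duration_s={spikes.duration!r}\n")
        fh.write("neuron_id\ttime_s\n")
        for i, t in zip(ids[order], ts[order]):
            fh.write(f"{int(i)}\t{float(t)!r}\n")


def read_spikes(path: str | Path) -> SpikeTrains:
    """Read spike trains written by :func:`write_spikes`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("spike TSV must start with a '# n_neurons=... duration_s=...' line")
        fields = dict(kv.split("=") for kv in header[1:].split())
        n = int(fields["n_neurons"])
        duration = float(fields["duration_s"])
        fh.readline()  # column header
        data = np.loadtxt(fh, ndmin=2)
    times: list[np.ndarray] = [np.empty(0) for _ in range(n)]
    if data.size:
        ids = data[:, 0].astype(int)
        ts = data[:, 1]
        for i in range(n):
            times[i] = np.sort(ts[ids == i])
    return SpikeTrains(times=times, duration=duration)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, cls=_NumpyEncoder))
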