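"""Plain-text snapshot format and trajectory storage.

A snapshot is a versioned, self-describing text container with a ``nodes``
table (id, x, y, pinned, boundary) and an ``edges`` table (node_a, node_b,
multiplicity); coordinates are written in full precision (repr round-trip), so
save → load is lossless.
"""

from __future__ import annotations

import io as _io
import os
from typing import TextIO, Union

import numpy as np

from .network import LiquidNetwork
from .params import DomainBoundary

__all__ = ["write_snapshot", "read_snapshot", "write_trajectory_scalars"]

FORMAT_VERSION = 1


def write_snapshot(net: LiquidNetwork, path_or_file: Union[str, os.PathLike, TextIO]) -> None:
    """Write a network snapshot to a plain-text file (see module docstring)."""
    close = False
    if isinstance(path_or_file, (str, os.PathLike)):
        fh = open(path_or_file, "w")
        close = True
    else:
        fh = path_or_file
    try:
        net = net.compact()
        d = net.domain
        fh.write(f"# liquidnet snapshot v{FORMAT_VERSION}\n")
        fh.write(f"time\t{net.time!r}\n")
        if d.kind == "circle":
            fh.write(f"domain\tcircle\t{d.radius!r}\n")
        elif d.kind == "periodic":
            fh.write(f"domain\tperiodic\t{d.extents[0]!r}\t{d.extents[1]!r}\n")
        else:
            fh.write("domain\tnone\n")
        fh.write(f"nodes\t{net.n_nodes}\n")
        fh.write("id\tx\ty\tpinned\tboundary\n")
        for i in range(net.n_nodes):
            fh.write(f"{i}\t{float(net.pos[i, 0])!r}\t{float(net.pos[i, 1])!r}"
                     f"\t{int(net.pinned[i])}\t{int(net.boundary[i])}\n")
        fh.write(f"edges\t{net.n_edges}\n")
        fh.write("node_a\tnode_b\tmultiplicity\n")
        order = np.lexsort((net.edge_mult[: net.n_edges],
                            net.edges[: net.n_edges, 1],
                            net.edges[: net.n_edges, 0]))
        for e in order:
            a, b = net.edges[e]
            fh.write(f"{a}\t{b}\t{int(net.edge_mult[e])}\n")
    finally:
        if close:
            fh.close()


def read_snapshot(path_or_file: Union[str, os.PathLike, TextIO]) -> LiquidNetwork:
    """Read a snapshot written by :func:`write_snapshot`."""
    close = False
    if isinstance(path_or_file, (str, os.PathLike)):
        fh = open(path_or_file)
        close = True
    else:
        fh = path_or_file
    try:
        header = fh.readline().strip()
        if not header.startswith("# liquidnet snapshot v"):
            raise ValueError("not a liquidnet snapshot file")
        version = int(header.rsplit("v", 1)[1])
        if version > FORMAT_VERSION:
            raise ValueError(f"unsupported snapshot version {version}")
        tline = fh.readline().split("\t")
        assert tline[0] == "time"
        t = float(tline[1])
        dline = fh.readline().strip().split("\t")
        assert dline[0] == "domain"
        if dline[1] == "circle":
            dom = DomainBoundary("circle", radius=float(dline[2]))
        elif dline[1] == "periodic":
            dom = DomainBoundary("periodic",
                                 extents=(float(dline[2]), float(dline[3])))
        else:
            dom = DomainBoundary("none")
        net = LiquidNetwork(dom)
        net.time = t
        nline = fh.readline().split("\t")
        assert nline[0] == "nodes"
        n = int(nline[1])
        fh.readline()  # column header
        for _ in range(n):
            row = fh.readline().split("\t")
            net.add_node((float(row[1]), float(row[2])),
                         pinned=bool(int(row[3])), boundary=bool(int(row[4])))
        eline = fh.readline().split("\t")
        assert eline[0] == "edges"
        m = int(eline[1])
        fh.readline()
        for _ in range(m):
            row = fh.readline().split("\t")
            net.add_edge(int(row[0]), int(row[1]))
        return net
    finally:
        if close:
            fh.close()


def snapshot_string(net: LiquidNetwork) -> str:
    buf = _io.StringIO()
    write_snapshot(net, buf)
    return buf.getvalue()


def write_trajectory_scalars(traj, path: Union[str, os.PathLike]) -> None:
    """Write the scalar time series (time, length, counts) as TSV."""
    df = traj.scalars()
    df.to_csv(path, sep="\t", index=False)
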