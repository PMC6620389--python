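"""Reading, validating and writing SWC neuron trees and Vaa3D marker files.

SWC is the plain-text neuron-reconstruction format: one node per line with
columns ``id type x y z radius parent``.  Tracing software (APP2 in Vaa3D)
emits coordinates in voxel units; every downstream threshold in this package
(2 µm angle windows, 4 µm suppression, 8 µm thickness windows, ...) is
physical, so unit conversion to µm happens once, at read time, through a
per-axis ``unit_scale``.  The node radius is scaled by the x/y factor because
tracing estimates radii in-plane.

Coordinates are 0-based voxel centers internally; the Vaa3D ``.marker``
dialect is written 1-based, per Vaa3D convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "SwcNode",
    "NeuronTree",
    "SeedMarker",
    "SwcParseError",
    "SwcStructureError",
    "read_swc",
    "write_swc",
    "read_marker",
    "write_marker",
]

#: Reserved SWC structure codes carrying manual labels (see classification).
VNC_STRUCTURE_CODE = 7
BLOB_STRUCTURE_CODE = 8


class SwcParseError(ValueError):
    """A malformed SWC/marker line; the message names the line number."""


class SwcStructureError(ValueError):
    """The node set does not form a single rooted tree."""


@dataclass(frozen=True)
class SwcNode:
    """One traced node: position and radius in µm after unit conversion."""

    id: int
    structure_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class SeedMarker:
    """A tracing seed in 0-based voxel coordinates."""

    x: float
    y: float
    z: float
    comment: str = ""

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) < 0:
            raise ValueError("marker coordinates must be non-negative")


class NeuronTree:
    """A rooted tree of traced nodes with SWC semantics.

    Invariants enforced at construction: unique ids, exactly one root
    (``parent_id == -1``), every other parent resolves, no cycles, all
    radii non-negative.  All geometric queries are in µm.
    """

    def __init__(
        self,
        nodes: Iterable[SwcNode],
        unit_scale: Sequence[float] = (1.0, 1.0, 1.0),
    ) -> None:
        node_list = list(nodes)
        self.nodes: dict[int, SwcNode] = {}
        roots = []
        for n in node_list:
            if n.id in self.nodes:
                raise SwcStructureError(f"duplicate node id {n.id}")
            if n.id <= 0:
                raise SwcStructureError(f"node id must be positive, got {n.id}")
            if n.radius < 0:
                raise SwcStructureError(f"negative radius at node {n.id}")
            self.nodes[n.id] = n
            if n.parent_id == -1:
                roots.append(n.id)
        if not self.nodes:
            raise SwcStructureError("empty tree")
        if len(roots) != 1:
            raise SwcStructureError(
                f"expected exactly one root, found {len(roots)}"
            )
        self.root_id: int = roots[0]
        self.unit_scale = tuple(float(s) for s in unit_scale)

        self._children: dict[int, list[int]] = {i: [] for i in self.nodes}
        for n in self.nodes.values():
            if n.parent_id != -1:
                if n.parent_id not in self.nodes:
                    raise SwcStructureError(
                        f"node {n.id} references missing parent {n.parent_id}"
                    )
                self._children[n.parent_id].append(n.id)
        self._check_connected_acyclic()

    def _check_connected_acyclic(self) -> None:
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            if i in seen:  # pragma: no cover - duplicate ids caught earlier
                raise SwcStructureError("cycle detected")
            seen.add(i)
            stack.extend(self._children[i])
        if len(seen) != len(self.nodes):
            # parent chains that never reach the root form cycles/forests
            raise SwcStructureError(
                "tree is not connected to the root (cycle or dangling subtree)"
            )

    # -- topology ---------------------------------------------------------
    def children(self, node_id: int) -> list[int]:
        return list(self._children[node_id])

    def degree(self, node_id: int) -> int:
        n = self.nodes[node_id]
        return len(self._children[node_id]) + (0 if n.parent_id == -1 else 1)

    def endpoints(self) -> list[int]:
        """Degree-1 non-root nodes (tips)."""
        return [
            i
            for i in self.nodes
            if not self._children[i] and i != self.root_id
        ]

    def topological_order(self) -> Iterator[int]:
        """Root first, every parent before its children."""
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            yield i
            stack.extend(reversed(self._children[i]))

    def edge_length(self, a: int, b: int) -> float:
        return float(
            np.linalg.norm(self.nodes[a].position - self.nodes[b].position)
        )

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NeuronTree):
            return NotImplemented
        return self.nodes == other.nodes

    def with_nodes(self, nodes: Iterable[SwcNode]) -> "NeuronTree":
        return NeuronTree(nodes, unit_scale=self.unit_scale)


def _parse_swc_line(line: str, lineno: int) -> SwcNode:
    parts = line.split()
    if len(parts) != 7:
        raise SwcParseError(
            f"line {lineno}: expected 7 whitespace-delimited fields, "
            f"got {len(parts)}"
        )
    try:
        return SwcNode(
            id=int(parts[0]),
            structure_code=int(parts[1]),
            x=float(parts[2]),
            y=float(parts[3]),
            z=float(parts[4]),
            radius=float(parts[5]),
            parent_id=int(parts[6]),
        )
    except ValueError as exc:
        raise SwcParseError(f"line {lineno}: {exc}") from None


def read_swc(
    path: str | Path,
    unit_scale: Sequence[float] = (1.0, 1.0, 1.0),
) -> NeuronTree:
    """Read a 7-column SWC file into a validated :class:`NeuronTree`.

    Coordinates are multiplied per-axis by ``unit_scale`` (µm per coordinate
    unit); the radius is scaled by the x/y factor.  ``structure_code`` is
    preserved verbatim.  ``#`` comment lines and blank lines are skipped.
    """
    sx, sy, sz = (float(s) for s in unit_scale)
    nodes: list[SwcNode] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n = _parse_swc_line(line, lineno)
            nodes.append(
                replace(
                    n,
                    x=n.x * sx,
                    y=n.y * sy,
                    z=n.z * sz,
                    radius=n.radius * sx,
                )
            )
    return NeuronTree(nodes, unit_scale=(sx, sy, sz))


def write_swc(tree: NeuronTree, path: str | Path) -> None:
    """Write standard 7-column SWC, parents before children.

    Coordinates are written as stored (µm); reading back with unit_scale 1
    reproduces the tree.
    """
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in tree.topological_order():
            n = tree.nodes[i]
            fh.write(
                f"{n.id} {n.structure_code} {n.x:.6f} {n.y:.6f} "
                f"{n.z:.6f} {n.radius:.6f} {n.parent_id}\n"
            )


def write_marker(seed: SeedMarker, path: str | Path) -> None:
    """Write a Vaa3D ``.marker`` CSV line (1-based coordinates)."""
    with open(path, "w") as fh:
        fh.write("#x,y,z,radius,shape,name,comment\n")
        fh.write(
            f"{seed.x + 1:g},{seed.y + 1:g},{seed.z + 1:g},"
            f"0,1,,{seed.comment}\n"
        )


def read_marker(path: str | Path) -> SeedMarker:
    """Read the first marker of a Vaa3D ``.marker`` file (0-based result)."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) < 3:
                raise SwcParseError(
                    f"line {lineno}: marker line needs at least x,y,z"
                )
            comment = parts[6] if len(parts) > 6 else ""
            return SeedMarker(
                x=float(parts[0]) - 1,
                y=float(parts[1]) - 1,
                z=float(parts[2]) - 1,
                comment=comment,
            )
    raise SwcParseError("no marker line found")
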