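"""SWC neuron morphology: trees, segments, tips and their orientations.

A reconstruction is a rooted forest of annotation nodes, each carrying a
3D location, a radius and a topological parent — the standard 7-column SWC
exchanged by tracing tools (Vaa3D dialect: 1-based ids, parent ``-1`` for
roots, ``#`` comment lines, whitespace-separated fields).

Coordinates are interpreted in voxel units of the companion image stack;
physical units enter only through the stack's voxel-size metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronNode",
    "NeuronTree",
    "Segment",
    "SWCParseError",
    "SWCStructureError",
    "read_swc",
    "write_swc",
    "decompose_segments",
    "tip_orientation",
]


class SWCParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SWCStructureError(ValueError):
    """The node table violates tree invariants (dangling parent, cycle...)."""


@dataclass(frozen=True)
class NeuronNode:
    """One SWC annotation node.

    ``type_code`` follows the SWC convention: 0 undefined, 1 soma, 2 axon,
    3 basal dendrite, 4 apical dendrite.
    """

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class NeuronTree:
    """An ordered collection of nodes forming a forest (≥ 0 roots)."""

    nodes: list[NeuronNode] = field(default_factory=list)
    name: str = ""
    comments: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    @property
    def node_ids(self) -> list[int]:
        return [n.id for n in self.nodes]

    def node(self, node_id: int) -> NeuronNode:
        return self._index()[node_id]

    def _index(self) -> dict[int, NeuronNode]:
        return {n.id: n for n in self.nodes}

    def children_map(self) -> dict[int, list[int]]:
        """Map node id -> ids of its children, in node order."""
        out: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent != -1:
                out[n.parent].append(n.id)
        return out

    def roots(self) -> list[int]:
        return [n.id for n in self.nodes if n.parent == -1]

    def positions(self) -> np.ndarray:
        """(N, 3) array of (x, y, z) in node order."""
        if not self.nodes:
            return np.zeros((0, 3))
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    def validate(self) -> None:
        """Raise :class:`SWCStructureError` on duplicate ids, dangling
        parents or cycles."""
        ids = [n.id for n in self.nodes]
        idset = set(ids)
        if len(idset) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SWCStructureError(f"duplicate node ids: {dup}")
        parent = {}
        for n in self.nodes:
            if n.parent != -1 and n.parent not in idset:
                raise SWCStructureError(
                    f"node {n.id} refers to missing parent {n.parent}"
                )
            if n.parent == n.id:
                raise SWCStructureError(f"node {n.id} is its own parent")
            parent[n.id] = n.parent
        # cycle check by walking to a root from every node with memoisation
        ok: set[int] = set()
        for start in ids:
            seen = []
            cur = start
            while cur != -1 and cur not in ok:
                if cur in seen:
                    raise SWCStructureError(f"cycle involving node {cur}")
                seen.append(cur)
                cur = parent[cur]
            ok.update(seen)

    def subtree_nodes(self, keep_ids: set[int]) -> "NeuronTree":
        """Restrict to ``keep_ids``; survivors whose parent was dropped
        become roots."""
        kept = []
        for n in self.nodes:
            if n.id not in keep_ids:
                continue
            if n.parent != -1 and n.parent not in keep_ids:
                n = replace(n, parent=-1)
            kept.append(n)
        return NeuronTree(kept, name=self.name, comments=list(self.comments))


@dataclass(frozen=True)
class Segment:
    """A maximal unbranched run of nodes of one type."""

    node_ids: tuple[int, ...]

    @property
    def tip_a(self) -> int:
        return self.node_ids[0]

    @property
    def tip_b(self) -> int:
        return self.node_ids[-1]

    def __len__(self) -> int:
        return len(self.node_ids)


def read_swc(path) -> NeuronTree:
    """Read a 7-column SWC file into a :class:`NeuronTree`.

    Comment lines are preserved as metadata; node order follows the file.
    Extra columns beyond the canonical seven (ESWC extensions) are ignored
    with a warning.
    """
    nodes: list[NeuronNode] = []
    comments: list[str] = []
    warned_extra = False
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line)
                continue
            parts = line.split()
            if len(parts) > 7 and not warned_extra:
                warnings.warn(
                    f"{path}: ignoring extra columns beyond 7 (line {lineno})",
                    stacklevel=2,
                )
                warned_extra = True
            if len(parts) < 7:
                raise SWCParseError(
                    f"{path}: line {lineno}: expected 7 fields, got {len(parts)}"
                )
            try:
                nodes.append(
                    NeuronNode(
                        id=int(parts[0]),
                        type_code=int(parts[1]),
                        x=float(parts[2]),
                        y=float(parts[3]),
                        z=float(parts[4]),
                        radius=float(parts[5]),
                        parent=int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SWCParseError(f"{path}: line {lineno}: {exc}") from exc
    tree = NeuronTree(nodes, name=str(path), comments=comments)
    tree.validate()
    return tree


def write_swc(tree: NeuronTree, path) -> None:
    """Write ``tree`` as 7-column SWC. Round-trips exactly with
    :func:`read_swc` (coordinates at full repr precision)."""
    tree.validate()
    with open(path, "w") as fh:
        if tree.comments:
            for c in tree.comments:
                fh.write(c + "\n")
        else:
            fh.write("# id type x y z radius parent\n")
        for n in tree.nodes:
            fh.write(
                f"{n.id} {n.type_code} {n.x:.9g} {n.y:.9g} {n.z:.9g} "
                f"{n.radius:.9g} {n.parent}\n"
            )


def decompose_segments(tree: NeuronTree) -> list[Segment]:
    """Partition the tree into maximal unbranched, single-type segments.

    Segments break at roots, at branch points (a node with ≥ 2 children
    ends its segment; each child starts a new one) and at type-code
    changes, so per-type statistics (axon vs dendrite) can be computed
    segment-wise. Every node belongs to exactly one segment.
    """
    tree.validate()
    children = tree.children_map()
    index = tree._index()
    segments: list[Segment] = []

    # a node starts a segment if it is a root, its parent branches,
    # or its type differs from its parent's
    starts = []
    for n in tree.nodes:
        if n.parent == -1:
            starts.append(n.id)
        else:
            p = index[n.parent]
            if len(children[p.id]) >= 2 or p.type_code != n.type_code:
                starts.append(n.id)

    for s in starts:
        run = [s]
        cur = s
        while True:
            kids = children[cur]
            if len(kids) != 1:
                break
            nxt = kids[0]
            if index[nxt].type_code != index[cur].type_code:
                break
            run.append(nxt)
            cur = nxt
        segments.append(Segment(tuple(run)))
    return segments


def tip_orientation(tree: NeuronTree, tip_id: int, depth: int = 5) -> np.ndarray:
    """Outward unit vector at a segment terminal.

    Uses the chord from the node ``min(depth, available)`` steps inward
    to the tip — cheap, deterministic and stable against node jitter.
    Raises ``ValueError`` for an isolated node or a tip that terminates
    no segment.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for seg in decompose_segments(tree):
        if len(seg) < 2:
            continue
        if seg.tip_a == tip_id:
            inner = seg.node_ids[min(depth, len(seg) - 1)]
            break
        if seg.tip_b == tip_id:
            inner = seg.node_ids[-1 - min(depth, len(seg) - 1)]
            break
    else:
        raise ValueError(
            f"node {tip_id} is not the terminal of any multi-node segment "
            "(orientation undefined)"
        )
    v = tree.node(tip_id).position - tree.node(inner).position
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValueError(f"zero-length chord at tip {tip_id}")
    return v / norm


def segment_orientation(points: np.ndarray, at_end: bool, depth: int = 5) -> np.ndarray:
    """Outward unit chord at one end of an ordered polyline of points.

    Same estimator as :func:`tip_orientation` but for a bare coordinate
    run (used for foreground fragments during gap connection).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points for an orientation")
    d = min(depth, len(pts) - 1)
    v = pts[-1] - pts[-1 - d] if at_end else pts[0] - pts[d]
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValueError("zero-length chord")
    return v / norm
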