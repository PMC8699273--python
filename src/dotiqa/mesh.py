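"""Structured triangular meshes on a disc and the boundary optode layout.

The simulated phantom is a circular breast-mimicking domain (default
diameter 80 mm).  Meshes are built as a fan of triangles sharing the centre
node, refined uniformly 1:4 a fixed number of times; every new node whose
parent edge lies on the boundary is projected radially onto the circle.
This construction is deterministic (bit-reproducible node ordering) and
yields the two canonical discretizations used throughout the package:

* forward mesh  — ``build_disc_mesh(8, 5, 40.0)`` → 4225 nodes, 8192 triangles
* inverse mesh  — ``build_disc_mesh(6, 4, 40.0)`` → 817 nodes, 1536 triangles

Sixteen sources and sixteen detectors are interleaved on the boundary at
22.5° like-optode spacing with an 11.25° source–detector offset, counted
counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangularMesh",
    "OptodeLayout",
    "build_disc_mesh",
    "mesh_summary",
    "place_optodes",
    "write_mesh",
    "read_mesh",
]

_BOUNDARY_TOL_MM = 1e-9


@dataclass
class TriangularMesh:
    """Piecewise-linear triangulation of a disc.

    Attributes
    ----------
    nodes : (V, 2) float array
        Node coordinates in mm, centre of the disc at the origin.
    triangles : (F, 3) int array
        Counterclockwise-oriented node index triples.
    boundary_nodes : (B,) int array
        Indices of nodes on the circle, ordered CCW starting at angle 0.
    radius : float
        Disc radius in mm.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_nodes: np.ndarray
    radius: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def signed_areas(self) -> np.ndarray:
        p = self.nodes
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))

    def boundary_angles(self) -> np.ndarray:
        """Angles (degrees in [0, 360)) of the boundary nodes, CCW order."""
        p = self.nodes[self.boundary_nodes]
        return np.degrees(np.arctan2(p[:, 1], p[:, 0])) % 360.0

    def unique_edges(self) -> np.ndarray:
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def validate(self) -> None:
        """Raise ValueError if any structural invariant is violated."""
        if np.any(self.signed_areas() <= 0):
            raise ValueError("mesh contains a non-CCW or degenerate triangle")
        r = np.hypot(*self.nodes[self.boundary_nodes].T)
        if np.any(np.abs(r - self.radius) > _BOUNDARY_TOL_MM):
            raise ValueError("boundary node off the circle by more than 1e-9 mm")
        n_edges = len(self.unique_edges())
        if self.n_nodes - n_edges + self.n_triangles != 1:
            raise ValueError("Euler characteristic V - E + F != 1")


@dataclass
class OptodeLayout:
    """Interleaved source/detector positions on the mesh boundary."""

    source_angles: np.ndarray
    detector_angles: np.ndarray
    source_nodes: np.ndarray
    detector_nodes: np.ndarray

    @property
    def n_sources(self) -> int:
        return len(self.source_nodes)

    @property
    def n_detectors(self) -> int:
        return len(self.detector_nodes)


def build_disc_mesh(base_fan_count: int, refinement_levels: int,
                    radius: float) -> TriangularMesh:
    """Build a structured disc mesh by uniform 1:4 refinement of a centre fan.

    Parameters
    ----------
    base_fan_count : int
        Number of triangles in the initial fan (>= 3).
    refinement_levels : int
        Number of uniform refinements; each splits every triangle into four
        by edge midpoints, projecting boundary midpoints onto the circle.
    radius : float
        Disc radius in mm (> 0).

    Returns
    -------
    TriangularMesh with ``base_fan_count * 4**refinement_levels`` triangles
    and ``base_fan_count * 2**refinement_levels`` boundary nodes.
    """
    if base_fan_count < 3:
        raise ValueError(f"base_fan_count must be >= 3, got {base_fan_count}")
    if refinement_levels < 0:
        raise ValueError("refinement_levels must be >= 0")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")

    f = base_fan_count
    angles = 2.0 * np.pi * np.arange(f) / f
    nodes = [np.array([0.0, 0.0])]
    nodes += [radius * np.array([np.cos(a), np.sin(a)]) for a in angles]
    nodes = np.array(nodes)
    triangles = np.array([[0, 1 + j, 1 + (j + 1) % f] for j in range(f)])
    boundary_edges = {tuple(sorted((1 + j, 1 + (j + 1) % f))) for j in range(f)}

    for _ in range(refinement_levels):
        # deterministic edge ordering: sorted lexicographically
        t = triangles
        raw = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        raw.sort(axis=1)
        edges = np.unique(raw, axis=0)
        midpoint_index = {}
        new_nodes = []
        for a, b in edges:
            m = 0.5 * (nodes[a] + nodes[b])
            if (a, b) in boundary_edges:
                m = m * (radius / np.hypot(*m))
            midpoint_index[(a, b)] = len(nodes) + len(new_nodes)
            new_nodes.append(m)
        nodes = np.vstack([nodes, np.array(new_nodes)])

        def mid(a, b):
            return midpoint_index[(a, b) if a < b else (b, a)]

        new_tris = []
        for a, b, c in triangles:
            mab, mbc, mca = mid(a, b), mid(b, c), mid(c, a)
            new_tris += [[a, mab, mca], [b, mbc, mab], [c, mca, mbc],
                         [mab, mbc, mca]]
        triangles = np.array(new_tris)

        new_boundary = set()
        for a, b in boundary_edges:
            m = midpoint_index[(a, b)]
            new_boundary.add(tuple(sorted((a, m))))
            new_boundary.add(tuple(sorted((m, b))))
        boundary_edges = new_boundary

    boundary_idx = sorted({i for e in boundary_edges for i in e})
    boundary_idx = np.array(boundary_idx)
    ang = np.arctan2(nodes[boundary_idx, 1], nodes[boundary_idx, 0]) % (2 * np.pi)
    boundary_idx = boundary_idx[np.argsort(ang)]

    mesh = TriangularMesh(nodes=nodes, triangles=triangles,
                          boundary_nodes=boundary_idx, radius=float(radius))
    mesh.validate()
    return mesh


def mesh_summary(mesh: TriangularMesh) -> dict:
    """Counts record: nodes, triangles, unique edges, boundary nodes, Euler χ."""
    v = mesh.n_nodes
    f = mesh.n_triangles
    e = len(mesh.unique_edges())
    return {
        "nodes": v,
        "triangles": f,
        "edges": e,
        "boundary_nodes": len(mesh.boundary_nodes),
        "euler_characteristic": v - e + f,
    }


def place_optodes(mesh: TriangularMesh, n_sources: int, n_detectors: int,
                  source_start_angle: float = 0.0,
                  angle_tol_deg: float = 1e-6) -> OptodeLayout:
    """Interleave sources and detectors CCW on the mesh boundary.

    Sources sit at ``source_start_angle + k*(360/n_sources)``; each detector
    sits halfway between consecutive sources.  Every optode must coincide
    with a boundary node to within ``angle_tol_deg`` — the structured mesh
    guarantees this when the boundary node count is a multiple of
    ``n_sources + n_detectors``.
    """
    if n_sources != n_detectors:
        raise ValueError("n_sources must equal n_detectors")
    n_b = len(mesh.boundary_nodes)
    if n_b % (n_sources + n_detectors) != 0:
        raise ValueError(
            f"boundary node count {n_b} not divisible by "
            f"{n_sources + n_detectors} optodes")

    pitch = 360.0 / n_sources
    src_ang = (source_start_angle + pitch * np.arange(n_sources)) % 360.0
    det_ang = (src_ang + pitch / 2.0) % 360.0
    b_ang = mesh.boundary_angles()

    def snap(target):
        d = np.abs((b_ang - target + 180.0) % 360.0 - 180.0)
        i = int(np.argmin(d))
        if d[i] > angle_tol_deg:
            raise ValueError(
                f"no boundary node within {angle_tol_deg}° of optode angle "
                f"{target:.4f}° (nearest at {d[i]:.4f}°); incompatible mesh "
                "refinement")
        return int(mesh.boundary_nodes[i])

    src_nodes = np.array([snap(a) for a in src_ang])
    det_nodes = np.array([snap(a) for a in det_ang])
    all_nodes = np.concatenate([src_nodes, det_nodes])
    if len(np.unique(all_nodes)) != len(all_nodes):
        raise ValueError("optode nodes are not all distinct")
    return OptodeLayout(source_angles=src_ang, detector_angles=det_ang,
                        source_nodes=src_nodes, detector_nodes=det_nodes)


def write_mesh(mesh: TriangularMesh, path) -> None:
    """Plain-text mesh format: header `V F`, then V `x y` lines, F `i j k` lines."""
    with open(path, "w") as fh:
        fh.write(f"{mesh.n_nodes} {mesh.n_triangles}\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.17g} {y:.17g}\n")
        for i, j, k in mesh.triangles:
            fh.write(f"{i} {j} {k}\n")


def read_mesh(path) -> TriangularMesh:
    """Read the text format written by :func:`write_mesh` (lossless round trip)."""
    with open(path) as fh:
        v, f = (int(s) for s in fh.readline().split())
        nodes = np.array([[float(s) for s in fh.readline().split()]
                          for _ in range(v)])
        triangles = np.array([[int(s) for s in fh.readline().split()]
                              for _ in range(f)])
    radius = float(np.max(np.hypot(nodes[:, 0], nodes[:, 1])))
    r = np.hypot(nodes[:, 0], nodes[:, 1])
    boundary = np.nonzero(np.abs(r - radius) <= _BOUNDARY_TOL_MM)[0]
    ang = np.arctan2(nodes[boundary, 1], nodes[boundary, 0]) % (2 * np.pi)
    boundary = boundary[np.argsort(ang)]
    return TriangularMesh(nodes=nodes, triangles=triangles,
                          boundary_nodes=boundary, radius=radius)
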