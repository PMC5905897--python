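"""Simplicial meshes and optode geometry for the imaging domain.

The reconstruction operates on P1 (linear nodal) finite-element meshes:
triangles in 2D, tetrahedra in 3D.  The builders here produce desk-scale
2D disk geometries — concentric rings of nodes triangulated by Delaunay —
which stand in for the large anatomical meshes used in full-scale studies.
All coordinates are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .errors import DimensionError, GeometryError, ParameterError

__all__ = [
    "Mesh",
    "OptodeArray",
    "build_disk_mesh",
    "build_layered_disk_mesh",
    "position_optodes",
    "build_link_table",
    "locate_point",
    "interpolation_weights",
]


@dataclass
class Mesh:
    """A simplicial mesh with per-node boundary flags and region labels.

    Attributes
    ----------
    nodes : (n_nodes, dim) float array, mm
    elements : (n_elements, dim+1) int array of node indices (0-based)
    boundary : (n_nodes,) bool array, True on the geometric boundary
    regions : (n_nodes,) int array of tissue labels
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary: np.ndarray
    regions: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.boundary = np.asarray(self.boundary, dtype=bool)
        self.regions = np.asarray(self.regions, dtype=np.int64)
        self.validate()

    @property
    def dimension(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def validate(self) -> None:
        if self.nodes.ndim != 2 or self.nodes.shape[1] not in (2, 3):
            raise GeometryError("nodes must be (n, 2) or (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != self.dimension + 1:
            raise GeometryError(
                f"elements must have {self.dimension + 1} nodes per simplex"
            )
        if self.elements.min(initial=0) < 0 or (
            self.n_elements and self.elements.max() >= self.n_nodes
        ):
            raise GeometryError("element index out of range")
        if self.boundary.shape != (self.n_nodes,):
            raise GeometryError("boundary flags must be per node")
        if self.regions.shape != (self.n_nodes,):
            raise GeometryError("region labels must be per node")
        if not self.boundary.any():
            raise GeometryError("mesh has no boundary nodes")
        self._orient()
        if np.any(self.element_volumes() <= 0):
            raise GeometryError("mesh contains degenerate (zero-volume) elements")

    def _orient(self) -> None:
        """Flip inverted simplices so all signed volumes are positive."""
        vol = self._signed_volumes()
        flip = vol < 0
        if flip.any():
            cols = self.elements[flip][:, [1, 0]]
            self.elements[np.ix_(flip, [0, 1])] = cols

    def _signed_volumes(self) -> np.ndarray:
        p = self.nodes[self.elements]
        edges = p[:, 1:, :] - p[:, :1, :]
        if self.dimension == 2:
            return 0.5 * np.linalg.det(edges)
        return np.linalg.det(edges) / 6.0

    def element_volumes(self) -> np.ndarray:
        """Areas (2D) or volumes (3D) of all elements."""
        return np.abs(self._signed_volumes())

    def boundary_facets(self) -> np.ndarray:
        """Facets (edges in 2D, triangular faces in 3D) on the mesh surface.

        A facet belongs to the boundary iff it appears in exactly one element.
        """
        d = self.dimension
        idx = [np.delete(np.arange(d + 1), i) for i in range(d + 1)]
        facets = np.concatenate([self.elements[:, j] for j in idx], axis=0)
        key = np.sort(facets, axis=1)
        _, first, counts = np.unique(
            key, axis=0, return_index=True, return_counts=True
        )
        return facets[first[counts == 1]]


def _ring_points(radius: float, n: int, phase: float = 0.0) -> np.ndarray:
    t = phase + 2.0 * np.pi * np.arange(n) / n
    return radius * np.column_stack([np.cos(t), np.sin(t)])


def _disk_points(break_radii: list[float], edge_length: float):
    """Concentric rings of points spanning [0, R], with rings placed exactly
    at every radius in ``break_radii`` (layer interfaces and the boundary)."""
    h = float(edge_length)
    pts = [np.zeros((1, 2))]
    radii_done = [0.0]
    for a, b in zip([0.0] + break_radii[:-1], break_radii):
        nseg = max(1, int(round((b - a) / h)))
        for j in range(1, nseg + 1):
            radii_done.append(a + (b - a) * j / nseg)
    ring_start = []
    for k, r in enumerate(radii_done[1:], start=1):
        n = max(6, int(round(2.0 * np.pi * r / h)))
        ring_start.append(sum(len(p) for p in pts))
        pts.append(_ring_points(r, n, phase=(np.pi / n) * (k % 2)))
    points = np.concatenate(pts, axis=0)
    outer_first = ring_start[-1] if ring_start else 0
    boundary = np.zeros(len(points), dtype=bool)
    boundary[outer_first:] = True
    return points, boundary


def build_disk_mesh(radius: float, edge_length: float) -> Mesh:
    """Triangulate a disk of the given radius with target edge length (mm).

    The characteristic element edge is within a factor of two of
    ``edge_length``; boundary nodes lie exactly on the circle.
    """
    if radius <= 0 or edge_length <= 0:
        raise ParameterError("radius and edge_length must be positive")
    if edge_length >= radius:
        raise ParameterError("edge_length must be smaller than radius")
    points, boundary = _disk_points([float(radius)], edge_length)
    tri = Delaunay(points)
    regions = np.zeros(len(points), dtype=np.int64)
    return Mesh(points, tri.simplices, boundary, regions)


def build_layered_disk_mesh(radii: list[float], edge_length: float) -> Mesh:
    """Concentric-annulus disk mesh; ``radii`` strictly decreasing, outermost first.

    Each node is labelled by the innermost annulus containing it: label 0 for
    the outer ring, ``len(radii) - 1`` at the centre.  Rings of nodes are
    placed exactly on every interface so regions are mesh-aligned.
    """
    radii = [float(r) for r in radii]
    if not radii or any(r <= 0 for r in radii):
        raise ParameterError("radii must be positive")
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise ParameterError("radii must be strictly decreasing (outermost first)")
    if edge_length <= 0 or edge_length >= radii[0]:
        raise ParameterError("edge_length must be in (0, outer radius)")
    breaks = sorted(radii)
    points, boundary = _disk_points(breaks, edge_length)
    tri = Delaunay(points)
    r = np.linalg.norm(points, axis=1)
    labels = np.zeros(len(points), dtype=np.int64)
    tol = 1e-9 * radii[0]
    for j, rj in enumerate(radii):
        labels[r <= rj + tol] = j
    return Mesh(points, tri.simplices, boundary, labels)


def _barycentric(mesh: Mesh, element: np.ndarray, point: np.ndarray) -> np.ndarray:
    p = mesh.nodes[element]
    T = (p[1:] - p[0]).T
    lam_rest = np.linalg.solve(T, point - p[0])
    return np.concatenate([[1.0 - lam_rest.sum()], lam_rest])


def locate_point(mesh: Mesh, point, tol: float = 1e-9):
    """Find the element containing ``point`` and its barycentric coordinates.

    Points marginally outside the mesh (a boundary optode on the true circle,
    off the polygonal hull by O(h²)) are clipped onto the nearest element as
    long as their most negative barycentric coordinate stays small; truly
    exterior points raise :class:`GeometryError`.
    """
    point = np.asarray(point, dtype=float)
    if point.shape != (mesh.dimension,):
        raise DimensionError("point dimension does not match mesh")
    p0 = mesh.nodes[mesh.elements[:, 0]]
    edges = mesh.nodes[mesh.elements[:, 1:]] - p0[:, None, :]
    # solve per-element for barycentric coords of `point`
    rhs = point[None, :] - p0
    lam_rest = np.linalg.solve(np.swapaxes(edges, 1, 2), rhs[..., None])[..., 0]
    lam0 = 1.0 - lam_rest.sum(axis=1)
    lam = np.column_stack([lam0, lam_rest])
    worst = lam.min(axis=1)
    best = int(np.argmax(worst))
    h = np.abs(edges[best]).max()  # element size, for the clip-distance guard
    if worst[best] < -0.25:
        raise GeometryError(f"point {point} lies outside the mesh")
    w = np.clip(lam[best], 0.0, None)
    w = w / w.sum()
    # reject points that are genuinely far outside (clip moved them > h/2)
    moved = np.linalg.norm(w @ mesh.nodes[mesh.elements[best]] - point)
    if moved > 0.5 * h + tol:
        raise GeometryError(f"point {point} lies outside the mesh")
    return best, w


def interpolation_weights(mesh: Mesh, points) -> "np.ndarray":
    """Sparse-friendly (n_points, n_nodes) dense matrix of P1 interpolation
    weights; row p restricted to the element containing point p."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    W = np.zeros((len(points), mesh.n_nodes))
    for i, pt in enumerate(points):
        el, w = locate_point(mesh, pt)
        W[i, mesh.elements[el]] = w
    return W


@dataclass
class OptodeArray:
    """Source and detector geometry plus the measured link table.

    ``interior_source_points`` hold each source moved one transport length
    (1/μs′ of the background) along the inward normal — the standard CW
    convention for representing a collimated surface source as an isotropic
    point source.
    """

    source_positions: np.ndarray
    detector_positions: np.ndarray
    link_table: np.ndarray  # (n_links, 2) [source_idx, detector_idx], 0-based
    interior_source_points: np.ndarray

    def __post_init__(self) -> None:
        self.source_positions = np.atleast_2d(np.asarray(self.source_positions, float))
        self.detector_positions = np.atleast_2d(
            np.asarray(self.detector_positions, float)
        )
        self.link_table = np.asarray(self.link_table, dtype=np.int64)
        self.interior_source_points = np.atleast_2d(
            np.asarray(self.interior_source_points, float)
        )
        if self.link_table.size and (
            self.link_table[:, 0].max() >= len(self.source_positions)
            or self.link_table[:, 1].max() >= len(self.detector_positions)
            or self.link_table.min() < 0
        ):
            raise DimensionError("link table index out of range")

    @property
    def n_links(self) -> int:
        return len(self.link_table)

    def link_distances(self) -> np.ndarray:
        """Euclidean source-detector separation per link (mm)."""
        s = self.source_positions[self.link_table[:, 0]]
        d = self.detector_positions[self.link_table[:, 1]]
        return np.linalg.norm(s - d, axis=1)


def build_link_table(
    sources: np.ndarray, detectors: np.ndarray, exclude_colocated: bool = True
) -> np.ndarray:
    """All source-detector pairs, optionally dropping co-located ones."""
    sources = np.atleast_2d(sources)
    detectors = np.atleast_2d(detectors)
    si, di = np.meshgrid(
        np.arange(len(sources)), np.arange(len(detectors)), indexing="ij"
    )
    links = np.column_stack([si.ravel(), di.ravel()])
    if exclude_colocated:
        dist = np.linalg.norm(
            sources[links[:, 0]] - detectors[links[:, 1]], axis=1
        )
        links = links[dist > 1e-9]
    return links


def position_optodes(
    mesh: Mesh,
    n_sources: int,
    n_detectors: int,
    layout: str = "ring",
    musp_background: float = 1.0,
) -> OptodeArray:
    """Place optodes on the boundary of a 2D disk mesh.

    ``ring``: sources and detectors equally spaced over the full circle
    (co-located pairs are excluded from the link table).
    ``grid-top-bottom``: sources spread over the lower semicircle and
    detectors over the upper one, a planar stand-in for transmission
    geometries with a source grid below and a detector grid above.
    """
    if n_sources < 1 or n_detectors < 1:
        raise ParameterError("optode counts must be >= 1")
    if musp_background <= 0:
        raise ParameterError("musp_background must be positive")
    if mesh.n_nodes == 0:
        raise GeometryError("mesh is empty")
    if mesh.dimension != 2:
        raise ParameterError(f"layout '{layout}' requires a 2D mesh")
    radius = float(np.linalg.norm(mesh.nodes[mesh.boundary], axis=1).max())
    if layout == "ring":
        src = _ring_points(radius, n_sources)
        det = _ring_points(radius, n_detectors)
    elif layout == "grid-top-bottom":
        ts = np.pi + np.pi * (np.arange(n_sources) + 0.5) / n_sources
        td = np.pi * (np.arange(n_detectors) + 0.5) / n_detectors
        src = radius * np.column_stack([np.cos(ts), np.sin(ts)])
        det = radius * np.column_stack([np.cos(td), np.sin(td)])
    else:
        raise ParameterError(f"unknown layout '{layout}'")
    depth = 1.0 / musp_background
    interior = src * (1.0 - depth / radius)
    links = build_link_table(src, det)
    return OptodeArray(src, det, links, interior)
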