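"""Triangulated single-cell geometry.

A cell is a closed triangulated membrane of particles plus one intracellular
particle (a stand-in for the microtubule-organising centre).  The membrane is
laid out as a prism-like solid of revolution: horizontal rings of 8 particles
stacked along the apico-basal axis, capped by an apical and a basal pole
particle.  Two mesh families are supported:

* ``hex_ring`` — circular rings (34 particles = 4 rings + 2 poles),
* ``square``  — rounded-square rings (42 particles = 5 rings + 2 poles).

All coordinates are dimensionless model units; there is no unit conversion
anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

APICAL = "apical"
BASAL = "basal"
LATERAL = "lateral"
NUCLEUS = "nucleus"

RING_SIZE = 8

#: (n_vertices, basis) pairs used in the experiments; any (8k+2, basis) works.
CANONICAL_MESHES = ((34, "hex_ring"), (42, "square"))


@dataclass(frozen=True)
class CellShapeSpec:
    """Target shape of an epithelial cell.

    Parameters
    ----------
    apical_radius:
        Radius ``R`` of the apical disc (circumradius of the apical ring).
    height:
        Apico-basal height ``h``.
    n_vertices:
        Number of membrane particles; must be ``8 * n_rings + 2``.
    basis:
        Ring cross-section family, ``"hex_ring"`` (circular) or ``"square"``
        (rounded square).
    """

    apical_radius: float = 0.5
    height: float = 2.0
    n_vertices: int = 34
    basis: str = "hex_ring"

    def __post_init__(self) -> None:
        if not self.apical_radius > 0:
            raise ValueError(f"apical_radius must be > 0, got {self.apical_radius}")
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if self.basis not in ("hex_ring", "square"):
            raise ValueError(
                f"unsupported basis {self.basis!r}; supported meshes: "
                f"{CANONICAL_MESHES} and any (8k+2, hex_ring|square), k >= 1"
            )
        if self.n_vertices < 8 + 2 or (self.n_vertices - 2) % RING_SIZE != 0:
            raise ValueError(
                f"unsupported n_vertices={self.n_vertices}; membrane must have "
                f"8k+2 particles (k >= 1 rings), e.g. {CANONICAL_MESHES}"
            )

    @property
    def n_rings(self) -> int:
        return (self.n_vertices - 2) // RING_SIZE

    @property
    def aspect_ratio(self) -> float:
        """height / width = h / (2R)."""
        return self.height / (2.0 * self.apical_radius)


@dataclass
class CellMesh:
    """One cell's membrane particles, triangulation and intracellular particle.

    ``positions`` are world coordinates ordered
    ``[apical pole, ring 0 (apical), ..., ring n-1 (basal), basal pole]``.
    """

    spec: CellShapeSpec
    positions: np.ndarray          # (n_vertices, 3)
    triangles: np.ndarray          # (n_faces, 3) int, local indices
    labels: np.ndarray             # (n_vertices,) str in {apical, basal, lateral}
    nucleus_position: np.ndarray   # (3,)
    polarity: np.ndarray           # unit apical -> basal
    center: np.ndarray = field(default=None)  # construction center

    @property
    def n_particles(self) -> int:
        return len(self.positions)


def _ring_radii(spec: CellShapeSpec, angles: np.ndarray, radius: float) -> np.ndarray:
    """Radial distance of ring points for the given basis."""
    if spec.basis == "square":
        # superellipse (p = 4): square with rounded corners
        c, s = np.abs(np.cos(angles)), np.abs(np.sin(angles))
        return radius * (c ** 4 + s ** 4) ** (-0.25)
    return np.full_like(angles, radius)


def layout_local(spec: CellShapeSpec, apical_radius: float | None = None) -> np.ndarray:
    """Canonical membrane layout in the cell frame.

    The frame has the polarity axis along +z, the apical pole at ``-h/2`` and
    the basal pole at ``+h/2``; the cell is centered on the origin.
    ``apical_radius`` overrides the radius of the apical ring only (used to
    construct apical-constriction target geometries).
    """
    n_rings = spec.n_rings
    h, R = spec.height, spec.apical_radius
    r_api = R if apical_radius is None else apical_radius
    # 22.5 deg offset so ring flats (not vertices) face axis-aligned neighbours
    angles = 2.0 * np.pi * (np.arange(RING_SIZE) + 0.5) / RING_SIZE
    zs = np.linspace(-h / 2.0, h / 2.0, n_rings)
    coords = np.empty((spec.n_vertices, 3))
    coords[0] = (0.0, 0.0, -h / 2.0)  # apical pole
    for r, z in enumerate(zs):
        rad = _ring_radii(spec, angles, r_api if r == 0 else R)
        block = coords[1 + r * RING_SIZE: 1 + (r + 1) * RING_SIZE]
        block[:, 0] = rad * np.cos(angles)
        block[:, 1] = rad * np.sin(angles)
        block[:, 2] = z
    coords[-1] = (0.0, 0.0, h / 2.0)  # basal pole
    return coords


def layout_labels(spec: CellShapeSpec) -> np.ndarray:
    labels = np.full(spec.n_vertices, LATERAL, dtype="<U7")
    labels[0] = APICAL
    labels[1: 1 + RING_SIZE] = APICAL
    labels[-1 - RING_SIZE: -1] = BASAL
    labels[-1] = BASAL
    return labels


def layout_triangles(spec: CellShapeSpec) -> np.ndarray:
    """Closed genus-0 triangulation: two pole fans plus ring-to-ring strips."""
    n_rings = spec.n_rings
    tris = []
    ring = lambda r, k: 1 + r * RING_SIZE + (k % RING_SIZE)  # noqa: E731
    for k in range(RING_SIZE):  # apical fan
        tris.append((0, ring(0, k + 1), ring(0, k)))
    for r in range(n_rings - 1):  # lateral strips
        for k in range(RING_SIZE):
            tris.append((ring(r, k), ring(r, k + 1), ring(r + 1, k)))
            tris.append((ring(r, k + 1), ring(r + 1, k + 1), ring(r + 1, k)))
    last = n_rings - 1
    for k in range(RING_SIZE):  # basal fan
        tris.append((spec.n_vertices - 1, ring(last, k), ring(last, k + 1)))
    return np.asarray(tris, dtype=np.int64)


def _rotation_to(polarity: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to ``polarity`` (Rodrigues)."""
    p = np.asarray(polarity, dtype=float)
    norm = np.linalg.norm(p)
    if norm == 0:
        raise ValueError("polarity must be a non-zero vector")
    p = p / norm
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, p)
    c = float(np.dot(z, p))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # antiparallel: flip about x
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def build_epithelial_cell(
    spec: CellShapeSpec,
    center: np.ndarray = (0.0, 0.0, 0.0),
    polarity: np.ndarray = (0.0, 0.0, 1.0),
    apical_radius: float | None = None,
) -> CellMesh:
    """Construct a closed prism-like epithelial cell.

    The apical disc (radius ``R``) sits at ``center - polarity * h/2``, the
    basal disc at ``center + polarity * h/2``; the intracellular particle is
    placed at the membrane centroid.  ``apical_radius`` overrides the apical
    ring radius, building the cell directly in an apically constricted rest
    shape (used by the rosette builder).  Deterministic for fixed inputs.
    """
    center = np.asarray(center, dtype=float)
    rot = _rotation_to(polarity)
    polarity = rot @ np.array([0.0, 0.0, 1.0])
    local = layout_local(spec, apical_radius=apical_radius)
    positions = center + local @ rot.T
    nucleus = positions.mean(axis=0)
    return CellMesh(
        spec=spec,
        positions=positions,
        triangles=layout_triangles(spec),
        labels=layout_labels(spec),
        nucleus_position=nucleus,
        polarity=polarity,
        center=center,
    )


def internal_neighbors(mesh: CellMesh) -> np.ndarray:
    """Symmetric membrane adjacency: i ~ j iff some triangle contains both.

    Returns the unique edge list as an ``(n_edges, 2)`` array with i < j.
    """
    t = mesh.triangles
    edges = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
    edges = np.sort(edges, axis=1)
    return np.unique(edges, axis=0)


def mesh_edges(triangles: np.ndarray) -> np.ndarray:
    """Unique undirected edges of a triangle list."""
    edges = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [0, 2]]])
    return np.unique(np.sort(edges, axis=1), axis=0)


def euler_characteristic(mesh: CellMesh) -> int:
    v = mesh.n_particles
    e = len(mesh_edges(mesh.triangles))
    f = len(mesh.triangles)
    return v - e + f


def is_closed_manifold(mesh: CellMesh) -> bool:
    """Every edge shared by exactly two triangles and every vertex used."""
    t = mesh.triangles
    edges = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(counts == 2):
        return False
    return len(np.unique(t)) == mesh.n_particles


def triangle_areas(positions: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = positions[triangles[:, 0]]
    b = positions[triangles[:, 1]]
    c = positions[triangles[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def face_area(mesh: CellMesh, label: str) -> float:
    """Total area of triangles whose three vertices all carry ``label``."""
    if label not in mesh.labels:
        raise ValueError(
            f"label {label!r} absent from mesh; present: {sorted(set(mesh.labels))}"
        )
    keep = np.all(np.isin(mesh.triangles, np.flatnonzero(mesh.labels == label)), axis=1)
    if not np.any(keep):
        return 0.0
    return float(triangle_areas(mesh.positions, mesh.triangles[keep]).sum())


def measured_polarity(positions: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Unit vector from the apical-face centroid to the basal-face centroid."""
    a = positions[labels == APICAL].mean(axis=0)
    b = positions[labels == BASAL].mean(axis=0)
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("degenerate cell: apical and basal centroids coincide")
    return d / n
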