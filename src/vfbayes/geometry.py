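"""Three-layer M5-style vocal-fold cross-section and deterministic triangulation.

The cross-section lives in the medial-lateral (x) / inferior-superior (z)
plane.  The coordinate origin sits at the inferior-lateral corner of the
fold: x increases medially so the glottal midline (plane of left-right
symmetry, and the contact plane during collision) is at ``x = height_ml``.
With the default dimensions the midline is at 8.4 mm, which makes the
"no medial compression" pre-stress parameter ``x0 = 8.4 mm`` literal.

The fold profile is a closed polygon built from four boundary chains:

* the lateral wall (x = 0), bonded to the mount -- fixed;
* the inferior attachment face (z = 0) -- fixed;
* the superior attachment face (z = depth_is) -- fixed;
* the medial/glottal surface running inferior -> superior -- free, loaded
  by the aerodynamic pressure.

The medial chain defaults to an M5-like shape (inferior ramp at ~46 deg,
rounded glottal entrance, short vertical medial face on the midline,
rounded superior edge).  The published M5 coordinates are not reproduced
here; the chain is a configurable polyline stored in coordinates
normalised by (height_ml, depth_is) so that scaling the dimensions scales
the profile affinely.

Meshing is a deterministic structured scheme: a transfinite (Coons) blend
between the lateral wall and the medial chain produces a quad grid that is
split into triangles.  Grid columns are allocated to the three histological
layers (body / ligament / cover) so no element ever straddles a layer
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VFGeometry",
    "TriMesh",
    "InvalidGeometryError",
    "RefinementError",
    "build_default_geometry",
    "triangulate",
    "polygon_area",
    "write_mesh_txt",
    "read_mesh_txt",
    "write_mesh_gmsh",
]

LAYERS = ("body", "ligament", "cover")

#: Medial-surface polyline of the default profile, normalised by
#: (height_ml, depth_is), ordered inferior -> superior.  Read
#: qualitatively off the M5 cross-section: attachment edge, inferior
#: ramp, rounded entrance, vertical medial face on the midline,
#: rounded superior edge, superior attachment edge.
DEFAULT_MEDIAL_CHAIN = np.array(
    [
        (0.2381, 0.0000),
        (0.8810, 0.5328),
        (0.9643, 0.6470),
        (0.9821, 0.7231),
        (1.0000, 0.8659),
        (0.9679, 0.9324),
        (0.8810, 0.9705),
        (0.4762, 1.0000),
    ]
)

#: Fraction of the wall-to-surface span occupied by the cover (SLP +
#: epithelium merged) and ligament layers.  Inputs, not estimates: the
#: layered structure is treated as known.
DEFAULT_COVER_FRAC = 0.14
DEFAULT_LIGAMENT_FRAC = 0.16


class InvalidGeometryError(ValueError):
    """Raised for non-positive dimensions or a degenerate medial chain."""


class RefinementError(ValueError):
    """Raised when a layer band is too thin for the requested resolution."""


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as an (n, 2) vertex array."""
    x, z = np.asarray(poly, float).T
    return 0.5 * abs(np.dot(x, np.roll(z, -1)) - np.dot(z, np.roll(x, -1)))


@dataclass
class VFGeometry:
    """Three-layer vocal-fold cross-section (all lengths in mm)."""

    depth_is: float = 10.51  # inferior-superior extent (z)
    height_ml: float = 8.40  # lateral wall -> medial surface (x)
    length_ap: float = 17.00  # anterior-posterior glottal length l_gl
    #: medial surface polyline in mm, inferior -> superior
    medial_chain: np.ndarray = field(default=None)  # type: ignore[assignment]
    cover_frac: float = DEFAULT_COVER_FRAC
    ligament_frac: float = DEFAULT_LIGAMENT_FRAC

    def __post_init__(self) -> None:
        if min(self.depth_is, self.height_ml, self.length_ap) <= 0:
            raise InvalidGeometryError("all dimensions must be positive")
        if self.medial_chain is None:
            scale = np.array([self.height_ml, self.depth_is])
            self.medial_chain = DEFAULT_MEDIAL_CHAIN * scale
        self.medial_chain = np.asarray(self.medial_chain, float)
        z = self.medial_chain[:, 1]
        if not (np.all(np.diff(z) > 0) or self.medial_chain.shape[0] < 2):
            raise InvalidGeometryError("medial chain must ascend monotonically in z")
        if abs(z[0]) > 1e-12 or abs(z[-1] - self.depth_is) > 1e-9:
            raise InvalidGeometryError("medial chain must span z = 0 .. depth_is")
        if not 0 < self.cover_frac < 1 or not 0 < self.ligament_frac < 1:
            raise InvalidGeometryError("layer fractions must lie in (0, 1)")
        if self.cover_frac + self.ligament_frac >= 1:
            raise InvalidGeometryError("cover + ligament fractions must be < 1")

    # -- derived quantities -------------------------------------------------

    @property
    def midline_x(self) -> float:
        """x-coordinate of the glottal midline / contact plane."""
        return self.height_ml

    @property
    def profile(self) -> np.ndarray:
        """Closed profile polygon (counter-clockwise, first vertex not repeated)."""
        chain = self.medial_chain
        return np.vstack([[0.0, 0.0], chain, [0.0, self.depth_is]])

    def _coons(self, u, v):
        """Transfinite blend: straight segments from the lateral wall to the
        medial chain (arc-length parameterised).  ``u``/``v`` broadcast."""
        u = np.asarray(u, float)
        v = np.asarray(v, float)
        chain = _resample_chain(self.medial_chain, v)
        wall = np.stack([np.zeros_like(v), v * self.depth_is], axis=-1)
        return (1.0 - u)[..., None] * wall + u[..., None] * chain

    @property
    def layer_polylines(self) -> dict[str, np.ndarray]:
        """Closed polygon per layer; simple, non-overlapping, union = profile.

        Layers are bands between transfinite isolines u = u1 (body|ligament)
        and u = u2 (ligament|cover), sampled at a fine fixed resolution.
        """
        u1 = 1.0 - self.cover_frac - self.ligament_frac
        u2 = 1.0 - self.cover_frac
        v = _pinned_param(self.medial_chain, 160)
        iso = {u: self._coons(np.full_like(v, u), v) for u in (0.0, u1, u2, 1.0)}
        out = {}
        for name, (ua, ub) in zip(LAYERS, ((0.0, u1), (u1, u2), (u2, 1.0))):
            out[name] = np.vstack([iso[ua], iso[ub][::-1]])
        return out


@dataclass
class TriMesh:
    """Linear-triangle mesh of a :class:`VFGeometry` (coordinates in mm)."""

    node_coords: np.ndarray  # (N, 2)
    triangles: np.ndarray  # (n_el, 3) node indices, positively oriented
    layer_of_element: np.ndarray  # (n_el,) index into LAYERS
    fixed_nodes: np.ndarray  # node ids on the bonded faces
    free_surface: np.ndarray  # ordered node chain, inferior -> superior
    geometry: VFGeometry | None = None
    #: free_surface plus its two fixed end nodes: the full station chain
    #: seen by the Bernoulli flow model
    surface_chain: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def element_areas(self) -> np.ndarray:
        p = self.node_coords[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])


# ---------------------------------------------------------------------------
# construction


def build_default_geometry(
    depth_is: float = 10.51,
    height_ml: float = 8.40,
    length_ap: float = 17.00,
    medial_chain: np.ndarray | None = None,
    cover_frac: float = DEFAULT_COVER_FRAC,
    ligament_frac: float = DEFAULT_LIGAMENT_FRAC,
) -> VFGeometry:
    """Build the M5-based three-layer cross-section.

    Raises :class:`InvalidGeometryError` for non-positive dimensions.
    """
    return VFGeometry(
        depth_is=depth_is,
        height_ml=height_ml,
        length_ap=length_ap,
        medial_chain=medial_chain,
        cover_frac=cover_frac,
        ligament_frac=ligament_frac,
    )


def _chain_arclen(chain: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(chain, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s / s[-1]


def _resample_chain(chain: np.ndarray, v) -> np.ndarray:
    """Point(s) on the polyline at normalised arc length ``v``."""
    s = _chain_arclen(chain)
    x = np.interp(v, s, chain[:, 0])
    z = np.interp(v, s, chain[:, 1])
    return np.stack([x, z], axis=-1)


def _pinned_param(chain: np.ndarray, n_rows: int) -> np.ndarray:
    """Arc-length parameter values for ``n_rows`` segments that include every
    original chain vertex (so the discrete boundary equals the polyline and
    triangle areas sum exactly to the profile area)."""
    s = _chain_arclen(chain)
    n_seg = len(s) - 1
    if n_rows < n_seg:
        raise RefinementError(
            f"need at least {n_seg} rows to honour the medial chain vertices"
        )
    lengths = np.diff(s)
    alloc = np.maximum(1, np.floor(lengths * n_rows).astype(int))
    # largest-remainder top-up to hit n_rows exactly (deterministic ties by index)
    while alloc.sum() < n_rows:
        frac = lengths * n_rows - alloc
        alloc[int(np.argmax(frac))] += 1
    while alloc.sum() > n_rows:
        over = np.where(alloc > 1, alloc - lengths * n_rows, -np.inf)
        alloc[int(np.argmax(over))] -= 1
    vs = [np.linspace(s[i], s[i + 1], alloc[i] + 1)[:-1] for i in range(n_seg)]
    return np.concatenate(vs + [[1.0]])


def _layer_columns(n_cols: int, cover_frac: float, ligament_frac: float):
    """u break-points for (body, ligament, cover) column bands."""
    n_cvr = max(1, round(cover_frac * n_cols))
    n_lig = max(1, round(ligament_frac * n_cols))
    n_bdy = n_cols - n_cvr - n_lig
    if n_bdy < 1:
        raise RefinementError("layer bands too thin for the requested resolution")
    u1 = 1.0 - cover_frac - ligament_frac
    u2 = 1.0 - cover_frac
    u = np.concatenate(
        [
            np.linspace(0.0, u1, n_bdy + 1)[:-1],
            np.linspace(u1, u2, n_lig + 1)[:-1],
            np.linspace(u2, 1.0, n_cvr + 1),
        ]
    )
    labels = np.repeat([0, 1, 2], [n_bdy, n_lig, n_cvr])
    return u, labels


def triangulate(
    geom: VFGeometry, target_elements: int = 205, fixation: str = "wall"
) -> TriMesh:
    """Deterministic structured triangulation with per-element layer labels.

    The element count lands within 15% of ``target_elements``.  Re-meshing
    with the same arguments is bit-identical (no randomised insertion).

    ``fixation`` chooses the clamped boundary: ``"wall"`` (default) bonds
    only the lateral wall -- the tracheal-wall interface -- leaving the
    inferior and superior faces traction-free, which preserves the
    rotational compliance the fold needs to flutter; ``"wall+faces"``
    additionally clamps both attachment faces (a much stiffer mount that
    suppresses self-oscillation at phonatory pressures).
    """
    if fixation not in ("wall", "wall+faces"):
        raise ValueError("fixation must be 'wall' or 'wall+faces'")
    if target_elements < 20:
        raise RefinementError("target_elements must be at least 20")
    # aspect heuristic: columns span wall->surface, rows run along the chain
    chain_len = np.linalg.norm(np.diff(geom.medial_chain, axis=0), axis=1).sum()
    span = 0.5 * (geom.height_ml + geom.medial_chain[:, 0].mean())
    aspect = span / chain_len
    n_quads = target_elements / 2.0
    n_cols = max(3, round(np.sqrt(n_quads * aspect)))
    n_rows = max(3, round(n_quads / n_cols))
    u, labels = _layer_columns(n_cols, geom.cover_frac, geom.ligament_frac)
    n_cols = len(u) - 1
    v = _pinned_param(geom.medial_chain, n_rows)
    n_rows = len(v) - 1

    uu, vv = np.meshgrid(u, v, indexing="ij")
    nodes = geom._coons(uu, vv).reshape(-1, 2)  # node id = i * (n_rows+1) + j

    def nid(i, j):
        return i * (n_rows + 1) + j

    tris, tri_layer = [], []
    for i in range(n_cols):
        for j in range(n_rows):
            a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
            # split along the (a, c) diagonal, counter-clockwise
            tris.append((a, b, c))
            tris.append((a, c, d))
            tri_layer += [labels[i], labels[i]]
    triangles = np.array(tris, dtype=np.int64)
    tri_layer = np.array(tri_layer, dtype=np.int64)

    mesh = TriMesh(
        node_coords=nodes,
        triangles=triangles,
        layer_of_element=tri_layer,
        fixed_nodes=np.empty(0, np.int64),
        free_surface=np.empty(0, np.int64),
        geometry=geom,
    )
    if np.any(mesh.element_areas() <= 0):
        raise RefinementError("degenerate element in transfinite grid")

    wall = [nid(0, j) for j in range(n_rows + 1)]
    bottom = [nid(i, 0) for i in range(1, n_cols + 1)]
    top = [nid(i, n_rows) for i in range(1, n_cols + 1)]
    if fixation == "wall+faces":
        mesh.fixed_nodes = np.unique(np.array(wall + bottom + top, np.int64))
    else:
        mesh.fixed_nodes = np.unique(np.array(wall, np.int64))
    # free surface: medial column, endpoints belong to the attachment faces
    mesh.free_surface = np.array(
        [nid(n_cols, j) for j in range(1, n_rows)], np.int64
    )
    mesh.surface_chain = np.array(
        [nid(n_cols, j) for j in range(n_rows + 1)], np.int64
    )
    if not 0.85 * target_elements <= mesh.n_elements <= 1.15 * target_elements:
        raise RefinementError(
            f"structured grid gives {mesh.n_elements} elements for "
            f"target {target_elements}"
        )
    return mesh


# ---------------------------------------------------------------------------
# plain-text persistence


def write_mesh_txt(mesh: TriMesh, path) -> None:
    """Node/element text format: `n <id> <x> <z>` and `e <id> <n1> <n2> <n3>
    <layer>` lines plus `fixed`/`free` node-set lines."""
    with open(path, "w") as fh:
        fh.write(f"# vfbayes mesh: {mesh.n_nodes} nodes {mesh.n_elements} elements\n")
        for i, (x, z) in enumerate(mesh.node_coords):
            fh.write(f"n {i} {x:.12g} {z:.12g}\n")
        for e, (t, lay) in enumerate(zip(mesh.triangles, mesh.layer_of_element)):
            fh.write(f"e {e} {t[0]} {t[1]} {t[2]} {LAYERS[lay]}\n")
        fh.write("fixed " + " ".join(map(str, mesh.fixed_nodes)) + "\n")
        fh.write("free " + " ".join(map(str, mesh.free_surface)) + "\n")
        if mesh.surface_chain is not None:
            fh.write("chain " + " ".join(map(str, mesh.surface_chain)) + "\n")


def read_mesh_txt(path) -> TriMesh:
    nodes, tris, layers = [], [], []
    fixed = free = chain = None
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok or tok[0] == "#":
                continue
            if tok[0] == "n":
                nodes.append((float(tok[2]), float(tok[3])))
            elif tok[0] == "e":
                tris.append(tuple(map(int, tok[2:5])))
                layers.append(LAYERS.index(tok[5]))
            elif tok[0] == "fixed":
                fixed = np.array(list(map(int, tok[1:])), np.int64)
            elif tok[0] == "free":
                free = np.array(list(map(int, tok[1:])), np.int64)
            elif tok[0] == "chain":
                chain = np.array(list(map(int, tok[1:])), np.int64)
    return TriMesh(
        node_coords=np.array(nodes, float),
        triangles=np.array(tris, np.int64),
        layer_of_element=np.array(layers, np.int64),
        fixed_nodes=fixed,
        free_surface=free,
        surface_chain=chain,
    )


def write_mesh_gmsh(mesh: TriMesh, path) -> None:
    """Gmsh .msh v2.2 ASCII export (physical tag = layer index + 1)."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
        fh.write(f"{mesh.n_nodes}\n")
        for i, (x, z) in enumerate(mesh.node_coords, start=1):
            fh.write(f"{i} {x:.12g} {z:.12g} 0\n")
        fh.write("$EndNodes\n$Elements\n")
        fh.write(f"{mesh.n_elements}\n")
        for e, (t, lay) in enumerate(zip(mesh.triangles, mesh.layer_of_element), 1):
            fh.write(f"{e} 2 2 {lay + 1} {lay + 1} {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
        fh.write("$EndElements\n")
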