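"""Idealized RVOT geometry, transannular patch region and device profile.

The patient-specific segmented anatomy is replaced by a parametric tube of
wall thickness H (default 1.5 mm) whose inner reference radius varies axially
(a smooth flare-waist-flare curve by default, so that the device contact zone
impinges the wall).  The tube carries a quad surface mesh on its inner
surface, an extruded layered hexahedral solid mesh, and a per-station
circumferential sector decomposition carrying material labels for the
patch-heterogeneity studies.

Coordinates: right-handed (radial, circumferential, axial) local frame at each
station; the axial coordinate z increases distal -> proximal; angles in
radians.  The tube ends are open (the physical vessel ends are fixed; caps are
irrelevant to the per-station surrogate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryError",
    "RadiusProfile",
    "constant_profile",
    "waist_profile",
    "VesselGeometry",
    "PatchRegion",
    "StentSpec",
    "make_rvot_tube",
    "embed_patch",
    "make_stent_profile",
    "patch_surface_area",
    "write_vtk",
]

VESSEL_MATERIAL_ID = 0
PATCH_MATERIAL_ID = 1

#: material-id integers used in mesh exports
MATERIAL_IDS = {"vessel": VESSEL_MATERIAL_ID, "patch": PATCH_MATERIAL_ID}


class GeometryError(ValueError):
    """Raised for invalid geometric input (non-positive radius, patch out of extent...)."""


@dataclass(frozen=True)
class RadiusProfile:
    """Parametric axial inner-radius function R_i(z) in mm.

    kind "constant": R(z) = radius.
    kind "waist":    R(z) = r_flare - (r_flare - r_waist) * exp(-((z - center)/width)^2),
    a smooth flare-waist-flare curve, monotone on each side of the waist.
    """

    kind: str
    params: dict

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "constant":
            return np.full_like(z, float(self.params["radius"]))
        if self.kind == "waist":
            rf = float(self.params["r_flare"])
            rw = float(self.params["r_waist"])
            c = float(self.params["center"])
            w = float(self.params["width"])
            return rf - (rf - rw) * np.exp(-(((z - c) / w) ** 2))
        raise GeometryError(f"unknown radius profile kind {self.kind!r}")


def constant_profile(radius: float) -> RadiusProfile:
    return RadiusProfile("constant", {"radius": radius})


def waist_profile(r_flare: float, r_waist: float, center: float, width: float) -> RadiusProfile:
    return RadiusProfile("waist", {"r_flare": r_flare, "r_waist": r_waist,
                                   "center": center, "width": width})


@dataclass(frozen=True)
class PatchRegion:
    """Diamond transannular patch in unrolled surface coordinates.

    The long diagonal d1 runs along the vessel axis (v = z), the short
    diagonal d2 along the circumferential arc length (u = R * theta, with R
    the mid-wall radius).  Membership:

        |v - v0| / (d1/2) + |u - u0| / (d2/2) <= 1.

    The ``position`` label records where the patch sits relative to the
    device: position 1 distal, position 2 proximal.
    """

    position: str = "position_1_distal"
    d1: float = 30.0
    d2: float = 20.0
    center_z: float = 0.0
    center_theta: float = 0.0

    def __post_init__(self) -> None:
        if self.d1 == 0.0 and self.d2 == 0.0:
            return  # degenerate no-op patch, allowed
        if not (self.d1 >= self.d2 > 0.0):
            raise GeometryError(
                f"patch diagonals must satisfy d1 >= d2 > 0, got d1={self.d1}, d2={self.d2}"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.d1 == 0.0 and self.d2 == 0.0

    def half_arc_width(self, z) -> np.ndarray:
        """Circumferential half-width u(z) of the diamond cross-section (mm)."""
        z = np.asarray(z, dtype=float)
        if self.is_degenerate:
            return np.zeros_like(z)
        s = 1.0 - np.abs(z - self.center_z) / (self.d1 / 2.0)
        return np.where(s > 0.0, s * self.d2 / 2.0, 0.0)

    def contains(self, u, v) -> np.ndarray:
        """Membership of unrolled points (u = arc length from the patch center
        meridian, v = axial coordinate)."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if self.is_degenerate:
            return np.zeros(np.broadcast(u, v).shape, dtype=bool)
        return (np.abs(v - self.center_z) / (self.d1 / 2.0)
                + np.abs(u) / (self.d2 / 2.0)) <= 1.0


@dataclass(frozen=True)
class VesselGeometry:
    """Idealized RVOT tube with surface/solid mesh and sector labels.

    ``sectors[j]`` is a list of ``(arc_fraction, material_name)`` pairs per
    axial station, fractions summing to 1.
    """

    z: np.ndarray                  # (n_z+1,) axial stations, mm, increasing
    R_inner: np.ndarray            # (n_z+1,) reference inner radius, mm
    H: float                       # wall thickness, mm
    n_layers: int
    n_theta: int
    profile: RadiusProfile | None = None
    patches: tuple[PatchRegion, ...] = ()

    def __post_init__(self) -> None:
        if np.any(self.R_inner <= 0.0):
            raise GeometryError("inner radius must be positive everywhere")
        if self.H <= 0.0:
            raise GeometryError("wall thickness must be positive")
        if not 1 <= self.n_layers <= 6:
            raise GeometryError(f"n_layers must be in 1..6, got {self.n_layers}")
        if np.any(np.diff(self.z) <= 0.0):
            raise GeometryError("axial stations must be strictly increasing")

    # -- derived quantities -------------------------------------------------

    @property
    def R_outer(self) -> np.ndarray:
        return self.R_inner + self.H

    @property
    def R_mid(self) -> np.ndarray:
        """Mid-wall radius used for unrolled arc-length coordinates."""
        return self.R_inner + 0.5 * self.H

    @property
    def length(self) -> float:
        return float(self.z[-1] - self.z[0])

    @property
    def theta(self) -> np.ndarray:
        """Circumferential vertex angles (n_theta,), rad."""
        return np.linspace(0.0, 2.0 * math.pi, self.n_theta, endpoint=False)

    def sectors(self, j: int) -> list[tuple[float, str]]:
        """Sector decomposition (arc_fraction, material_name) at station j."""
        Rm = float(self.R_mid[j])
        zj = float(self.z[j])
        frac = 0.0
        for p in self.patches:
            hw = float(p.half_arc_width(zj))
            frac = max(frac, min(2.0 * hw / (2.0 * math.pi * Rm), 1.0))
        if frac <= 0.0:
            return [(1.0, "vessel")]
        if frac >= 1.0:
            raise GeometryError("patch arc spans the full circumference")
        return [(frac, "patch"), (1.0 - frac, "vessel")]

    def all_sectors(self) -> list[list[tuple[float, str]]]:
        return [self.sectors(j) for j in range(len(self.z))]

    # -- surface mesh -------------------------------------------------------

    def surface_vertices(self, radius: np.ndarray | None = None) -> np.ndarray:
        """Inner-surface vertex grid flattened to ((n_z+1)*n_theta, 3)."""
        r = self.R_inner if radius is None else np.asarray(radius, dtype=float)
        th = self.theta
        x = r[:, None] * np.cos(th)[None, :]
        y = r[:, None] * np.sin(th)[None, :]
        zz = np.broadcast_to(self.z[:, None], x.shape)
        return np.stack([x, y, zz], axis=-1).reshape(-1, 3)

    def surface_quads(self) -> np.ndarray:
        """Quad connectivity ((n_z)*(n_theta), 4) with circumferential wrap."""
        nz1, nt = len(self.z), self.n_theta
        i = np.arange(nz1 - 1)
        j = np.arange(nt)
        jj, ii = np.meshgrid(j, i)
        j1 = (jj + 1) % nt
        v00 = ii * nt + jj
        v01 = ii * nt + j1
        v11 = (ii + 1) * nt + j1
        v10 = (ii + 1) * nt + jj
        return np.stack([v00, v01, v11, v10], axis=-1).reshape(-1, 4)

    def quad_material_ids(self) -> np.ndarray:
        """Integer material label per surface quad (patch labeling at quad centers)."""
        nz, nt = len(self.z) - 1, self.n_theta
        zc = 0.5 * (self.z[:-1] + self.z[1:])
        dth = 2.0 * math.pi / nt
        thc = self.theta + 0.5 * dth
        Rm_c = 0.5 * (self.R_mid[:-1] + self.R_mid[1:])
        labels = np.full((nz, nt), VESSEL_MATERIAL_ID, dtype=np.int32)
        for p in self.patches:
            if p.is_degenerate:
                continue
            dtheta = _wrap_angle(thc[None, :] - p.center_theta)
            u = Rm_c[:, None] * dtheta
            v = np.broadcast_to(zc[:, None], u.shape)
            labels[p.contains(u, v)] = PATCH_MATERIAL_ID
        return labels.reshape(-1)

    def surface_trimesh(self, radius: np.ndarray | None = None):
        """Triangulated inner surface as a :class:`trimesh.Trimesh`."""
        import trimesh

        verts = self.surface_vertices(radius)
        quads = self.surface_quads()
        tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
        return trimesh.Trimesh(vertices=verts, faces=tris, process=False)

    def write_surface(self, path: str) -> None:
        """Write the (triangulated) inner surface as STL or PLY (ASCII)."""
        mesh = self.surface_trimesh()
        path = str(path)
        if path.lower().endswith(".stl"):
            mesh.export(path, file_type="stl_ascii")
        elif path.lower().endswith(".ply"):
            mesh.export(path, file_type="ply", encoding="ascii")
        else:
            raise GeometryError(f"unsupported surface format for {path!r} (use .stl or .ply)")

    # -- solid mesh ---------------------------------------------------------

    def solid_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Layered hexahedral solid mesh (vertices, hexes, cell material ids).

        Vertices at radii R_inner + l*H/n_layers, l = 0..n_layers.  Hexes use
        VTK_HEXAHEDRON node ordering.
        """
        nz1, nt, nl = len(self.z), self.n_theta, self.n_layers
        th = self.theta
        radii = self.R_inner[None, :, None] + (
            np.arange(nl + 1)[:, None, None] * (self.H / nl)
        )  # (nl+1, nz1, 1)
        x = radii * np.cos(th)[None, None, :]
        y = radii * np.sin(th)[None, None, :]
        zz = np.broadcast_to(self.z[None, :, None], x.shape)
        verts = np.stack([x, y, zz], axis=-1).reshape(-1, 3)

        def vid(l, i, j):
            return (l * nz1 + i) * nt + (j % nt)

        i = np.arange(nz1 - 1)
        j = np.arange(nt)
        l = np.arange(nl)
        ll, ii, jj = np.meshgrid(l, i, j, indexing="ij")
        hexes = np.stack(
            [
                vid(ll, ii, jj), vid(ll, ii, jj + 1), vid(ll, ii + 1, jj + 1), vid(ll, ii + 1, jj),
                vid(ll + 1, ii, jj), vid(ll + 1, ii, jj + 1), vid(ll + 1, ii + 1, jj + 1), vid(ll + 1, ii + 1, jj),
            ],
            axis=-1,
        ).reshape(-1, 8)
        mat = np.tile(self.quad_material_ids(), nl)
        return verts, hexes, mat

    def solid_cell_volumes(self) -> np.ndarray:
        verts, hexes, _ = self.solid_mesh()
        return hex_volumes(verts[hexes])

    def wall_volume(self) -> float:
        """Reference wall volume by exact annulus integration (mm^3)."""
        area = math.pi * (self.R_outer**2 - self.R_inner**2)
        return float(np.trapezoid(area, self.z))


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return (np.asarray(a) + math.pi) % (2.0 * math.pi) - math.pi


def hex_volumes(cells: np.ndarray) -> np.ndarray:
    """Signed volumes of hexahedra (..., 8, 3) in VTK node order.

    Decomposition into five tetrahedra; exact for planar-faced cells and a
    consistent convergent approximation for the mildly warped cells of the
    extruded tube.
    """
    c = np.asarray(cells, dtype=float)
    tets = [(0, 1, 2, 5), (0, 2, 7, 5), (0, 2, 3, 7), (0, 5, 7, 4), (2, 7, 5, 6)]
    vol = np.zeros(c.shape[:-2])
    for (a, b, d, e) in tets:
        va = c[..., b, :] - c[..., a, :]
        vb = c[..., d, :] - c[..., a, :]
        vc = c[..., e, :] - c[..., a, :]
        vol = vol + np.einsum("...i,...i->...", va, np.cross(vb, vc)) / 6.0
    return vol


def make_rvot_tube(
    profile: RadiusProfile,
    length: float,
    mesh_size: float = 1.5,
    n_layers: int = 4,
    z0: float = 0.0,
    n_theta: int | None = None,
    H: float = 1.5,
) -> VesselGeometry:
    """Generate the idealized RVOT tube.

    Stations are spaced at approximately ``mesh_size`` along z; the
    circumferential vertex count targets the same element size at the mean
    radius.  Raises :class:`GeometryError` if the profile is non-positive
    anywhere.
    """
    if length <= 0.0:
        raise GeometryError("length must be positive")
    if mesh_size <= 0.0:
        raise GeometryError("mesh_size must be positive")
    n_z = max(2, int(round(length / mesh_size)))
    z = z0 + np.linspace(0.0, length, n_z + 1)
    R = np.asarray(profile(z), dtype=float)
    if np.any(R <= 0.0):
        raise GeometryError("radius profile non-positive within the vessel extent")
    if n_theta is None:
        n_theta = max(8, int(round(2.0 * math.pi * float(np.mean(R)) / mesh_size)))
    return VesselGeometry(
        z=z, R_inner=R, H=H, n_layers=n_layers, n_theta=n_theta, profile=profile
    )


def embed_patch(geom: VesselGeometry, patch: PatchRegion) -> VesselGeometry:
    """Embed a diamond patch; idempotent (re-embedding the same patch is a no-op).

    Raises :class:`GeometryError` if the patch is not fully contained in the
    vessel axial extent or would span the full circumference.
    """
    if patch.is_degenerate:
        return geom
    if patch in geom.patches:
        return geom
    lo, hi = patch.center_z - patch.d1 / 2.0, patch.center_z + patch.d1 / 2.0
    if lo < geom.z[0] - 1e-9 or hi > geom.z[-1] + 1e-9:
        raise GeometryError(
            f"patch axial extent [{lo:g}, {hi:g}] outside vessel [{geom.z[0]:g}, {geom.z[-1]:g}]"
        )
    new = replace(geom, patches=geom.patches + (patch,))
    # validate arc coverage at every station (raises if the patch wraps around)
    new.all_sectors()
    return new


def patch_surface_area(geom: VesselGeometry) -> float:
    """Unrolled mid-wall area (mm^2) of the patch-labeled surface quads.

    Converges to the diamond area d1*d2/2 as the mesh is refined.
    """
    labels = geom.quad_material_ids().reshape(len(geom.z) - 1, geom.n_theta)
    dz = np.diff(geom.z)
    Rm_c = 0.5 * (geom.R_mid[:-1] + geom.R_mid[1:])
    du = 2.0 * math.pi * Rm_c / geom.n_theta
    cell_area = np.broadcast_to((dz * du)[:, None], labels.shape)
    return float(cell_area[labels == PATCH_MATERIAL_ID].sum())


@dataclass(frozen=True)
class StentSpec:
    """Self-expanding device profile and radial-force law.

    ``r_free`` is the unconstrained device radius at each device station;
    ``K_s`` the radial stiffness (kPa per unit relative recoil): the device
    exerts pressure ``K_s * max(0, (r_free - r) / r_free)``.  Beam-element
    constants of the physical device are carried as metadata only.
    """

    z: np.ndarray                # device stations (subset of vessel stations), mm
    r_free: np.ndarray           # (len(z),) free radius, mm
    K_s: float = 50.0
    beam_metadata: dict = field(default_factory=lambda: dict())
    oversize_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.r_free <= 0.0):
            raise GeometryError("stent free radius must be positive")
        if self.K_s <= 0.0:
            raise GeometryError("stent radial stiffness must be positive")

    @property
    def length(self) -> float:
        return float(self.z[-1] - self.z[0])

    @property
    def third_boundaries(self) -> tuple[float, float]:
        """Axial boundaries splitting the device into equal thirds (mm)."""
        return (
            float(self.z[0] + self.length / 3.0),
            float(self.z[0] + 2.0 * self.length / 3.0),
        )

    def region_of(self, z) -> np.ndarray:
        """'distal' / 'middle' / 'proximal' label per axial coordinate."""
        b1, b2 = self.third_boundaries
        z = np.asarray(z, dtype=float)
        return np.where(z < b1, "distal", np.where(z < b2, "middle", "proximal"))

    def r_free_at(self, z) -> np.ndarray:
        return np.interp(np.asarray(z, dtype=float), self.z, self.r_free)

    def covers(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return (z >= self.z[0] - 1e-9) & (z <= self.z[-1] + 1e-9)


def make_stent_profile(
    geom: VesselGeometry,
    free_radius: float = 12.5,
    stiffness: float = 50.0,
    length: float | None = None,
    center: float | None = None,
    logger=None,
) -> StentSpec:
    """Constant-free-radius device clipped to the vessel, split into thirds.

    Oversizing (free radius above the local reference radius) is allowed and
    flagged per station.
    """
    if length is None:
        length = min(45.0, geom.length)
    if center is None:
        center = 0.5 * float(geom.z[0] + geom.z[-1])
    lo = max(float(geom.z[0]), center - length / 2.0)
    hi = min(float(geom.z[-1]), center + length / 2.0)
    mask = (geom.z >= lo - 1e-9) & (geom.z <= hi + 1e-9)
    z = geom.z[mask]
    if len(z) < 2:
        raise GeometryError("stent does not overlap the vessel axially")
    r_free = np.full(len(z), float(free_radius))
    oversize = r_free > geom.R_inner[mask]
    if oversize.any() and logger is not None:
        logger.info(
            "stent oversized at %d/%d stations (free radius %.3g mm)",
            int(oversize.sum()), len(z), free_radius,
        )
    return StentSpec(
        z=z, r_free=r_free, K_s=float(stiffness),
        beam_metadata={}, oversize_flags=oversize,
    )


def enclosed_free_volume(stent: StentSpec) -> float:
    """Volume enclosed by the unconstrained device, trapezoidal in z (mm^3)."""
    return float(np.trapezoid(math.pi * stent.r_free**2, stent.z))


# ---------------------------------------------------------------------------
# Mesh checks and I/O
# ---------------------------------------------------------------------------

def edge_face_counts(quads: np.ndarray) -> dict[tuple[int, int], int]:
    """Count how many quads share each undirected edge."""
    counts: dict[tuple[int, int], int] = {}
    for q in np.asarray(quads):
        for a, b in ((q[0], q[1]), (q[1], q[2]), (q[2], q[3]), (q[3], q[0])):
            key = (int(min(a, b)), int(max(a, b)))
            counts[key] = counts.get(key, 0) + 1
    return counts


def check_surface_topology(geom: VesselGeometry) -> dict:
    """Validate the open-tube quad surface.

    Every interior edge must be shared by exactly 2 quads; boundary edges (the
    two end rings) by exactly 1; and the Euler characteristic V - E + F of the
    open tube must be 0 (torus-like).
    """
    quads = geom.surface_quads()
    counts = edge_face_counts(quads)
    n_v = len(geom.z) * geom.n_theta
    n_e = len(counts)
    n_f = len(quads)
    boundary = [e for e, c in counts.items() if c == 1]
    bad = [e for e, c in counts.items() if c not in (1, 2)]
    return {
        "euler_characteristic": n_v - n_e + n_f,
        "n_boundary_edges": len(boundary),
        "n_nonmanifold_edges": len(bad),
        "watertight_interior": len(bad) == 0 and len(boundary) == 2 * geom.n_theta,
    }


def write_vtk(path: str, vertices: np.ndarray, hexes: np.ndarray,
              cell_data: dict[str, np.ndarray] | None = None,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a legacy-ASCII VTK unstructured grid of hexahedral cells.

    ``cell_data`` integer/float arrays are emitted as CELL_DATA scalar fields
    (the solid-mesh export uses an integer field named ``material_id``).
    """
    vertices = np.asarray(vertices, dtype=float)
    hexes = np.asarray(hexes, dtype=int)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("tpvdeploy unstructured grid\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(vertices)} double\n")
        np.savetxt(f, vertices, fmt="%.9g")
        f.write(f"CELLS {len(hexes)} {len(hexes) * 9}\n")
        np.savetxt(f, np.column_stack([np.full(len(hexes), 8), hexes]), fmt="%d")
        f.write(f"CELL_TYPES {len(hexes)}\n")
        np.savetxt(f, np.full(len(hexes), 12, dtype=int), fmt="%d")
        if cell_data:
            f.write(f"CELL_DATA {len(hexes)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                fmt = "%d" if kind == "int" else "%.9g"
                f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr.reshape(-1, 1), fmt=fmt)
        if point_data:
            f.write(f"POINT_DATA {len(vertices)}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(arr, dtype=float).reshape(-1, 1), fmt="%.9g")


def write_solid_vtk(geom: VesselGeometry, path: str) -> None:
    """Export the layered solid mesh with its integer ``material_id`` labels."""
    verts, hexes, mat = geom.solid_mesh()
    write_vtk(path, verts, hexes, cell_data={"material_id": mat})


def load_surface(path: str):
    """Read a surface mesh (STL/PLY, binary or ASCII) as a trimesh.Trimesh."""
    import trimesh

    mesh = trimesh.load(str(path), force="mesh")
    return mesh
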