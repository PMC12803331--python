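"""Reduced-order deployment surrogate: per-station thick-walled-ring equilibrium.

The 3-D contact problem of a self-expanding device opening a vessel is
replaced by independent plane-strain, exactly incompressible thick-walled-ring
inflations at each axial station.  The incompressible radial map is

    r(R) = sqrt(r_i^2 + R^2 - R_i^2),   lam_theta = r/R,  lam_r = R/r,  lam_z = 1,

the wall supports an internal pressure

    p_w(r_i) = int_{r_i}^{r_o} (sigma_tt - sigma_rr) / r dr

(evaluated by Gauss quadrature with one panel per wall layer), and the device
pushes with the linear radial-force law

    p_s(r) = K_s * max(0, (r_free - r) / r_free).

p_w is increasing and p_s decreasing in r_i, so the equilibrium radius is the
unique bracketed root.  Stations whose circumference mixes materials (the
transannular patch) are solved as a composite ring in series: a single hoop
tension shared by all sectors, with the deployed circumference distributed by
per-sector stretches (Sum_s phi_s lam_s = lam_bar).  The homogeneous limit of
the composite path coincides with the single-material path exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import StentSpec, VesselGeometry
from .materials import plane_strain_dev_stress

__all__ = [
    "RingSpec",
    "SectorSolution",
    "RingSolution",
    "DeploymentResult",
    "StationConvergenceError",
    "wall_pressure",
    "stent_pressure",
    "solve_station",
    "deploy",
    "staged_deploy",
]

_PRESSURE_TOL = 1e-8        # kPa, equilibrium residual at convergence
_BRACKET_TOL = 1e-10        # mm, bisection bracket width before Newton polish


class StationConvergenceError(RuntimeError):
    """Raised when a station's equilibrium root cannot be bracketed."""


class OverCompressionError(ValueError):
    """Raised when r_i would make the incompressible map complex."""


@dataclass(frozen=True)
class RingSpec:
    """One axial station of the vessel as a thick-walled ring."""

    R_i: float
    H: float
    sectors: tuple  # ((arc_fraction, material_name), ...)
    n_layers: int = 4
    lam_z: float = 1.0
    z: float = 0.0

    def __post_init__(self) -> None:
        if self.R_i <= 0 or self.H <= 0:
            raise ValueError("ring radius and thickness must be positive")
        if self.lam_z <= 0:
            raise ValueError("axial stretch must be positive")
        total = sum(f for f, _ in self.sectors)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"sector arc fractions must sum to 1, got {total!r}")

    @property
    def R_o(self) -> float:
        return self.R_i + self.H


def _bracketed_root(f, a: float, b: float, fa: float | None = None,
                    fb: float | None = None, xtol: float = _BRACKET_TOL) -> float:
    """Deterministic bisection to ``xtol`` bracket width plus one Newton polish."""
    fa = f(a) if fa is None else fa
    fb = f(b) if fb is None else fb
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if fa * fb > 0.0:
        raise StationConvergenceError(
            f"no sign change in bracket [{a:g}, {b:g}] (f(a)={fa:g}, f(b)={fb:g})"
        )
    while b - a > xtol:
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0.0:
            return m
        if fa * fm < 0.0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    x = 0.5 * (a + b)
    # one Newton step with a central finite-difference slope
    h = max(1e-7 * max(abs(x), 1.0), 1e-12)
    d = (f(x + h) - f(x - h)) / (2.0 * h)
    if d != 0.0:
        x_new = x - f(x) / d
        if a - h <= x_new <= b + h:
            x = x_new
    return x


def _gauss_nodes(r_i: float, R_i: float, R_o: float, n_panels: int, n_gauss: int = 4):
    """Gauss-Legendre nodes/weights over R in [R_i, R_o], one panel per layer."""
    gx, gw = np.polynomial.legendre.leggauss(n_gauss)
    edges = np.linspace(R_i, R_o, n_panels + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * np.diff(edges)
    R = (mid[:, None] + half[:, None] * gx[None, :]).reshape(-1)
    w = (half[:, None] * gw[None, :]).reshape(-1)
    return R, w


def _deformed_radius(R: np.ndarray, r_i: float, R_i: float) -> np.ndarray:
    arg = r_i * r_i + R * R - R_i * R_i
    if np.any(arg <= 0.0):
        raise OverCompressionError(
            f"inner radius {r_i:g} over-compresses the ring (R_i={R_i:g})"
        )
    return np.sqrt(arg)


def wall_pressure(ring: RingSpec, r_i: float, material,
                  tension_only: bool = True, n_gauss: int = 4) -> float:
    """Internal pressure supported by a homogeneous ring at inner radius r_i (kPa).

    ``p_w = int (sigma_tt - sigma_rr)/r dr`` with the deviatoric constitutive
    stresses on the exactly incompressible plane-strain path; Gauss quadrature
    with ``ring.n_layers`` panels.
    """
    if r_i <= 0.0:
        raise ValueError("inner radius must be positive")
    R, w = _gauss_nodes(r_i, ring.R_i, ring.R_o, ring.n_layers, n_gauss)
    r = _deformed_radius(R, r_i, ring.R_i)
    lam = r / R
    t_t, _, t_r = plane_strain_dev_stress(material, lam, tension_only)
    # dr = (R/r) dR  ->  integrand over R is (t_t - t_r)/r * R/r
    return float(np.sum(w * (t_t - t_r) * R / (r * r)))


def stent_pressure(stent: StentSpec, r_i: float, z: float) -> float:
    """Radial pressure exerted by the device at inner radius r_i (kPa).

    Linear recoil law, zero at and beyond the free radius.
    """
    if r_i <= 0.0:
        raise ValueError("inner radius must be positive")
    r_free = float(stent.r_free_at(z))
    return stent.K_s * max(0.0, (r_free - r_i) / r_free)


@dataclass(frozen=True)
class SectorSolution:
    """Through-wall solution of one circumferential sector."""

    material_name: str
    arc_fraction: float
    lam_theta_inner: float       # hoop stretch at the inner surface
    p_wall: float                # sector pressure integral at its stretch (kPa)
    t_nodes: np.ndarray          # distance ratios in [0, 1], inner to outer
    lam_theta: np.ndarray        # hoop stretch at each node
    sigma: np.ndarray            # (n_nodes, 3) full Cauchy diag (tt, zz, rr), kPa
    sigma1: np.ndarray           # 1st principal Cauchy stress per node, kPa
    E1: np.ndarray               # 1st principal Green-Lagrange strain per node


@dataclass(frozen=True)
class RingSolution:
    """Equilibrium of one station: deployed radius and through-wall fields."""

    spec: RingSpec
    r_i: float                   # mean deployed inner radius, mm
    p_wall: float                # wall pressure at equilibrium, kPa
    p_stent: float               # device pressure at equilibrium, kPa
    sectors: tuple               # SectorSolution per sector
    converged: bool
    iterations: int
    contact: bool                # False -> identity solution (device clear of wall)

    @property
    def residual(self) -> float:
        return abs(self.p_wall - self.p_stent)


def _sector_fields(ring: RingSpec, material, lam_inner: float, p_int: float,
                   name: str, frac: float, tension_only: bool) -> SectorSolution:
    """Full through-wall state of a sector at inner hoop stretch ``lam_inner``.

    The radial Cauchy stress follows from equilibrium,
    ``sigma_rr(r) = -p_int + int_{r_i}^{r} (sigma_tt - sigma_rr)/r' dr'``, which
    fixes the pressure left undetermined by the incompressible deviatoric law.
    """
    r_i = lam_inner * ring.R_i
    # layer nodes plus layer midpoints: profiles keep exact endpoints at t=0,1
    # while the field table reads off mid-thickness values directly
    t = np.linspace(0.0, 1.0, 2 * ring.n_layers + 1)
    R = ring.R_i + t * ring.H
    r = _deformed_radius(R, r_i, ring.R_i)
    lam = r / R
    t_t, t_z, t_r = plane_strain_dev_stress(material, lam, tension_only)
    dtt = t_t - t_r  # sigma_tt - sigma_rr, pressure-free
    dzz = t_z - t_r
    # cumulative trapezoid of dtt/r in r from the inner surface
    integrand = dtt / r
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(r))])
    sig_rr = -p_int + cum
    sig_tt = sig_rr + dtt
    sig_zz = sig_rr + dzz
    sigma = np.column_stack([sig_tt, sig_zz, sig_rr])
    sigma1 = sigma.max(axis=1)
    # Green-Lagrange strain diag: ((lam^2-1)/2, 0, (lam^-2 - 1)/2)
    E_diag = np.column_stack([(lam**2 - 1.0) / 2.0, np.zeros_like(lam), (lam**-2 - 1.0) / 2.0])
    E1 = E_diag.max(axis=1)
    return SectorSolution(
        material_name=name, arc_fraction=frac, lam_theta_inner=lam_inner,
        p_wall=p_int, t_nodes=t, lam_theta=lam, sigma=sigma, sigma1=sigma1, E1=E1,
    )


def _identity_solution(ring: RingSpec, materials: dict, tension_only: bool) -> RingSolution:
    sectors = tuple(
        _sector_fields(ring, materials[name], 1.0, 0.0, name, frac, tension_only)
        for frac, name in ring.sectors
    )
    return RingSolution(spec=ring, r_i=ring.R_i, p_wall=0.0, p_stent=0.0,
                        sectors=sectors, converged=True, iterations=0, contact=False)


def solve_station(ring: RingSpec, stent: StentSpec, materials: dict,
                  tension_only: bool = True) -> RingSolution:
    """Equilibrium of one station against the device radial-force law.

    ``materials`` maps sector material names to constitutive parameter objects.
    If the device free radius does not exceed the reference radius the station
    is untouched (identity solution).  Raises
    :class:`StationConvergenceError` when no equilibrium bracket exists.
    """
    r_free = float(stent.r_free_at(ring.z))
    if r_free <= ring.R_i * (1.0 + 1e-12):
        return _identity_solution(ring, materials, tension_only)

    n_eval = 0

    if len(ring.sectors) == 1:
        frac, name = ring.sectors[0]
        mat = materials[name]

        def f(r):
            nonlocal n_eval
            n_eval += 1
            return wall_pressure(ring, r, mat, tension_only) - stent_pressure(stent, r, ring.z)

        r_eq = _bracketed_root(f, ring.R_i, r_free)
        p_w = wall_pressure(ring, r_eq, mat, tension_only)
        p_s = stent_pressure(stent, r_eq, ring.z)
        lam = r_eq / ring.R_i
        sectors = (_sector_fields(ring, mat, lam, p_w, name, frac, tension_only),)
        return RingSolution(spec=ring, r_i=r_eq, p_wall=p_w, p_stent=p_s,
                            sectors=sectors, converged=True, iterations=n_eval,
                            contact=True)

    # --- composite ring: shared hoop tension T = P_s(lam) * lam * R_i -------
    lam_max = r_free / ring.R_i

    def sector_tension(mat, lam):
        nonlocal n_eval
        n_eval += 1
        return wall_pressure(ring, lam * ring.R_i, mat, tension_only) * lam * ring.R_i

    def lam_of_tension(mat, T):
        if T <= 0.0:
            return 1.0
        lo, hi = 1.0, lam_max
        f_hi = sector_tension(mat, hi) - T
        while f_hi < 0.0:  # very soft sector: expand beyond the free radius
            hi *= 1.5
            f_hi = sector_tension(mat, hi) - T
            if hi > 100.0 * lam_max:
                raise StationConvergenceError("sector tension never reaches shared value")
        return _bracketed_root(lambda l: sector_tension(mat, l) - T, lo, hi,
                               fb=f_hi, xtol=1e-12)

    def residual(T):
        lam_bar = sum(frac * lam_of_tension(materials[name], T) for frac, name in ring.sectors)
        r_bar = lam_bar * ring.R_i
        return stent_pressure(stent, r_bar, ring.z) * r_bar - T

    T_lo, f_lo = 0.0, residual(0.0)
    if f_lo <= 0.0:  # device already clear of the wall
        return _identity_solution(ring, materials, tension_only)
    T_hi = f_lo
    f_hi = residual(T_hi)
    while f_hi > 0.0:
        T_hi *= 2.0
        f_hi = residual(T_hi)
        if T_hi > 1e12:
            raise StationConvergenceError("composite tension bracket not found")
    T_eq = _bracketed_root(residual, T_lo, T_hi, fa=f_lo, fb=f_hi,
                           xtol=_BRACKET_TOL * stent.K_s * ring.R_i)

    sectors = []
    lam_bar = 0.0
    for frac, name in ring.sectors:
        mat = materials[name]
        lam_s = lam_of_tension(mat, T_eq)
        p_s_wall = wall_pressure(ring, lam_s * ring.R_i, mat, tension_only)
        sectors.append(_sector_fields(ring, mat, lam_s, p_s_wall, name, frac, tension_only))
        lam_bar += frac * lam_s
    r_bar = lam_bar * ring.R_i
    p_stent = stent_pressure(stent, r_bar, ring.z)
    p_wall_eff = T_eq / r_bar  # effective membrane pressure carried by the composite
    return RingSolution(spec=ring, r_i=r_bar, p_wall=p_wall_eff, p_stent=p_stent,
                        sectors=tuple(sectors), converged=True, iterations=n_eval,
                        contact=True)


@dataclass(frozen=True)
class DeploymentResult:
    """Assembled per-station solutions, field table and deployed geometry."""

    geometry: VesselGeometry
    stent: StentSpec
    stations: tuple              # RingSolution per vessel station (None if failed)
    failed_stations: tuple       # indices of non-converged stations
    field_table: "object"        # pandas.DataFrame, one row per (station, sector, layer)

    @property
    def z(self) -> np.ndarray:
        return self.geometry.z

    @property
    def r_inner_deployed(self) -> np.ndarray:
        """Mean deployed inner radius per station (mm); reference radius where failed."""
        out = self.geometry.R_inner.astype(float).copy()
        for j, sol in enumerate(self.stations):
            if sol is not None:
                out[j] = sol.r_i
        return out

    def station_solution(self, j: int) -> RingSolution:
        sol = self.stations[j]
        if sol is None:
            raise StationConvergenceError(f"station {j} did not converge")
        return sol

    def deployed_surface_trimesh(self):
        """Triangulated deployed inner surface.

        Heterogeneous stations place each vertex at its sector's deployed
        radius (patch arc centered on the patch meridian); circumferential
        repositioning within a station is not modeled.
        """
        radii_grid = np.empty((len(self.z), self.geometry.n_theta))
        th = self.geometry.theta
        for j in range(len(self.z)):
            sol = self.stations[j]
            if sol is None:
                radii_grid[j] = self.geometry.R_inner[j]
                continue
            r_row = np.full(self.geometry.n_theta, sol.r_i)
            if len(sol.sectors) > 1:
                patch = self.geometry.patches[0] if self.geometry.patches else None
                for sec in sol.sectors:
                    if sec.material_name != "patch" or patch is None:
                        continue
                    half = sec.arc_fraction * math.pi
                    d = np.abs(np.angle(np.exp(1j * (th - patch.center_theta))))
                    r_row = np.where(d <= half, sec.lam_theta_inner * self.geometry.R_inner[j],
                                     r_row)
                    vessel = [s for s in sol.sectors if s.material_name != "patch"]
                    if vessel:
                        r_row = np.where(d > half,
                                         vessel[0].lam_theta_inner * self.geometry.R_inner[j],
                                         r_row)
            radii_grid[j] = r_row
        import trimesh

        x = radii_grid * np.cos(th)[None, :]
        y = radii_grid * np.sin(th)[None, :]
        zz = np.broadcast_to(self.z[:, None], x.shape)
        verts = np.stack([x, y, zz], axis=-1).reshape(-1, 3)
        quads = self.geometry.surface_quads()
        tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
        return trimesh.Trimesh(vertices=verts, faces=tris, process=False)

    def write_field_csv(self, path: str, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as f:
            for line in header_lines or []:
                f.write(f"# {line}\n")
            self.field_table.to_csv(f, index=False)

    def write_vtk(self, path: str) -> None:
        """Deployed solid mesh with nodal 1st-principal stress/strain arrays."""
        from .geometry import write_vtk as _write

        geom = self.geometry
        nl = geom.n_layers
        nz1, nt = len(geom.z), geom.n_theta
        # nodal radii and fields from the per-station through-wall node values
        radii = np.empty((nl + 1, nz1))
        s1 = np.zeros((nl + 1, nz1))
        e1 = np.zeros((nl + 1, nz1))
        for j in range(nz1):
            sol = self.stations[j]
            if sol is None or not sol.sectors:
                R = geom.R_inner[j] + np.arange(nl + 1) * geom.H / nl
                radii[:, j] = R
                continue
            main = max(sol.sectors, key=lambda s: s.arc_fraction)
            R = geom.R_inner[j] + main.t_nodes[0::2] * geom.H
            radii[:, j] = main.lam_theta[0::2] * R
            s1[:, j] = main.sigma1[0::2]
            e1[:, j] = main.E1[0::2]
        th = geom.theta
        x = radii[:, :, None] * np.cos(th)[None, None, :]
        y = radii[:, :, None] * np.sin(th)[None, None, :]
        zz = np.broadcast_to(geom.z[None, :, None], x.shape)
        verts = np.stack([x, y, zz], axis=-1).reshape(-1, 3)
        _, hexes, mat = geom.solid_mesh()
        _write(path, verts, hexes, cell_data={"material_id": mat},
               point_data={
                   "stress_1st_principal": np.broadcast_to(
                       s1[:, :, None], (nl + 1, nz1, nt)).reshape(-1),
                   "lagrangian_strain_1st_principal": np.broadcast_to(
                       e1[:, :, None], (nl + 1, nz1, nt)).reshape(-1),
               })


def _station_weights(z: np.ndarray) -> np.ndarray:
    """Trapezoidal axial weights Delta z_j per station."""
    dz = np.diff(z)
    w = np.zeros(len(z))
    w[:-1] += 0.5 * dz
    w[1:] += 0.5 * dz
    return w


def deploy(geom: VesselGeometry, stent: StentSpec, materials: dict,
           tension_only: bool = True, max_failed_fraction: float = 0.10) -> DeploymentResult:
    """Quasi-static deployment endpoint over all stations.

    Builds the volume-weighted field table: one row per station, sector and
    through-wall sample node (layer boundaries plus layer midpoints), each
    carrying its trapezoidal shell-volume weight.  Raises if more than
    ``max_failed_fraction`` of contacted stations fail to converge.
    """
    import pandas as pd

    solutions: list[RingSolution | None] = []
    failed: list[int] = []
    covered = stent.covers(geom.z)
    sector_lists = geom.all_sectors()
    for j, zj in enumerate(geom.z):
        ring = RingSpec(R_i=float(geom.R_inner[j]), H=geom.H,
                        sectors=tuple(sector_lists[j]), n_layers=geom.n_layers,
                        z=float(zj))
        if not covered[j]:
            solutions.append(_identity_solution(ring, materials, tension_only))
            continue
        try:
            solutions.append(solve_station(ring, stent, materials, tension_only))
        except (StationConvergenceError, OverCompressionError):
            solutions.append(None)
            failed.append(j)

    n_contact = int(covered.sum())
    if n_contact and len(failed) / n_contact > max_failed_fraction:
        raise StationConvergenceError(
            f"{len(failed)}/{n_contact} contacted stations failed to converge"
        )

    dz = _station_weights(geom.z)
    rows = []
    for j, sol in enumerate(solutions):
        if sol is None:
            continue
        ring = sol.spec
        for sec in sol.sectors:
            # trapezoidal radial volume weights of 2 pi R dR at the sample
            # nodes (exact for the linear integrand: weights sum to the
            # annulus area); reference volume = deployed volume since J = 1
            R = ring.R_i + sec.t_nodes * ring.H
            seg = 0.5 * (2.0 * math.pi) * (R[1:] + R[:-1]) * np.diff(R)
            w = np.zeros_like(R)
            w[:-1] += 0.5 * seg
            w[1:] += 0.5 * seg
            for k in range(len(R)):
                rows.append((float(geom.z[j]), j, sec.material_name,
                             float(sec.t_nodes[k]),
                             float(sec.arc_fraction * w[k] * dz[j]),
                             float(sec.sigma1[k]), float(sec.E1[k])))
    table = pd.DataFrame(rows, columns=[
        "station_mm", "station_index", "material_id", "distance_ratio",
        "volume_mm3", "stress1_kPa", "strain1",
    ])
    return DeploymentResult(geometry=geom, stent=stent, stations=tuple(solutions),
                            failed_stations=tuple(failed), field_table=table)


def staged_deploy(geom: VesselGeometry, stent_stages: list[StentSpec], materials: dict,
                  **kw) -> list[DeploymentResult]:
    """Ordered sequence of device profiles (compress -> distal -> proximal).

    The quasi-static surrogate is path independent, so each stage is an
    independent endpoint; the list mirrors the staged-release protocol.
    """
    return [deploy(geom, s, materials, **kw) for s in stent_stages]
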