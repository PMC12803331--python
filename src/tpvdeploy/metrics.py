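"""Outcome metrics: percentile field statistics, intramural profiles,
mesh-convergence selection, surface-distance comparison and enclosed volumes.

Field percentiles are volume-weighted over all through-wall samples of all
stations (high percentiles such as the 95th/99th are preferred to the maximum
to suppress contact "hotspots").  Geometry comparison uses seeded surface
sampling: Hausdorff distance, mean symmetric distance and the 95th percentile
of the pooled two-directional point-to-surface distances.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .geometry import StentSpec
from .rings import DeploymentResult

__all__ = [
    "weighted_percentiles",
    "field_statistics",
    "MetricsReport",
    "intramural_profile",
    "convergence_study",
    "mesh_distances",
    "perimeter_derived_diameter",
    "section_perimeter",
    "stent_enclosed_volume",
]


def weighted_percentiles(values, weights, q) -> np.ndarray:
    """Weighted empirical quantiles with the inclusive linear-interpolation rule.

    Sorted cumulative-weight positions ``p_i = (S_i - w_i) / (S_n - w_n)`` span
    [0, 1]; with unit weights this reduces to numpy's default "linear" method.
    Doubling all weights leaves every quantile unchanged.
    """
    v = np.asarray(values, dtype=float).reshape(-1)
    w = np.asarray(weights, dtype=float).reshape(-1)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if v.size == 0:
        raise ValueError("cannot take percentiles of an empty field")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantiles must lie in [0, 1]")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    S = np.cumsum(w)
    denom = S[-1] - w[-1]
    if denom <= 0:  # single sample: every quantile is that value
        return np.full(q.shape, v[0])
    p = (S - w) / denom
    return np.interp(q, p, v)


def field_statistics(field_table: pd.DataFrame, scope: str | None = None) -> dict:
    """Volume-weighted summary of sigma_1 and E_1 over the field table.

    ``scope`` optionally restricts to a material label (e.g. "patch"); returns
    a flat dict with max/p99/p95/p75/mean per field, NaN if the scope is empty.
    """
    t = field_table if scope is None else field_table[field_table["material_id"] == scope]
    out: dict[str, float] = {}
    for col, tag in (("stress1_kPa", "stress"), ("strain1", "strain")):
        if len(t) == 0:
            out.update({f"{tag}_{k}": float("nan") for k in
                        ("max", "p99", "p95", "p75", "mean")})
            continue
        v = t[col].to_numpy()
        w = t["volume_mm3"].to_numpy()
        p75, p95, p99 = weighted_percentiles(v, w, [0.75, 0.95, 0.99])
        out[f"{tag}_max"] = float(v.max())
        out[f"{tag}_p99"] = float(p99)
        out[f"{tag}_p95"] = float(p95)
        out[f"{tag}_p75"] = float(p75)
        out[f"{tag}_mean"] = float(np.average(v, weights=w))
    return out


@dataclass(frozen=True)
class MetricsReport:
    """Percentile field statistics plus geometry and volume blocks."""

    scope: str                       # "whole-vessel" or "patch-only"
    stress_max: float
    stress_p99: float
    stress_p95: float
    stress_p75: float
    stress_mean: float
    strain_max: float
    strain_p99: float
    strain_p95: float
    strain_p75: float
    strain_mean: float
    hausdorff_mm: float = float("nan")
    mean_symmetric_mm: float = float("nan")
    p95_symmetric_mm: float = float("nan")
    narrowest_diameter_mm: float = float("nan")
    volume_distal_mm3: float = float("nan")
    volume_middle_mm3: float = float("nan")
    volume_proximal_mm3: float = float("nan")

    @classmethod
    def from_result(cls, result: DeploymentResult, scope: str | None = None,
                    **geometry_blocks) -> "MetricsReport":
        stats = field_statistics(result.field_table,
                                 scope if scope != "whole-vessel" else None)
        label = scope or "whole-vessel"
        return cls(scope="patch-only" if scope == "patch" else label,
                   **{k: stats[k] for k in stats}, **geometry_blocks)

    def to_dict(self) -> dict:
        return asdict(self)


def intramural_profile(result: DeploymentResult, station: int,
                       sector: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Through-wall 1st-principal Green-Lagrange strain at one station.

    Returns (distance ratio, E1) with the abscissa spanning exactly [0, 1]
    from the inner to the outer surface.  ``sector`` picks a material label on
    heterogeneous stations (default: the widest sector).
    """
    sol = result.station_solution(station)
    if sector is None:
        sec = max(sol.sectors, key=lambda s: s.arc_fraction)
    else:
        match = [s for s in sol.sectors if s.material_name == sector]
        if not match:
            raise ValueError(f"no sector labeled {sector!r} at station {station}")
        sec = match[0]
    return sec.t_nodes.copy(), sec.E1.copy()


def convergence_study(run, layers=range(1, 7), criterion_pct: float = 1.0) -> tuple[pd.DataFrame, int | None]:
    """Wall-layer refinement study on the 95th/99th percentile strain.

    ``run(n_layers)`` must return a :class:`DeploymentResult`.  Selects the
    smallest layer count at which both percentile changes from the previous
    refinement fall below ``criterion_pct`` percent; returns (table, selected)
    with ``selected = None`` if no layer count converges.
    """
    if criterion_pct <= 0:
        raise ValueError("criterion_pct must be positive")
    rows = []
    prev = None
    selected = None
    for n in layers:
        res = run(n)
        v = res.field_table["strain1"].to_numpy()
        w = res.field_table["volume_mm3"].to_numpy()
        p95, p99 = weighted_percentiles(v, w, [0.95, 0.99])
        d95 = d99 = float("nan")
        if prev is not None:
            d95 = 100.0 * abs(p95 - prev[0]) / max(abs(prev[0]), 1e-300)
            d99 = 100.0 * abs(p99 - prev[1]) / max(abs(prev[1]), 1e-300)
            if selected is None and d95 < criterion_pct and d99 < criterion_pct:
                selected = n
        rows.append((n, p95, p99, d95, d99))
        prev = (p95, p99)
    table = pd.DataFrame(rows, columns=[
        "n_layers", "strain_p95", "strain_p99", "change_p95_pct", "change_p99_pct",
    ])
    return table, selected


# ---------------------------------------------------------------------------
# Geometry comparison
# ---------------------------------------------------------------------------

def _sample_surface(mesh, n: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded area-weighted surface sampling (barycentric on triangles)."""
    area = mesh.area_faces
    faces = rng.choice(len(area), size=n, p=area / area.sum())
    u = rng.random(n)
    v = rng.random(n)
    flip = u + v > 1.0
    u[flip], v[flip] = 1.0 - u[flip], 1.0 - v[flip]
    tri = mesh.triangles[faces]
    return tri[:, 0] + u[:, None] * (tri[:, 1] - tri[:, 0]) + v[:, None] * (tri[:, 2] - tri[:, 0])


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray,
                             chunk: int = 256) -> np.ndarray:
    """Exact min distance from each point to a triangle soup (vectorized).

    Closest-point-on-triangle by barycentric clamping (Ericson), evaluated for
    every (point, triangle) pair in chunks to bound memory.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        p = points[lo:lo + chunk][:, None, :]          # (P, 1, 3)
        ap = p - a[None, :, :]
        d1 = np.einsum("tk,ptk->pt", ab, ap)
        d2 = np.einsum("tk,ptk->pt", ac, ap)
        bp = p - b[None, :, :]
        d3 = np.einsum("tk,ptk->pt", ab, bp)
        d4 = np.einsum("tk,ptk->pt", ac, bp)
        cp = p - c[None, :, :]
        d5 = np.einsum("tk,ptk->pt", ab, cp)
        d6 = np.einsum("tk,ptk->pt", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        with np.errstate(divide="ignore", invalid="ignore"):
            v_edge_ab = np.clip(d1 / (d1 - d3), 0.0, 1.0)
            w_edge_ac = np.clip(d2 / (d2 - d6), 0.0, 1.0)
            w_edge_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0, 1.0)
            denom = va + vb + vc
            v_in = vb / denom
            w_in = vc / denom
        v = np.where(np.isfinite(v_edge_ab), v_edge_ab, 0.0)
        w = np.zeros_like(v)
        # region tests, applied from faces outward (later assignments win)
        inside = np.ones_like(v, dtype=bool)
        # vertex A region
        regA = (d1 <= 0) & (d2 <= 0)
        # vertex B region
        regB = (d3 >= 0) & (d4 <= d3)
        # vertex C region
        regC = (d6 >= 0) & (d5 <= d6)
        # edge AB region
        regAB = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        # edge AC region
        regAC = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        # edge BC region
        regBC = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
        v = np.where(np.isfinite(v_in), v_in, 0.0)
        w = np.where(np.isfinite(w_in), w_in, 0.0)
        v = np.where(regBC, 1.0 - w_edge_bc, v)
        w = np.where(regBC, w_edge_bc, w)
        v = np.where(regAC, 0.0, v)
        w = np.where(regAC, w_edge_ac, w)
        v = np.where(regAB, v_edge_ab, v)
        w = np.where(regAB, 0.0, w)
        v = np.where(regC, 0.0, v)
        w = np.where(regC, 1.0, w)
        v = np.where(regB, 1.0, v)
        w = np.where(regB, 0.0, w)
        v = np.where(regA, 0.0, v)
        w = np.where(regA, 0.0, w)
        closest = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]
        d = np.linalg.norm(p - closest, axis=-1)
        out[lo:lo + chunk] = d.min(axis=1)
        del inside
    return out


def _points_to_surface(points: np.ndarray, target) -> np.ndarray:
    return _point_triangle_distance(np.asarray(points, dtype=float),
                                    np.asarray(target.triangles, dtype=float))


def mesh_distances(mesh_a, mesh_b, n_surface_samples: int = 5000,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> tuple[float, float, float]:
    """(Hausdorff, mean symmetric, 95%ile symmetric) distance in mm.

    Accepts ``trimesh.Trimesh`` surfaces (seeded dense sampling, point-to-
    surface distances both ways) or raw (N, 3) point arrays (exact brute-force
    point-to-point-set distances).  Symmetric statistics pool both directions;
    the Hausdorff distance is the max over both directional maxima.

    Each mesh's sample stream is keyed to (seed, mesh content), so swapping
    the two arguments leaves all three outputs unchanged exactly.
    """
    if rng is not None:
        seed = int(rng.integers(2**31))
    elif seed is None:
        seed = 0

    def as_points_and_target(m):
        if isinstance(m, np.ndarray):
            pts = np.asarray(m, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
                raise ValueError("point clouds must be non-empty (N, 3) arrays")
            return pts, pts
        if getattr(m, "faces", None) is None or len(m.faces) == 0:
            raise ValueError("degenerate mesh: no faces")
        digest = int.from_bytes(
            hashlib.sha256(np.asarray(m.vertices, dtype=float).tobytes()).digest()[:4],
            "little")
        mesh_rng = np.random.default_rng([seed, digest])
        pts = np.vstack([m.vertices, _sample_surface(m, n_surface_samples, mesh_rng)])
        return pts, m

    pts_a, target_a = as_points_and_target(mesh_a)
    pts_b, target_b = as_points_and_target(mesh_b)

    def one_way(points, target):
        if isinstance(target, np.ndarray):
            from scipy.spatial import cKDTree

            return cKDTree(target).query(points)[0]
        return _points_to_surface(points, target)

    d_ab = one_way(pts_a, target_b)
    d_ba = one_way(pts_b, target_a)
    pooled = np.concatenate([d_ab, d_ba])
    hausdorff = float(max(d_ab.max(), d_ba.max()))
    return hausdorff, float(pooled.mean()), float(np.quantile(pooled, 0.95))


def section_perimeter(points2d: np.ndarray) -> float:
    """Closed-polyline length of a planar cross-section (mm)."""
    p = np.asarray(points2d, dtype=float)
    d = np.diff(np.vstack([p, p[:1]]), axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def perimeter_derived_diameter(result: DeploymentResult, station: int | None = None) -> float:
    """Deployed cross-section perimeter divided by pi (mm).

    With ``station=None`` returns the value at the narrowest deployed station
    within the device extent.  Sector-resolved perimeter:
    ``sum_s phi_s 2 pi r_s``.
    """
    def station_perimeter(j: int) -> float:
        sol = result.stations[j]
        if sol is None:
            return math.inf
        return sum(2.0 * math.pi * sec.lam_theta_inner * sol.spec.R_i * sec.arc_fraction
                   for sec in sol.sectors)

    covered = result.stent.covers(result.z)
    candidates = [j for j in range(len(result.z)) if covered[j]]
    if station is None:
        station = min(candidates, key=station_perimeter)
    return station_perimeter(station) / math.pi


def stent_enclosed_volume(result: DeploymentResult, stent: StentSpec | None = None) -> dict:
    """Volume enclosed by the deployed device, split into axial thirds (mm^3).

    Trapezoidal integration of ``pi r_i(z)^2`` with the third boundaries
    inserted exactly, so the three regions sum to the total.
    """
    stent = stent or result.stent
    z = result.z
    r = result.r_inner_deployed
    mask = stent.covers(z)
    zs, rs = z[mask], r[mask]
    b1, b2 = stent.third_boundaries
    grid = np.unique(np.concatenate([zs, [b1, b2]]))
    grid = grid[(grid >= zs[0] - 1e-12) & (grid <= zs[-1] + 1e-12)]
    rg = np.interp(grid, zs, rs)
    area = math.pi * rg**2

    def integrate(lo, hi):
        m = (grid >= lo - 1e-12) & (grid <= hi + 1e-12)
        return float(np.trapezoid(area[m], grid[m]))

    vols = {
        "distal": integrate(zs[0], b1),
        "middle": integrate(b1, b2),
        "proximal": integrate(b2, zs[-1]),
    }
    vols["total"] = vols["distal"] + vols["middle"] + vols["proximal"]
    return vols
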