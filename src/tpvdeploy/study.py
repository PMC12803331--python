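"""End-to-end studies: wall-layer convergence, material UQ, patch sweep.

Each study is a pure function of (config, seed) returning in-memory tables;
the CLI writes them with provenance headers (config hash, seed, version).
All randomness flows through a single seeded generator per study.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StudyConfig
from .geometry import embed_patch
from .materials import make_patch_material
from .metrics import (
    convergence_study, field_statistics, mesh_distances,
    perimeter_derived_diameter, stent_enclosed_volume,
)
from .rings import StationConvergenceError, deploy
from .uq import HGO_PARAMETER_NAMES, PolynomialChaosExpansion

log = logging.getLogger("tpvdeploy")

UQ_METRICS = ("stress_p95", "stress_p75", "stress_mean",
              "strain_p95", "strain_p75", "strain_mean")


def _materials_dict(config: StudyConfig, hgo=None, patch_E: float | None = None) -> dict:
    mats = {"vessel": hgo or config.baseline_hgo()}
    if patch_E is not None:
        mats["patch"] = make_patch_material(patch_E)
    return mats


def run_convergence(config: StudyConfig, seed: int | None = None,
                    criterion_pct: float = 1.0):
    """Layer-refinement study; returns (table, selected layer count).

    Deterministic: the deployment surrogate has no randomness, the seed is
    accepted only for interface uniformity.
    """
    mats = _materials_dict(config)

    def run(n_layers: int):
        geom = config.vessel(n_layers=n_layers)
        stent = config.stent_for(geom)
        return deploy(geom, stent, mats,
                      tension_only=config.material["tension_only_fibers"])

    t0 = time.perf_counter()
    table, selected = convergence_study(run, layers=range(1, 7),
                                        criterion_pct=criterion_pct)
    log.info("convergence study: %d layer counts in %.2fs, selected %s",
             len(table), time.perf_counter() - t0, selected)
    return table, selected


def _deployment_metrics(geom, stent, mats, tension_only: bool) -> dict:
    res = deploy(geom, stent, mats, tension_only=tension_only)
    return field_statistics(res.field_table), res


def run_material_uq(config: StudyConfig, seed: int = 0, n_layers: int | None = None):
    """The sensitivity study: design, per-run metrics, PCE fits, Sobol, emulator.

    Returns a dict with the design table, per-metric PCE results/Sobol frames,
    emulator summaries, the mean-field map across runs, and the baseline
    deployment's geometry-comparison block.
    """
    rng = np.random.default_rng(seed)
    uq = config.uq
    pce = PolynomialChaosExpansion(config.gamma_specs(), order=uq["order"])
    X = pce.design(oversample=uq["oversample"], rng=rng)
    tension_only = config.material["tension_only_fibers"]

    n_layers = n_layers or config.geometry["n_layers"]
    geom = config.vessel(n_layers=n_layers)
    stent = config.stent_for(geom)
    baseline = config.baseline_hgo()

    rows = []
    outputs = {m: np.full(len(X), np.nan) for m in UQ_METRICS}
    field_maps = []
    results = []
    t0 = time.perf_counter()
    for i, x in enumerate(X):
        params = dict(zip(HGO_PARAMETER_NAMES, x))
        hgo = baseline.replace(c=params["c"], k1=params["k1"], k2=params["k2"],
                               gamma_deg=params["gamma"], kappa=params["kappa"])
        status = "ok"
        try:
            stats, res = _deployment_metrics(geom, stent, {"vessel": hgo}, tension_only)
            for m in UQ_METRICS:
                outputs[m][i] = stats[m]
            field_maps.append(res.field_table[["station_mm", "distance_ratio",
                                               "stress1_kPa", "strain1"]])
            results.append(res)
        except StationConvergenceError:
            status = "failed"
            results.append(None)
        rows.append({"run": i, **{f"{n}{'_kPa' if n in ('c', 'k1') else '_deg' if n == 'gamma' else ''}": v
                                  for n, v in params.items()},
                     "status": status,
                     **{m: outputs[m][i] for m in UQ_METRICS}})
    design = pd.DataFrame(rows)
    n_failed = int((design["status"] == "failed").sum())
    if n_failed / len(X) > uq["max_failed_fraction"]:
        raise StationConvergenceError(
            f"{n_failed}/{len(X)} runs failed (> {uq['max_failed_fraction']:.1%}); "
            f"survivors: {len(X) - n_failed}"
        )
    log.info("UQ: %d runs (%d failed) in %.2fs", len(X), n_failed,
             time.perf_counter() - t0)

    fits, sobol_rows, emulator = {}, [], {}
    for m in UQ_METRICS:
        res_m = pce.fit(X, outputs[m])
        fits[m] = res_m
        for name, s1, st in zip(*_sobol_triplet(res_m)):
            sobol_rows.append({"metric": m, "parameter": name,
                               "S_first": s1, "S_total": st})
        summ = res_m.sample_summary(n=uq["emulator_queries"], rng=rng)
        emulator[m] = {k: v for k, v in summ.items() if k != "samples"}
    sobol = pd.DataFrame(sobol_rows)

    # mean-field map across completed runs (per station and wall depth)
    mean_field = (pd.concat(field_maps)
                  .groupby(["station_mm", "distance_ratio"], as_index=False)
                  .mean())

    geometry_block = _geometry_comparison(results, geom, stent,
                                          {"vessel": baseline}, tension_only, rng)

    return {"design": design, "pce": fits, "sobol": sobol, "emulator": emulator,
            "mean_field": mean_field, "geometry": geometry_block, "n_failed": n_failed}


def _sobol_triplet(res):
    s = res.sobol()
    return s.parameters, s.first_order, s.total_order


def _geometry_comparison(results, geom, stent, baseline_mats, tension_only,
                         rng) -> dict:
    """Hausdorff / symmetric distances of each run's deployed surface to the
    baseline deployment, reported as (max, min) across runs, plus the
    baseline's narrowest perimeter-derived diameter.

    Uses the deployed vertex grids as dense point samples (exact point-set
    distances); adequate for the nearly coaxial tube surfaces compared here.
    """
    base = deploy(geom, stent, baseline_mats, tension_only=tension_only)
    base_pts = np.asarray(base.deployed_surface_trimesh().vertices)
    d_haus, d_mean, d_p95 = [], [], []
    for res in results:
        if res is None:
            continue
        pts = np.asarray(res.deployed_surface_trimesh().vertices)
        h, m, p = mesh_distances(pts, base_pts, rng=rng)
        d_haus.append(h)
        d_mean.append(m)
        d_p95.append(p)
    diam = perimeter_derived_diameter(base)
    return {
        "narrowest_diameter_mm": diam,
        "hausdorff_mm_max": float(np.max(d_haus)),
        "hausdorff_mm_min": float(np.min(d_haus)),
        "hausdorff_pct_of_diameter_max": 100.0 * float(np.max(d_haus)) / diam,
        "hausdorff_pct_of_diameter_min": 100.0 * float(np.min(d_haus)) / diam,
        "mean_symmetric_mm_max": float(np.max(d_mean)),
        "p95_symmetric_mm_max": float(np.max(d_p95)),
    }


def run_patch_study(config: StudyConfig, seed: int | None = None,
                    n_layers: int | None = None) -> pd.DataFrame:
    """Baseline plus two positions x four stiffness conditions (9 rows).

    Per condition: whole-vessel and patch-only max/95th/75th/mean 1st
    principal stress and Lagrangian strain, and per-third enclosed volumes.
    Deterministic.
    """
    tension_only = config.material["tension_only_fibers"]
    n_layers = n_layers or config.geometry["n_layers"]
    geom = config.vessel(n_layers=n_layers)
    stent = config.stent_for(geom)

    conditions = [("baseline", None, None)]
    for pos in config.patch["positions"]:
        for i, E in enumerate(config.patch["stiffness_kPa"], start=1):
            conditions.append((f"{pos}_stiffness_{i}", pos, E))

    rows = []
    for name, pos, E in conditions:
        g = geom
        mats = _materials_dict(config, patch_E=E)
        if pos is not None:
            g = embed_patch(geom, config.patch_region(geom, stent, pos))
        t0 = time.perf_counter()
        res = deploy(g, stent, mats, tension_only=tension_only)
        whole = field_statistics(res.field_table)
        patch_only = field_statistics(res.field_table, scope="patch")
        vols = stent_enclosed_volume(res, stent)
        log.info("patch condition %s in %.2fs", name, time.perf_counter() - t0)
        rows.append({
            "condition": name, "position": pos or "", "patch_E_kPa": E,
            **whole,
            **{f"patch_{k}": v for k, v in patch_only.items()},
            **{f"volume_{k}_mm3": v for k, v in vols.items()},
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, config: StudyConfig,
                seed: int | None = None) -> None:
    """CSV with a provenance comment header (config hash, seed, version)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        for line in config.provenance_lines(seed):
            f.write(f"# {line}\n")
        df.to_csv(f, index=False)
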