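"""Study configuration: geometry, materials, device, UQ and patch blocks.

One schema serves YAML and JSON files; :func:`default_config` carries the
study conditions (literature baselines, media-layer std percentages, the four
patch stiffness conditions, order-4 / 136-run / 1000-query UQ settings).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .geometry import (
    PatchRegion, RadiusProfile, StentSpec, VesselGeometry,
    constant_profile, waist_profile, make_rvot_tube, make_stent_profile,
)
from .materials import HGOParams, IsotropicElastic, make_patch_material
from .uq import GammaSpec, HGO_PARAMETER_NAMES, PRINTED_STD_PCT, BASELINE_MEANS


class ConfigError(ValueError):
    """Raised for malformed or inconsistent study configuration."""


@dataclass
class StudyConfig:
    """Flat dictionary-backed study configuration with typed accessors."""

    geometry: dict
    material: dict
    stent: dict
    uq: dict
    patch: dict
    output_dir: str = "results"
    seed: int = 0

    # -- builders ------------------------------------------------------------

    def radius_profile(self) -> RadiusProfile:
        g = self.geometry
        kind = g.get("profile", "waist")
        if kind == "constant":
            return constant_profile(g["radius"])
        if kind == "waist":
            return waist_profile(g["r_flare"], g["r_waist"], g["waist_center"],
                                 g["waist_width"])
        raise ConfigError(f"unknown radius profile {kind!r}")

    def vessel(self, n_layers: int | None = None) -> VesselGeometry:
        g = self.geometry
        return make_rvot_tube(
            self.radius_profile(), length=g["length"], mesh_size=g["mesh_size"],
            n_layers=n_layers or g["n_layers"], H=g["thickness"],
        )

    def stent_for(self, geom: VesselGeometry) -> StentSpec:
        s = self.stent
        return make_stent_profile(geom, free_radius=s["free_radius"],
                                  stiffness=s["radial_stiffness"],
                                  length=s["length"])

    def baseline_hgo(self) -> HGOParams:
        m = self.material
        return HGOParams(c=m["c"], k1=m["k1"], k2=m["k2"], gamma_deg=m["gamma"],
                         kappa=m["kappa"], k_bulk=m["k_bulk"], rho=m["rho"])

    def gamma_specs(self) -> dict[str, GammaSpec]:
        pct = self.material["std_pct"]
        missing = [n for n in HGO_PARAMETER_NAMES if n not in pct]
        if missing:
            raise ConfigError(f"std_pct missing parameters: {missing}")
        means = {"c": self.material["c"], "k1": self.material["k1"],
                 "k2": self.material["k2"], "gamma": self.material["gamma"],
                 "kappa": self.material["kappa"]}
        return {n: GammaSpec(means[n], pct[n]) for n in HGO_PARAMETER_NAMES}

    def patch_materials(self) -> list[IsotropicElastic]:
        return [make_patch_material(E) for E in self.patch["stiffness_kPa"]]

    def patch_region(self, geom: VesselGeometry, stent: StentSpec,
                     position: str) -> PatchRegion:
        """Diamond patch centered on the distal or proximal device third."""
        b1, b2 = stent.third_boundaries
        if position == "position_1_distal":
            center_z = 0.5 * (float(stent.z[0]) + b1)
        elif position == "position_2_proximal":
            center_z = 0.5 * (b2 + float(stent.z[-1]))
        else:
            raise ConfigError(f"unknown patch position {position!r}")
        return PatchRegion(position=position, d1=self.patch["d1"],
                           d2=self.patch["d2"], center_z=center_z,
                           center_theta=self.patch.get("center_theta", 0.0))

    # -- provenance ----------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance_lines(self, seed: int | None = None) -> list[str]:
        from . import __version__

        return [
            f"tpvdeploy {__version__}",
            f"config_hash {self.hash()}",
            f"seed {self.seed if seed is None else seed}",
        ]

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        try:
            with open(path) as f:
                data = yaml.safe_load(f) if path.suffix in (".yml", ".yaml") else json.load(f)
        except (OSError, ValueError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        base = default_config()
        for block in ("geometry", "material", "stent", "uq", "patch"):
            merged = dict(getattr(base, block))
            merged.update(data.get(block, {}))
            setattr(base, block, merged)
        base.output_dir = data.get("output_dir", base.output_dir)
        base.seed = int(data.get("seed", base.seed))
        return base


def default_config() -> StudyConfig:
    """The default study conditions.

    Geometry: 60 mm tube, smooth flare-waist-flare (16 -> 9 -> 16 mm inner
    radius, waist distal of the device center) standing in for a dilated RVOT
    with a narrowed device landing zone; 1.5 mm wall and mesh size.  Device: 25 mm nominal diameter
    (free radius 12.5 mm), 45 mm long, radial stiffness 50 kPa per unit
    relative recoil.  UQ: order 4, 10 oversamples (136 runs), 1000 emulator
    queries.  Patch: 30 x 20 mm diamond, stiffnesses 1.1/2.2/4.4/8.8 MPa.
    """
    return StudyConfig(
        geometry={
            # waist placed distal of the device center: a real dilated RVOT is
            # not symmetric about the device, so the two patch positions load
            # differently
            "profile": "waist", "length": 60.0, "r_flare": 16.0, "r_waist": 9.0,
            "waist_center": 27.0, "waist_width": 18.0,
            "mesh_size": 1.5, "thickness": 1.5, "n_layers": 4,
        },
        material={
            "c": BASELINE_MEANS["c"], "k1": BASELINE_MEANS["k1"],
            "k2": BASELINE_MEANS["k2"], "gamma": BASELINE_MEANS["gamma"],
            "kappa": BASELINE_MEANS["kappa"], "k_bulk": 1500.0, "rho": 1.02e-6,
            "std_pct": {n: PRINTED_STD_PCT[n] for n in HGO_PARAMETER_NAMES},
            "tension_only_fibers": True,
        },
        stent={"free_radius": 12.5, "radial_stiffness": 50.0, "length": 45.0},
        uq={"order": 4, "oversample": 10, "emulator_queries": 1000,
            "max_failed_fraction": 0.025},
        patch={"d1": 30.0, "d2": 20.0, "center_theta": 0.0,
               "positions": ["position_1_distal", "position_2_proximal"],
               "stiffness_kPa": [1.1e3, 2.2e3, 4.4e3, 8.8e3],
               "nu": 0.495, "rho": 1.41e-6},
    )
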