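"""Pipeline orchestration, configuration and serialization.

Ties the stages together: synthetic or loaded wall clouds -> per-phase
surface fits (periodic circumferential) -> swept hexahedral control mesh ->
trivariate solid per phase -> adjacent-phase displacement fields -> sampled
strain/stress lattices with VTK/CSV/JSON outputs.

All phases are fitted with a shared configuration (net sizes, degrees, knot
vectors) and with the surface parameters of the reference phase, so control
grids correspond materially across phases and control-point differences are
valid displacement fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import geometry, mechanics
from .geometry import SurfaceFit, WallPointCloud
from .mechanics import DisplacementField, FieldGrid, MaterialParams
from .splinecore import SolidModel, SurfaceModel, ValidationError

__all__ = [
    "PipelineConfig",
    "PhaseResult",
    "ConfigError",
    "load_config",
    "save_config",
    "run_pipeline",
    "save_model_json",
    "load_model_json",
]


class ConfigError(ValueError):
    """A configuration document violates the schema; names the bad key."""


@dataclass
class PipelineConfig:
    """Everything needed to run the modelling/analysis pipeline.

    Defaults carry the standard experiment settings: cubic splines in all
    directions, an 8x6 circumferential-by-longitudinal net, 4 radial layers,
    and passive myocardium at E = 11 kPa, mu = 0.49.
    """

    degrees: tuple[int, int, int] = (3, 3, 3)
    net_size: tuple[int, int] = (8, 6)
    radial_layers: int = 4
    material: MaterialParams = dc_field(default_factory=MaterialParams)
    quadrature_order: int = 4
    resolution: tuple[int, int, int] = (16, 8, 4)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        k1, k2, k3 = self.degrees
        n_c, n_l = self.net_size
        if min(self.degrees) < 1:
            raise ConfigError("degrees: all spline degrees must be >= 1")
        if n_c < k1 + 1 or n_l < k2 + 1:
            raise ConfigError("net_size: net must exceed the degree in each direction")
        if self.radial_layers < k3 + 1:
            raise ConfigError(
                f"radial_layers: {self.radial_layers} layers cannot carry a "
                f"degree-{k3} radial basis"
            )
        if self.quadrature_order < 1:
            raise ConfigError("quadrature_order: must be >= 1")
        if min(self.resolution) < 2:
            raise ConfigError("resolution: must be >= 2 per direction")


_CONFIG_KEYS = {
    "degrees", "net_size", "radial_layers", "material",
    "quadrature_order", "resolution", "seed", "output_dir",
}


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON pipeline configuration, validating the schema."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config: document root must be a mapping")
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> PipelineConfig:
    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"config: unknown key(s) {sorted(unknown)}")
    kwargs: dict = {}

    def _tuple(key: str, n: int):
        v = doc[key]
        if not isinstance(v, (list, tuple)) or len(v) != n:
            raise ConfigError(f"{key}: expected a length-{n} sequence")
        return tuple(int(x) for x in v)

    if "degrees" in doc:
        kwargs["degrees"] = _tuple("degrees", 3)
    if "net_size" in doc:
        kwargs["net_size"] = _tuple("net_size", 2)
    if "resolution" in doc:
        kwargs["resolution"] = _tuple("resolution", 3)
    for key in ("radial_layers", "quadrature_order", "seed"):
        if key in doc:
            try:
                kwargs[key] = int(doc[key])
            except (TypeError, ValueError):
                raise ConfigError(f"{key}: expected an integer") from None
    if "material" in doc:
        m = doc["material"]
        if not isinstance(m, dict) or not {"E", "mu"} >= set(m):
            raise ConfigError("material: expected a mapping with keys E, mu")
        try:
            kwargs["material"] = MaterialParams(
                E=float(m.get("E", 11.0)), mu=float(m.get("mu", 0.49)))
        except ValidationError as exc:
            raise ConfigError(f"material: {exc}") from None
    if "output_dir" in doc and doc["output_dir"] is not None:
        kwargs["output_dir"] = str(doc["output_dir"])
    return PipelineConfig(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict:
    return {
        "degrees": list(cfg.degrees),
        "net_size": list(cfg.net_size),
        "radial_layers": cfg.radial_layers,
        "material": {"E": cfg.material.E, "mu": cfg.material.mu},
        "quadrature_order": cfg.quadrature_order,
        "resolution": list(cfg.resolution),
        "seed": cfg.seed,
        "output_dir": cfg.output_dir,
    }


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------


def save_model_json(model: SolidModel | SurfaceModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model_json(path) -> SolidModel | SurfaceModel:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("type") == "surface":
        return SurfaceModel.from_dict(d)
    if d.get("type") == "solid":
        return SolidModel.from_dict(d)
    raise ValidationError(f"unknown model type {d.get('type')!r} in {path}")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PhaseResult:
    """Output of one adjacent-phase analysis (phase p -> p+1)."""

    solid_t0: SolidModel
    solid_t1: SolidModel
    field: DisplacementField
    grid: FieldGrid
    summary: dict


def build_solid_for_phase(inner: WallPointCloud, outer: WallPointCloud,
                          cfg: PipelineConfig,
                          ref_params: tuple | None = None
                          ) -> tuple[SolidModel, dict, tuple]:
    """Fit both wall surfaces, sweep, and assemble the phase's solid.

    ``ref_params`` carries the (inner, outer) surface parameters of the
    reference phase so later phases stay materially corresponded.
    """
    k1, k2, k3 = cfg.degrees
    pi = ref_params[0] if ref_params else None
    po = ref_params[1] if ref_params else None
    fit_in = geometry.fit_surface(inner, cfg.net_size, (k1, k2), params=pi)
    fit_out = geometry.fit_surface(outer, cfg.net_size, (k1, k2), params=po)
    mesh = geometry.sweep_hex_mesh(fit_in.surface, fit_out.surface,
                                   cfg.radial_layers)
    solid = geometry.fit_solid(mesh, degrees=(k1, k2, k3))
    residuals = {"inner_rms_mm": fit_in.rms, "outer_rms_mm": fit_out.rms}
    return solid, residuals, (fit_in.params, fit_out.params)


def _component_stats(arr: np.ndarray, names: Sequence[str]) -> dict:
    out = {}
    for i, name in enumerate(names):
        comp = arr[..., i]
        out[name] = {"min": float(comp.min()), "max": float(comp.max()),
                     "mean": float(comp.mean())}
    return out


_STRAIN_NAMES = ("eps_x", "eps_y", "eps_z", "gamma_xy", "gamma_yz", "gamma_xz")
_STRESS_NAMES = ("sig_x", "sig_y", "sig_z", "tau_xy", "tau_yz", "tau_xz")


def run_pipeline(cfg: PipelineConfig,
                 phases: Sequence[tuple[WallPointCloud, WallPointCloud]]
                 ) -> list[PhaseResult]:
    """Run the full analysis over consecutive cardiac phases.

    ``phases`` is a list of (inner, outer) cloud pairs, one per time point,
    with corresponding slice/ring indexing across phases.  For each adjacent
    pair a displacement field and a sampled strain/stress lattice are
    produced; if ``cfg.output_dir`` is set, VTK, CSV and JSON summaries are
    written there.
    """
    if len(phases) < 2:
        raise ValidationError("run_pipeline needs at least 2 phases")
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    solids: list[SolidModel] = []
    residuals: list[dict] = []
    ref_params = None
    for p, (inner, outer) in enumerate(phases):
        solid, res, params = build_solid_for_phase(inner, outer, cfg, ref_params)
        if p == 0:
            ref_params = params
        solids.append(solid)
        residuals.append(res)
        if outdir is not None:
            save_model_json(solid, outdir / f"solid_phase{p}.json")

    results = []
    for p in range(len(solids) - 1):
        field = mechanics.field_difference_displacements(solids[p], solids[p + 1])
        grid = mechanics.evaluate_field_grid(solids[p], field, cfg.material,
                                             cfg.resolution)
        volume = mechanics.integrate_volume(solids[p], cfg.quadrature_order)
        summary = {
            "phase_pair": [p, p + 1],
            "fit_residuals": {"t0": residuals[p], "t1": residuals[p + 1]},
            "volume_mm3": volume,
            "det_j": {"min": float(grid.det_j.min()),
                      "max": float(grid.det_j.max())},
            "strain": _component_stats(grid.strain, _STRAIN_NAMES),
            "stress_kpa": _component_stats(grid.stress, _STRESS_NAMES),
            "principal_strain_max": float(grid.principal_strain.max()),
            "principal_stress_max_kpa": float(grid.principal_stress.max()),
            "material": {"E_kpa": cfg.material.E, "mu": cfg.material.mu},
        }
        if outdir is not None:
            mechanics.export_vtk(grid, outdir / f"fields_{p}_{p + 1}.vtk")
            mechanics.export_csv(grid, outdir / f"fields_{p}_{p + 1}.csv")
            with open(outdir / f"summary_{p}_{p + 1}.json", "w") as fh:
                json.dump(summary, fh, indent=2)
        results.append(PhaseResult(solids[p], solids[p + 1], field, grid, summary))
    return results
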