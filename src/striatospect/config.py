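"""YAML/JSON configuration loading with strict validation.

A config file is a nested mapping with up to five sections: ``phantom``,
``acquisition``, ``recon``, ``smoothing`` and ``study``.  Every key is
optional — an empty config yields the full default study (120 views at 3
degrees, 150 mm orbit, 30 subsets, 10 iterations, uniform-AC mu 0.11/cm,
11.8 mm scalp dilation, 7 acquisitions spanning true SUR 2.08-14.70,
smoothing 0-16 mm).  Unknown keys are rejected by name.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import json
import yaml

from .experiments import StudyConfig, default_recon_specs, default_smoothing_sweep
from .phantom import Ellipsoid, PhantomSpec, VoxelGrid
from .projector import AcquisitionGeometry, PsfModel
from .recon import ReconSpec

__all__ = ["ConfigError", "load_config", "save_config", "config_to_dict"]


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


def _check_keys(section: Dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_psf(d: Dict, where: str) -> PsfModel:
    if isinstance(d, str):
        named = {"none": PsfModel.none, "method1": PsfModel.method1,
                 "method2": PsfModel.method2,
                 "default_constant": PsfModel.constant,
                 "constant_method2": PsfModel.constant_method2}
        if d not in named:
            raise ConfigError(f"unknown PSF name {d!r} in {where}")
        return named[d]()
    _check_keys(d, {"kind", "fwhm_mm", "intercept_mm", "slope_mm_per_mm", "tag"},
                where)
    try:
        return PsfModel(**d)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{where}: {e}") from e


def _parse_phantom(section: Dict) -> PhantomSpec:
    allowed = {"grid", "head_semiaxes_mm", "scalp_thickness_mm", "chambers",
               "background_concentration", "striatal_concentration_left",
               "striatal_concentration_right", "mu_background", "mu_chambers",
               "mu_scalp", "rng_seed"}
    _check_keys(section, allowed, "phantom")
    kwargs = dict(section)
    if "grid" in kwargs:
        grid = kwargs["grid"]
        _check_keys(grid, {"shape", "voxel_size_mm"}, "phantom.grid")
        kwargs["grid"] = VoxelGrid(**{k: tuple(v) if k == "shape" else v
                                      for k, v in grid.items()})
    if "chambers" in kwargs:
        chambers = {}
        for name, c in kwargs["chambers"].items():
            _check_keys(c, {"center_mm", "semiaxes_mm"}, f"phantom.chambers.{name}")
            chambers[name] = Ellipsoid(tuple(c["center_mm"]),
                                       tuple(c["semiaxes_mm"]))
        kwargs["chambers"] = chambers
    if "head_semiaxes_mm" in kwargs:
        kwargs["head_semiaxes_mm"] = tuple(kwargs["head_semiaxes_mm"])
    try:
        return PhantomSpec(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"phantom: {e}") from e


def _parse_acquisition(section: Dict) -> AcquisitionGeometry:
    allowed = {"n_views", "angular_step_deg", "start_angle_deg",
               "orbit_radius_mm", "total_count_budget", "rng_seed"}
    _check_keys(section, allowed, "acquisition")
    try:
        return AcquisitionGeometry(**section)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"acquisition: {e}") from e


def _parse_recon_specs(section) -> List[ReconSpec]:
    if isinstance(section, dict):
        _check_keys(section, {"parameter_set"}, "recon")
        return default_recon_specs(**section)
    specs = []
    for i, d in enumerate(section):
        where = f"recon[{i}]"
        _check_keys(d, {"ac_mode", "ac_mu_uniform", "scalp_dilation_mm",
                        "psf_correction", "n_subsets", "n_iterations",
                        "epsilon"}, where)
        kwargs = dict(d)
        if "psf_correction" in kwargs:
            kwargs["psf_correction"] = _parse_psf(kwargs["psf_correction"], where)
        try:
            specs.append(ReconSpec(**kwargs))
        except (TypeError, ValueError) as e:
            raise ConfigError(f"{where}: {e}") from e
    return specs


def load_config(path: Optional[str | Path] = None,
                data: Optional[Dict] = None) -> StudyConfig:
    """Load and validate a study configuration.

    Either ``path`` (YAML or JSON file) or an already-parsed mapping
    ``data`` may be given; both absent yields the default bundle.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            text = Path(path).read_text()
            data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")
    _check_keys(data, {"phantom", "acquisition", "recon", "smoothing", "study"},
                "top level")

    kwargs = {}
    if "phantom" in data:
        kwargs["phantom"] = _parse_phantom(data["phantom"])
    if "acquisition" in data:
        kwargs["geometry"] = _parse_acquisition(data["acquisition"])
    if "recon" in data:
        kwargs["recon_specs"] = tuple(_parse_recon_specs(data["recon"]))
    if "smoothing" in data:
        sect = data["smoothing"]
        _check_keys(sect, {"fwhms_mm"}, "smoothing")
        kwargs["smoothing_fwhms"] = tuple(float(s) for s in sect["fwhms_mm"])
    if "study" in data:
        sect = data["study"]
        _check_keys(sect, {"sur_pairs", "master_seed", "simulation_psf"}, "study")
        if "sur_pairs" in sect:
            kwargs["sur_pairs"] = tuple((float(a), float(b))
                                        for a, b in sect["sur_pairs"])
        if "master_seed" in sect:
            kwargs["master_seed"] = int(sect["master_seed"])
        if "simulation_psf" in sect:
            kwargs["simulation_psf"] = _parse_psf(sect["simulation_psf"],
                                                  "study.simulation_psf")
    try:
        return StudyConfig(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(str(e)) from e


def config_to_dict(config: StudyConfig) -> Dict:
    """Round-trippable plain-dict form of a StudyConfig."""
    ph = config.phantom
    return {
        "phantom": {
            "grid": {"shape": list(ph.grid.shape),
                     "voxel_size_mm": ph.grid.voxel_size_mm},
            "head_semiaxes_mm": list(ph.head_semiaxes_mm),
            "scalp_thickness_mm": ph.scalp_thickness_mm,
            "chambers": {name: {"center_mm": list(c.center_mm),
                                "semiaxes_mm": list(c.semiaxes_mm)}
                         for name, c in ph.chambers.items()},
            "background_concentration": ph.background_concentration,
            "striatal_concentration_left": ph.striatal_concentration_left,
            "striatal_concentration_right": ph.striatal_concentration_right,
            "mu_background": ph.mu_background,
            "mu_chambers": ph.mu_chambers,
            "mu_scalp": ph.mu_scalp,
            "rng_seed": ph.rng_seed,
        },
        "acquisition": {
            "n_views": config.geometry.n_views,
            "angular_step_deg": config.geometry.angular_step_deg,
            "start_angle_deg": config.geometry.start_angle_deg,
            "orbit_radius_mm": config.geometry.orbit_radius_mm,
            "total_count_budget": config.geometry.total_count_budget,
            "rng_seed": config.geometry.rng_seed,
        },
        "recon": [
            {"ac_mode": s.ac_mode, "ac_mu_uniform": s.ac_mu_uniform,
             "scalp_dilation_mm": s.scalp_dilation_mm,
             "psf_correction": {"kind": s.psf_correction.kind,
                                "fwhm_mm": s.psf_correction.fwhm_mm,
                                "intercept_mm": s.psf_correction.intercept_mm,
                                "slope_mm_per_mm": s.psf_correction.slope_mm_per_mm,
                                "tag": s.psf_correction.tag},
             "n_subsets": s.n_subsets, "n_iterations": s.n_iterations}
            for s in config.recon_specs
        ],
        "smoothing": {"fwhms_mm": list(config.smoothing_fwhms)},
        "study": {
            "sur_pairs": [list(p) for p in config.sur_pairs],
            "master_seed": config.master_seed,
            "simulation_psf": {"kind": config.simulation_psf.kind,
                               "fwhm_mm": config.simulation_psf.fwhm_mm,
                               "intercept_mm": config.simulation_psf.intercept_mm,
                               "slope_mm_per_mm": config.simulation_psf.slope_mm_per_mm,
                               "tag": config.simulation_psf.tag},
        },
    }


def save_config(config: StudyConfig, path: str | Path) -> Path:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path
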