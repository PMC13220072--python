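"""YAML run configuration -> validated component specs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .artery import TABLE1_COEFFS, ArteryMaterial
from .dynamics import DynamicsConfig
from .stent import ATM_TO_MPA, StentSpec

__all__ = ["RunConfig", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "stent": {
        "length_mm": 34.0,
        "diameter_mm": 2.15,
        "crimped_radius_mm": 0.5,
        "strut_thickness_mm": 0.08,
        "youngs_modulus_gpa": 233.0,
        "poisson": 0.35,
    },
    "balloon": {"pressure_atm": 9.0},
    "artery": {
        **{f"C{i}0": c for i, c in enumerate(TABLE1_COEFFS, start=1)},
        "lambda_res": 1.4,
    },
    "model": {"threshold_T": 0.01},
    "dynamics": {
        "gamma": 0.65,
        "alpha": 0.1,
        "beta": 0.1,
        "max_steps": 5000,
        "tol_disp": 1e-4,
    },
}


@dataclass
class RunConfig:
    stent: StentSpec
    material: ArteryMaterial
    dynamics: DynamicsConfig
    raw: dict = field(default_factory=dict)

    def echo(self) -> dict:
        """Derived device quantities for the run log."""
        return self.stent.derived()


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from YAML (optional) plus CLI overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(Path(path)) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)

    st = cfg["stent"]
    spec = StentSpec(
        E=float(st["youngs_modulus_gpa"]) * 1000.0,
        nu=float(st["poisson"]),
        r_crimp=float(st["crimped_radius_mm"]),
        D=float(st["diameter_mm"]),
        L=float(st["length_mm"]),
        t_strut=float(st["strut_thickness_mm"]),
        P_nom=float(cfg["balloon"]["pressure_atm"]) * ATM_TO_MPA,
        T=float(cfg["model"]["threshold_T"]),
    )
    ar = cfg["artery"]
    material = ArteryMaterial(
        coeffs=tuple(float(ar[f"C{i}0"]) for i in range(1, 7)),
        lambda_res=float(ar["lambda_res"]),
        nu=float(st["poisson"]),
    )
    dy = cfg["dynamics"]
    dynamics = DynamicsConfig(
        gamma=float(dy["gamma"]),
        alpha=float(dy["alpha"]),
        beta=float(dy["beta"]),
        max_steps=int(dy["max_steps"]),
        tol_disp=float(dy["tol_disp"]),
        seed=int(dy.get("seed", 0)),
    )
    return RunConfig(stent=spec, material=material, dynamics=dynamics, raw=cfg)
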