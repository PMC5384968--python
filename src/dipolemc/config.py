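"""Run configuration: TOML file with [lattice] / [potential] / [moves] /
[protocol] / [output] sections plus a top-level seed.

Every field has a printable default; unknown keys are rejected with the
offending key named.  All randomness in a run flows from the single seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

from .energetics import PairPotentialParams
from .lattice import LatticeSpec
from .mc import ProtocolSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config_toml"]


class ConfigError(ValueError):
    """Invalid or unknown run-configuration content."""


_LATTICE_KEYS = {"symmetry", "n_rows", "n_cols", "dipole_length_l", "spacing_s"}
_POTENTIAL_KEYS = {
    "coulomb_prefactor_C",
    "lj_epsilon",
    "lj_sigma",
    "r_cutoff",
    "core_clamp_dmin",
    "units_mode",
}
_MOVES_KEYS = {"k", "dalpha_max", "pinned"}
_PROTOCOL_KEYS = {
    "mode",
    "schedule",
    "sweeps_per_point",
    "equilibration_sweeps",
    "record_every",
    "n_replicates",
    "temperature",
    "quench_T",
    "quench_schedule",
    "quench_sweeps",
    "fixed_seed_per_k",
}
_OUTPUT_KEYS = {"directory", "textures", "scale_px_per_nm"}
_TOP_KEYS = {"seed", "lattice", "potential", "moves", "protocol", "output"}


@dataclass
class RunConfig:
    lattice: LatticeSpec
    params: PairPotentialParams
    protocol: ProtocolSpec
    k: float = 0.1
    dalpha_max: float = math.pi / 2.0
    pinned: bool = False
    seed: int = 0
    output_directory: str = "run"
    textures: bool = True
    scale_px_per_nm: float = 20.0

    def manifest(self) -> dict:
        """Fully resolved configuration; sufficient to reproduce the run."""
        import numba
        import numpy

        from . import __version__

        return {
            "seed": self.seed,
            "lattice": dataclasses.asdict(self.lattice),
            "potential": dataclasses.asdict(self.params),
            "moves": {
                "k": self.k,
                "dalpha_max": self.dalpha_max,
                "pinned": self.pinned,
            },
            "protocol": dataclasses.asdict(self.protocol),
            "output": {
                "directory": self.output_directory,
                "textures": self.textures,
                "scale_px_per_nm": self.scale_px_per_nm,
            },
            "versions": {
                "dipolemc": __version__,
                "numpy": numpy.__version__,
                "numba": numba.__version__,
                "python": sys.version.split()[0],
            },
        }

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1, default=str)


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(f"unknown key '{key}' in section [{name}]")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: invalid TOML: {exc}") from exc

    _check_keys(raw, _TOP_KEYS, "top level")
    for required in ("lattice", "protocol"):
        if required not in raw:
            raise ConfigError(f"missing required section [{required}]")

    lat = dict(raw["lattice"])
    _check_keys(lat, _LATTICE_KEYS, "lattice")
    try:
        lattice = LatticeSpec(
            symmetry=lat.get("symmetry", "rectangular"),
            n_rows=lat.get("n_rows", 15),
            n_cols=lat.get("n_cols", 15),
            dipole_length_l=lat.get("dipole_length_l", 0.5),
            spacing_s=lat.get("spacing_s"),
        )
    except ValueError as exc:
        raise ConfigError(f"[lattice]: {exc}") from exc

    pot = dict(raw.get("potential", {}))
    _check_keys(pot, _POTENTIAL_KEYS, "potential")
    try:
        defaults = PairPotentialParams.for_spacing(
            lattice.spacing_s,
            coulomb_prefactor_C=pot.get("coulomb_prefactor_C", 1.0),
            r_cutoff=pot.get("r_cutoff"),
        )
        params = PairPotentialParams(
            coulomb_prefactor_C=defaults.coulomb_prefactor_C,
            lj_epsilon=pot.get("lj_epsilon", defaults.lj_epsilon),
            lj_sigma=pot.get("lj_sigma", defaults.lj_sigma),
            r_cutoff=pot.get("r_cutoff"),
            core_clamp_dmin=pot.get("core_clamp_dmin"),
            units_mode=pot.get("units_mode", "reduced"),
        )
    except ValueError as exc:
        raise ConfigError(f"[potential]: {exc}") from exc

    mov = dict(raw.get("moves", {}))
    _check_keys(mov, _MOVES_KEYS, "moves")

    pro = dict(raw["protocol"])
    _check_keys(pro, _PROTOCOL_KEYS, "protocol")
    if "mode" not in pro:
        raise ConfigError("[protocol]: missing required key 'mode'")
    if "schedule" not in pro:
        raise ConfigError("[protocol]: missing required key 'schedule'")
    try:
        protocol = ProtocolSpec(
            mode=pro["mode"],
            schedule=tuple(float(v) for v in pro["schedule"]),
            sweeps_per_point=pro.get("sweeps_per_point", 500),
            equilibration_sweeps=pro.get("equilibration_sweeps", 500),
            seed=int(raw.get("seed", 0)),
            record_every=pro.get("record_every", 10),
            n_replicates=pro.get("n_replicates", 1),
            temperature=pro.get("temperature", 0.2),
            quench_T=pro.get("quench_T"),
            quench_schedule=(
                tuple(float(v) for v in pro["quench_schedule"])
                if "quench_schedule" in pro
                else None
            ),
            quench_sweeps=pro.get("quench_sweeps", 0),
            fixed_seed_per_k=pro.get("fixed_seed_per_k", False),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"[protocol]: {exc}") from exc

    out = dict(raw.get("output", {}))
    _check_keys(out, _OUTPUT_KEYS, "output")

    return RunConfig(
        lattice=lattice,
        params=params,
        protocol=protocol,
        k=float(mov.get("k", 0.1)),
        dalpha_max=float(mov.get("dalpha_max", math.pi / 2.0)),
        pinned=bool(mov.get("pinned", False)),
        seed=int(raw.get("seed", 0)),
        output_directory=out.get("directory", "run"),
        textures=bool(out.get("textures", True)),
        scale_px_per_nm=float(out.get("scale_px_per_nm", 20.0)),
    )


def default_config_toml(mode: str = "temperature_ramp") -> str:
    """A complete, runnable configuration with all defaults spelled out."""
    if mode == "temperature_ramp":
        schedule = "[0.05, 0.0674, 0.0909, 0.1226, 0.1653, 0.2229, 0.3006, 0.40]"
        extra = (
            "quench_schedule = [0.20, 0.17, 0.15, 0.13, 0.11, 0.09, 0.07, 0.05, 0.035]\n"
            "quench_sweeps = 3000"
        )
        lattice = 'symmetry = "rectangular"\nn_rows = 15\nn_cols = 15'
        moves = "pinned = true"
    else:
        schedule = (
            "[0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50, "
            "0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 1.00]"
        )
        extra = "temperature = 0.2\nn_replicates = 3"
        lattice = 'symmetry = "hexagonal"\nn_rows = 20\nn_cols = 20'
        moves = "pinned = false"
    return f"""# dipolemc run configuration ({mode})
seed = 0

[lattice]
{lattice}
dipole_length_l = 0.5
# spacing_s defaults to 2 * dipole_length_l

[potential]
coulomb_prefactor_C = 1.0
# lj_sigma defaults to 0.75 * spacing; lj_epsilon to C / (4 * spacing)
# r_cutoff = 3.0
units_mode = "reduced"

[moves]
dalpha_max = {math.pi / 2.0}
{moves}

[protocol]
mode = "{mode}"
schedule = {schedule}
sweeps_per_point = 500
equilibration_sweeps = 500
record_every = 10
{extra}

[output]
directory = "run"
textures = true
scale_px_per_nm = 20.0
"""
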