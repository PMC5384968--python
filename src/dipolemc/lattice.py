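"""Dipole lattice construction and configuration persistence.

The membrane surface layer is modelled as ``N`` finite electric dipoles of
length ``l`` whose centres sit on a rectangular or hexagonal (triangular
close-packed) matrix with centre spacing ``s`` (default ``2 l``).  Each dipole
rotates in the membrane plane; its state is an in-plane angle ``alpha``
measured counter-clockwise from +x.  Boundaries are free (non-periodic): the
model represents a small finite patch of membrane whose edge textures are part
of the physics.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "LatticeSpec",
    "DipoleConfiguration",
    "ConfigurationParseError",
    "build_rectangular_lattice",
    "build_hexagonal_lattice",
    "build_lattice",
    "randomize_orientations",
    "save_configuration",
    "load_configuration",
]

RECTANGULAR = "rectangular"
HEXAGONAL = "hexagonal"


class ConfigurationParseError(ValueError):
    """Raised when a saved configuration file cannot be parsed."""


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the initial dipole matrix.

    Parameters
    ----------
    symmetry
        ``"rectangular"`` or ``"hexagonal"``.
    n_rows, n_cols
        Matrix dimensions (>= 1 each).
    dipole_length_l
        Dipole length ``l`` in nm (default 0.5, the phosphatidylcholine
        head-group scale).
    spacing_s
        Centre-centre spacing in nm.  Defaults to ``2 * l``.
    """

    symmetry: str
    n_rows: int
    n_cols: int
    dipole_length_l: float = 0.5
    spacing_s: float | None = None

    def __post_init__(self) -> None:
        if self.symmetry not in (RECTANGULAR, HEXAGONAL):
            raise ValueError(f"unknown lattice symmetry: {self.symmetry!r}")
        if int(self.n_rows) != self.n_rows or int(self.n_cols) != self.n_cols:
            raise ValueError("n_rows and n_cols must be integers")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.dipole_length_l <= 0:
            raise ValueError("dipole length l must be > 0")
        if self.spacing_s is None:
            object.__setattr__(self, "spacing_s", 2.0 * self.dipole_length_l)
        if self.spacing_s <= 0:
            raise ValueError("spacing_s must be > 0")

    @property
    def n_dipoles(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class DipoleConfiguration:
    """Positions (nm) and in-plane angles (rad) of ``N`` dipoles.

    ``bounds`` is the bounding box (xmin, xmax, ymin, ymax) of the *initial*
    lattice; it is preserved under Monte Carlo moves so that gap analysis is
    always referred to the membrane patch the simulation started from.
    """

    positions: np.ndarray  # (N, 2) float64
    angles: np.ndarray  # (N,) float64, stored mod 2*pi
    l: float
    spacing: float | None = None
    symmetry: str | None = None
    bounds: tuple[float, float, float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.angles = np.mod(
            np.ascontiguousarray(self.angles, dtype=np.float64), 2.0 * math.pi
        )
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if self.angles.shape != (self.positions.shape[0],):
            raise ValueError("angles must have shape (N,)")
        if self.l <= 0:
            raise ValueError("dipole length l must be > 0")
        if self.bounds is None and self.n > 0:
            x, y = self.positions[:, 0], self.positions[:, 1]
            self.bounds = (float(x.min()), float(x.max()), float(y.min()), float(y.max()))

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def half_vectors(self) -> np.ndarray:
        """Tip half-vectors a_i = (l/2)(cos alpha_i, sin alpha_i), shape (N, 2)."""
        a = np.empty_like(self.positions)
        a[:, 0] = 0.5 * self.l * np.cos(self.angles)
        a[:, 1] = 0.5 * self.l * np.sin(self.angles)
        return a

    def copy(self) -> "DipoleConfiguration":
        return DipoleConfiguration(
            positions=self.positions.copy(),
            angles=self.angles.copy(),
            l=self.l,
            spacing=self.spacing,
            symmetry=self.symmetry,
            bounds=self.bounds,
        )


def _lattice_sites(spec: LatticeSpec) -> np.ndarray:
    s = spec.spacing_s
    rows = np.arange(spec.n_rows)
    cols = np.arange(spec.n_cols)
    jj, ii = np.meshgrid(cols, rows)  # row-major: index = i * n_cols + j
    if spec.symmetry == RECTANGULAR:
        x = jj * s
        y = ii * s
    else:
        x = jj * s + (ii % 2) * (0.5 * s)
        y = ii * s * (math.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel().astype(float), y.ravel().astype(float)])


def _build(spec: LatticeSpec, seed: int) -> DipoleConfiguration:
    pos = _lattice_sites(spec)
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0.0, 2.0 * math.pi, size=pos.shape[0])
    return DipoleConfiguration(
        positions=pos,
        angles=ang,
        l=spec.dipole_length_l,
        spacing=spec.spacing_s,
        symmetry=spec.symmetry,
    )


def build_rectangular_lattice(spec: LatticeSpec, seed: int) -> DipoleConfiguration:
    """Rectangular matrix: centres at (j*s, i*s), uniform random angles."""
    if spec.symmetry != RECTANGULAR:
        raise ValueError("spec.symmetry must be 'rectangular'")
    return _build(spec, seed)


def build_hexagonal_lattice(spec: LatticeSpec, seed: int) -> DipoleConfiguration:
    """Triangular close packing: row pitch s*sqrt(3)/2, odd rows offset s/2.

    Every interior site has six nearest neighbours at distance ``s``.
    """
    if spec.symmetry != HEXAGONAL:
        raise ValueError("spec.symmetry must be 'hexagonal'")
    return _build(spec, seed)


def build_lattice(spec: LatticeSpec, seed: int) -> DipoleConfiguration:
    if spec.symmetry == RECTANGULAR:
        return build_rectangular_lattice(spec, seed)
    return build_hexagonal_lattice(spec, seed)


def randomize_orientations(config: DipoleConfiguration, seed: int) -> DipoleConfiguration:
    """Return a copy with angles redrawn i.i.d. uniform on [0, 2*pi)."""
    rng = np.random.default_rng(seed)
    out = config.copy()
    out.angles = rng.uniform(0.0, 2.0 * math.pi, size=config.n)
    return out


# ---------------------------------------------------------------------------
# Persistence: CSV of (x_nm, y_nm, alpha_rad) plus a JSON metadata sidecar.
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def save_configuration(config: DipoleConfiguration, path: str | Path) -> Path:
    """Write a configuration as CSV plus a ``.meta.json`` sidecar.

    The round trip through :func:`load_configuration` is lossless to full
    float64 precision (coordinates are written with repr-faithful formatting).
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_nm", "y_nm", "alpha_rad"])
        for (x, y), a in zip(config.positions, config.angles):
            writer.writerow([f"{x:.17g}", f"{y:.17g}", f"{a:.17g}"])
    meta = {
        "n": config.n,
        "l": config.l,
        "spacing": config.spacing,
        "symmetry": config.symmetry,
        "bounds": list(config.bounds) if config.bounds is not None else None,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def load_configuration(path: str | Path) -> DipoleConfiguration:
    """Read a configuration written by :func:`save_configuration`.

    Raises :class:`ConfigurationParseError` (with the offending line number)
    on malformed input, on an empty file, and on a mismatch between the
    sidecar's ``n`` and the number of CSV rows.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ConfigurationParseError(f"missing metadata sidecar {sidecar}")
    try:
        with open(sidecar) as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ConfigurationParseError(f"bad sidecar JSON in {sidecar}: {exc}") from exc

    rows: list[tuple[float, float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ConfigurationParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != ["x_nm", "y_nm", "alpha_rad"]:
            raise ConfigurationParseError(f"{path}: line 1: bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ConfigurationParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(row)}"
                )
            try:
                rows.append((float(row[0]), float(row[1]), float(row[2])))
            except ValueError as exc:
                raise ConfigurationParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    if not rows:
        raise ConfigurationParseError(f"{path}: no dipole rows")
    if "n" in meta and meta["n"] is not None and meta["n"] != len(rows):
        raise ConfigurationParseError(
            f"{path}: sidecar declares n={meta['n']} but file has {len(rows)} rows"
        )
    arr = np.asarray(rows, dtype=np.float64)
    bounds = meta.get("bounds")
    return DipoleConfiguration(
        positions=arr[:, :2],
        angles=arr[:, 2],
        l=float(meta["l"]),
        spacing=meta.get("spacing"),
        symmetry=meta.get("symmetry"),
        bounds=tuple(bounds) if bounds is not None else None,
    )
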