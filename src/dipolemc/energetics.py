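"""Pair and total potential energy of the finite-dipole system.

Each dipole ``i`` carries charges ``+e`` and ``-e`` at its tips
``r_i + a_i`` and ``r_i - a_i``, where ``a_i = (l/2)(cos alpha_i, sin
alpha_i)``.  The pair potential is the sum of the four tip-charge Coulomb
terms and a 12-6 Lennard-Jones term acting on the centre distance ``|d_ij|``::

    U_ij = C * ( 1/|d + a_j - a_i| - 1/|d - a_j - a_i|
               + 1/|d - a_j + a_i| - 1/|d + a_j + a_i| )
         + 4 eps [ (sigma/|d|)^12 - (sigma/|d|)^6 ]

with ``C = e^2 / (4 pi eps0 eps_r)``.  The binding energy of the layer is
``E_p = sum_{i<j} U_ij``.

Default units are reduced: ``C = 1`` (energy * length), ``e = 1``,
``k_B = 1``.  An SI preset reports energies in zJ with lengths in nm.

This module is the plain-numpy reference implementation; the Monte Carlo
engine uses an equivalent compiled kernel that is cross-checked against these
functions in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairPotentialParams",
    "PairGeometry",
    "CoreOverlapError",
    "coulomb_pair_energy",
    "lj_pair_energy",
    "pair_energy",
    "total_energy",
    "delta_energy_move",
    "point_dipole_energy",
]

# e^2/(4 pi eps0) = 230.71 zJ nm  (e = 1.602176634e-19 C, eps0 in SI)
_E2_OVER_4PI_EPS0_ZJ_NM = (1.602176634e-19) ** 2 / (
    4.0 * math.pi * 8.8541878128e-12
) * 1e30  # J*m -> zJ*nm: 1e21 * 1e9
_KB_ZJ_PER_K = 1.380649e-2  # Boltzmann constant in zJ/K


class CoreOverlapError(ValueError):
    """Two dipole centres are closer than the hard-core clamp distance."""


@dataclass(frozen=True)
class PairPotentialParams:
    """Parameters of the Coulomb + Lennard-Jones pair potential.

    Attributes
    ----------
    coulomb_prefactor_C
        ``e^2/(4 pi eps0 eps_r)`` in energy*length units (1 in reduced mode).
    lj_epsilon, lj_sigma
        Lennard-Jones well depth and diameter.
    r_cutoff
        Plain truncation radius for the whole pair potential, or ``None``
        for no cutoff.  If set it must be at least ``3 * lj_sigma``.
    core_clamp_dmin
        Centre-centre distances below this reject the configuration (the
        finite-charge tips would otherwise approach a Coulomb singularity
        that the centre-distance LJ term does not bound).
    units_mode
        ``"reduced"`` or ``"SI"`` (energies in zJ, lengths in nm).
    """

    coulomb_prefactor_C: float = 1.0
    lj_epsilon: float = 0.25
    lj_sigma: float = 0.75
    r_cutoff: float | None = None
    core_clamp_dmin: float | None = None
    units_mode: str = "reduced"

    def __post_init__(self) -> None:
        if self.coulomb_prefactor_C < 0:
            raise ValueError("coulomb_prefactor_C must be >= 0")
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be >= 0")
        if self.lj_sigma <= 0:
            raise ValueError("lj_sigma must be > 0")
        if self.r_cutoff is not None and self.r_cutoff < 3.0 * self.lj_sigma:
            raise ValueError("r_cutoff must be >= 3 * lj_sigma")
        if self.core_clamp_dmin is None:
            # Default assumes sigma = 1.5 * dipole_length, placing the clamp at
            # 1.1 * dipole_length: the four-charge Coulomb term is singular for
            # any centre distance <= dipole length (tip charges can coincide),
            # so the clamp must exclude that whole region, not just 0.5 sigma.
            object.__setattr__(
                self, "core_clamp_dmin", (1.1 / 1.5) * self.lj_sigma
            )
        if self.units_mode not in ("reduced", "SI"):
            raise ValueError("units_mode must be 'reduced' or 'SI'")

    @classmethod
    def for_spacing(
        cls,
        spacing_s: float,
        coulomb_prefactor_C: float = 1.0,
        r_cutoff: float | None = None,
        dipole_length: float | None = None,
    ) -> "PairPotentialParams":
        """Defaults tied to the lattice spacing ``s`` (and ``l = s/2``).

        ``sigma = 0.75 s = 1.5 l`` models the head group as wider than its
        charge separation but narrower than the lattice spacing, so mobile
        dipoles can approach below ``s`` into the strongly bound tip-to-tip
        (chain) contact while the LJ wall still bounds the tip-charge gap;
        ``eps = C / (4 s)`` keeps the lattice cohesion LJ-weak enough that the
        aggregated liquid-crystal state is Coulomb-dominated.  The core clamp
        sits at ``1.1 l``, outside the region (centre distance <= ``l``) where
        the four tip charges can coincide and the Coulomb term diverges.
        """
        l = dipole_length if dipole_length is not None else 0.5 * spacing_s
        return cls(
            coulomb_prefactor_C=coulomb_prefactor_C,
            lj_epsilon=coulomb_prefactor_C / (4.0 * spacing_s),
            lj_sigma=0.75 * spacing_s,
            r_cutoff=r_cutoff,
            core_clamp_dmin=1.1 * l,
        )

    @classmethod
    def si_preset(
        cls,
        spacing_s: float = 1.0,
        eps_r: float = 80.0,
        r_cutoff: float | None = None,
    ) -> "PairPotentialParams":
        """SI mode: C from e^2/(4 pi eps0 eps_r) in zJ*nm (default eps_r=80,
        an aqueous interface), LJ scaled the same way as the reduced preset."""
        c = _E2_OVER_4PI_EPS0_ZJ_NM / eps_r
        p = cls.for_spacing(spacing_s, coulomb_prefactor_C=c, r_cutoff=r_cutoff)
        object.__setattr__(p, "units_mode", "SI")
        return p

    @property
    def kB(self) -> float:
        return _KB_ZJ_PER_K if self.units_mode == "SI" else 1.0


@dataclass(frozen=True)
class PairGeometry:
    """Geometry of one dipole pair: centre separation and tip half-vectors."""

    d_ij: np.ndarray  # (2,) centre-to-centre vector, nm
    a_i: np.ndarray  # (2,) half-vector of dipole i
    a_j: np.ndarray  # (2,) half-vector of dipole j

    @classmethod
    def from_angles(
        cls, r_i, r_j, alpha_i: float, alpha_j: float, l: float
    ) -> "PairGeometry":
        r_i = np.asarray(r_i, dtype=float)
        r_j = np.asarray(r_j, dtype=float)
        h = 0.5 * l
        return cls(
            d_ij=r_j - r_i,
            a_i=h * np.array([math.cos(alpha_i), math.sin(alpha_i)]),
            a_j=h * np.array([math.cos(alpha_j), math.sin(alpha_j)]),
        )


def _norm(v: np.ndarray) -> float:
    return math.hypot(float(v[0]), float(v[1]))


def coulomb_pair_energy(geom: PairGeometry, params: PairPotentialParams) -> float:
    """Four tip-charge Coulomb energy of one pair.

    Beyond ``r_cutoff`` (centre distance) the contribution is zero; below the
    core clamp a :class:`CoreOverlapError` is raised (the caller treats this
    as move rejection).
    """
    d = np.asarray(geom.d_ij, dtype=float)
    r = _norm(d)
    if r <= 0:
        raise CoreOverlapError("coincident dipole centres")
    if r < params.core_clamp_dmin:
        raise CoreOverlapError(f"centre distance {r} below clamp {params.core_clamp_dmin}")
    if params.r_cutoff is not None and r > params.r_cutoff:
        return 0.0
    ai, aj = np.asarray(geom.a_i, float), np.asarray(geom.a_j, float)
    return params.coulomb_prefactor_C * (
        1.0 / _norm(d + aj - ai)
        - 1.0 / _norm(d - aj - ai)
        + 1.0 / _norm(d - aj + ai)
        - 1.0 / _norm(d + aj + ai)
    )


def lj_pair_energy(r: float, params: PairPotentialParams) -> float:
    """12-6 Lennard-Jones on the centre distance; zero beyond the cutoff."""
    if r <= 0:
        raise ValueError("centre distance must be > 0")
    if params.r_cutoff is not None and r > params.r_cutoff:
        return 0.0
    x6 = (params.lj_sigma / r) ** 6
    return 4.0 * params.lj_epsilon * (x6 * x6 - x6)


def pair_energy(geom: PairGeometry, params: PairPotentialParams) -> float:
    """Full pair potential U_ij (Coulomb four-term + LJ)."""
    return coulomb_pair_energy(geom, params) + lj_pair_energy(_norm(geom.d_ij), params)


def _pairwise_tables(config) -> tuple[np.ndarray, np.ndarray]:
    pos = config.positions
    a = config.half_vectors()
    return pos, a


def _pair_energy_matrix(pos: np.ndarray, a: np.ndarray, params: PairPotentialParams,
                        check_clamp: bool = True) -> np.ndarray:
    """(N, N) matrix of pair energies (diagonal zero), vectorised."""
    d = pos[None, :, :] - pos[:, None, :]  # d[i, j] = r_j - r_i
    r = np.sqrt((d ** 2).sum(-1))
    n = pos.shape[0]
    iu = ~np.eye(n, dtype=bool)
    if check_clamp and n > 1 and r[iu].min() < params.core_clamp_dmin:
        raise CoreOverlapError("configuration contains a pair below the core clamp")

    def inv(v):
        return 1.0 / np.sqrt((v ** 2).sum(-1))

    aj = a[None, :, :]
    ai = a[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        uc = params.coulomb_prefactor_C * (
            inv(d + aj - ai) - inv(d - aj - ai) + inv(d - aj + ai) - inv(d + aj + ai)
        )
        x6 = (params.lj_sigma / np.where(r > 0, r, np.inf)) ** 6
    u = uc + 4.0 * params.lj_epsilon * (x6 * x6 - x6)
    u[~iu] = 0.0
    if params.r_cutoff is not None:
        u[r > params.r_cutoff] = 0.0
    return u


def total_energy(config, params: PairPotentialParams) -> float:
    """Binding energy E_p = sum over unordered pairs of U_ij."""
    if config.n < 2:
        return 0.0
    pos, a = _pairwise_tables(config)
    u = _pair_energy_matrix(pos, a, params)
    return float(np.triu(u, 1).sum())


def delta_energy_move(
    config,
    params: PairPotentialParams,
    index: int,
    new_position,
    new_angle: float,
) -> float:
    """Energy change of moving one dipole, summed over its pairs only.

    Returns ``+inf`` if the move would violate the core clamp (the Metropolis
    rule then rejects it unconditionally).
    """
    n = config.n
    if not 0 <= index < n:
        raise IndexError(f"dipole index {index} out of range for N={n}")
    if n < 2:
        return 0.0
    pos = config.positions
    a = config.half_vectors()
    new_position = np.asarray(new_position, dtype=float)
    h = 0.5 * config.l
    new_a = h * np.array([math.cos(new_angle), math.sin(new_angle)])

    others = np.arange(n) != index
    d_old = pos[others] - pos[index]
    d_new = pos[others] - new_position
    r_new = np.sqrt((d_new ** 2).sum(-1))
    if r_new.min() < params.core_clamp_dmin:
        return math.inf

    def energy_against(d, ai):
        r = np.sqrt((d ** 2).sum(-1))
        inv = lambda v: 1.0 / np.sqrt((v ** 2).sum(-1))
        aj = a[others]
        uc = params.coulomb_prefactor_C * (
            inv(d + aj - ai) - inv(d - aj - ai) + inv(d - aj + ai) - inv(d + aj + ai)
        )
        x6 = (params.lj_sigma / r) ** 6
        u = uc + 4.0 * params.lj_epsilon * (x6 * x6 - x6)
        if params.r_cutoff is not None:
            u = np.where(r > params.r_cutoff, 0.0, u)
        return float(u.sum())

    return energy_against(d_new, new_a) - energy_against(d_old, a[index])


def point_dipole_energy(p1, p2, d, C: float = 1.0) -> float:
    """Analytic point-dipole energy C*[p1.p2 - 3(p1.dhat)(p2.dhat)]/|d|^3.

    This is the ``l/|d| -> 0`` limit of the four-charge Coulomb term and
    serves as an independent oracle for it at large separation.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    d = np.asarray(d, float)
    r = _norm(d)
    if r <= 0:
        raise ValueError("separation must be nonzero")
    dhat = d / r
    return C * (float(p1 @ p2) - 3.0 * float(p1 @ dhat) * float(p2 @ dhat)) / r ** 3
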