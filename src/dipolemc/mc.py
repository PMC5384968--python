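"""Metropolis Monte Carlo engine and the two simulation protocols.

Moves couple rotation and translation through the dimensionless mobility
parameter ``k = (pi / l) * <dx> / <dalpha>``: each elementary step rotates one
randomly drawn dipole by a uniform angle on ``(-dalpha_max, +dalpha_max)`` and
simultaneously displaces it by a uniform magnitude on ``(0, dx_max)`` in a
uniform direction, with ``dx_max = k * l * dalpha_max / pi`` so the ratio of
mean displacement to mean rotation equals ``k l / pi``.  ``k`` is the model's
proxy for membrane fluidity: small ``k`` freezes translation (gel-like), large
``k`` lets dipoles leave their lattice sites and aggregate (liquid-crystal
like).

Protocols:

* :func:`run_temperature_ramp` — pinned rotors (Fig.-6-style): one system is
  heated through an ascending temperature schedule, equilibrating and
  recording at each point; heating shakes the rotor system out of metastable
  domain arrangements toward the staggered antiparallel ground state.  An
  optional final low-temperature quench stage measures the ordered state.
* :func:`run_k_scan` — mobile dipoles: one independent simulation per ``k``
  value (fresh seed per point by default); the final mean binding energy as a
  function of ``k`` exhibits the gel / liquid-crystal transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import energetics
from ._kernels import run_mc_kernel
from .lattice import DipoleConfiguration, LatticeSpec, build_lattice

__all__ = [
    "MoveScale",
    "RAMP_SCHEDULE",
    "QUENCH_SCHEDULE",
    "KSCAN_SCHEDULE",
    "KSCAN_TEMPERATURE",
    "default_ramp_protocol",
    "default_kscan_protocol",
    "Thermostat",
    "MCState",
    "ProtocolSpec",
    "EnergyTrace",
    "RampResult",
    "KScanResult",
    "propose_move",
    "metropolis_accept",
    "run_sweeps",
    "run_temperature_ramp",
    "run_k_scan",
]

REJECT = math.inf  # sentinel delta-E for clamped-core moves

# Canonical study conditions (reduced units).  The temperature ramp heats a
# pinned rotor lattice from deep in the ordered regime to just below the rotor
# disordering scale, then descends in stages so domain walls anneal out rather
# than freeze in; the k-scan runs at a bath temperature cold enough to keep
# the k -> 0 lattice intact over the run but warm enough for mobile dipoles to
# rearrange into the aggregated state.
RAMP_SCHEDULE: tuple[float, ...] = (
    0.05, 0.0674, 0.0909, 0.1226, 0.1653, 0.2229, 0.3006, 0.40,
)
QUENCH_SCHEDULE: tuple[float, ...] = (
    0.20, 0.17, 0.15, 0.13, 0.11, 0.09, 0.07, 0.05, 0.035,
)
KSCAN_SCHEDULE: tuple[float, ...] = tuple(
    round(0.05 * i, 2) for i in range(1, 21)
)
KSCAN_TEMPERATURE = 0.2


def default_ramp_protocol(seed: int = 0) -> "ProtocolSpec":
    """Fig.-6-style protocol: ascending ramp + staged low-T equilibration."""
    return ProtocolSpec(
        mode="temperature_ramp",
        schedule=RAMP_SCHEDULE,
        sweeps_per_point=400,
        equilibration_sweeps=400,
        seed=seed,
        record_every=50,
        quench_schedule=QUENCH_SCHEDULE,
        quench_sweeps=3000,
    )


def default_kscan_protocol(seed: int = 0, n_replicates: int = 3) -> "ProtocolSpec":
    """Fig.-8-style protocol: independent runs over the k grid 0.05..1.0."""
    return ProtocolSpec(
        mode="k_scan",
        schedule=KSCAN_SCHEDULE,
        sweeps_per_point=500,
        equilibration_sweeps=500,
        seed=seed,
        record_every=50,
        n_replicates=n_replicates,
        temperature=KSCAN_TEMPERATURE,
    )


@dataclass(frozen=True)
class MoveScale:
    """Proposal half-widths for the coupled rotation + translation move.

    The invariant ``dx_max = k * l * dalpha_max / pi`` makes the mean
    displacement-to-rotation ratio of uniform proposals equal ``k l / pi``.
    ``pinned=True`` freezes translation entirely regardless of ``k``.
    """

    k: float
    dalpha_max: float
    dx_max: float
    pinned: bool = False

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.dalpha_max <= 0:
            raise ValueError("dalpha_max must be > 0")

    @classmethod
    def from_k(
        cls,
        k: float,
        l: float,
        dalpha_max: float = math.pi / 2.0,
        pinned: bool = False,
    ) -> "MoveScale":
        return cls(
            k=k,
            dalpha_max=dalpha_max,
            dx_max=k * l * dalpha_max / math.pi,
            pinned=pinned,
        )

    @property
    def effective_dx_max(self) -> float:
        return 0.0 if self.pinned else self.dx_max


@dataclass(frozen=True)
class Thermostat:
    """Temperature in the Metropolis weight exp(-dE / (kB * T))."""

    T: float
    kB: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be > 0")
        if self.kB <= 0:
            raise ValueError("kB must be > 0")

    @property
    def kBT(self) -> float:
        return self.kB * self.T


@dataclass
class MCState:
    """Mutable Markov-chain state: configuration, running energy, counters."""

    config: DipoleConfiguration
    params: energetics.PairPotentialParams
    E_p: float = field(init=False)
    step_count: int = 0
    accept_count: int = 0
    rng: np.random.Generator = field(init=False)
    seed: int = 0

    def __post_init__(self) -> None:
        self.rng = np.random.default_rng(self.seed)
        self.E_p = energetics.total_energy(self.config, self.params)

    def recompute_energy(self) -> float:
        """Full O(N^2) recomputation (bookkeeping check / resync)."""
        return energetics.total_energy(self.config, self.params)


@dataclass(frozen=True)
class ProtocolSpec:
    """Schedule and bookkeeping of a simulation protocol.

    ``schedule`` holds temperatures for ``temperature_ramp`` and ``k`` values
    for ``k_scan``.  ``temperature`` is the fixed bath temperature of the
    k-scan.  A final low-temperature equilibration after a ramp is specified
    either by ``quench_T`` (single stage) or ``quench_schedule`` (a descending
    sequence of stage temperatures — a staged descent avoids re-trapping
    domain walls that a hard quench would freeze in); ``quench_sweeps`` is
    spent at each stage, and the recording window runs at the last stage's
    temperature.
    """

    mode: str
    schedule: tuple[float, ...]
    sweeps_per_point: int = 500
    equilibration_sweeps: int = 500
    seed: int = 0
    record_every: int = 10
    n_replicates: int = 1
    temperature: float = 0.2
    quench_T: float | None = None
    quench_schedule: tuple[float, ...] | None = None
    quench_sweeps: int = 0
    fixed_seed_per_k: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("temperature_ramp", "k_scan", "single_run"):
            raise ValueError(f"unknown protocol mode: {self.mode!r}")
        if len(self.schedule) == 0:
            raise ValueError("schedule must be non-empty")
        if self.sweeps_per_point < 1:
            raise ValueError("sweeps_per_point must be >= 1")
        if self.equilibration_sweeps < 0:
            raise ValueError("equilibration_sweeps must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.quench_schedule is None and self.quench_T is not None:
            object.__setattr__(self, "quench_schedule", (self.quench_T,))
        if self.quench_schedule is not None:
            if len(self.quench_schedule) == 0:
                raise ValueError("quench_schedule must be non-empty if given")
            if self.quench_T is None:
                object.__setattr__(self, "quench_T", self.quench_schedule[-1])


@dataclass
class EnergyTrace:
    """Per-run time series of binding energy and acceptance rate."""

    sweeps: np.ndarray
    energy: np.ndarray
    acceptance: np.ndarray
    tracked_angles: np.ndarray | None = None

    @property
    def mean_energy(self) -> float:
        return float(self.energy.mean()) if self.energy.size else math.nan


def propose_move(
    state: MCState, scale: MoveScale, rng: np.random.Generator
) -> tuple[int, np.ndarray, float]:
    """Draw one coupled rotation + translation proposal.

    Reference (pure-Python) implementation of the move distribution used by
    the compiled sweep kernel: index uniform over N, rotation uniform on
    ``(-dalpha_max, +dalpha_max)``, displacement magnitude uniform on
    ``(0, dx_max)`` with uniform direction; pinned mode proposes zero
    displacement.
    """
    n = state.config.n
    index = int(rng.integers(n))
    dalpha = float(rng.uniform(-scale.dalpha_max, scale.dalpha_max))
    new_angle = float(state.config.angles[index] + dalpha)
    dx_max = scale.effective_dx_max
    if dx_max > 0.0:
        step = float(rng.uniform(0.0, dx_max))
        theta = float(rng.uniform(0.0, 2.0 * math.pi))
        delta = np.array([step * math.cos(theta), step * math.sin(theta)])
    else:
        delta = np.zeros(2)
    return index, state.config.positions[index] + delta, new_angle


def metropolis_accept(
    delta_E: float, thermostat: Thermostat, rng: np.random.Generator
) -> bool:
    """Accept iff dE <= 0, else with probability exp(-dE / kB T).

    The core-clamp rejection sentinel (``+inf``) is always rejected.
    """
    if delta_E <= 0.0:
        return True
    if not math.isfinite(delta_E):
        return False
    return float(rng.random()) < math.exp(-delta_E / thermostat.kBT)


def _kernel_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_sweeps(
    state: MCState,
    scale: MoveScale,
    thermostat: Thermostat,
    n_sweeps: int,
    record_every: int = 1,
    track_index: int | None = None,
    movable: np.ndarray | None = None,
) -> EnergyTrace:
    """Advance the chain by ``n_sweeps`` sweeps (one elementary step per
    movable dipole per sweep), updating ``state`` in place.

    Identical (state seed, arguments) give identical traces.  Core-clamp
    violations are silent rejections.  ``track_index`` records that dipole's
    angle once per sweep (used for sampling checks).
    """
    if n_sweeps < 0:
        raise ValueError("n_sweeps must be >= 0")
    if n_sweeps == 0:
        return EnergyTrace(
            sweeps=np.empty(0, dtype=np.int64),
            energy=np.empty(0),
            acceptance=np.empty(0),
        )
    cfg = state.config
    params = state.params
    if movable is None:
        movable = np.arange(cfg.n, dtype=np.int64)
    else:
        movable = np.asarray(movable, dtype=np.int64)
        if movable.size == 0:
            raise ValueError("movable index set must be non-empty")

    dx_max = scale.effective_dx_max
    rcut = params.r_cutoff if params.r_cutoff is not None else -1.0
    skin = max(params.lj_sigma, 2.1 * dx_max) if rcut > 0 else 0.0

    out = run_mc_kernel(
        cfg.positions,
        cfg.angles,
        movable,
        0.5 * cfg.l,
        params.coulomb_prefactor_C,
        params.lj_epsilon,
        params.lj_sigma,
        rcut,
        params.core_clamp_dmin,
        thermostat.kBT,
        scale.dalpha_max,
        dx_max,
        n_sweeps,
        record_every,
        _kernel_seed(state.rng),
        skin,
        -1 if track_index is None else int(track_index),
        64,
    )
    rec_sweeps, rec_e, rec_acc, tracked, n_acc, n_steps, e_final = out
    state.E_p = float(e_final)
    state.step_count += int(n_steps)
    state.accept_count += int(n_acc)
    return EnergyTrace(
        sweeps=rec_sweeps + 0,  # copy out of kernel buffers
        energy=rec_e,
        acceptance=rec_acc,
        tracked_angles=tracked if track_index is not None else None,
    )


@dataclass
class RampResult:
    """Output of the pinned-rotor temperature ramp."""

    temperatures: np.ndarray
    mean_Ep: np.ndarray
    std_Ep: np.ndarray
    acceptance: np.ndarray
    snapshots: list[DipoleConfiguration]
    final_config: DipoleConfiguration
    quench_T: float | None = None
    quench_mean_Ep: float | None = None
    n_dipoles: int = 0
    # recorded rows (global_sweep, T, E_p, acceptance), ramp + quench stages
    trace: np.ndarray | None = None

    @property
    def mean_Ep_per_dipole(self) -> np.ndarray:
        return self.mean_Ep / max(self.n_dipoles, 1)


def run_temperature_ramp(
    protocol: ProtocolSpec,
    lattice: LatticeSpec,
    params: energetics.PairPotentialParams,
    dalpha_max: float = math.pi / 2.0,
) -> RampResult:
    """Heat one pinned rotor lattice through the temperature schedule.

    The same Markov chain is carried through the schedule (the system is
    heated, not re-initialised), equilibrated and then recorded at each
    temperature; a final quench stage runs if ``protocol.quench_T`` is set.
    """
    if protocol.mode != "temperature_ramp":
        raise ValueError("protocol.mode must be 'temperature_ramp'")
    config = build_lattice(lattice, seed=protocol.seed)
    state = MCState(config=config, params=params, seed=protocol.seed)
    scale = MoveScale.from_k(0.0, config.l, dalpha_max=dalpha_max, pinned=True)

    means, stds, accs, snaps = [], [], [], []
    trace_rows: list[list[float]] = []
    sweep_offset = 0
    for T in protocol.schedule:
        thermostat = Thermostat(T=T, kB=params.kB)
        if protocol.equilibration_sweeps:
            run_sweeps(
                state, scale, thermostat, protocol.equilibration_sweeps,
                record_every=protocol.equilibration_sweeps,
            )
            sweep_offset += protocol.equilibration_sweeps
        trace = run_sweeps(
            state, scale, thermostat, protocol.sweeps_per_point,
            record_every=protocol.record_every,
        )
        for sw, ep, ac in zip(trace.sweeps, trace.energy, trace.acceptance):
            trace_rows.append([sweep_offset + int(sw), T, float(ep), float(ac)])
        sweep_offset += protocol.sweeps_per_point
        means.append(trace.energy.mean())
        stds.append(trace.energy.std())
        accs.append(trace.acceptance.mean())
        snaps.append(state.config.copy())

    quench_mean = None
    if protocol.quench_schedule is not None and protocol.quench_sweeps > 0:
        for T in protocol.quench_schedule:
            thermostat = Thermostat(T=T, kB=params.kB)
            run_sweeps(
                state, scale, thermostat, protocol.quench_sweeps,
                record_every=protocol.quench_sweeps,
            )
            sweep_offset += protocol.quench_sweeps
        T_final = protocol.quench_schedule[-1]
        thermostat = Thermostat(T=T_final, kB=params.kB)
        trace = run_sweeps(
            state, scale, thermostat, protocol.sweeps_per_point,
            record_every=protocol.record_every,
        )
        for sw, ep, ac in zip(trace.sweeps, trace.energy, trace.acceptance):
            trace_rows.append(
                [sweep_offset + int(sw), T_final, float(ep), float(ac)]
            )
        quench_mean = float(trace.energy.mean())

    return RampResult(
        temperatures=np.asarray(protocol.schedule, dtype=float),
        mean_Ep=np.asarray(means),
        std_Ep=np.asarray(stds),
        acceptance=np.asarray(accs),
        snapshots=snaps,
        final_config=state.config.copy(),
        quench_T=protocol.quench_T,
        quench_mean_Ep=quench_mean,
        n_dipoles=config.n,
        trace=np.asarray(trace_rows) if trace_rows else None,
    )


@dataclass
class KScanResult:
    """Output of the mobility scan: one independent run per (k, replicate)."""

    k_values: np.ndarray
    mean_Ep: np.ndarray  # (n_k, n_replicates) recorded-window means
    initial_Ep: np.ndarray  # (n_k, n_replicates)
    acceptance: np.ndarray  # (n_k, n_replicates)
    final_configs: list[list[DipoleConfiguration]]  # [ik][rep]
    temperature: float
    n_dipoles: int

    @property
    def mean_Ep_per_dipole(self) -> np.ndarray:
        return self.mean_Ep / max(self.n_dipoles, 1)

    @property
    def relative_Ep(self) -> np.ndarray:
        """Final mean energy normalised to the initial-state energy."""
        return self.mean_Ep / self.initial_Ep

    def estimate_kc(self, **kwargs):
        from .observables import estimate_kc

        return estimate_kc(self.k_values, self.mean_Ep, **kwargs)


def run_k_scan(
    protocol: ProtocolSpec,
    lattice: LatticeSpec,
    params: energetics.PairPotentialParams,
    dalpha_max: float = math.pi / 2.0,
    keep_configs: bool = True,
) -> KScanResult:
    """One independent mobile-dipole simulation per ``k`` in the schedule.

    Every run starts from lattice positions with fresh random orientations
    (fresh seed per (k, replicate) unless ``fixed_seed_per_k``, which reuses
    the same initial state and random stream across the k grid for variance
    reduction).  The recorded quantity is the mean binding energy over the
    recording window after equilibration — the "final state" energy of the
    scan.
    """
    if protocol.mode != "k_scan":
        raise ValueError("protocol.mode must be 'k_scan'")
    n_k = len(protocol.schedule)
    n_rep = protocol.n_replicates
    mean_ep = np.empty((n_k, n_rep))
    init_ep = np.empty((n_k, n_rep))
    acc = np.empty((n_k, n_rep))
    configs: list[list[DipoleConfiguration]] = []
    thermostat = Thermostat(T=protocol.temperature, kB=params.kB)

    for ik, k in enumerate(protocol.schedule):
        row: list[DipoleConfiguration] = []
        for rep in range(n_rep):
            if protocol.fixed_seed_per_k:
                entropy = [int(protocol.seed), rep]
            else:
                entropy = [int(protocol.seed), ik, rep]
            run_seed = int(
                np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31 - 1)
            )
            config = build_lattice(lattice, seed=run_seed)
            state = MCState(config=config, params=params, seed=run_seed)
            init_ep[ik, rep] = state.E_p
            scale = MoveScale.from_k(k, config.l, dalpha_max=dalpha_max)
            if protocol.equilibration_sweeps:
                run_sweeps(
                    state, scale, thermostat, protocol.equilibration_sweeps,
                    record_every=protocol.equilibration_sweeps,
                )
            trace = run_sweeps(
                state, scale, thermostat, protocol.sweeps_per_point,
                record_every=protocol.record_every,
            )
            mean_ep[ik, rep] = trace.energy.mean()
            acc[ik, rep] = trace.acceptance.mean()
            if keep_configs:
                row.append(state.config.copy())
        configs.append(row)

    return KScanResult(
        k_values=np.asarray(protocol.schedule, dtype=float),
        mean_Ep=mean_ep,
        initial_Ep=init_ep,
        acceptance=acc,
        final_configs=configs,
        temperature=protocol.temperature,
        n_dipoles=lattice.n_dipoles,
    )
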