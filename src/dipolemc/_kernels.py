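"""Numba-compiled inner loops for the Metropolis engine.

The pair potential here mirrors :mod:`dipolemc.energetics` exactly (four
tip-charge Coulomb terms plus centre-distance Lennard-Jones, plain truncation
at ``r_cutoff``); the test suite cross-checks the two paths.  With a cutoff, a
Verlet neighbour list (radius ``r_cutoff + skin``) is rebuilt whenever any
dipole has accumulated more than ``skin/2`` of displacement, which guarantees
no interacting pair is ever missed as long as single-move displacements stay
below ``skin/2`` (enforced by the caller).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_mc_kernel", "total_energy_kernel", "min_pair_distance"]


@njit(cache=True)
def _pair_u(dx, dy, axi, ayi, axj, ayj, C, eps, sigma, rcut):
    """U_ij for centre separation d = r_j - r_i and half-vectors a_i, a_j."""
    r2 = dx * dx + dy * dy
    if rcut > 0.0 and r2 > rcut * rcut:
        return 0.0
    # Coulomb: charges +e at r +/- a tips; signs as in the four-term sum
    ux = dx + axj - axi
    uy = dy + ayj - ayi
    t1 = 1.0 / np.sqrt(ux * ux + uy * uy)
    ux = dx - axj - axi
    uy = dy - ayj - ayi
    t2 = 1.0 / np.sqrt(ux * ux + uy * uy)
    ux = dx - axj + axi
    uy = dy - ayj + ayi
    t3 = 1.0 / np.sqrt(ux * ux + uy * uy)
    ux = dx + axj + axi
    uy = dy + ayj + ayi
    t4 = 1.0 / np.sqrt(ux * ux + uy * uy)
    uc = C * (t1 - t2 + t3 - t4)
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    return uc + 4.0 * eps * (s6 * s6 - s6)


@njit(cache=True)
def total_energy_kernel(pos, ax, ay, C, eps, sigma, rcut):
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            e += _pair_u(
                pos[j, 0] - pos[i, 0],
                pos[j, 1] - pos[i, 1],
                ax[i], ay[i], ax[j], ay[j],
                C, eps, sigma, rcut,
            )
    return e


@njit(cache=True)
def min_pair_distance(pos):
    n = pos.shape[0]
    best = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            r2 = dx * dx + dy * dy
            if r2 < best:
                best = r2
    return np.sqrt(best)


@njit(cache=True)
def _build_neighbor_list(pos, rlist, nbr, nnbr):
    """Symmetric adjacency within rlist.  Returns True on overflow."""
    n = pos.shape[0]
    maxn = nbr.shape[1]
    rl2 = rlist * rlist
    for i in range(n):
        nnbr[i] = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            if dx * dx + dy * dy <= rl2:
                if nnbr[i] >= maxn or nnbr[j] >= maxn:
                    return True
                nbr[i, nnbr[i]] = j
                nnbr[i] += 1
                nbr[j, nnbr[j]] = i
                nnbr[j] += 1
    return False


@njit(cache=True)
def run_mc_kernel(
    pos,
    ang,
    movable,
    half_l,
    C,
    eps,
    sigma,
    rcut,
    dmin,
    kBT,
    dalpha_max,
    dx_max,
    n_sweeps,
    record_every,
    seed,
    skin,
    track_idx,
    max_neighbors,
):
    """Run Metropolis sweeps in place; one sweep = one elementary step per
    movable dipole.  Each step rotates a randomly drawn movable dipole by a
    uniform angle on (-dalpha_max, +dalpha_max) and displaces it by a uniform
    magnitude on (0, dx_max) in a uniform direction; downhill moves are always
    accepted, uphill with probability exp(-dE/kBT); moves taking any centre
    pair below ``dmin`` are rejected outright.

    Returns (rec_sweeps, rec_energy, rec_acceptance, tracked_angles,
    total_accepts, total_steps, final_energy).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_mov = movable.shape[0]
    twopi = 2.0 * np.pi

    ax = np.empty(n)
    ay = np.empty(n)
    for i in range(n):
        ax[i] = half_l * np.cos(ang[i])
        ay[i] = half_l * np.sin(ang[i])

    use_nbr = rcut > 0.0 and n > 8
    rlist = rcut + skin
    if use_nbr:
        nbr = np.empty((n, max_neighbors), dtype=np.int64)
        nnbr = np.zeros(n, dtype=np.int64)
        disp = np.zeros(n)
        overflow = _build_neighbor_list(pos, rlist, nbr, nnbr)
        while overflow:
            max_neighbors *= 2
            nbr = np.empty((n, max_neighbors), dtype=np.int64)
            overflow = _build_neighbor_list(pos, rlist, nbr, nnbr)
    else:
        nbr = np.empty((1, 1), dtype=np.int64)
        nnbr = np.zeros(1, dtype=np.int64)
        disp = np.zeros(1)

    e = total_energy_kernel(pos, ax, ay, C, eps, sigma, rcut)

    n_rec = n_sweeps // record_every if record_every > 0 else 0
    rec_sweeps = np.empty(n_rec, dtype=np.int64)
    rec_e = np.empty(n_rec)
    rec_acc = np.empty(n_rec)
    tracked = np.empty(n_sweeps if track_idx >= 0 else 0)

    total_acc = 0
    total_steps = 0
    win_acc = 0
    win_steps = 0
    rec_i = 0

    for sweep in range(n_sweeps):
        for _ in range(n_mov):
            i = movable[np.int64(np.random.random() * n_mov)]
            da = (2.0 * np.random.random() - 1.0) * dalpha_max
            new_ang = ang[i] + da
            if dx_max > 0.0:
                step = np.random.random() * dx_max
                theta = np.random.random() * twopi
                nx = pos[i, 0] + step * np.cos(theta)
                ny = pos[i, 1] + step * np.sin(theta)
            else:
                step = 0.0
                nx = pos[i, 0]
                ny = pos[i, 1]
            nax = half_l * np.cos(new_ang)
            nay = half_l * np.sin(new_ang)

            de = 0.0
            reject = False
            if use_nbr:
                for m in range(nnbr[i]):
                    j = nbr[i, m]
                    dx_n = pos[j, 0] - nx
                    dy_n = pos[j, 1] - ny
                    if dx_n * dx_n + dy_n * dy_n < dmin * dmin:
                        reject = True
                        break
                    de += _pair_u(dx_n, dy_n, nax, nay, ax[j], ay[j],
                                  C, eps, sigma, rcut)
                    de -= _pair_u(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                                  ax[i], ay[i], ax[j], ay[j],
                                  C, eps, sigma, rcut)
            else:
                for j in range(n):
                    if j == i:
                        continue
                    dx_n = pos[j, 0] - nx
                    dy_n = pos[j, 1] - ny
                    if dx_n * dx_n + dy_n * dy_n < dmin * dmin:
                        reject = True
                        break
                    de += _pair_u(dx_n, dy_n, nax, nay, ax[j], ay[j],
                                  C, eps, sigma, rcut)
                    de -= _pair_u(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1],
                                  ax[i], ay[i], ax[j], ay[j],
                                  C, eps, sigma, rcut)

            accept = False
            if not reject:
                if de <= 0.0:
                    accept = True
                elif np.random.random() < np.exp(-de / kBT):
                    accept = True

            if accept:
                pos[i, 0] = nx
                pos[i, 1] = ny
                ang[i] = new_ang % twopi
                ax[i] = nax
                ay[i] = nay
                e += de
                total_acc += 1
                win_acc += 1
                if use_nbr and step > 0.0:
                    disp[i] += step
                    if disp[i] > 0.5 * skin:
                        overflow = _build_neighbor_list(pos, rlist, nbr, nnbr)
                        while overflow:
                            max_neighbors *= 2
                            nbr = np.empty((n, max_neighbors), dtype=np.int64)
                            overflow = _build_neighbor_list(pos, rlist, nbr, nnbr)
                        for q in range(n):
                            disp[q] = 0.0
            total_steps += 1
            win_steps += 1

        if track_idx >= 0:
            tracked[sweep] = ang[track_idx]
        if record_every > 0 and (sweep + 1) % record_every == 0:
            rec_sweeps[rec_i] = sweep + 1
            rec_e[rec_i] = e
            rec_acc[rec_i] = win_acc / win_steps if win_steps > 0 else 0.0
            rec_i += 1
            win_acc = 0
            win_steps = 0

    return rec_sweeps, rec_e, rec_acc, tracked, total_acc, total_steps, e
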