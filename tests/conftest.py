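import math

import numpy as np
import pytest

from dipolemc import LatticeSpec, PairPotentialParams


@pytest.fixture
def reduced_params():
    """Canonical reduced-unit potential for spacing s = 1 nm (l = 0.5 nm)."""
    return PairPotentialParams.for_spacing(1.0)


@pytest.fixture
def coulomb_only():
    """Pure four-charge Coulomb term (no LJ), generous clamp-free geometry."""
    return PairPotentialParams(
        coulomb_prefactor_C=1.0, lj_epsilon=0.0, lj_sigma=0.75,
        core_clamp_dmin=1e-9,
    )


@pytest.fixture
def square_15(reduced_params):
    return LatticeSpec("rectangular", 15, 15, 0.5)


def random_configuration(n, seed, l=0.5, min_dist=0.8, box=6.0):
    """Well-separated random dipole configuration for invariance tests."""
    from dipolemc import DipoleConfiguration

    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        cand = rng.uniform(0.0, box, size=2)
        if all(np.hypot(*(cand - p)) >= min_dist for p in pts):
            pts.append(cand)
    return DipoleConfiguration(
        positions=np.array(pts),
        angles=rng.uniform(0.0, 2.0 * math.pi, size=n),
        l=l,
    )
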