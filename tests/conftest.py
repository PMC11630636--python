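"""Shared fixtures and frozen oracle values.

The six-state example model admits exact analysis: its stationary vector is
the rational nullspace of the generator's transpose (computed once with
exact rational arithmetic and frozen below) and its steady-state current
follows in closed form from the boundary-edge formula.
"""

import numpy as np
import pytest

from permkin import (discretize, kcsa_toy_model, simulate_ctmc,
                     LumpingMap)

# Rational-arithmetic nullspace of Q^T, normalized:
# [1861/10202, 3965/15303, 437/10202, 1247/30606, 4955/30606, 4790/15303]
TOY_PINF = np.array([
    0.1824152127033915,
    0.2590995229693524,
    0.04283473828661047,
    0.040743645036920864,
    0.16189636019081227,
    0.3130105208129125,
])

# e0 * (Pinf_0 * Q_01 - Pinf_1 * Q_10) in pA, exact rational arithmetic
TOY_CURRENT_PA = 2.0923675116310525

# Minimal-path fluxes between the six ion configurations, in units of 1/7
# (hand-enumerated on the single-file chain: each entry is the signed number
# of intervals crossed along the shortest ion-move pathway)
TOY_F7 = np.array([
    [0, 1, 2, -3, -2, -1],
    [-1, 0, 1, 3, -3, -2],
    [-2, -1, 0, 2, 3, -3],
    [3, -3, -2, 0, 1, 2],
    [2, 3, -3, -1, 0, 1],
    [1, 2, 3, -2, -1, 0],
], dtype=float)

# states KOKOOK, KOOKOK, WKOKOK merged into one macrostate
FIG3B_PARTITION = {
    "WOKKOK": "WOKKOK",
    "KOKKOK": "KOKKOK",
    "KOKKOO": "KOKKOO",
    "KOKOOK": "X",
    "KOOKOK": "X",
    "WKOKOK": "X",
}


@pytest.fixture(scope="session")
def toy():
    return kcsa_toy_model()


@pytest.fixture(scope="session")
def fig3b_map():
    return LumpingMap(FIG3B_PARTITION)


@pytest.fixture(scope="session")
def replica_trajs(toy):
    """Four 0.25 ms replicas (1 ms total) sampled every 0.1 ns."""
    out = []
    for r in range(4):
        ev = simulate_ctmc(toy.Q, 250_000.0, seed=1000 + r)
        out.append(discretize(ev, 0.1, replica_id=r))
    return out
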