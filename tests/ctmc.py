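"""Shared small-system CTMC machinery: chain grids, a dense pressure
oracle, and the enumerated master-equation generator for movement-only
dynamics on a 3-voxel chain."""

from itertools import product

import numpy as np

from avtumor.dlcm import PopulationState
from avtumor.fields import ModelParams
from avtumor.grid import grid_from_mask

#: movement-only parameters: ample oxygen (no sink), division, death and
#: degradation all switched off
MOVE_ONLY = ModelParams(mu_prol=0.0, mu_death=0.0, mu_deg=0.0, kappa_prol=1.0,
                        kappa_death=0.0, lam=0.0, D1=1.0, D2=25.0)


def chain_grid(n=3, h=0.1):
    return grid_from_mask(h, np.ones((n, 1), dtype=bool))


def chain_state(grid, occupancies):
    u = np.array(occupancies, dtype=np.int8).reshape(-1, 1)
    return PopulationState(u, grid)


def chain_pressure_oracle(u, h):
    """Independent dense solve of the 1D chain pressure problem.

    Tumor nodes (u != 0) are unknowns; empty in-chain nodes are Dirichlet 0;
    ends are zero-flux.  Returns the full per-node pressure with NaN on
    nodes that are neither.
    """
    n = len(u)
    tumor = [i for i in range(n) if u[i] != 0]
    pos = {i: k for k, i in enumerate(tumor)}
    A = np.zeros((len(tumor), len(tumor)))
    b = np.zeros(len(tumor))
    for i in tumor:
        k = pos[i]
        for j in (i - 1, i + 1):
            if j < 0 or j >= n:
                continue  # zero-flux end
            A[k, k] += 1.0 / h**2
            if j in pos:
                A[k, pos[j]] -= 1.0 / h**2
            # else: empty Dirichlet node at value 0 (no b contribution)
        b[k] = 1.0 if u[i] == 2 else 0.0
    x = np.linalg.solve(A, b)
    full = np.full(n, np.nan)
    for i in tumor:
        full[i] = x[pos[i]]
    for i in range(n):
        if u[i] == 0:
            full[i] = 0.0
    return full


def enumerate_chain_generator(h=0.1):
    """All 27 occupancy states of the movement-only 3-chain and the exact
    CTMC generator built from the dense pressure oracle."""
    states = [s for s in product((0, 1, 2), repeat=3)]
    index = {s: i for i, s in enumerate(states)}
    Q = np.zeros((27, 27))
    D1, D2 = MOVE_ONLY.D1, MOVE_ONLY.D2
    for s in states:
        if 2 not in s:
            continue  # no pressure source: no movement channels
        if 0 not in s:
            continue  # packed domain: no free volume, no movement
        p = chain_pressure_oracle(list(s), h)
        for i, j in ((0, 1), (1, 0), (1, 2), (2, 1)):
            ui, uj = s[i], s[j]
            flux = (p[i] - p[j]) / h**2
            if flux <= 0:
                continue
            if ui >= 1 and uj == 0:
                rate = D1 * flux
            elif ui == 2 and uj == 1:
                rate = D2 * flux
            else:
                continue
            t = list(s)
            t[i] -= 1
            t[j] += 1
            Q[index[s], index[tuple(t)]] += rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return states, index, Q
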