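"""Shared fixtures and small state-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from stemcpm.cpm_core import LatticeState, SimulationConfig
from stemcpm.hierarchy import CellType


def make_config(**kw) -> SimulationConfig:
    """A small, fast config for unit tests; overrides welcome."""
    defaults = dict(lattice_size=48, stop_volume=64, seed=1234)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def place_block(
    state: LatticeState,
    r0: int,
    c0: int,
    height: int,
    width: int,
    cell_type: CellType = CellType.CSC,
    phenotype: int = 0,
    target: float | None = None,
    **cell_kw,
) -> int:
    """Create a cell occupying a rectangular block of lattice sites."""
    sigma = state.new_cell(cell_type, phenotype=phenotype, **cell_kw)
    for r in range(r0, r0 + height):
        for c in range(c0, c0 + width):
            state.claim_site(sigma, r, c)
    if target is not None:
        state.target[sigma] = target
    else:
        state.target[sigma] = float(state.volume[sigma])
    return sigma


def brute_force_adhesion(grid: np.ndarray, j_cc: float, j_cm: float, neighborhood: int) -> float:
    """Independent O(N^2 * k) enumeration of all unordered contact pairs."""
    n = grid.shape[0]
    if neighborhood == 8:
        shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]
    else:
        shifts = [(0, 1), (1, 0)]
    energy = 0.0
    for i in range(n):
        for j in range(n):
            for dr, dc in shifts:
                ni, nj = i + dr, j + dc
                if not (0 <= ni < n and 0 <= nj < n):
                    continue
                a, b = grid[i, j], grid[ni, nj]
                if a == b:
                    continue
                energy += j_cm if (a == 0 or b == 0) else j_cc
    return energy


def brute_force_total_energy(state: LatticeState, config: SimulationConfig) -> float:
    """Full re-scan oracle: volume term per live cell + pair enumeration."""
    e = brute_force_adhesion(
        state.grid, config.adhesion_j, config.adhesion_j_medium, config.neighborhood
    )
    for sigma in state.live_sigmas():
        v = int(state.volume[sigma])
        t = float(state.target[sigma])
        e += config.lambda_stiffness * (v - t) ** 2
    return e


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
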