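"""The lattice engine: a 2-D cellular Potts model of tumor growth.

Cells are connected domains of lattice sites sharing a positive integer
identifier sigma (0 = medium). The system energy is the Hamiltonian

    H = E_v + E_a
    E_v = sum_cells lambda * (V_sigma - V_target)^2      (volume elasticity)
    E_a = sum_{neighbor pairs, different sigma} J(tau1, tau2)  (adhesion)

and evolves by Metropolis copy attempts: a random site takes the
identifier of a random neighbor; the move is accepted with probability
1 if it lowers the energy and exp(-dH/T) otherwise. On top of the
Potts dynamics each non-quiescent cell raises its target volume by a
fitness-scaled increment per Monte-Carlo step, divides by a geometric
lattice split once a full cycle of target growth has accumulated
(target doubled from V0 to 2*V0), and may die in a daily apoptosis
sweep. One Monte-Carlo step (MCS) maps to a configurable number of
simulated hours (default 0.25 h, i.e. four relaxation sweeps per
simulated hour), with the target-volume increment calibrated so a
reference-fitness cell doubles its volume demand in one cell cycle.

The inner attempt loop is compiled with numba over flat per-cell
arrays; ``metropolis_attempt`` exposes the identical single-attempt
logic at Python level for testing and instrumentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as _dc_fields, replace as _dc_replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage as _ndimage

from . import analysis_stats, hierarchy, mutation_models
from .hierarchy import CellType, FateRule

__all__ = [
    "SimulationConfig",
    "CellRecord",
    "LatticeState",
    "SimulationResult",
    "BoundaryContactError",
    "AuditError",
    "volume_energy",
    "adhesion_energy",
    "total_energy",
    "accept_probability",
    "metropolis_attempt",
    "monte_carlo_step",
    "grow_cells",
    "divide_cell",
    "kill_cell",
    "apoptosis_sweep",
    "audit_state",
    "seed_founder",
    "auto_lattice_size",
    "run_simulation",
]

MODES = ("neutral", "fitness", "therapy", "constant_population")

TIMESERIES_COLUMNS = [
    "time_hours",
    "mcs",
    "n_cells",
    "n_csc",
    "n_tac",
    "n_dc",
    "divisions",
    "shannon_norm",
    "mean_fitness",
]


class BoundaryContactError(RuntimeError):
    """The tumor reached the lattice boundary; the lattice is too small."""


class AuditError(RuntimeError):
    """Grid and cell registry disagree (internal consistency violation)."""


# --- configuration ------------------------------------------------------


@dataclass
class SimulationConfig:
    """All model parameters plus engineering knobs.

    Defaults are the published operating point of the model: cell cycle
    c = 20 h, methylation error rate mu = 2e-5 per CpG per division,
    adhesion J = 9, stiffness lambda = 3, TAC depth G = 5, apoptosis
    a = 0.01 per 24 h in neutral runs and a_f = 0.02 in fitness-driven
    runs, non-neutral mutation rate mu_f = 0.1 per division. The
    Metropolis temperature T is an engineering parameter of the same
    order as J; it rescales membrane fluctuation only.
    """

    lattice_size: int = 2000
    sites_per_cell: int = 16
    base_target_volume: Optional[int] = None  # V0; defaults to sites_per_cell
    lambda_stiffness: float = 3.0
    adhesion_j: float = 9.0
    adhesion_j_medium: float = 9.0
    temperature: float = 8.0
    cell_cycle_hours: float = 20.0
    hours_per_mcs: float = 0.25
    psi: float = 0.1
    max_tac_divisions: int = 5
    apoptosis_rate: Optional[float] = None  # a (neutral: 0.01) / a_f (else: 0.02)
    methylation_rate: float = 2e-5
    n_cpg: int = 64
    nonneutral_rate: float = 0.1
    phenotype_min: int = mutation_models.PHENOTYPE_MIN
    phenotype_max: int = mutation_models.PHENOTYPE_MAX
    landscape: str = "neutral"
    stop_volume: int = 100_000
    mode: str = "neutral"
    seed: int = 0
    neighborhood: int = 8  # Moore; 4 = von Neumann
    sample_every_hours: float = 24.0
    therapy_trigger_volume: int = 30_000
    therapy_rule: str = "fitness"  # kill non-quiescent cells w.p. f(x)/f_max
    therapy_window_hours: float = 72.0  # used by the "window" rule
    constpop_start_volume: int = 25_000
    constpop_division_budget: int = 1_200_000
    growth_gate_margin: float = 4.0  # contact inhibition: sites of tolerated lag
    max_hours: float = 1.0e7  # hard safety stop

    def __post_init__(self) -> None:
        if self.base_target_volume is None:
            self.base_target_volume = self.sites_per_cell
        if self.apoptosis_rate is None:
            self.apoptosis_rate = 0.01 if self.mode == "neutral" else 0.02
        self.validate()

    def validate(self) -> None:
        err = []
        if self.mode not in MODES:
            err.append(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0.0 <= self.psi <= 1.0:
            err.append(f"psi must lie in [0, 1], got {self.psi}")
        if self.max_tac_divisions < 0:
            err.append(f"max_tac_divisions must be >= 0, got {self.max_tac_divisions}")
        if not 0.0 <= self.methylation_rate <= 1.0:
            err.append(f"methylation_rate must lie in [0, 1], got {self.methylation_rate}")
        if not 0.0 <= self.nonneutral_rate <= 1.0:
            err.append(f"nonneutral_rate must lie in [0, 1], got {self.nonneutral_rate}")
        if not 0.0 <= self.apoptosis_rate < 1.0:
            err.append(f"apoptosis_rate must lie in [0, 1), got {self.apoptosis_rate}")
        if self.temperature <= 0:
            err.append(f"temperature must be > 0, got {self.temperature}")
        if self.lambda_stiffness < 0:
            err.append(f"lambda_stiffness must be >= 0, got {self.lambda_stiffness}")
        if self.base_target_volume is not None and self.base_target_volume < 4:
            err.append(f"base_target_volume must be >= 4, got {self.base_target_volume}")
        if not self.phenotype_min < 0 < self.phenotype_max:
            err.append("phenotype domain must straddle 0")
        if self.n_cpg != mutation_models.N_CPG_SITES:
            err.append(f"n_cpg is fixed at {mutation_models.N_CPG_SITES}")
        if self.neighborhood not in (4, 8):
            err.append(f"neighborhood must be 4 or 8, got {self.neighborhood}")
        if self.lattice_size < 8:
            err.append(f"lattice_size must be >= 8, got {self.lattice_size}")
        if self.cell_cycle_hours <= 0 or self.hours_per_mcs <= 0:
            err.append("cell_cycle_hours and hours_per_mcs must be positive")
        if self.stop_volume < 1:
            err.append(f"stop_volume must be >= 1, got {self.stop_volume}")
        if self.landscape not in mutation_models._LANDSCAPE_FUNCS:
            err.append(f"unknown landscape {self.landscape!r}")
        if self.therapy_rule not in ("fitness", "cycling", "window"):
            err.append(
                f"therapy_rule must be 'fitness', 'cycling' or 'window', got {self.therapy_rule!r}"
            )
        if self.therapy_window_hours < 0:
            err.append("therapy_window_hours must be >= 0")
        if err:
            raise ValueError("; ".join(err))

    @property
    def target_volume_increment(self) -> float:
        """delta-V per MCS for a reference-fitness cell: V0 * dt / c."""
        return self.base_target_volume * self.hours_per_mcs / self.cell_cycle_hours

    @property
    def division_volume(self) -> int:
        """Division trigger: target volume doubled from V0 to 2 * V0."""
        return 2 * self.base_target_volume

    def fate_rule(self) -> FateRule:
        return FateRule(psi=self.psi, max_tac_divisions=self.max_tac_divisions)

    def replace(self, **kwargs) -> "SimulationConfig":
        return _dc_replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in _dc_fields(self)}


def auto_lattice_size(stop_volume: int, sites_per_cell: int = 16) -> int:
    """A lattice comfortably larger than the final tumor footprint.

    Sized so a roughly circular tumor of ``stop_volume`` cells sits well
    clear of the boundary even with irregular, lobed, off-center
    growth (factor 2.8 over the nominal circular diameter, minimum 64).
    """
    diameter = 2.0 * math.sqrt(stop_volume * sites_per_cell / math.pi)
    return max(64, int(math.ceil(2.8 * diameter)))


# --- state --------------------------------------------------------------


@dataclass(frozen=True)
class CellRecord:
    """Snapshot of one cell in the registry."""

    sigma: int
    cell_type: CellType
    divisions_used: int
    volume: int
    target_volume: float
    methylation: int
    phenotype: int
    parent_sigma: int
    birth_hours: float


_BBOX_EMPTY = np.array([np.iinfo(np.int32).max, -1, np.iinfo(np.int32).max, -1], dtype=np.int64)


class LatticeState:
    """Integer grid of cell identifiers plus the array-backed registry.

    Per-cell attributes live in flat arrays indexed by sigma, so the
    compiled Metropolis kernel and the vectorized growth rule can touch
    them without boxing. Identifiers are never reused; row 0 is the
    medium and always dead. Each cell carries a bounding box that is a
    superset of its sites (grown on accepted copies, tightened at
    division and during audits).
    """

    def __init__(self, config: SimulationConfig, capacity: int = 1024):
        self.config = config
        n = config.lattice_size
        self.grid = np.zeros((n, n), dtype=np.int32)
        self._cap = max(capacity, 16)
        self.volume = np.zeros(self._cap, dtype=np.int64)
        self.target = np.zeros(self._cap, dtype=np.float64)
        self.ctype = np.zeros(self._cap, dtype=np.int8)
        self.divs = np.zeros(self._cap, dtype=np.int16)
        self.phen = np.zeros(self._cap, dtype=np.int16)
        self.meth = np.zeros(self._cap, dtype=np.uint64)
        self.alive = np.zeros(self._cap, dtype=np.bool_)
        self.parent = np.zeros(self._cap, dtype=np.int32)
        self.birth = np.zeros(self._cap, dtype=np.float64)
        self.bbox = np.tile(_BBOX_EMPTY, (self._cap, 1))
        self.tumor_bbox = _BBOX_EMPTY.copy()
        self.next_sigma = 1
        self.clock_mcs = 0
        self.clock_hours = 0.0
        self.total_divisions = 0
        self.total_attempts = 0
        ss = np.random.SeedSequence(config.seed)
        py_ss, kernel_ss = ss.spawn(2)
        self.rng = np.random.Generator(np.random.PCG64(py_ss))
        kseed = kernel_ss.generate_state(1, dtype=np.uint64)
        self.kstate = np.where(kseed == 0, np.uint64(0x9E3779B97F4A7C15), kseed)

    # -- registry plumbing ----------------------------------------------

    def _ensure_capacity(self, n: int) -> None:
        if n < self._cap:
            return
        new_cap = self._cap
        while new_cap <= n:
            new_cap *= 2
        for name in ("volume", "target", "ctype", "divs", "phen", "meth",
                     "alive", "parent", "birth"):
            old = getattr(self, name)
            grown = np.zeros(new_cap, dtype=old.dtype)
            grown[: self._cap] = old
            setattr(self, name, grown)
        grown_bbox = np.tile(_BBOX_EMPTY, (new_cap, 1))
        grown_bbox[: self._cap] = self.bbox
        self.bbox = grown_bbox
        self._cap = new_cap

    def new_cell(
        self,
        cell_type: CellType,
        divisions_used: int = 0,
        phenotype: int = 0,
        methylation: int = 0,
        parent_sigma: int = 0,
    ) -> int:
        sigma = self.next_sigma
        self._ensure_capacity(sigma)
        self.next_sigma += 1
        self.volume[sigma] = 0
        self.target[sigma] = float(self.config.base_target_volume)
        self.ctype[sigma] = int(cell_type)
        self.divs[sigma] = divisions_used
        self.phen[sigma] = phenotype
        self.meth[sigma] = np.uint64(methylation)
        self.alive[sigma] = True
        self.parent[sigma] = parent_sigma
        self.birth[sigma] = self.clock_hours
        self.bbox[sigma] = _BBOX_EMPTY
        return sigma

    def claim_site(self, sigma: int, r: int, c: int) -> None:
        """Assign a medium site to a cell (setup/division bookkeeping)."""
        if self.grid[r, c] != 0:
            raise ValueError("site already occupied")
        self.grid[r, c] = sigma
        self.volume[sigma] += 1
        self._expand_bbox(sigma, r, c)

    def _expand_bbox(self, sigma: int, r: int, c: int) -> None:
        b = self.bbox[sigma]
        b[0] = min(b[0], r)
        b[1] = max(b[1], r)
        b[2] = min(b[2], c)
        b[3] = max(b[3], c)
        t = self.tumor_bbox
        t[0] = min(t[0], r)
        t[1] = max(t[1], r)
        t[2] = min(t[2], c)
        t[3] = max(t[3], c)

    # -- views ------------------------------------------------------------

    def live_sigmas(self) -> np.ndarray:
        return np.flatnonzero(self.alive[: self.next_sigma])

    def live_mask(self) -> np.ndarray:
        return self.alive[: self.next_sigma]

    def cell_type_array(self) -> np.ndarray:
        return self.ctype[: self.next_sigma]

    def phenotype_array(self) -> np.ndarray:
        return self.phen[: self.next_sigma].astype(np.int64)

    def methylation_array(self) -> np.ndarray:
        return self.meth[: self.next_sigma]

    def n_live_cells(self) -> int:
        return int(np.count_nonzero(self.alive[: self.next_sigma]))

    def count_type(self, cell_type: CellType) -> int:
        m = self.alive[: self.next_sigma] & (self.ctype[: self.next_sigma] == int(cell_type))
        return int(np.count_nonzero(m))

    def n_proliferative(self) -> int:
        """Live cells still able to divide (CSCs and TACs)."""
        m = self.alive[: self.next_sigma] & (self.ctype[: self.next_sigma] != int(CellType.DC))
        return int(np.count_nonzero(m))

    def cell(self, sigma: int) -> CellRecord:
        if not (0 < sigma < self.next_sigma) or not self.alive[sigma]:
            raise KeyError(f"no live cell with identifier {sigma}")
        return CellRecord(
            sigma=sigma,
            cell_type=CellType(int(self.ctype[sigma])),
            divisions_used=int(self.divs[sigma]),
            volume=int(self.volume[sigma]),
            target_volume=float(self.target[sigma]),
            methylation=int(self.meth[sigma]),
            phenotype=int(self.phen[sigma]),
            parent_sigma=int(self.parent[sigma]),
            birth_hours=float(self.birth[sigma]),
        )

    def records(self) -> Iterator[CellRecord]:
        for sigma in self.live_sigmas():
            yield self.cell(int(sigma))

    def cell_sites(self, sigma: int) -> np.ndarray:
        """(k, 2) row/col coordinates of the cell's sites (bbox scan)."""
        r0, r1, c0, c1 = self.bbox[sigma]
        sub = self.grid[r0 : r1 + 1, c0 : c1 + 1]
        coords = np.argwhere(sub == sigma)
        coords[:, 0] += r0
        coords[:, 1] += c0
        return coords

    def sampling_window(self, margin: int = 2) -> tuple[int, int, int, int]:
        """Tumor bounding window (inclusive-exclusive) padded by ``margin``."""
        n = self.config.lattice_size
        t = self.tumor_bbox
        if t[1] < 0:  # no tumor yet
            return 0, n, 0, n
        r0 = max(0, int(t[0]) - margin)
        r1 = min(n, int(t[1]) + margin + 1)
        c0 = max(0, int(t[2]) - margin)
        c1 = min(n, int(t[3]) + margin + 1)
        return r0, r1, c0, c1

    def check_boundary(self) -> None:
        n = self.config.lattice_size
        t = self.tumor_bbox
        if t[1] < 0:
            return
        if t[0] <= 0 or t[2] <= 0 or t[1] >= n - 1 or t[3] >= n - 1:
            raise BoundaryContactError(
                f"tumor touched the lattice boundary (bbox {t.tolist()}, N={n}); "
                "use a larger lattice_size"
            )


def seed_founder(state: LatticeState, phenotype: int = 0, methylation: int = 0) -> int:
    """Place the founder CSC as a compact square block at the lattice center."""
    cfg = state.config
    v0 = cfg.base_target_volume
    side = int(math.ceil(math.sqrt(v0)))
    n = cfg.lattice_size
    r_start = (n - side) // 2
    c_start = (n - side) // 2
    sigma = state.new_cell(CellType.CSC, phenotype=phenotype, methylation=methylation)
    placed = 0
    for r in range(r_start, r_start + side):
        for c in range(c_start, c_start + side):
            if placed >= v0:
                break
            state.claim_site(sigma, r, c)
            placed += 1
    return sigma


# --- energies -----------------------------------------------------------


def volume_energy(cell: CellRecord, lambda_stiffness: float) -> float:
    """Elastic energy lambda * (V - V_target)^2 of one cell."""
    if lambda_stiffness < 0:
        raise ValueError(f"lambda must be >= 0, got {lambda_stiffness}")
    if cell.volume < 0 or cell.target_volume < 0:
        raise ValueError("volumes must be nonnegative")
    dv = cell.volume - cell.target_volume
    return float(lambda_stiffness * dv * dv)


def _neighbor_shifts(neighborhood: int):
    shifts = [(0, 1), (1, 0)]
    if neighborhood == 8:
        shifts += [(1, 1), (1, -1)]
    return shifts


def adhesion_energy(state: LatticeState, config: SimulationConfig) -> float:
    """Total contact energy over unordered neighboring site pairs.

    Pairs sharing a sigma contribute nothing (the beta exclusion);
    cell-cell contacts cost J, cell-medium contacts J_medium.
    """
    g = state.grid
    j_cc = config.adhesion_j
    j_cm = config.adhesion_j_medium
    energy = 0.0
    for dr, dc in _neighbor_shifts(config.neighborhood):
        if dc >= 0:
            a = g[: g.shape[0] - dr, : g.shape[1] - dc]
            b = g[dr:, dc:]
        else:  # anti-diagonal
            a = g[: g.shape[0] - dr, -dc:]
            b = g[dr:, : g.shape[1] + dc]
        diff = a != b
        med = (a == 0) | (b == 0)
        energy += j_cc * np.count_nonzero(diff & ~med)
        energy += j_cm * np.count_nonzero(diff & med)
    return float(energy)


def total_energy(state: LatticeState, config: SimulationConfig) -> float:
    """Hamiltonian: volume elasticity over live cells plus adhesion."""
    lam = config.lambda_stiffness
    mask = state.live_mask()
    v = state.volume[: state.next_sigma][mask].astype(float)
    t = state.target[: state.next_sigma][mask]
    return float(np.sum(lam * (v - t) ** 2) + adhesion_energy(state, config))


# --- Metropolis kernel ---------------------------------------------------


@njit(cache=True, inline="always")
def _pair_cost(a, b, j_cc, j_cm):
    if a == b:
        return 0.0
    if a == 0 or b == 0:
        return j_cm
    return j_cc


@njit(cache=True)
def _delta_h(grid, volume, target, i, j, s_old, s_new, lam, j_cc, j_cm, offs):
    """Energy change of relabeling site (i, j) from s_old to s_new."""
    n = grid.shape[0]
    dh = 0.0
    if s_old > 0:
        v = float(volume[s_old])
        t = target[s_old]
        dh += lam * ((v - 1.0 - t) ** 2 - (v - t) ** 2)
    if s_new > 0:
        v = float(volume[s_new])
        t = target[s_new]
        dh += lam * ((v + 1.0 - t) ** 2 - (v - t) ** 2)
    for k in range(offs.shape[0]):
        ni = i + offs[k, 0]
        nj = j + offs[k, 1]
        if ni < 0 or nj < 0 or ni >= n or nj >= n:
            continue
        sn = grid[ni, nj]
        dh += _pair_cost(s_new, sn, j_cc, j_cm) - _pair_cost(s_old, sn, j_cc, j_cm)
    return dh


@njit(cache=True, inline="always")
def _xorshift(s):
    s ^= s >> np.uint64(12)
    s ^= (s << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(27)
    return s


@njit(cache=True, inline="always")
def _rand_u64(s):
    return s * np.uint64(0x2545F4914F6CDD1D)


@njit(cache=True)
def _run_attempts(
    grid, volume, target, alive, bbox, tumor_bbox, kstate,
    n_attempts, r0, r1, c0, c1, lam, j_cc, j_cm, temperature, offs,
):
    """Execute ``n_attempts`` Metropolis copy attempts inside the window."""
    s = kstate[0]
    height = np.uint64(r1 - r0)
    width = np.uint64(c1 - c0)
    ndir = np.uint64(offs.shape[0])
    inv53 = 1.0 / 9007199254740992.0
    for _ in range(n_attempts):
        s = _xorshift(s)
        i = r0 + np.int64(_rand_u64(s) % height)
        s = _xorshift(s)
        j = c0 + np.int64(_rand_u64(s) % width)
        s = _xorshift(s)
        d = np.int64(_rand_u64(s) % ndir)
        ni = i + offs[d, 0]
        nj = j + offs[d, 1]
        if ni < 0 or nj < 0 or ni >= grid.shape[0] or nj >= grid.shape[1]:
            continue
        s_new = grid[ni, nj]
        s_old = grid[i, j]
        if s_new == s_old:
            continue
        dh = _delta_h(grid, volume, target, i, j, s_old, s_new, lam, j_cc, j_cm, offs)
        if dh >= 0.0:
            s = _xorshift(s)
            u = float(_rand_u64(s) >> np.uint64(11)) * inv53
            if u >= np.exp(-dh / temperature):
                continue
        grid[i, j] = s_new
        if s_old > 0:
            volume[s_old] -= 1
            if volume[s_old] == 0:
                alive[s_old] = False
        if s_new > 0:
            volume[s_new] += 1
            if i < bbox[s_new, 0]:
                bbox[s_new, 0] = i
            if i > bbox[s_new, 1]:
                bbox[s_new, 1] = i
            if j < bbox[s_new, 2]:
                bbox[s_new, 2] = j
            if j > bbox[s_new, 3]:
                bbox[s_new, 3] = j
            if i < tumor_bbox[0]:
                tumor_bbox[0] = i
            if i > tumor_bbox[1]:
                tumor_bbox[1] = i
            if j < tumor_bbox[2]:
                tumor_bbox[2] = j
            if j > tumor_bbox[3]:
                tumor_bbox[3] = j
    kstate[0] = s


@njit(cache=True)
def _rebuild_geometry(grid, n_sigma):
    """Recompute exact volumes, bboxes and tumor bbox from the grid."""
    volume = np.zeros(n_sigma, dtype=np.int64)
    bbox = np.empty((n_sigma, 4), dtype=np.int64)
    big = np.int64(np.iinfo(np.int32).max)
    for k in range(n_sigma):
        bbox[k, 0] = big
        bbox[k, 1] = -1
        bbox[k, 2] = big
        bbox[k, 3] = -1
    tumor = np.array([big, -1, big, -1], dtype=np.int64)
    n = grid.shape[0]
    for i in range(n):
        for j in range(n):
            sg = grid[i, j]
            if sg <= 0:
                continue
            volume[sg] += 1
            if i < bbox[sg, 0]:
                bbox[sg, 0] = i
            if i > bbox[sg, 1]:
                bbox[sg, 1] = i
            if j < bbox[sg, 2]:
                bbox[sg, 2] = j
            if j > bbox[sg, 3]:
                bbox[sg, 3] = j
            if i < tumor[0]:
                tumor[0] = i
            if i > tumor[1]:
                tumor[1] = i
            if j < tumor[2]:
                tumor[2] = j
            if j > tumor[3]:
                tumor[3] = j
    return volume, bbox, tumor


@njit(cache=True)
def _population_counts(alive, ctype, volume):
    """(n_live, n_proliferative, n_occupied_sites) in one pass."""
    n_live = 0
    n_prolif = 0
    occupied = 0
    for s in range(1, alive.shape[0]):
        if alive[s]:
            n_live += 1
            occupied += volume[s]
            if ctype[s] != 2:
                n_prolif += 1
    return n_live, n_prolif, occupied


@njit(cache=True)
def _grow_and_collect_ready(
    alive, ctype, volume, target, phen, fit_table, phen_min,
    dv, cap, margin, use_fitness,
):
    """Apply one MCS of gated target growth; return division-ready sigmas."""
    n = alive.shape[0]
    ready = np.empty(n, dtype=np.int64)
    n_ready = 0
    for s in range(1, n):
        if not alive[s] or ctype[s] == 2:
            continue
        if volume[s] >= target[s] - margin:
            if use_fitness:
                inc = dv * fit_table[phen[s] - phen_min]
            else:
                inc = dv
            t = target[s] + inc
            if t > cap:
                t = cap
            target[s] = t
        if target[s] >= cap - 1e-9 and volume[s] >= 2:
            ready[n_ready] = s
            n_ready += 1
    return ready[:n_ready]


def _offsets(neighborhood: int) -> np.ndarray:
    if neighborhood == 8:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    return np.array(offs, dtype=np.int64)


def accept_probability(delta_h: float, temperature: float) -> float:
    """Metropolis acceptance probability: 1 if dH < 0, else exp(-dH/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_h < 0:
        return 1.0
    return math.exp(-delta_h / temperature)


def metropolis_attempt(
    state: LatticeState,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    site: Optional[tuple[int, int]] = None,
    neighbor: Optional[tuple[int, int]] = None,
) -> bool:
    """One elementary copy attempt at Python level.

    A random lattice site takes the identifier of a random neighbor;
    the move is accepted with the Metropolis probability. ``site`` and
    ``neighbor`` may be forced for instrumented tests. Returns whether
    the new state was accepted (attempts whose source and target share
    a sigma change nothing and count as accepted, dH = 0).
    """
    if state.n_live_cells() == 0:
        raise ValueError("metropolis_attempt requires at least one cell")
    rng = rng if rng is not None else state.rng
    n = config.lattice_size
    offs = _offsets(config.neighborhood)
    if site is None:
        i, j = int(rng.integers(n)), int(rng.integers(n))
    else:
        i, j = site
    if neighbor is None:
        d = offs[int(rng.integers(len(offs)))]
        ni, nj = i + int(d[0]), j + int(d[1])
        if ni < 0 or nj < 0 or ni >= n or nj >= n:
            state.total_attempts += 1
            return False
    else:
        ni, nj = neighbor
    state.total_attempts += 1
    s_old = int(state.grid[i, j])
    s_new = int(state.grid[ni, nj])
    if s_old == s_new:
        return True
    dh = float(
        _delta_h(
            state.grid, state.volume, state.target, i, j, s_old, s_new,
            config.lambda_stiffness, config.adhesion_j, config.adhesion_j_medium,
            offs,
        )
    )
    if dh >= 0 and rng.random() >= accept_probability(dh, config.temperature):
        return False
    state.grid[i, j] = s_new
    if s_old > 0:
        state.volume[s_old] -= 1
        if state.volume[s_old] == 0:
            state.alive[s_old] = False
    if s_new > 0:
        state.volume[s_new] += 1
        state._expand_bbox(s_new, i, j)
    return True


# --- growth, division, death --------------------------------------------


def grow_cells(state: LatticeState, config: SimulationConfig, landscape=None) -> None:
    """Raise target volumes by one MCS of fitness-scaled growth.

    A cell at the reference fitness (that of the founder phenotype)
    gains delta-V = V0 * hours_per_mcs / c per MCS, doubling its target
    in one cell cycle; a cell with fitness f grows f/f_ref times as
    fast. Quiescent DCs do not grow, and cycle progression is
    contact-inhibited: a cell whose actual volume has fallen more than
    ``growth_gate_margin`` sites behind its target (it is compressed by
    its neighbors) pauses its clock until it catches up, which bounds
    the pressure any cell can exert. Targets cap at 2 * V0: a cell that
    has accumulated a full cycle of growth is ready to divide.
    """
    n = state.next_sigma
    growing = (
        state.alive[:n]
        & (state.ctype[:n] != int(CellType.DC))
        & (state.volume[:n] >= state.target[:n] - config.growth_gate_margin)
    )
    if not growing.any():
        return
    dv = config.target_volume_increment
    if landscape is not None and landscape.name != "neutral":
        factors = landscape.fitness(state.phen[:n][growing].astype(np.int64))
        factors = factors / landscape.reference_fitness
        inc = dv * factors
    else:
        inc = dv
    cap = float(2 * config.base_target_volume)
    state.target[:n][growing] = np.minimum(state.target[:n][growing] + inc, cap)


def divide_cell(
    state: LatticeState,
    sigma: int,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[int, int]:
    """Split a doubled cell into two connected halves of equal size (+-1).

    The cell's largest connected component is cut through its pixel
    centroid perpendicular to the principal (major) axis; the far half
    becomes the daughter under a fresh identifier. Both offspring reset
    their target volume to V0 and restart their cycle; fates follow the
    hierarchy rules, and the methylation pattern (and, outside neutral
    mode, the phenotype) of each offspring is mutated independently.
    Detached fragments, if any, stay with the mother.
    """
    rng = rng if rng is not None else state.rng
    if not state.alive[sigma]:
        raise ValueError(f"cell {sigma} is not alive")
    if state.volume[sigma] < 2:
        raise ValueError("a cell of volume < 2 cannot divide")
    if state.ctype[sigma] == int(CellType.DC):
        raise ValueError("quiescent cells cannot divide")

    coords = state.cell_sites(sigma)
    # tighten the mother bbox while we have the sites
    state.bbox[sigma] = (
        coords[:, 0].min(), coords[:, 0].max(), coords[:, 1].min(), coords[:, 1].max(),
    )
    structure = np.ones((3, 3), dtype=bool) if config.neighborhood == 8 else None
    r0, r1c = int(state.bbox[sigma][0]), int(state.bbox[sigma][1])
    c0, c1c = int(state.bbox[sigma][2]), int(state.bbox[sigma][3])
    sub = state.grid[r0 : r1c + 1, c0 : c1c + 1] == sigma
    labels, n_comp = _ndimage.label(sub, structure=structure)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        main_label = int(np.argmax(sizes)) + 1
        main_mask = labels[coords[:, 0] - r0, coords[:, 1] - c0] == main_label
        main = coords[main_mask]
        frags = coords[~main_mask]
        if len(main) < 2:  # fully fragmented: split all sites instead
            main, frags = coords, coords[:0]
    else:
        main = coords
        frags = coords[:0]

    centered = main.astype(float) - main.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] < 1e-9:  # isotropic: random cut direction
        theta = rng.random() * math.pi
        axis = np.array([math.cos(theta), math.sin(theta)])
    else:
        axis = evecs[:, 1]  # major axis
    proj = centered @ axis
    order = np.lexsort((rng.random(len(proj)), proj))
    n_main = len(main)
    n_mother = (n_main + 1) // 2
    daughter_sites = main[order[n_mother:]]

    fate_mother, fate_daughter = hierarchy.daughter_fates(
        CellType(int(state.ctype[sigma])), int(state.divs[sigma]), config.fate_rule(), rng
    )

    mu = config.methylation_rate
    mother_meth = mutation_models.mutate_methylation(state.meth[sigma], mu, rng)
    daughter_meth = mutation_models.mutate_methylation(state.meth[sigma], mu, rng)
    if config.mode != "neutral":
        mu_f = config.nonneutral_rate
        mother_phen = mutation_models.mutate_phenotype(
            int(state.phen[sigma]), mu_f, rng, config.phenotype_min, config.phenotype_max
        )
        daughter_phen = mutation_models.mutate_phenotype(
            int(state.phen[sigma]), mu_f, rng, config.phenotype_min, config.phenotype_max
        )
    else:
        mother_phen = daughter_phen = int(state.phen[sigma])

    d_sigma = state.new_cell(
        fate_daughter.cell_type,
        divisions_used=fate_daughter.divisions_used,
        phenotype=daughter_phen,
        methylation=int(daughter_meth),
        parent_sigma=sigma,
    )
    state.grid[daughter_sites[:, 0], daughter_sites[:, 1]] = d_sigma
    state.volume[d_sigma] = len(daughter_sites)
    state.bbox[d_sigma] = (
        daughter_sites[:, 0].min(), daughter_sites[:, 0].max(),
        daughter_sites[:, 1].min(), daughter_sites[:, 1].max(),
    )

    mother_sites = main[order[:n_mother]]
    keep = np.vstack([mother_sites, frags]) if len(frags) else mother_sites
    state.volume[sigma] = len(keep)
    state.bbox[sigma] = (
        keep[:, 0].min(), keep[:, 0].max(), keep[:, 1].min(), keep[:, 1].max(),
    )
    state.target[sigma] = float(config.base_target_volume)
    state.ctype[sigma] = int(fate_mother.cell_type)
    state.divs[sigma] = fate_mother.divisions_used
    state.meth[sigma] = np.uint64(mother_meth)
    state.phen[sigma] = mother_phen
    state.total_divisions += 1
    return sigma, d_sigma


def kill_cell(state: LatticeState, sigma: int) -> None:
    """Remove a cell: its sites revert to medium, its record is retired."""
    if not state.alive[sigma]:
        return
    r0, r1, c0, c1 = state.bbox[sigma]
    sub = state.grid[r0 : r1 + 1, c0 : c1 + 1]
    sub[sub == sigma] = 0
    state.volume[sigma] = 0
    state.alive[sigma] = False


def apoptosis_sweep(
    state: LatticeState,
    rate_per_24h: float,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """One daily apoptosis draw: each live cell dies with probability a.

    All cell types are eligible, CSCs included. Returns the number of
    cells killed.
    """
    if not 0.0 <= rate_per_24h < 1.0:
        raise ValueError(f"apoptosis rate must lie in [0, 1), got {rate_per_24h}")
    rng = rng if rng is not None else state.rng
    sigmas = state.live_sigmas()
    if rate_per_24h == 0.0 or sigmas.size == 0:
        return 0
    doomed = sigmas[rng.random(sigmas.size) < rate_per_24h]
    for sigma in doomed:
        kill_cell(state, int(sigma))
    return int(doomed.size)


def audit_state(state: LatticeState, tighten: bool = True) -> None:
    """Verify grid/registry consistency; optionally tighten all bboxes.

    Checks that every live cell's registered volume equals its count of
    grid sites and that no grid label refers to a dead or unknown cell.
    Raises :class:`AuditError` on mismatch.
    """
    n_sigma = state.next_sigma
    volume, bbox, tumor = _rebuild_geometry(state.grid, n_sigma)
    alive = state.alive[:n_sigma]
    reg = state.volume[:n_sigma].copy()
    reg[~alive] = 0
    if not np.array_equal(volume, reg):
        bad = np.flatnonzero(volume != reg)
        raise AuditError(f"volume mismatch for identifiers {bad.tolist()[:10]}")
    if np.any(volume[~alive] > 0):
        raise AuditError("grid refers to dead cells")
    if tighten:
        state.bbox[:n_sigma] = bbox
        state.tumor_bbox[:] = tumor


def monte_carlo_step(
    state: LatticeState,
    config: SimulationConfig,
    landscape=None,
    therapy_active: bool = False,
) -> LatticeState:
    """One MCS: A copy attempts, then growth and division checks.

    A equals the number of non-medium sites plus a boundary-shell
    allowance (the perimeter of the padded tumor window). Attempts are
    drawn inside that window; sites outside it are medium surrounded by
    medium, for which every copy is a no-op. During a therapy window,
    cells reaching the division trigger die instead of dividing.
    """
    n = state.next_sigma
    _, _, n_occupied = _population_counts(
        state.alive[:n], state.ctype[:n], state.volume[:n]
    )
    n_occupied = int(n_occupied)
    if n_occupied > 0:
        state.check_boundary()
        r0, r1, c0, c1 = state.sampling_window()
        shell = 2 * ((r1 - r0) + (c1 - c0)) + 4
        n_attempts = n_occupied + shell
        _run_attempts(
            state.grid, state.volume, state.target, state.alive, state.bbox,
            state.tumor_bbox, state.kstate, n_attempts, r0, r1, c0, c1,
            config.lambda_stiffness, config.adhesion_j, config.adhesion_j_medium,
            config.temperature, _offsets(config.neighborhood),
        )
        state.total_attempts += n_attempts
    state.clock_mcs += 1
    state.clock_hours += config.hours_per_mcs
    if n_occupied == 0:
        return state
    n = state.next_sigma
    use_fitness = landscape is not None and landscape.name != "neutral"
    if use_fitness:
        fit_table = landscape.table / landscape.reference_fitness
    else:
        fit_table = np.ones(1, dtype=np.float64)
    ready = _grow_and_collect_ready(
        state.alive[:n], state.ctype[:n], state.volume[:n], state.target[:n],
        state.phen[:n], fit_table,
        config.phenotype_min if use_fitness else 0,
        config.target_volume_increment, float(config.division_volume),
        config.growth_gate_margin, use_fitness,
    )
    for sigma in ready:
        if not state.alive[sigma]:  # may have been annihilated meanwhile
            continue
        if therapy_active:
            kill_cell(state, int(sigma))
        else:
            divide_cell(state, int(sigma), config)
    return state


# --- simulation loop ------------------------------------------------------


@dataclass
class SimulationResult:
    """Outputs of one run: final state, time series and clone table."""

    config: SimulationConfig
    state: LatticeState
    timeseries: pd.DataFrame
    clone_table: pd.DataFrame
    status: str
    landscape: object = None

    @property
    def n_cells(self) -> int:
        return self.state.n_live_cells()


def _sample_row(state: LatticeState, config: SimulationConfig, landscape) -> list:
    n_live = state.n_live_cells()
    label_kind = "methylation" if config.mode == "neutral" else "phenotype"
    if n_live > 0:
        table = analysis_stats.clone_abundance(state, label_kind=label_kind)
        shannon = analysis_stats.normalized_shannon(table)
    else:
        shannon = float("nan")
    if config.mode != "neutral" and n_live > 0:
        mfit = analysis_stats.mean_fitness(state, landscape)
    else:
        mfit = float("nan")
    return [
        state.clock_hours,
        state.clock_mcs,
        n_live,
        state.count_type(CellType.CSC),
        state.count_type(CellType.TAC),
        state.count_type(CellType.DC),
        state.total_divisions,
        shannon,
        mfit,
    ]


def clone_table_frame(state: LatticeState, config: SimulationConfig) -> pd.DataFrame:
    label_kind = "methylation" if config.mode == "neutral" else "phenotype"
    if state.n_live_cells() == 0:
        return pd.DataFrame({"label": [], "count": []})
    table = analysis_stats.clone_abundance(state, label_kind=label_kind)
    return pd.DataFrame({"label": table.labels, "count": table.counts})


def run_simulation(
    config: SimulationConfig,
    state: Optional[LatticeState] = None,
    stop_volume: Optional[int] = None,
    therapy_until_hours: Optional[float] = None,
    on_sample=None,
) -> SimulationResult:
    """Grow a tumor from a single founder CSC until a stopping rule fires.

    Seeds one founder (phenotype 0, unmethylated) at the lattice center
    unless an existing ``state`` is resumed. Runs Monte-Carlo steps with
    daily apoptosis sweeps until the live-cell count reaches
    ``stop_volume``, no proliferative cell remains, or the safety clock
    expires. Extinction is reported through ``status``, not raised.
    """
    config.validate()
    landscape = mutation_models.get_landscape(
        config.landscape if config.mode != "neutral" else "neutral"
    )
    if state is None:
        state = LatticeState(config)
        seed_founder(state)
    stop = stop_volume if stop_volume is not None else config.stop_volume
    rows = []
    sample_every = config.sample_every_hours
    next_sample = state.clock_hours + sample_every
    next_apoptosis = (math.floor(state.clock_hours / 24.0) + 1) * 24.0
    rows.append(_sample_row(state, config, landscape))
    status = "running"
    while True:
        ns = state.next_sigma
        n_live, n_prolif, _ = _population_counts(
            state.alive[:ns], state.ctype[:ns], state.volume[:ns]
        )
        if n_live >= stop:
            status = "reached_volume"
            break
        if n_live == 0:
            status = "extinct"
            break
        if n_prolif == 0:
            status = "quiescent"
            break
        if state.clock_hours >= config.max_hours:
            status = "timeout"
            break
        therapy_active = (
            therapy_until_hours is not None and state.clock_hours < therapy_until_hours
        )
        monte_carlo_step(state, config, landscape, therapy_active=therapy_active)
        if state.clock_hours >= next_apoptosis:
            audit_state(state)  # tighten bboxes; verify invariants daily
            apoptosis_sweep(state, config.apoptosis_rate)
            next_apoptosis += 24.0
        if state.clock_hours >= next_sample:
            rows.append(_sample_row(state, config, landscape))
            if on_sample is not None:
                on_sample(rows[-1])
            next_sample += sample_every
    rows.append(_sample_row(state, config, landscape))
    timeseries = pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
    return SimulationResult(
        config=config,
        state=state,
        timeseries=timeseries,
        clone_table=clone_table_frame(state, config),
        status=status,
        landscape=landscape,
    )
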