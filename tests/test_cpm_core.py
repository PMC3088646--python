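"""The lattice engine: energies, Metropolis dynamics, growth, division,
apoptosis, and the simulation loop."""

import math

import numpy as np
import pytest
from scipy import ndimage

import stemcpm.cpm_core as core
from stemcpm.cpm_core import (
    BoundaryContactError,
    CellRecord,
    LatticeState,
    SimulationConfig,
    accept_probability,
    adhesion_energy,
    apoptosis_sweep,
    audit_state,
    divide_cell,
    grow_cells,
    metropolis_attempt,
    monte_carlo_step,
    run_simulation,
    seed_founder,
    total_energy,
    volume_energy,
)
from stemcpm.hierarchy import CellType
from stemcpm.mutation_models import get_landscape

from conftest import brute_force_adhesion, brute_force_total_energy, make_config, place_block


class _AlwaysAccept:
    """Stub RNG for forced-acceptance instrumentation."""

    def random(self):
        return 0.0

    def integers(self, *a, **kw):  # pragma: no cover - not used when forced
        raise AssertionError("site must be forced")


def random_multicell_state(rng, n=20, n_cells=5, neighborhood=8):
    """A consistent random state: several blob cells grown by random
    claimed sites, targets set near their volumes."""
    cfg = make_config(lattice_size=n, neighborhood=neighborhood)
    state = LatticeState(cfg)
    for k in range(n_cells):
        r = 2 + int(rng.integers(n - 8))
        c = 2 + int(rng.integers(n - 8))
        h = 2 + int(rng.integers(3))
        w = 2 + int(rng.integers(3))
        sigma = state.new_cell(CellType.CSC)
        for i in range(r, min(r + h, n)):
            for j in range(c, min(c + w, n)):
                if state.grid[i, j] == 0:
                    state.claim_site(sigma, i, j)
        if state.volume[sigma] == 0:
            state.alive[sigma] = False
            continue
        state.target[sigma] = float(state.volume[sigma]) + float(rng.integers(-2, 3))
    return cfg, state


class TestConfig:
    def test_defaults_match_published_operating_point(self):
        cfg = SimulationConfig()
        assert cfg.cell_cycle_hours == 20.0
        assert cfg.methylation_rate == 2e-5
        assert cfg.adhesion_j == 9.0
        assert cfg.lambda_stiffness == 3.0
        assert cfg.max_tac_divisions == 5
        assert cfg.apoptosis_rate == 0.01  # neutral mode
        assert cfg.nonneutral_rate == 0.1
        assert (cfg.phenotype_min, cfg.phenotype_max) == (-24, 25)
        assert SimulationConfig(mode="fitness").apoptosis_rate == 0.02

    @pytest.mark.parametrize(
        "bad",
        [
            dict(psi=1.2),
            dict(max_tac_divisions=-1),
            dict(apoptosis_rate=1.0),
            dict(temperature=0.0),
            dict(landscape="nope"),
            dict(mode="warp"),
            dict(neighborhood=6),
            dict(base_target_volume=2),
        ],
    )
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)

    def test_growth_increment_calibrated_to_cycle(self):
        cfg = SimulationConfig(cell_cycle_hours=20.0, hours_per_mcs=1.0)
        assert cfg.target_volume_increment == pytest.approx(0.8)  # 16 * 1 / 20


class TestEnergies:
    def test_volume_energy_zero_at_target(self):
        cell = CellRecord(1, CellType.CSC, 0, 16, 16.0, 0, 0, 0, 0.0)
        assert volume_energy(cell, 3.0) == 0.0

    @pytest.mark.parametrize("v", [18, 14])  # symmetric quadratic: both give 12
    def test_volume_energy_quadratic(self, v):
        cell = CellRecord(1, CellType.CSC, 0, v, 16.0, 0, 0, 0, 0.0)
        assert volume_energy(cell, 3.0) == pytest.approx(12.0)

    def test_negative_stiffness_rejected(self):
        cell = CellRecord(1, CellType.CSC, 0, 16, 16.0, 0, 0, 0, 0.0)
        with pytest.raises(ValueError):
            volume_energy(cell, -1.0)

    def test_isolated_cell_no_medium_cost(self):
        cfg = make_config(adhesion_j_medium=0.0)
        state = LatticeState(cfg)
        place_block(state, 10, 10, 4, 4)
        assert adhesion_energy(state, cfg) == 0.0

    def test_two_squares_shared_edge_four_neighborhood(self):
        """Two 2x2 cells sharing a 2-site edge: exactly two differing-sigma
        pairs, each costing J = 9."""
        cfg = make_config(neighborhood=4, adhesion_j=9.0, adhesion_j_medium=0.0)
        state = LatticeState(cfg)
        place_block(state, 10, 10, 2, 2)
        place_block(state, 10, 12, 2, 2)
        assert adhesion_energy(state, cfg) == pytest.approx(18.0)

    def test_beta_excludes_same_cell_pairs(self, rng):
        """Counting same-sigma pairs too must give a strictly larger value."""
        cfg, state = random_multicell_state(rng)
        with_beta = adhesion_energy(state, cfg)
        # oracle without the exclusion: every occupied-adjacent pair costs J
        n = state.grid.shape[0]
        no_beta = 0.0
        for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
            for i in range(n):
                for j in range(n):
                    ni, nj = i + dr, j + dc
                    if not (0 <= ni < n and 0 <= nj < n):
                        continue
                    a, b = state.grid[i, j], state.grid[ni, nj]
                    if a == 0 and b == 0:
                        continue
                    if a == 0 or b == 0:
                        no_beta += cfg.adhesion_j_medium
                    else:
                        no_beta += cfg.adhesion_j
        assert no_beta > with_beta

    @pytest.mark.parametrize("neighborhood", [4, 8])
    def test_adhesion_matches_brute_force(self, rng, neighborhood):
        cfg, state = random_multicell_state(rng, neighborhood=neighborhood)
        expected = brute_force_adhesion(
            state.grid, cfg.adhesion_j, cfg.adhesion_j_medium, neighborhood
        )
        assert adhesion_energy(state, cfg) == pytest.approx(expected)

    def test_total_energy_empty_lattice_zero(self):
        cfg = make_config()
        assert total_energy(LatticeState(cfg), cfg) == 0.0

    def test_total_energy_single_cell_at_target(self):
        cfg = make_config(adhesion_j_medium=0.0)
        state = LatticeState(cfg)
        place_block(state, 10, 10, 4, 4)
        assert total_energy(state, cfg) == 0.0

    def test_total_energy_matches_full_rescan(self, rng):
        for _ in range(5):
            cfg, state = random_multicell_state(rng)
            assert total_energy(state, cfg) == pytest.approx(
                brute_force_total_energy(state, cfg)
            )


class TestMetropolis:
    def test_downhill_always_accepted(self):
        assert accept_probability(-5.0, 8.0) == 1.0
        assert accept_probability(0.0, 8.0) == 1.0

    def test_incremental_dh_equals_energy_difference(self, rng):
        """Direct check: _delta_h == total_energy(after) - total_energy(before)
        as long as no cell is annihilated (annihilation removes a live
        volume term from the Hamiltonian by design)."""
        cfg, state = random_multicell_state(rng)
        offs = core._offsets(cfg.neighborhood)
        n = state.grid.shape[0]
        checked = 0
        for _ in range(2000):
            i, j = int(rng.integers(1, n - 1)), int(rng.integers(1, n - 1))
            k = int(rng.integers(len(offs)))
            ni, nj = i + int(offs[k, 0]), j + int(offs[k, 1])
            s_old, s_new = int(state.grid[i, j]), int(state.grid[ni, nj])
            if s_old == s_new:
                continue
            if s_old > 0 and state.volume[s_old] == 1:
                continue  # annihilation: registry term disappears
            dh = float(
                core._delta_h(
                    state.grid, state.volume, state.target, i, j, s_old, s_new,
                    cfg.lambda_stiffness, cfg.adhesion_j, cfg.adhesion_j_medium, offs,
                )
            )
            e_before = brute_force_total_energy(state, cfg)
            assert metropolis_attempt(
                state, cfg, rng=_AlwaysAccept(), site=(i, j), neighbor=(ni, nj)
            )
            e_after = brute_force_total_energy(state, cfg)
            assert dh == pytest.approx(e_after - e_before, abs=1e-9)
            checked += 1
            if checked >= 50:
                break
        assert checked >= 20

    def test_acceptance_frequency_matches_boltzmann(self, rng):
        """Empirical acceptance of a fixed uphill move matches exp(-dH/T)
        within binomial error."""
        cfg = make_config(temperature=8.0, adhesion_j_medium=0.0, adhesion_j=0.0,
                          lambda_stiffness=1.0)
        state = LatticeState(cfg)
        sigma = place_block(state, 10, 10, 4, 4, target=16.0)
        # forced copy: medium eats a corner site -> dH = lam*((15-16)^2-(16-16)^2)...
        # compute exactly via the kernel for the chosen site
        offs = core._offsets(cfg.neighborhood)
        i, j, ni, nj = 10, 10, 9, 10  # cell site takes medium's sigma (0)
        dh = float(
            core._delta_h(state.grid, state.volume, state.target, i, j,
                          int(state.grid[i, j]), 0,
                          cfg.lambda_stiffness, cfg.adhesion_j, cfg.adhesion_j_medium, offs)
        )
        assert dh > 0
        p_expected = math.exp(-dh / cfg.temperature)
        n_trials, accepted = 10_000, 0
        grid0 = state.grid.copy()
        vol0 = state.volume.copy()
        for _ in range(n_trials):
            if metropolis_attempt(state, cfg, rng=rng, site=(i, j), neighbor=(ni, nj)):
                accepted += 1
                state.grid[:] = grid0
                state.volume[:] = vol0
                state.alive[sigma] = True
        freq = accepted / n_trials
        se = math.sqrt(p_expected * (1 - p_expected) / n_trials)
        assert abs(freq - p_expected) < 3.5 * se

    def test_same_sigma_copy_is_accepted_noop(self):
        cfg = make_config()
        state = LatticeState(cfg)
        place_block(state, 10, 10, 4, 4)
        before = state.grid.copy()
        assert metropolis_attempt(state, cfg, site=(0, 0), neighbor=(0, 1))
        assert np.array_equal(state.grid, before)


class TestMonteCarloStep:
    def test_empty_state_only_advances_clocks(self):
        cfg = make_config()
        state = LatticeState(cfg)
        monte_carlo_step(state, cfg)
        assert state.clock_mcs == 1
        assert state.clock_hours == cfg.hours_per_mcs
        assert state.total_attempts == 0

    def test_attempt_counter_increments_by_a(self):
        cfg = make_config()
        state = LatticeState(cfg)
        seed_founder(state)
        r0, r1, c0, c1 = state.sampling_window()
        expected = 16 + 2 * ((r1 - r0) + (c1 - c0)) + 4
        monte_carlo_step(state, cfg)
        assert state.total_attempts == expected

    def test_volume_audit_passes_along_trajectory(self):
        """Grid/registry consistency after every MCS of a 50x50 run."""
        cfg = SimulationConfig(
            lattice_size=50, stop_volume=60, psi=0.5, seed=5, apoptosis_rate=0.0,
            hours_per_mcs=1.0,
        )
        state = LatticeState(cfg)
        seed_founder(state)
        lsc = get_landscape("neutral")
        for _ in range(400):
            if state.n_live_cells() >= 30:  # keep clear of the small boundary
                break
            monte_carlo_step(state, cfg, lsc)
            audit_state(state, tighten=False)
            occupied = int(np.count_nonzero(state.grid))
            registry = int(state.volume[: state.next_sigma][state.live_mask()].sum())
            assert occupied == registry


class TestGrowth:
    def test_reference_increment(self):
        cfg = make_config(cell_cycle_hours=20.0, hours_per_mcs=1.0)
        state = LatticeState(cfg)
        place_block(state, 10, 10, 4, 4, target=16.0)
        grow_cells(state, cfg)
        assert state.target[1] == pytest.approx(16.8)

    def test_quiescent_cells_do_not_grow(self):
        cfg = make_config()
        state = LatticeState(cfg)
        sigma = place_block(state, 10, 10, 4, 4, CellType.DC, target=16.0)
        grow_cells(state, cfg)
        assert state.target[sigma] == 16.0

    def test_compressed_cells_pause(self):
        """Contact inhibition: a cell far below its target does not run
        its growth clock."""
        cfg = make_config()
        state = LatticeState(cfg)
        sigma = place_block(state, 10, 10, 2, 2, target=16.0)  # volume 4 << 16
        grow_cells(state, cfg)
        assert state.target[sigma] == 16.0

    def test_double_fitness_halves_doubling_time(self):
        """A cell at twice the reference fitness accumulates its cycle in
        half the MCS count (deterministic integration, volume tracking
        disabled by keeping volume at target)."""
        cfg = make_config(
            mode="fitness", landscape="linear", cell_cycle_hours=20.0, hours_per_mcs=1.0,
            apoptosis_rate=0.02,
        )
        lsc = get_landscape("linear")
        state = LatticeState(cfg)
        ref = place_block(state, 5, 5, 4, 4, phenotype=0, target=16.0)  # f = 8
        fast = place_block(state, 20, 5, 4, 4, phenotype=8, target=16.0)  # f = 16
        steps_ref = steps_fast = None
        for step in range(1, 100):
            state.volume[ref] = int(math.ceil(state.target[ref]))
            state.volume[fast] = int(math.ceil(state.target[fast]))
            grow_cells(state, cfg, lsc)
            if steps_fast is None and state.target[fast] >= 32.0 - 1e-9:
                steps_fast = step
            if steps_ref is None and state.target[ref] >= 32.0 - 1e-9:
                steps_ref = step
                break
        assert steps_fast == 10 and steps_ref == 20


class TestDivision:
    def test_rectangle_splits_into_equal_connected_halves(self, rng):
        cfg = make_config(methylation_rate=0.0)
        state = LatticeState(cfg)
        sigma = place_block(state, 10, 10, 4, 8)  # 32 sites
        state.target[sigma] = 32.0
        mother, daughter = divide_cell(state, sigma, cfg, rng)
        assert state.volume[mother] == state.volume[daughter] == 16
        for s in (mother, daughter):
            mask = state.grid == s
            _, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
            assert n_comp == 1
        # the cut is perpendicular to the long axis: each half spans 4 rows
        for s in (mother, daughter):
            rows = np.unique(np.argwhere(state.grid == s)[:, 0])
            assert len(rows) == 4

    def test_zero_rates_copy_heritable_state_exactly(self, rng):
        cfg = make_config(methylation_rate=0.0, nonneutral_rate=0.0, mode="fitness",
                          landscape="sinusoidal_S", apoptosis_rate=0.02)
        state = LatticeState(cfg)
        sigma = place_block(state, 10, 10, 4, 8, methylation=0xABCD, phenotype=3)
        state.target[sigma] = 32.0
        mother, daughter = divide_cell(state, sigma, cfg, rng)
        assert int(state.meth[mother]) == int(state.meth[daughter]) == 0xABCD
        assert int(state.phen[mother]) == int(state.phen[daughter]) == 3

    def test_full_self_renewal_daughter_is_csc(self, rng):
        cfg = make_config(psi=1.0)
        state = LatticeState(cfg)
        sigma = place_block(state, 10, 10, 4, 8)
        _, daughter = divide_cell(state, sigma, cfg, rng)
        assert CellType(int(state.ctype[daughter])) == CellType.CSC

    def test_offspring_reset_targets_and_count_division(self, rng):
        cfg = make_config()
        state = LatticeState(cfg)
        sigma = place_block(state, 10, 10, 4, 8)
        state.target[sigma] = 32.0
        before = state.total_divisions
        mother, daughter = divide_cell(state, sigma, cfg, rng)
        assert state.total_divisions == before + 1
        assert state.target[mother] == state.target[daughter] == 16.0

    def test_tiny_cell_cannot_divide(self, rng):
        cfg = make_config()
        state = LatticeState(cfg)
        sigma = place_block(state, 10, 10, 1, 1)
        with pytest.raises(ValueError, match="volume"):
            divide_cell(state, sigma, cfg, rng)


class TestApoptosis:
    def test_zero_rate_kills_nothing(self):
        cfg = make_config()
        state = LatticeState(cfg)
        place_block(state, 10, 10, 4, 4)
        assert apoptosis_sweep(state, 0.0) == 0
        assert state.n_live_cells() == 1

    def test_rate_one_rejected(self):
        cfg = make_config()
        state = LatticeState(cfg)
        place_block(state, 10, 10, 4, 4)
        with pytest.raises(ValueError):
            apoptosis_sweep(state, 1.0)

    def test_kill_count_binomial(self):
        """a = 0.01 over 10,000 cells kills ~100 within the 99% CI."""
        cfg = SimulationConfig(lattice_size=128, seed=77)
        state = LatticeState(cfg)
        for k in range(10_000):
            sigma = state.new_cell(CellType.DC)
            state.claim_site(sigma, k // 100, k % 100)
        killed = apoptosis_sweep(state, 0.01)
        assert 70 <= killed <= 132  # ~3.3 sigma around 100
        assert state.n_live_cells() == 10_000 - killed
        audit_state(state)

    def test_killed_cells_leave_medium_behind(self, rng):
        cfg = make_config()
        state = LatticeState(cfg)
        sigma = place_block(state, 10, 10, 4, 4)
        core.kill_cell(state, sigma)
        assert np.count_nonzero(state.grid) == 0
        assert not state.alive[sigma]


class TestRunSimulation:
    def test_pure_binary_expansion(self):
        """psi = 1, no apoptosis: 8 cells require exactly 7 divisions and
        every cell is a CSC throughout."""
        cfg = SimulationConfig(
            lattice_size=48, stop_volume=8, psi=1.0, apoptosis_rate=0.0, seed=42,
        )
        res = run_simulation(cfg)
        assert res.status == "reached_volume"
        assert res.n_cells == 8
        assert res.state.total_divisions == 7
        ts = res.timeseries
        assert (ts.n_csc == ts.n_cells).all()  # classical reduction

    def test_bit_identical_reproducibility(self):
        cfg = SimulationConfig(lattice_size=48, stop_volume=30, psi=0.5, seed=99)
        res1 = run_simulation(cfg)
        res2 = run_simulation(cfg)
        assert np.array_equal(res1.state.grid, res2.state.grid)
        assert res1.timeseries.equals(res2.timeseries)
        assert res1.clone_table.equals(res2.clone_table)

    def test_division_clock_near_cell_cycle(self):
        """An isolated founder completes its first divisions on the
        growth-clock cadence: one division per cycle, with only the small
        lag of the volume catching up to the doubled target."""
        cfg = SimulationConfig(
            lattice_size=64, stop_volume=4, psi=1.0, apoptosis_rate=0.0, seed=7,
        )
        res = run_simulation(cfg)
        ts = res.timeseries
        t_final = ts.time_hours.iloc[-1]
        # two doublings at c = 20 h: ideal 40 h, allow the catch-up lag
        assert 40.0 <= t_final <= 80.0

    def test_extinction_reported_not_raised(self):
        cfg = SimulationConfig(
            lattice_size=48, stop_volume=1000, psi=0.0, max_tac_divisions=0,
            apoptosis_rate=0.5, seed=3, sample_every_hours=24.0,
        )
        res = run_simulation(cfg)
        assert res.status in ("extinct", "quiescent")

    def test_boundary_contact_aborts_with_clear_error(self):
        cfg = SimulationConfig(lattice_size=12, stop_volume=50, psi=1.0,
                               apoptosis_rate=0.0, seed=1)
        with pytest.raises(BoundaryContactError, match="lattice_size"):
            run_simulation(cfg)

    def test_timeseries_columns_and_monotone_clock(self):
        cfg = SimulationConfig(lattice_size=48, stop_volume=20, psi=1.0,
                               apoptosis_rate=0.0, seed=11)
        res = run_simulation(cfg)
        assert list(res.timeseries.columns) == core.TIMESERIES_COLUMNS
        assert res.timeseries.time_hours.is_monotonic_increasing
        assert int(res.clone_table["count"].sum()) == res.n_cells
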