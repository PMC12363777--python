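"""Potts engine: incremental energy change vs a brute-force Hamiltonian
oracle, Metropolis acceptance statistics, pressure, bookkeeping invariants
and seeded determinism."""

import numpy as np
import pytest

from corneasim import _kernels
from corneasim.fields import ScalarField
from corneasim.potts import (
    LatticeState,
    LinkSpring,
    compute_pressure,
    delta_hamiltonian,
    metropolis_mcs,
    seed_kernel,
)
from corneasim.types import BASAL, STEM, SUPER, TEAR, WALL, WING

from conftest import (
    brute_force_energy,
    make_state,
    random_two_cell_state,
    uniform_params,
)


def _apply_copy(state, source_px, target_px):
    sx, sy = source_px
    x, y = target_px
    state.owner_grid[y, x] = state.owner_grid[sy, sx]
    state.refresh_stats()


class TestDeltaHamiltonian:
    def test_volume_term_at_target_is_2_lambda(self):
        # both cells exactly at target volume/surface, J = 0, no field:
        # expanding the quadratic gives λ((V+1−V)²−0) + λ((V−1−V)²−0) = 2λ
        st, (a, b) = make_state(8, 8, [(BASAL, 0, 8, 0, 4), (WING, 0, 8, 4, 8)])
        params = uniform_params(J=0.0, lam_v=2.0, lam_s=0.0)
        dh = delta_hamiltonian(st, params, [], (3, 4), (4, 4))
        assert dh == pytest.approx(2 * 2.0)

    def test_uniform_field_zero_chemotaxis(self):
        st, _ = make_state(8, 8, [(BASAL, 0, 8, 0, 4), (WING, 0, 8, 4, 8)])
        params = uniform_params(mu=50.0)
        fld = ScalarField(name="EGF", conc=np.full((8, 8), 0.7),
                          clamp_type=None)
        base = delta_hamiltonian(st, params, [], (3, 4), (4, 4))
        with_field = delta_hamiltonian(st, params, [fld], (3, 4), (4, 4))
        assert with_field == pytest.approx(base)

    def test_chemotaxis_term_is_minus_mu_delta_c(self):
        st, _ = make_state(8, 8, [(BASAL, 0, 8, 0, 4), (WING, 0, 8, 4, 8)])
        params = uniform_params(mu=50.0)
        conc = np.tile(np.linspace(0, 1, 8), (8, 1))
        fld = ScalarField(name="EGF", conc=conc, clamp_type=None)
        base = delta_hamiltonian(st, params, [], (3, 4), (4, 4))
        dh = delta_hamiltonian(st, params, [fld], (3, 4), (4, 4))
        assert dh - base == pytest.approx(-50.0 * (conc[4, 4] - conc[4, 3]))

    def test_incremental_matches_brute_force_on_random_states(self):
        """1000 random copy attempts on random 8x8 two-cell configurations:
        ΔH must equal H(after) − H(before) from global summation to 1e-9."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            st, (a, b) = random_two_cell_state(rng)
            params = uniform_params(J=float(rng.uniform(1, 10)),
                                    lam_v=float(rng.uniform(0, 3)),
                                    lam_s=float(rng.uniform(0, 2)))
            params.J += rng.uniform(0, 2, params.J.shape)
            params.J = (params.J + params.J.T) / 2
            for _ in range(20):
                y = int(rng.integers(0, 8))
                x = int(rng.integers(0, 8))
                k = int(rng.integers(0, 8))
                dx, dy = ([1, -1, 0, 0, 1, 1, -1, -1][k],
                          [0, 0, 1, -1, 1, -1, 1, -1][k])
                sx, sy = x + dx, y + dy
                if not (0 <= sx < 8 and 0 <= sy < 8):
                    continue
                if st.owner_grid[sy, sx] == st.owner_grid[y, x]:
                    continue
                before = brute_force_energy(st, params)
                dh = delta_hamiltonian(st, params, [], (sx, sy), (x, y))
                _apply_copy(st, (sx, sy), (x, y))
                after = brute_force_energy(st, params)
                assert dh == pytest.approx(after - before, abs=1e-9)
                checked += 1

    def test_link_spring_energy_matches_brute_force(self):
        st, (a, b) = make_state(8, 8, [(BASAL, 0, 8, 0, 3), (WING, 0, 8, 3, 8)])
        params = uniform_params()
        params.links.append(LinkSpring(a, b, rest_length=2.0, stiffness=1.5))
        before = brute_force_energy(st, params)
        dh = delta_hamiltonian(st, params, [], (2, 3), (3, 3))
        _apply_copy(st, (2, 3), (3, 3))
        after = brute_force_energy(st, params)
        assert dh == pytest.approx(after - before, abs=1e-9)

    def test_contract_violations_raise(self):
        st, _ = make_state(8, 8, [(BASAL, 0, 8, 0, 4), (WING, 0, 8, 4, 8)])
        params = uniform_params()
        with pytest.raises(ValueError):
            delta_hamiltonian(st, params, [], (0, 0), (1, 0))  # same owner
        with pytest.raises(ValueError):
            delta_hamiltonian(st, params, [], (7, 7), (8, 7))  # out of bounds
        with pytest.raises(ValueError):
            delta_hamiltonian(st, params, [], (1, 1), (3, 3))  # not adjacent
        st2, _ = make_state(8, 8, [(WALL, 0, 8, 0, 4), (WING, 0, 8, 4, 8)])
        with pytest.raises(ValueError):
            delta_hamiltonian(st2, params, [], (3, 4), (4, 4))  # frozen


class TestMetropolis:
    def test_acceptance_statistics_match_boltzmann(self):
        """Logged accept decisions at fixed ΔH > 0 match exp(−ΔH/T) within
        a 99% binomial confidence interval over 2·10⁵ attempts."""
        seed_kernel(123)
        n = 200_000
        dh, T = 3.0, 2.0
        p = np.exp(-dh / T)
        acc = _kernels.accept_decisions(dh, T, n)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(acc / n - p) < 2.576 * se * 1.5
        # ΔH ≤ 0 always accepted
        assert _kernels.accept_decisions(-0.5, T, 1000) == 1000

    def test_zero_temperature_limit_rejects_uphill(self):
        """At T → 0⁺ on an energy-minimal configuration no energy-raising
        flip is accepted, so the flat two-cell interface stays flat."""
        st, _ = make_state(12, 12, [(BASAL, 0, 12, 0, 6), (WING, 0, 12, 6, 12)])
        params = uniform_params(J=5.0, lam_v=2.0, T=1e-9)
        seed_kernel(5)
        before = brute_force_energy(st, params)
        metropolis_mcs(st, params)
        after = brute_force_energy(st, params)
        assert after <= before + 1e-12

    def test_fixed_seed_bit_identical_grids(self):
        """Same seed, same config → bit-identical owner grids after 100 MCS."""
        grids = []
        for _ in range(2):
            st, _ = make_state(16, 16, [(BASAL, 0, 16, 0, 8),
                                        (WING, 0, 16, 8, 16)])
            params = uniform_params(J=4.0, T=8.0)
            seed_kernel(77)
            for _ in range(100):
                metropolis_mcs(st, params)
            grids.append(st.owner_grid.copy())
        assert np.array_equal(grids[0], grids[1])

    def test_bookkeeping_matches_rescan_after_sweeps(self):
        st, ids = make_state(16, 16, [(BASAL, 0, 16, 0, 8),
                                      (WING, 0, 16, 8, 16)])
        params = uniform_params(J=4.0, T=12.0)
        seed_kernel(9)
        for _ in range(50):
            metropolis_mcs(st, params)
        t = st.table
        vol = t.volume[:t.next_id].copy()
        surf = t.surface[:t.next_id].copy()
        sx = t.sum_x[:t.next_id].copy()
        st.refresh_stats()
        assert np.array_equal(vol, t.volume[:t.next_id])
        assert np.array_equal(surf, t.surface[:t.next_id])
        assert np.array_equal(sx, t.sum_x[:t.next_id])
        st.check_invariants()

    def test_frozen_types_never_move(self):
        st, ids = make_state(16, 16, [
            (WALL, 0, 16, 0, 16), (BASAL, 4, 12, 4, 8), (WING, 4, 12, 8, 12)])
        wall = ids[0]
        params = uniform_params(J=4.0, T=20.0)
        seed_kernel(3)
        wall_pixels = (st.owner_grid == wall).copy()
        for _ in range(30):
            metropolis_mcs(st, params)
        assert np.array_equal(st.owner_grid == wall, wall_pixels)


class TestPressure:
    def test_pressure_examples(self):
        st, (a,) = make_state(8, 8, [(BASAL, 0, 8, 0, 8)])
        params = uniform_params(lam_v=2.0)
        cell = st.cell(a)
        cell.target_volume = float(cell.volume)
        assert compute_pressure(cell, params) == 0.0
        st.table.volume[a] = 25
        cell.target_volume = 30.0
        assert compute_pressure(cell, params) == pytest.approx(10.0)
        # overshoot clamps to zero: bigger-than-target cells are not crowded
        st.table.volume[a] = 40
        assert compute_pressure(cell, params) == 0.0
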