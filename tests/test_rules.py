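"""Rule engine: Hill-function growth, volume-triggered mitosis, contact
differentiation and probabilistic sloughing, with closed-form and
statistical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from corneasim.fields import ScalarField
from corneasim.rules import (
    ContactData,
    RuleParams,
    apply_growth,
    attempt_mitosis,
    differentiate,
    growth_density,
    growth_egf,
    mitosis_sweep,
    slough,
)
from corneasim.types import (
    BASAL, LIMB, MEMB, STEM, STROMA, SUPER, TEAR, WING,
)

from conftest import make_state, uniform_params


class TestHillFunctions:
    @pytest.mark.parametrize("fn,x,km,expect", [
        (growth_egf, 0.0, 0.5, 0.0),
        (growth_egf, 0.5, 0.5, 0.5),       # half saturation
        (growth_egf, 1e9, 0.5, 1.0),       # saturation limit
        (growth_density, 0.0, 8.0, 1.0),
        (growth_density, 8.0, 8.0, 0.5),   # half inhibition
        (growth_density, 1e9, 8.0, 0.0),
    ])
    def test_limits_and_half_saturation(self, fn, x, km, expect):
        assert fn(x, km) == pytest.approx(expect, abs=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            growth_egf(-0.1, 0.5)
        with pytest.raises(ValueError):
            growth_density(-0.1, 8.0)

    @given(e1=st_h.floats(0, 10), e2=st_h.floats(0, 10),
           p1=st_h.floats(0, 100), p2=st_h.floats(0, 100))
    @settings(deadline=None, max_examples=200)
    def test_bounds_and_monotonicity(self, e1, e2, p1, p2):
        """G ∈ [0,1]; EGF activation is monotone increasing, density
        inhibition monotone decreasing, hence G_total ∈ [0, δ]."""
        ge1, ge2 = growth_egf(e1, 0.3), growth_egf(e2, 0.3)
        gd1, gd2 = growth_density(p1, 8.0), growth_density(p2, 8.0)
        for g in (ge1, ge2, gd1, gd2):
            assert 0.0 <= g <= 1.0
        if e1 <= e2:
            assert ge1 <= ge2 + 1e-12
        if p1 <= p2:
            assert gd1 >= gd2 - 1e-12
        delta = 25.0 / 80.0
        assert 0.0 <= delta * ge1 * gd1 <= delta


def _growth_setup(conc):
    st, ids = make_state(20, 12, [
        (MEMB, 0, 1, 0, 20), (BASAL, 1, 6, 0, 10), (WING, 1, 6, 10, 20),
        (TEAR, 6, 10, 0, 20)])
    fld = ScalarField.zeros(st, clamp_type=None, dirichlet_top_bottom=False)
    fld.conc[:] = conc
    from corneasim.fields import update_cell_averages
    update_cell_averages(fld, st)
    return st, ids, fld


class TestGrowth:
    def test_saturating_egf_gives_max_rate_and_8h_doubling(self):
        """With saturating EGF and zero pressure the growth rate is the
        intrinsic maximum δ = 25 px / 80 MCS, i.e. an 8-hour doubling of a
        25-pixel cell."""
        st, ids, fld = _growth_setup(1e6)
        rules = RuleParams()
        params = uniform_params()
        basal = ids[1]
        tv0 = st.table.target_volume[basal]
        apply_growth(st, fld, rules, params)
        gained = st.table.target_volume[basal] - tv0
        assert gained == pytest.approx(25.0 / 80.0)
        assert 25.0 / gained == pytest.approx(80.0)  # MCS to add one volume

    def test_wing_cells_do_not_grow(self):
        st, ids, fld = _growth_setup(1e6)
        wing = ids[2]
        tv0 = st.table.target_volume[wing]
        apply_growth(st, fld, RuleParams(), uniform_params())
        assert st.table.target_volume[wing] == tv0

    def test_zero_egf_means_zero_growth(self):
        st, ids, fld = _growth_setup(0.0)
        tv0 = st.table.target_volume.copy()
        apply_growth(st, fld, RuleParams(), uniform_params())
        assert np.array_equal(tv0, st.table.target_volume)


class TestMitosis:
    def _dividable(self, ctype=BASAL, w=10, h=5):
        st, ids = make_state(16, 10, [(TEAR, 0, 10, 0, 16),
                                      (ctype, 2, 2 + h, 2, 2 + w)])
        return st, ids[1]

    def test_volume_50_splits_into_equal_daughters(self):
        st, cid = self._dividable(w=10, h=5)     # exactly 50 px
        rng = np.random.default_rng(0)
        out = attempt_mitosis(st, cid, rng)
        assert out is not None
        da, db = out
        va, vb = st.table.volume[da], st.table.volume[db]
        assert va + vb == 50
        assert abs(va - vb) <= 1
        assert st.table.ctype[da] == st.table.ctype[db] == BASAL
        assert not st.table.alive[cid]

    def test_below_threshold_is_noop(self):
        st, cid = self._dividable(w=7, h=7)      # 49 px
        assert attempt_mitosis(st, cid, np.random.default_rng(0)) is None
        assert st.table.alive[cid]

    def test_stem_daughters_separate_along_x(self):
        st, ids = make_state(16, 10, [(TEAR, 0, 10, 0, 16),
                                      (STEM, 2, 7, 2, 12)])
        out = attempt_mitosis(st, ids[1], np.random.default_rng(1))
        da, db = out
        ax = st.table.sum_x[da] / st.table.volume[da]
        bx = st.table.sum_x[db] / st.table.volume[db]
        ay = st.table.sum_y[da] / st.table.volume[da]
        by = st.table.sum_y[db] / st.table.volume[db]
        assert abs(ax - bx) > 2.0          # centripetal split: x separation
        assert abs(ay - by) < 0.5          # no vertical separation

    def test_volume_conserved_over_1000_random_divisions(self):
        """|V_a + V_b − V_parent| ≤ 1 over randomized shapes and random
        cleavage planes; daughters are always within one pixel of half."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            w = int(rng.integers(5, 14))
            h = max(4, int(np.ceil(50 / w)))
            st, ids = make_state(20, 20, [(TEAR, 0, 20, 0, 20),
                                          (BASAL, 2, 2 + h, 2, 2 + w)])
            cid = ids[1]
            # roughen the shape a bit without dropping below threshold
            vp = int(st.table.volume[cid])
            out = attempt_mitosis(st, cid, rng)
            assert out is not None
            da, db = out
            va, vb = int(st.table.volume[da]), int(st.table.volume[db])
            assert va + vb == vp
            assert abs(va - vb) <= 1


class TestDifferentiation:
    def test_stem_with_limbal_contact_stays_stem(self):
        st, ids = make_state(16, 8, [
            (LIMB, 0, 1, 0, 16), (STEM, 1, 4, 0, 8), (TEAR, 1, 8, 8, 16)])
        differentiate(st, RuleParams())
        assert st.table.ctype[ids[1]] == STEM

    def test_stem_without_limbal_contact_becomes_basal(self):
        st, ids = make_state(16, 8, [
            (MEMB, 0, 1, 0, 16), (STEM, 1, 4, 0, 8), (TEAR, 1, 8, 8, 16)])
        differentiate(st, RuleParams())
        assert st.table.ctype[ids[1]] == BASAL

    @pytest.mark.parametrize("footprint,expect", [(6, BASAL), (5, WING)])
    def test_basal_contact_threshold_is_five_pixels(self, footprint, expect):
        # the membrane-contact area A equals the bottom-row footprint
        st, ids = make_state(20, 10, [
            (TEAR, 0, 10, 0, 20), (MEMB, 0, 1, 0, 20),
            (BASAL, 1, 1 + int(np.ceil(25 / footprint)), 2, 2 + footprint)])
        differentiate(st, RuleParams())
        assert st.table.ctype[ids[2]] == expect

    def test_wing_to_superficial_requires_tear_and_wing_only(self):
        # wing touching tear + wing, and no basal/membrane/stem neighbors
        st, ids = make_state(20, 10, [
            (TEAR, 0, 10, 0, 20), (BASAL, 0, 2, 0, 20),
            (WING, 2, 5, 0, 10), (WING, 2, 5, 10, 20), (WING, 5, 8, 4, 16)])
        top_wing = ids[4]
        differentiate(st, RuleParams())
        assert st.table.ctype[top_wing] == SUPER
        # the low wings touch basal cells and stay wings
        assert st.table.ctype[ids[2]] == WING
        assert st.table.ctype[ids[3]] == WING

    def test_transitions_applied_from_one_snapshot(self):
        """A basal that qualifies for wing conversion does not convert to
        superficial in the same MCS even if its neighbors would then allow
        it — the relation is snapshotted before any transition."""
        st, ids = make_state(20, 10, [
            (TEAR, 0, 10, 0, 20), (MEMB, 0, 1, 0, 20),
            (BASAL, 1, 9, 2, 5), (WING, 1, 9, 5, 8)])
        # basal footprint 3 <= 5 -> becomes WING, not SUPER, this MCS
        differentiate(st, RuleParams())
        assert st.table.ctype[ids[2]] == WING


class TestSlough:
    def test_probability_constant(self):
        assert RuleParams().slough_prob_per_mcs == pytest.approx(1.0 / 720)

    def test_no_tear_contact_never_sloughs(self):
        st, ids = make_state(16, 8, [
            (STROMA, 0, 8, 0, 16), (SUPER, 2, 5, 2, 10)])
        rng = np.random.default_rng(0)
        tear = st.table.new_cell(TEAR)
        st.table.alive[tear] = True
        for _ in range(200):
            gone = slough(st, RuleParams(), rng, tear)
            assert gone == []
        assert st.table.alive[ids[1]]

    def test_lifetime_is_geometric_with_mean_720(self):
        """Exposure-based estimate of the sloughing hazard over >2000 events
        matches the geometric mean lifetime of 720 MCS (3 days) within 5%."""
        W = H = 250
        st = LatticeStateFactory(W, H)
        rules = RuleParams()
        rng = np.random.default_rng(12345)
        tear = st[1]
        state = st[0]
        events = 0
        exposure = 0
        for _ in range(700):
            n_before = int(np.count_nonzero(
                state.table.alive[: state.table.next_id]
                & (state.table.ctype[: state.table.next_id] == SUPER)))
            if n_before == 0:
                break
            gone = slough(state, rules, rng, tear)
            exposure += n_before
            events += len(gone)
        assert events >= 2000
        mean_lifetime = exposure / events
        assert mean_lifetime == pytest.approx(720.0, rel=0.05)


def LatticeStateFactory(W, H):
    """Many isolated superficial cells, each bordered by tear film."""
    from corneasim.potts import LatticeState
    state = LatticeState(W, H)
    tear = state.table.new_cell(TEAR)
    state.owner_grid[:] = tear
    for y in range(1, H - 1, 2):
        for x in range(1, W - 1, 4):
            cid = state.table.new_cell(SUPER)
            state.owner_grid[y, x:x + 3] = cid
    state.refresh_stats()
    return state, tear


class TestTypeGraph:
    def test_transition_graph_is_forward_only(self, homeo_runs):
        """Across entire homeostasis runs, no cell ever moves backward in
        the STEM→BASAL→WING→SUPER sequence (checked from the event log)."""
        order = {STEM: 0, BASAL: 1, WING: 2, SUPER: 3}
        for res in homeo_runs[:1]:
            last = {}
            for mcs, kind, ev in res.events:
                if kind != "diff":
                    continue
                cid, old, new = ev
                assert order[new] == order[old] + 1
                if cid in last:
                    assert order[old] >= last[cid]
                last[cid] = order[new]
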